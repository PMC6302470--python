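# crcscreen

Loss-of-function variant screening and multi-omics tumor-suppressor
prioritization for sporadic colorectal cancer (sCRC), with the statistics
and RNA-seq stages that accompany such a screen.

## What problem this addresses

Finding a new tumor suppressor in a sporadic cancer starts from tumor/normal
exome calls and ends, many filters later, with one candidate gene whose loss
is plausibly causal. `crcscreen` implements that analysis chain as a tested,
reusable desk-scale pipeline:

1. **LoF screen** (`variant_screen`) — classify variant consequences
   (nonsense, frameshift, canonical splice, missense, synonymous) against
   transcript CDS models, and apply the four screening criteria: known
   variants (dbSNP/1000G-style blacklist) removed; tumor variant quality
   ≥ 100; read depth in [10, 200]; variants in the last 5% of the gene
   coding region removed. Somatic status is called against the matched
   normal sample.
2. **Candidate prioritization** (`gene_prioritization`) — four evidence
   criteria over the mutated-gene universe: target-tissue expression ranked
   top 7 of 37 normal tissues (with tumor-downregulation direction),
   differential expression in ≥ 2 independent adenoma/polyp series,
   best-separation Kaplan–Meier survival screen (log-rank p over the
   20–80% expression-quantile grid), and pathway membership. Candidates
   are ranked by satisfied-criterion count.
3. **Statistics kernel** (`assoc_stats`) — 2×2 chi-square (Yates) and
   Fisher exact tests, paired t / Wilcoxon signed-rank, Pearson
   correlation, fold-change correlation, Kaplan–Meier/log-rank,
   Benjamini–Hochberg FDR, and the xenograft volume formula
   V = 0.5·a·b².
4. **RNA-seq stage** (`rnaseq_de`) — median-of-ratios size factors, a
   negative-binomial likelihood-ratio differential-expression test with
   the fold-change rule (> 1.5 or < 0.667), Fisher-exact gene-set
   enrichment with BH FDR, and Pearson coexpression networks with
   hub-gene (maximum-degree) identification.
5. **Synthetic data** (`synthetic_data`) — seeded generators for every
   input (paired VCFs with engineered filter fates, tissue panels, DE
   series, survival cohorts, gene sets, NB count matrices, coexpression
   hubs) with complete ground-truth tables, so every stage is testable
   end-to-end without downloads.

File formats (VCF, BED12/GFF3, TSV matrices, GMT) are handled in
`io_formats` on pysam / gffutils / pandas.

## Worked example

The bundled case-series tables reproduce the screen's headline numbers:

```python
from crcscreen.datasets import BMP5_MUTATIONS, BMP5_COHORT_SIZE, IHC_BREAST
from crcscreen.variant_screen import parse_protein_change, summarize_cohort
from crcscreen.assoc_stats import chisq_2x2

muts = [(s, parse_protein_change(n).kind) for s, n in BMP5_MUTATIONS]
summary = summarize_cohort(muts, BMP5_COHORT_SIZE)
print(f"mutation frequency: {100 * summary.mutation_frequency:.1f}%")
print(f"truncating fraction: {100 * summary.truncating_fraction:.1f}%")
res = chisq_2x2(IHC_BREAST)
print(f"breast IHC: chi2 = {res.statistic:.2f}, p = {res.p_value:.4f}")
```

prints

```
mutation frequency: 7.7%
truncating fraction: 37.5%
breast IHC: chi2 = 12.82, p = 0.0003
```

— 8 of 104 patients carry a BMP5 mutation (7.7%), 3 of the 8 mutations
truncate the protein (37.5%), and the breast tissue-microarray
contingency test gives the Yates-corrected p of 0.0003.

The same works from the shell on synthetic fixtures:

```bash
crcscreen synth --seed 1 --out fx/
crcscreen screen --tumor-vcf fx/variants/S001-T.vcf \
    --normal-vcf fx/variants/S001-N.vcf \
    --models fx/variants/models.bed --blacklist fx/variants/blacklist.tsv \
    --sample-id S001 --out decisions.tsv
# -> 5/11 variants retained
```

`decisions.tsv` holds one row per somatic variant with a pass/fail column
per criterion and the final retained flag.

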