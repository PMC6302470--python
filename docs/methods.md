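# Methods

This note records the models, conventions and design choices behind
`crcscreen`, in the order the pipeline runs.

## Coordinates, variant identity, formats

All genomic coordinates in memory are 1-based inclusive (VCF/GFF3 native);
BED12 inputs are converted at the boundary (`start+1 .. end`). Variant
identity everywhere is the exact tuple `(chrom, pos, ref, alt)` with
uppercase alleles and no normalization — deterministic, documented
matching for blacklist membership and tumor/normal subtraction.
Multi-allelic VCF lines are split into one record per ALT, since every
filter decision is per-allele. Read depth is taken from the sample FORMAT
`DP` when present, else INFO `DP`, else treated as missing (and a missing
depth fails the depth criterion downstream, because it is the tumor-sample
depth that the screen constrains).

## The loss-of-function screen

Four criteria are evaluated independently for every variant, and every
violated criterion is recorded (not only the first):

| criterion | rule | default |
|---|---|---|
| `known_variant` | blacklist membership | — |
| `quality` | variant quality ≥ threshold | 100 (quality exactly 100 passes) |
| `depth` | closed interval | [10, 200] (both endpoints pass) |
| `cds_tail` | CDS fraction strictly greater than 1 − tail removed | tail = 0.05 |

Conventions fixed where natural language is ambiguous: "between 10 and
200" is read as the closed interval; "last 5% of the coding region" uses a
strict inequality, so a variant exactly at the 95th-percentile coding base
is kept. Both are configurable. When several transcript models overlap a
variant, the longest CDS is used (deterministic); a variant covered by no
model fails the positional criterion, since its coding-region position
cannot be certified. Frameshift and splice variants are positionally
filtered like any other variant but are exempt from codon translation.

Consequence classification translates the affected codon under the
standard genetic code (substitutions), calls indels with net length change
not divisible by 3 frameshifts (in-frame indels → `other`), and calls
non-coding positions within 2 bases of a CDS-segment boundary canonical
splice variants. The classifier is verified against an independent oracle
that mutates the whole CDS, translates both proteins completely and
compares them, for every substitution of a 300-bp two-exon test CDS on
both strands.

The truncating class is {nonsense, frameshift}; canonical splice counts as
LoF but not truncating (this is what makes 3 stop-gains of 8 mutations a
37.5% truncating fraction in the bundled case series). Somatic status is
exact-key subtraction of the matched normal's calls — the desk-scale
equivalent of confirmation resequencing against blood.

## Prioritization

Four boolean criteria per gene, score = count satisfied, rank by
descending score with lexicographic gene-id tie-break (fully
deterministic):

* **tissue**: the best target tissue (max over colon/rectum) ranks ≤ 7
  among all 37 tissues, ties taking the best rank; being rank-based the
  call is invariant under monotone transforms of a gene's expression.
  Under the tumor-suppressor direction policy the gene must additionally
  be consistently *down* in tumors; a discordant cross-series direction
  blocks this combined criterion but still counts for the DEG tally.
* **early DEG**: significant in ≥ 2 independent series.
* **survival**: best-separation screen over the 20–80% expression
  quantiles in 5% steps; the raw minimum log-rank p is reported together
  with the number of cutoffs actually tested, and no multiplicity
  correction is applied (the convention of the public-atlas
  "best separation" survival annotation this emulates). Users can correct
  using the reported grid size; the null simulations in the test suite
  show the expected anti-conservative behaviour. Direction compares
  restricted mean survival between arms at the best cutoff.
* **pathway**: membership in ≥ 1 curated gene set.

## Statistics kernel

* 2×2 chi-square applies the Yates continuity correction by default; on
  the bundled breast tissue-microarray counts the corrected test gives
  p = 0.00034 (printed 0.0003) where the uncorrected gives 0.00013, which
  pins the convention.
* Fisher exact is two-sided by the "sum of all tables with the observed
  margins whose probability does not exceed the observed" convention, and
  is verified exhaustively against full enumeration for every table with
  grand total ≤ 30.
* Wilcoxon signed-rank is exact for ≤ 25 non-zero differences, else
  normal-approximate with continuity correction.
* The two-group log-rank uses the O−E statistic with the hypergeometric
  variance at each distinct event time (standard tie handling); the
  array-level kernel is cross-checked against an independent survival
  library implementation in the tests, and KM curves themselves are
  produced by that library. Three or more groups use the multivariate
  extension.
* BH FDR is the standard step-up adjustment capped at 1.

## RNA-seq differential expression

Normalization is median-of-ratios: `factor_j = median_g(count_gj /
geomean_g)` over genes positive in every sample. The test per gene is a
negative-binomial likelihood-ratio test: twice the log-likelihood gain of
separate condition means over a common mean, against chi-square(1), at a
fixed per-gene dispersion. Dispersion is estimated by per-condition
method-of-moments pooled per gene, then shrunk in log space toward a
fitted mean–dispersion trend `alpha(mu) = a0 + a1/mu` with gene weight
`max(df − 4, 0)/(df + 16)` — at three-vs-three (residual df 4) the
per-gene moment estimate is essentially noise, so the trend is used
outright, which is what keeps the raw p-values calibrated at small n (the
acceptance suite verifies a null type-I rate of 0.05 ± 0.02). This is a
compact test in the DESeq tradition, not a re-implementation of any
specific release.

A gene is called DE when its BH-adjusted p is below alpha (default 0.05)
**and** its fold change is strictly > 1.5 or strictly < 0.667; the
fold-change bounds are strict, so a gene at exactly 1.5-fold is not
called. A 0.5 pseudocount enters the reported fold change only when a
condition mean is zero, and is flagged. Enrichment builds one 2×2 per
gene set (in-set vs not × DE vs not over the declared universe), uses the
shared Fisher kernel, and BH-adjusts across sets.

Coexpression networks keep an edge when |r| ≥ 0.8 and the BH-adjusted
correlation p ≤ 0.05 (both configurable; whether to adjust is a flag,
since published network conventions differ). Constant genes are excluded
with a warning. The "core" gene is operationalized as the maximum-degree
node with lexicographic tie-break — the simplest defensible reading of a
hub; betweenness or other centralities can be computed from the returned
graph.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *study design*, not the biology: a
104-sample cohort with mutation prevalence 8/104 in one spiked gene
(nonsense/frameshift/splice cycled across carriers, so 8 carriers yield a
6/8 truncating fraction by construction); a 37-tissue panel with the
spiked gene and four co-candidate "extras" engineered into the top 7, one
boundary decoy at rank exactly 8, and 11 undetected genes; three DE
series with the spiked gene down in 2; exponential survival with
protective high expression (hazard ratio 0.5 by default for the
single-gene generator; 0.35 for the engineered all-criteria spike in the
prioritization suite, strong enough that recovery is deterministic at the
tested cohort size of 200 patients with ~30% censoring); four pathway
sets covering 19 genes. Count matrices are NB with log-normal means
(median ≈ 200), dispersion 0.1, three samples per condition, and 100
genes spiked at fold change 4 among 900 nulls; the coexpression fixture
is one driver, eight followers (driver + N(0, 0.3²) noise) and 40
independent decoys over 20 samples.

Engineering guarantees that matter for the tests: spiked LoF variants are
placed outside the last 5% of the CDS so the positional filter cannot
silently remove truth; decoy variants draw their CDS positions from
disjoint ranges per intent class so a blacklisted key can never collide
with a passing variant in another sample; the "extras" are excluded from
pathway sets and given null survival so the spiked gene is the unique
all-criteria candidate. A single master seed derives fixed per-stage
substreams, so stages regenerate independently and fixed seeds give
byte-identical files.

What the generator does **not** model: mutational signatures and
context-dependent error rates, linkage and population structure, batch
effects, realistic censoring mechanisms, or correlated gene-gene
expression beyond the one engineered hub. Passing the recovery tests
therefore demonstrates that the pipeline's logic is correct and
calibrated under its stated model, not that it is robust to artefacts of
real cohorts.

## Numerical choices and degenerate inputs

Ties break lexicographically everywhere (tissue ranks take the best rank;
candidate ranking and hub selection take the smallest gene id).
Zero-variance inputs raise `DegenerateDataError` rather than returning
NaN (paired t on constant differences, correlation of constant vectors,
survival screens on constant expression, networks of constant genes —
the last is a per-gene exclusion with a warning). Fold-change pairs with
non-positive expression are dropped with a warning, and fewer than three
usable pairs is an error. All-zero genes get p = 1 and are never DE.
Problem sizes in the test and acceptance suites (20 seeds for recovery
and calibration, 1000-gene count matrices, 200-patient survival cohorts,
Fisher tables to total 30) are chosen so each stage's check completes in
seconds to about a minute on one CPU.

## Known limitations

Copy-number/structural variants, mutational signatures and pathogenicity
prediction are out of scope (the screen consumes small-variant VCFs).
The DE test assumes a shared mean–dispersion trend and will be
mis-calibrated for genes whose dispersion departs wildly from it at tiny
replicate numbers. The best-separation survival screen intentionally
reports an uncorrected minimum p, and inherits that convention's
optimism. The per-ALT splitting and exact-key matching mean left-aligned
and non-normalized representations of the same indel are treated as
different variants; inputs should be normalized upstream if that matters.
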