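"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the study's inputs at desk scale: a 104-sample
tumor/normal variant cohort with loss-of-function spike-ins in one gene, a
37-tissue normal expression panel, three adenoma/polyp differential-
expression series, per-gene survival cohorts, pathway gene sets, and
negative-binomial RNA-seq count matrices with spiked fold changes and an
engineered coexpression hub.

Every stage draws from its own substream derived from a single master seed
(fixed offsets), so stages regenerate independently and a fixed seed yields
byte-identical output files.  Truth tables record each emitted variant's or
gene's intended fate, computed from the construction itself — never by
running the pipeline under test.

Spiked loss-of-function variants are deliberately placed outside the last
5% of the synthetic CDS so the positional tail filter can never silently
remove planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc_stats import SurvivalRecord
from .errors import DomainError
from .io_formats import (
    GeneSetCollection,
    LabeledMatrix,
    TranscriptModel,
    VariantRecord,
    write_blacklist,
    write_gmt,
    write_matrix,
    write_vcf,
)

__all__ = [
    "SpikeConfig",
    "VariantCohort",
    "gen_variant_cohort",
    "gen_tissue_matrix",
    "gen_deg_series",
    "gen_survival",
    "gen_gene_sets",
    "gen_counts",
    "gen_coexpression_matrix",
    "gen_prioritization_suite",
    "nb_draws",
]

# substream offsets per stage (master seed -> independent streams)
_STREAM = {
    "variants": 101,
    "tissue": 202,
    "deg": 303,
    "survival": 404,
    "counts": 505,
    "coexpr": 606,
    "pathway": 707,
}

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SpikeConfig:
    """All knobs of the synthetic study, with defaults set to the cohort
    sizes and effect sizes the screened study design calls for."""

    seed: int = 1

    # --- variant cohort (exome screen emulation) ---
    n_samples: int = 104
    mutation_prevalence: float = 8 / 104
    spiked_gene: str = "GENE_S"
    spike_types: tuple[str, ...] = ("nonsense", "frameshift", "canonical_splice")
    n_variant_decoy_genes: int = 6
    decoys_per_sample: int = 3

    # --- prioritization universe ---
    n_decoy_genes: int = 70          # gene universe = spiked + decoys = 71
    n_tissues: int = 37
    top_k: int = 7
    n_enriched_extra: int = 4        # co-candidates: enriched + down, nothing else
    n_undetected: int = 11
    deg_series: tuple[str, ...] = ("series_1", "series_2", "series_3")
    deg_spiked_n_series: int = 2
    n_pathway_genes: int = 19

    # --- survival ---
    survival_n_patients: int = 200
    survival_hazard_ratio: float = 0.5
    prioritization_hazard_ratio: float = 0.35   # engineered all-criteria spike
    censoring_rate: float = 0.3
    baseline_hazard: float = 0.1

    # --- RNA-seq counts ---
    de_n_genes: int = 1000
    de_n_spiked: int = 100
    de_fold_change: float = 4.0
    de_dispersion: float = 0.1
    de_n_per_group: int = 3

    # --- coexpression hub ---
    hub_module_size: int = 8
    hub_n_decoys: int = 40
    hub_noise_sd: float = 0.3
    coexpr_n_samples: int = 20

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2**31), _STREAM[stage]])


# ---------------------------------------------------------------------------
# helpers


def nb_draws(rng: np.random.Generator, mu: float, dispersion: float, size) -> np.ndarray:
    """Negative-binomial draws parameterized by mean and dispersion alpha
    (variance = mu + alpha*mu^2); alpha = 0 degenerates to Poisson."""
    if dispersion <= 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p, size=size)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
    return "".join(_NONSTOP_CODONS[i] for i in idx)


def _cds_to_genomic(model: TranscriptModel, cds_pos: int) -> int:
    """Inverse of the CDS coordinate mapping (1-based both ways)."""
    plus_pos = cds_pos if model.strand == "+" else model.cds_length + 1 - cds_pos
    offset = 0
    for start, end in model.cds_segments:
        seg_len = end - start + 1
        if plus_pos <= offset + seg_len:
            return start + (plus_pos - offset - 1)
        offset += seg_len
    raise DomainError(f"cds position {cds_pos} outside model {model.transcript_id}")


def _genomic_base(model: TranscriptModel, cds_seq: str, cds_pos: int) -> str:
    """Genomic-strand reference base at a CDS position."""
    base = cds_seq[cds_pos - 1]
    return base if model.strand == "+" else base.translate(_COMPLEMENT)


# ---------------------------------------------------------------------------
# variant cohort


@dataclass
class VariantCohort:
    """In-memory paired tumor/normal variant cohort plus its truth table."""

    config: SpikeConfig
    models: list[TranscriptModel]
    cds_sequences: dict[str, str]               # transcript_id -> CDS 5'->3'
    blacklist: set[tuple[str, int, str, str]]
    tumor: dict[str, list[VariantRecord]]       # sample -> records
    normal: dict[str, list[VariantRecord]]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample, records in self.tumor.items():
            write_vcf(records, outdir / f"{sample}-T.vcf", sample)
        for sample, records in self.normal.items():
            write_vcf(records, outdir / f"{sample}-N.vcf", sample)
        write_blacklist(self.blacklist, outdir / "blacklist.tsv")
        self.truth.to_csv(outdir / "variant_truth.tsv", sep="\t", index=False)
        with open(outdir / "models.bed", "w") as fh:
            for m in self.models:
                fh.write(_to_bed12(m) + "\n")
        with open(outdir / "cds.fasta", "w") as fh:
            for tx, seq in self.cds_sequences.items():
                fh.write(f">{tx}\n{seq}\n")


def _to_bed12(m: TranscriptModel) -> str:
    chrom_start = m.cds_segments[0][0] - 1
    chrom_end = m.cds_segments[-1][1]
    sizes = ",".join(str(e - s + 1) for s, e in m.cds_segments) + ","
    starts = ",".join(str(s - 1 - chrom_start) for s, _e in m.cds_segments) + ","
    name = f"{m.gene_id}|{m.transcript_id}"
    return "\t".join(
        str(x)
        for x in (
            m.chrom, chrom_start, chrom_end, name, 0, m.strand,
            chrom_start, chrom_end, "0", len(m.cds_segments), sizes, starts,
        )
    )


def _build_models(config: SpikeConfig, rng: np.random.Generator):
    """One spiked two-segment gene plus single-segment decoy genes, each
    with a 300-bp stop-free CDS; 'CAA' codons are planted in the spiked
    gene (inside the first 80% of the CDS) as nonsense-ready sites."""
    models, seqs = [], {}
    spiked = TranscriptModel(
        gene_id=config.spiked_gene, transcript_id=f"{config.spiked_gene}.t1",
        chrom="chrS", strand="+",
        cds_segments=((1001, 1150), (2001, 2150)),
    )
    n_codons = spiked.cds_length // 3
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
    codons = [_NONSTOP_CODONS[i] for i in idx]
    nonsense_slots = [9, 19, 29, 39, 49, 59, 69, 79]  # codon indices, < 80% of 100
    for slot in nonsense_slots:
        codons[slot] = "CAA"                           # C->T gives TAA (stop)
    seqs[spiked.transcript_id] = "".join(codons)
    models.append(spiked)
    for i in range(config.n_variant_decoy_genes):
        strand = "+" if i % 2 == 0 else "-"
        m = TranscriptModel(
            gene_id=f"DVG{i + 1:02d}", transcript_id=f"DVG{i + 1:02d}.t1",
            chrom=f"chrD{i + 1}", strand=strand,
            cds_segments=((1001, 1300),),
        )
        seqs[m.transcript_id] = _random_cds(rng, m.cds_length // 3)
        models.append(m)
    return models, seqs, nonsense_slots


def gen_variant_cohort(config: SpikeConfig | None = None) -> VariantCohort:
    """Generate the paired tumor/normal variant cohort with spike-ins.

    Per sample: shared germline variants (in both files, mostly
    blacklisted), somatic decoys engineered to violate each filter
    criterion in turn (including exact boundary values quality = 100,
    depth = 10 and 200, cds_fraction = 0.95), and — in the carrier
    samples — one spiked loss-of-function variant in the spiked gene.
    The truth table records every variant's intended failed-criteria set,
    retained fate, and consequence.
    """
    config = config or SpikeConfig()
    rng = config.rng("variants")
    models, seqs, nonsense_slots = _build_models(config, rng)
    spiked_model = models[0]
    decoy_models = models[1:]
    spiked_seq = seqs[spiked_model.transcript_id]

    n_carriers = int(round(config.mutation_prevalence * config.n_samples))
    if config.mutation_prevalence > 0 and n_carriers < 1:
        import warnings

        warnings.warn("prevalence * n_samples < 1: no spike realized")
    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    carriers = sorted(rng.choice(config.n_samples, size=n_carriers, replace=False))

    # cohort-wide common germline variants (3 of 5 blacklisted)
    blacklist: set = set()
    germline = []
    for j in range(5):
        m = decoy_models[j % len(decoy_models)]
        cds_pos = 50 + 10 * j
        gpos = _cds_to_genomic(m, cds_pos)
        ref = _genomic_base(m, seqs[m.transcript_id], cds_pos)
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        germline.append((m.chrom, gpos, ref, alt, j < 3))
        if j < 3:
            blacklist.add((m.chrom, gpos, ref, alt))

    # somatic decoy intents cycled per sample: label set each must fail
    intents = [
        frozenset(), frozenset({"quality"}), frozenset({"depth"}),
        frozenset({"known_variant"}), frozenset({"cds_tail"}),
        frozenset({"quality", "depth"}),
    ]
    # boundary variants (placed in sample 1, all criteria otherwise passing):
    # (quality, depth, cds_pos, expected failed set); positions sit in a
    # reserved CDS range no other variant class can draw from
    boundaries = [
        (100.0, 50, 2, frozenset()),
        (99.0, 50, 3, frozenset({"quality"})),
        (150.0, 10, 4, frozenset()),
        (150.0, 200, 5, frozenset()),
        (150.0, 9, 6, frozenset({"depth"})),
        (150.0, 201, 7, frozenset({"depth"})),
        (150.0, 50, 285, frozenset()),                 # fraction exactly 0.95
        (150.0, 50, 286, frozenset({"cds_tail"})),     # fraction > 0.95
    ]

    tumor: dict[str, list[VariantRecord]] = {}
    normal: dict[str, list[VariantRecord]] = {}
    truth_rows = []
    spike_cycle = 0

    def add_truth(sample, rec, in_normal, failed, consequence, spiked):
        truth_rows.append(
            {
                "sample_id": sample, "chrom": rec.chrom, "pos": rec.pos,
                "ref": rec.ref, "alt": rec.alt,
                "quality": rec.quality, "depth": rec.depth,
                "in_normal": in_normal, "is_known": rec.is_known,
                "expected_failed": ";".join(sorted(failed)),
                "expected_retained": not failed,
                "expected_consequence": consequence,
                "is_spiked": spiked,
            }
        )

    for si, sample in enumerate(samples):
        t_recs: list[VariantRecord] = []
        n_recs: list[VariantRecord] = []
        used: set = set()

        for chrom, gpos, ref, alt, known in germline:
            if rng.random() < 0.8:
                for bucket in (t_recs, n_recs):
                    bucket.append(
                        VariantRecord(
                            chrom=chrom, pos=gpos, ref=ref, alt=alt,
                            quality=150.0, depth=50, sample_id=sample,
                            is_known=known,
                        )
                    )
                used.add((chrom, gpos))
                add_truth(
                    sample, t_recs[-1], True,
                    frozenset({"known_variant"}) if known else frozenset(),
                    "", False,
                )

        for d in range(config.decoys_per_sample):
            intent = intents[(si * config.decoys_per_sample + d) % len(intents)]
            m = decoy_models[int(rng.integers(0, len(decoy_models)))]
            mseq = seqs[m.transcript_id]
            # disjoint CDS position ranges per class, so a key blacklisted
            # through one sample's known-intent decoy can never coincide
            # with another sample's passing variant (alt is deterministic
            # in ref, so identical positions imply identical keys):
            # boundaries 2-9, germline 50-90, plain decoys 96-219,
            # known-intent 220-284, tail-intent 287-300
            for _attempt in range(50):
                if "cds_tail" in intent:
                    cds_pos = int(rng.integers(287, 301))   # fraction > 0.95
                elif "known_variant" in intent:
                    cds_pos = int(rng.integers(220, 285))
                else:
                    cds_pos = int(rng.integers(96, 220))
                gpos = _cds_to_genomic(m, cds_pos)
                if (m.chrom, gpos) not in used:
                    break
            used.add((m.chrom, gpos))
            ref = _genomic_base(m, mseq, cds_pos)
            alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
            quality = float(rng.integers(30, 100)) if "quality" in intent else float(
                rng.integers(100, 251)
            )
            if "depth" in intent:
                depth = int(rng.integers(1, 10)) if rng.random() < 0.5 else int(
                    rng.integers(201, 400)
                )
            else:
                depth = int(rng.integers(10, 201))
            known = "known_variant" in intent
            rec = VariantRecord(
                chrom=m.chrom, pos=gpos, ref=ref, alt=alt,
                quality=quality, depth=depth, sample_id=sample, is_known=known,
            )
            if known:
                blacklist.add(rec.key)
            t_recs.append(rec)
            add_truth(sample, rec, False, intent, "", False)

        if si == 0:
            m = decoy_models[0]
            mseq = seqs[m.transcript_id]
            for quality, depth, cds_pos, failed in boundaries:
                gpos = _cds_to_genomic(m, cds_pos)
                if (m.chrom, gpos) in used:
                    continue
                used.add((m.chrom, gpos))
                ref = _genomic_base(m, mseq, cds_pos)
                alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
                known = "known_variant" in failed
                rec = VariantRecord(
                    chrom=m.chrom, pos=gpos, ref=ref, alt=alt,
                    quality=quality, depth=depth, sample_id=sample,
                    is_known=known,
                )
                t_recs.append(rec)
                add_truth(sample, rec, False, failed, "", False)

        if si in carriers:
            spike_type = config.spike_types[spike_cycle % len(config.spike_types)]
            spike_cycle += 1
            quality = float(rng.integers(110, 201))
            depth = int(rng.integers(30, 151))
            if spike_type == "nonsense":
                slot = nonsense_slots[spike_cycle % len(nonsense_slots)]
                cds_pos = 3 * slot + 1                  # the C of the CAA codon
                gpos = _cds_to_genomic(spiked_model, cds_pos)
                rec = VariantRecord(
                    chrom=spiked_model.chrom, pos=gpos, ref="C", alt="T",
                    quality=quality, depth=depth, sample_id=sample,
                )
            elif spike_type == "frameshift":
                cds_pos = int(rng.integers(95, 140))    # segment-1 interior
                gpos = _cds_to_genomic(spiked_model, cds_pos)
                ref = spiked_seq[cds_pos - 1 : cds_pos + 1]
                rec = VariantRecord(
                    chrom=spiked_model.chrom, pos=gpos, ref=ref, alt=ref[0],
                    quality=quality, depth=depth, sample_id=sample,
                )
            elif spike_type == "canonical_splice":
                gpos = spiked_model.cds_segments[0][1] + 1   # donor +1 intron base
                rec = VariantRecord(
                    chrom=spiked_model.chrom, pos=gpos, ref="G", alt="A",
                    quality=quality, depth=depth, sample_id=sample,
                )
            else:
                raise DomainError(f"unknown spike type {spike_type!r}")
            t_recs.append(rec)
            add_truth(sample, rec, False, frozenset(), spike_type, True)

        tumor[sample] = t_recs
        normal[sample] = n_recs

    truth = pd.DataFrame(truth_rows)
    return VariantCohort(
        config=config, models=models, cds_sequences=seqs,
        blacklist=blacklist, tumor=tumor, normal=normal, truth=truth,
    )


# ---------------------------------------------------------------------------
# prioritization-stage inputs


def _gene_universe(config: SpikeConfig) -> list[str]:
    extras = [f"E{i + 1:02d}" for i in range(config.n_enriched_extra)]
    n_plain = config.n_decoy_genes - config.n_enriched_extra
    decoys = [f"D{i + 1:03d}" for i in range(n_plain)]
    return [config.spiked_gene] + extras + decoys


def gen_tissue_matrix(config: SpikeConfig | None = None) -> tuple[LabeledMatrix, pd.DataFrame]:
    """Gene x tissue expression panel with engineered target-tissue ranks.

    The spiked gene and the 'extra' co-candidates rank 1..top_k in the
    target tissue (colon); one decoy sits at rank top_k + 1 exactly (the
    boundary); ``n_undetected`` decoys have zero colon and rectum
    expression; all remaining decoys rank strictly below top_k + 1.
    """
    config = config or SpikeConfig()
    rng = config.rng("tissue")
    genes = _gene_universe(config)
    tissues = ["colon", "rectum"] + [f"tissue_{i + 1:02d}" for i in range(config.n_tissues - 2)]
    n_t = len(tissues)

    enriched = set(genes[: 1 + config.n_enriched_extra])
    plain = genes[1 + config.n_enriched_extra :]
    boundary_gene = plain[0]
    undetected = set(plain[1 : 1 + config.n_undetected])

    rows = []
    truth_rows = []
    for gi, gene in enumerate(genes):
        draws = np.sort(rng.lognormal(mean=2.0, sigma=1.0, size=n_t))[::-1]
        row = np.empty(n_t)
        if gene in enriched:
            target_rank = (gi % config.top_k) + 1
        elif gene == boundary_gene:
            target_rank = config.top_k + 1
        elif gene in undetected:
            target_rank = None
        else:
            target_rank = int(rng.integers(config.top_k + 2, n_t))
        if target_rank is None:
            other = draws[: n_t - 2]
            rng.shuffle(other)
            row[0] = row[1] = 0.0
            row[2:] = other
        else:
            # colon takes the value at the target rank; rectum strictly below
            rectum_rank = int(rng.integers(max(target_rank + 1, config.top_k + 2), n_t + 1))
            colon_val = draws[target_rank - 1]
            rectum_val = draws[rectum_rank - 1]
            rest = np.delete(draws, [target_rank - 1, rectum_rank - 1])
            rng.shuffle(rest)
            row[0], row[1], row[2:] = colon_val, rectum_val, rest
        rows.append(row)
        truth_rows.append(
            {
                "gene_id": gene,
                "enriched": gene in enriched,
                "detected": gene not in undetected,
                "target_rank": target_rank if target_rank is not None else -1,
            }
        )
    matrix = LabeledMatrix(values=pd.DataFrame(rows, index=genes, columns=tissues))
    return matrix, pd.DataFrame(truth_rows)


def gen_deg_series(config: SpikeConfig | None = None) -> tuple[dict, pd.DataFrame]:
    """Per-series DE call tables emulating three adenoma/polyp series.

    The spiked gene and the enriched extras are 'down' in
    ``deg_spiked_n_series`` series; a handful of decoys are concordantly
    down or up in >= 2 series; one decoy is engineered discordant and the
    rest get at most one significant call.
    """
    config = config or SpikeConfig()
    rng = config.rng("deg")
    genes = _gene_universe(config)
    series = list(config.deg_series)
    extras = genes[1 : 1 + config.n_enriched_extra]
    plain = genes[1 + config.n_enriched_extra :]

    calls = {s: {} for s in series}
    truth_rows = []

    def set_calls(gene, direction, n_series):
        chosen = rng.choice(len(series), size=n_series, replace=False)
        for k, s in enumerate(series):
            calls[s][gene] = direction if k in chosen else "none"

    down_multi = [genes[0]] + extras + plain[-2:]            # 7 down in >= 2
    up_multi = plain[-8:-2]                                   # 6 up in >= 2
    discordant_gene = plain[-9]
    for gene in genes:
        if gene in down_multi:
            set_calls(gene, "down", config.deg_spiked_n_series)
            consensus, n_sig = "down", config.deg_spiked_n_series
        elif gene in up_multi:
            set_calls(gene, "up", 2)
            consensus, n_sig = "up", 2
        elif gene == discordant_gene:
            calls[series[0]][gene] = "up"
            calls[series[1]][gene] = "down"
            calls[series[2]][gene] = "none"
            consensus, n_sig = "discordant", 2
        else:
            if rng.random() < 0.25:
                s = series[int(rng.integers(0, len(series)))]
                d = "down" if rng.random() < 0.5 else "up"
                for s2 in series:
                    calls[s2][gene] = d if s2 == s else "none"
                consensus, n_sig = d, 1
            else:
                for s2 in series:
                    calls[s2][gene] = "none"
                consensus, n_sig = "none", 0
        truth_rows.append(
            {"gene_id": gene, "consensus": consensus, "n_significant": n_sig}
        )
    return calls, pd.DataFrame(truth_rows)


def gen_survival(
    config: SpikeConfig | None = None,
    hazard_ratio: float | None = None,
    n_patients: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[SurvivalRecord]]:
    """Exponential survival cohort for one gene.

    Expression is log-normal; subjects above the median carry hazard
    ``baseline_hazard * hazard_ratio`` (ratio < 1 = protective high
    expression).  Censoring is an independent exponential calibrated to the
    configured censoring fraction; a rate >= 1 leaves no events and raises.
    """
    config = config or SpikeConfig()
    if config.censoring_rate >= 1:
        raise DomainError("censoring rate >= 1 leaves no observable events")
    rng = rng if rng is not None else config.rng("survival")
    hr = hazard_ratio if hazard_ratio is not None else config.survival_hazard_ratio
    n = n_patients if n_patients is not None else config.survival_n_patients

    expr = rng.lognormal(mean=1.0, sigma=0.6, size=n)
    high = expr > np.median(expr)
    hazard = config.baseline_hazard * np.where(high, hr, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    c_rate = config.baseline_hazard * config.censoring_rate / (1 - config.censoring_rate)
    t_cens = rng.exponential(1.0 / c_rate, size=n) if c_rate > 0 else np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    records = [
        SurvivalRecord(time=float(t), event=bool(e), group="")
        for t, e in zip(time, event)
    ]
    return expr, records


def gen_gene_sets(config: SpikeConfig | None = None) -> tuple[GeneSetCollection, set]:
    """Pathway gene sets covering ``n_pathway_genes`` of the universe; the
    spiked gene sits in the TGF-beta set, the enriched extras in none."""
    config = config or SpikeConfig()
    rng = config.rng("pathway")
    genes = _gene_universe(config)
    plain = genes[1 + config.n_enriched_extra :]
    members = list(rng.choice(plain, size=config.n_pathway_genes - 1, replace=False))
    set_names = ["wnt_signaling", "tgf_beta_signaling", "hippo_signaling", "jak_stat_signaling"]
    assignment: dict[str, list[str]] = {s: [] for s in set_names}
    assignment["tgf_beta_signaling"].append(config.spiked_gene)
    for i, g in enumerate(members):
        assignment[set_names[i % len(set_names)]].append(g)
    collection = GeneSetCollection(
        sets={
            name: (f"synthetic {name.replace('_', ' ')} pathway", tuple(sorted(gl)))
            for name, gl in assignment.items()
            if gl
        }
    )
    return collection, set(members) | {config.spiked_gene}


def gen_counts(config: SpikeConfig | None = None):
    """NB count matrix, control vs treatment, with spiked fold changes.

    Gene means are log-normal; the first ``de_n_spiked`` genes carry the
    configured fold change in the treatment condition.  Returns the
    CountMatrix and a truth table of per-gene DE flags.
    """
    from .rnaseq_de import CountMatrix

    config = config or SpikeConfig()
    rng = config.rng("counts")
    n_g, n_s = config.de_n_genes, config.de_n_per_group
    genes = [f"G{i + 1:04d}" for i in range(n_g)]
    samples = [f"C{i + 1}" for i in range(n_s)] + [f"T{i + 1}" for i in range(n_s)]
    condition = {s: ("control" if s.startswith("C") else "treatment") for s in samples}

    mu = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=n_g)
    spiked = np.zeros(n_g, dtype=bool)
    spiked[: config.de_n_spiked] = True
    counts = np.empty((n_g, 2 * n_s), dtype=np.int64)
    for gi in range(n_g):
        mu_t = mu[gi] * (config.de_fold_change if spiked[gi] else 1.0)
        counts[gi, :n_s] = nb_draws(rng, mu[gi], config.de_dispersion, n_s)
        counts[gi, n_s:] = nb_draws(rng, mu_t, config.de_dispersion, n_s)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        condition=condition,
    )
    truth = pd.DataFrame(
        {"gene_id": genes, "is_de": spiked, "true_fc": np.where(spiked, config.de_fold_change, 1.0)}
    )
    return cm, truth


def gen_coexpression_matrix(config: SpikeConfig | None = None) -> tuple[LabeledMatrix, str]:
    """Continuous expression matrix with one engineered hub module: a
    driver gene, ``hub_module_size`` followers equal to the driver plus
    small Gaussian noise, and independent decoys.  Returns the matrix and
    the driver gene id."""
    config = config or SpikeConfig()
    rng = config.rng("coexpr")
    n_s = config.coexpr_n_samples
    driver = "HUB_DRIVER"
    driver_expr = rng.normal(10.0, 2.0, size=n_s)
    rows = {driver: driver_expr}
    for i in range(config.hub_module_size):
        rows[f"HUB_F{i + 1:02d}"] = driver_expr + rng.normal(0, config.hub_noise_sd, size=n_s)
    for i in range(config.hub_n_decoys):
        rows[f"N{i + 1:03d}"] = rng.normal(10.0, 2.0, size=n_s)
    matrix = LabeledMatrix(
        values=pd.DataFrame.from_dict(rows, orient="index",
                                      columns=[f"S{i + 1}" for i in range(n_s)])
    )
    return matrix, driver


def gen_prioritization_suite(config: SpikeConfig | None = None) -> dict:
    """All four evidence inputs for the ranking stage, with one gene
    engineered to satisfy every criterion.

    The spiked gene is tissue-enriched, down in >= 2 series, in a pathway
    set, and carries a strongly protective survival effect
    (``prioritization_hazard_ratio``); the enriched extras are engineered
    to satisfy at most three criteria (no pathway membership, null
    survival), so the spiked gene is the unique all-criteria candidate.
    """
    config = config or SpikeConfig()
    tissue_matrix, tissue_truth = gen_tissue_matrix(config)
    deg_calls, deg_truth = gen_deg_series(config)
    sets, pathway_members = gen_gene_sets(config)
    rng = config.rng("survival")
    survival = {}
    for gene in _gene_universe(config):
        hr = config.prioritization_hazard_ratio if gene == config.spiked_gene else 1.0
        expr, records = gen_survival(config, hazard_ratio=hr, rng=rng)
        survival[gene] = (expr, records)
    return {
        "tissue_matrix": tissue_matrix,
        "tissue_truth": tissue_truth,
        "deg_calls": deg_calls,
        "deg_truth": deg_truth,
        "gene_sets": sets,
        "pathway_members": pathway_members,
        "survival": survival,
        "spiked_gene": config.spiked_gene,
    }
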