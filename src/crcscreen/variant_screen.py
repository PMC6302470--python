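"""Loss-of-function variant screening.

Implements the four-criterion screen used to nominate tumor-suppressor
candidates from tumor exome calls:

1. known variants (dbSNP/1000G-style blacklist membership) are removed;
2. variant quality in the tumor must be >= 100;
3. read depth must lie in the closed interval [10, 200];
4. variants in the last 5% of the gene coding region are removed
   (strictly past the 95th-percentile coding base; the boundary base is kept).

Somatic status is determined against the matched normal sample, emulating
the confirmation resequencing step at desk scale.  Consequence calls
(nonsense / frameshift / canonical splice / missense / synonymous) are made
per-allele against a transcript CDS model and its coding sequence.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .errors import DegenerateDataError, DomainError, PairingError, ParseError
from .io_formats import TranscriptModel, VariantRecord

__all__ = [
    "Consequence",
    "LOF_CLASSES",
    "TRUNCATING_CLASSES",
    "ProteinChange",
    "parse_protein_change",
    "cds_position",
    "classify_consequence",
    "FilterConfig",
    "FilterDecision",
    "TranscriptIndex",
    "apply_lof_filters",
    "call_somatic",
    "CohortSummary",
    "summarize_cohort",
]


class Consequence(str, Enum):
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    CANONICAL_SPLICE = "canonical_splice"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    NONCODING = "noncoding"
    OTHER = "other"


#: Consequences expected to abolish protein function.
LOF_CLASSES = frozenset(
    {Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.CANONICAL_SPLICE}
)
#: LoF subclasses producing a shortened protein.
TRUNCATING_CLASSES = frozenset({Consequence.NONSENSE, Consequence.FRAMESHIFT})


# ---------------------------------------------------------------------------
# HGVS-like protein notation


@dataclass(frozen=True)
class ProteinChange:
    """A one-letter amino-acid change, e.g. R174* (Arg 174 -> stop)."""

    ref_aa: str
    position: int
    alt_aa: str

    @property
    def kind(self) -> Consequence:
        if self.alt_aa == "*":
            return Consequence.NONSENSE
        if self.alt_aa == self.ref_aa:
            return Consequence.SYNONYMOUS
        return Consequence.MISSENSE


_PROTEIN_RE = re.compile(r"^p\s*\.?\s*([A-Z])\s*(\d+)\s*([A-Z*])$")


def parse_protein_change(notation: str) -> ProteinChange:
    """Parse 'p.R174*'-style notation (interior spaces tolerated, as printed
    in clinical tables, e.g. 'p. V289 M')."""
    m = _PROTEIN_RE.match(notation.strip())
    if not m:
        raise ParseError(f"cannot parse protein change {notation!r}")
    ref_aa, pos, alt_aa = m.group(1), int(m.group(2)), m.group(3)
    if pos < 1:
        raise ParseError(f"codon number must be >= 1 in {notation!r}")
    return ProteinChange(ref_aa=ref_aa, position=pos, alt_aa=alt_aa)


# ---------------------------------------------------------------------------
# CDS coordinates and consequence classification


def cds_position(
    variant: VariantRecord, model: TranscriptModel
) -> tuple[int | None, float | None]:
    """Map a genomic position into 1-based CDS coordinates.

    On the + strand coding bases are counted from the lowest genomic
    coordinate of the CDS; on the - strand from the highest.  Returns
    ``(None, None)`` for positions outside every CDS segment.
    """
    if model.cds_length == 0:
        raise DegenerateDataError(
            f"transcript {model.transcript_id} has an empty CDS"
        )
    if variant.chrom != model.chrom:
        raise DomainError(
            f"variant on {variant.chrom} vs model on {model.chrom}"
        )
    pos = variant.pos
    offset = 0
    plus_pos = None
    for start, end in model.cds_segments:
        if start <= pos <= end:
            plus_pos = offset + (pos - start) + 1
            break
        offset += end - start + 1
    if plus_pos is None:
        return (None, None)
    cds_pos = plus_pos if model.strand == "+" else model.cds_length + 1 - plus_pos
    return (cds_pos, cds_pos / model.cds_length)


def _in_splice_window(pos: int, model: TranscriptModel, window: int) -> bool:
    """True when pos is outside every CDS segment but within ``window`` bases
    of a segment boundary (the intron-side canonical splice positions)."""
    for start, end in model.cds_segments:
        if start <= pos <= end:
            return False
    for start, end in model.cds_segments:
        if start - window <= pos < start or end < pos <= end + window:
            return True
    return False


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def classify_consequence(
    variant: VariantRecord,
    model: TranscriptModel,
    coding_sequence: str,
    splice_window: int = 2,
) -> Consequence:
    """Classify one variant against a transcript model and its CDS sequence.

    ``coding_sequence`` is the 5'->3' mRNA coding sequence (already reverse-
    complemented for - strand models) and must match the model's CDS length.
    Substitutions are translated at the affected codon with the standard
    genetic code; coding indels with a net length change not divisible by 3
    are frameshifts (in-frame indels -> other); non-coding positions within
    ``splice_window`` bases of a CDS-segment boundary are canonical splice
    variants.
    """
    coding_sequence = coding_sequence.upper()
    if len(coding_sequence) != model.cds_length:
        raise DomainError(
            f"coding sequence length {len(coding_sequence)} != CDS length "
            f"{model.cds_length} for {model.transcript_id}"
        )

    if variant.is_indel:
        span_lo = variant.pos
        span_hi = variant.pos + max(len(variant.ref), 1) - 1
        overlaps_cds = any(
            start <= span_hi and span_lo <= end for start, end in model.cds_segments
        )
        if overlaps_cds:
            net = len(variant.alt) - len(variant.ref)
            return Consequence.FRAMESHIFT if net % 3 != 0 else Consequence.OTHER
        if _in_splice_window(variant.pos, model, splice_window):
            return Consequence.CANONICAL_SPLICE
        return Consequence.NONCODING

    cds_pos, _frac = cds_position(variant, model)
    if cds_pos is None:
        if _in_splice_window(variant.pos, model, splice_window):
            return Consequence.CANONICAL_SPLICE
        return Consequence.NONCODING

    alt_base = variant.alt if model.strand == "+" else variant.alt.translate(_COMPLEMENT)
    codon_idx = (cds_pos - 1) // 3
    codon_start = codon_idx * 3
    codon = coding_sequence[codon_start : codon_start + 3]
    if len(codon) < 3:
        # trailing partial codon of a partial model: not translatable
        return Consequence.OTHER
    within = (cds_pos - 1) % 3
    mutated = codon[:within] + alt_base + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mutated).translate())
    if alt_aa == "*" and ref_aa != "*":
        return Consequence.NONSENSE
    if alt_aa == ref_aa:
        return Consequence.SYNONYMOUS
    return Consequence.MISSENSE


# ---------------------------------------------------------------------------
# Filter cascade


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the four-criterion LoF screen."""

    quality_min: float = 100.0
    depth_min: int = 10
    depth_max: int = 200
    cds_tail_fraction: float = 0.05
    splice_window: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.cds_tail_fraction < 1):
            raise DomainError("cds_tail_fraction must be in (0, 1)")
        if self.depth_min > self.depth_max:
            raise DomainError("depth_min must be <= depth_max")


@dataclass(frozen=True)
class FilterDecision:
    variant: VariantRecord
    failed_criteria: frozenset[str]

    @property
    def retained(self) -> bool:
        return not self.failed_criteria


class TranscriptIndex:
    """Resolve variants to transcript models.

    Among models on the variant's chromosome whose CDS span (plus a flank)
    covers the position, the longest-CDS model is chosen; ties break on
    transcript_id.  Positions covered by no model resolve to ``None``.
    """

    def __init__(self, models: Iterable[TranscriptModel], flank: int = 10_000):
        self.flank = flank
        self._by_chrom: dict[str, list[TranscriptModel]] = {}
        for m in models:
            self._by_chrom.setdefault(m.chrom, []).append(m)

    def resolve(self, variant: VariantRecord) -> TranscriptModel | None:
        candidates = []
        for m in self._by_chrom.get(variant.chrom, ()):
            if m.cds_length == 0:
                continue
            lo, hi = m.span
            if lo - self.flank <= variant.pos <= hi + self.flank:
                candidates.append(m)
        if not candidates:
            return None
        return max(candidates, key=lambda m: (m.cds_length, m.transcript_id))


def apply_lof_filters(
    variants: Sequence[VariantRecord],
    models: TranscriptIndex | Iterable[TranscriptModel],
    config: FilterConfig | None = None,
) -> list[FilterDecision]:
    """Evaluate all four screening criteria independently for every variant.

    ``failed_criteria`` lists every violated criterion (labels
    ``known_variant``, ``quality``, ``depth``, ``cds_tail``), not only the
    first.  Missing depth fails the depth criterion; a variant that no
    transcript model covers fails the positional (cds_tail) criterion, since
    its coding-region position cannot be certified.
    """
    config = config or FilterConfig()
    index = models if isinstance(models, TranscriptIndex) else TranscriptIndex(models)

    decisions = []
    for v in variants:
        failed = set()
        if v.is_known:
            failed.add("known_variant")
        if v.quality is None or v.quality < config.quality_min:
            failed.add("quality")
        if v.depth is None or not (config.depth_min <= v.depth <= config.depth_max):
            failed.add("depth")
        model = index.resolve(v)
        if model is None:
            failed.add("cds_tail")
        else:
            _pos, frac = cds_position(v, model)
            if frac is not None and frac > 1 - config.cds_tail_fraction:
                failed.add("cds_tail")
        decisions.append(FilterDecision(variant=v, failed_criteria=frozenset(failed)))
    return decisions


def call_somatic(
    tumor: Sequence[VariantRecord], normal: Sequence[VariantRecord]
) -> list[VariantRecord]:
    """Somatic = tumor variants absent (by exact key) from the matched
    normal; input order preserved.  Both lists must come from one individual
    (identical sample_id prefixes up to a -T/-N style suffix are accepted)."""
    if tumor and normal:
        t_base = _individual(tumor[0].sample_id)
        n_base = _individual(normal[0].sample_id)
        if t_base != n_base:
            raise PairingError(
                f"tumor sample {tumor[0].sample_id!r} does not match normal "
                f"{normal[0].sample_id!r}"
            )
    normal_keys = {v.key for v in normal}
    return [v for v in tumor if v.key not in normal_keys]


def _individual(sample_id: str) -> str:
    return re.sub(r"[-_.](T|N|tumor|normal|blood)$", "", sample_id, flags=re.I)


# ---------------------------------------------------------------------------
# Cohort summary


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level mutation statistics for one gene."""

    n_samples: int
    n_mutated_samples: int
    mutation_frequency: float
    counts_by_consequence: Mapping[Consequence, int]
    truncating_fraction: float | None

    @property
    def n_mutations(self) -> int:
        return sum(self.counts_by_consequence.values())


def summarize_cohort(
    mutations: Sequence[tuple[str, Consequence]], n_samples: int
) -> CohortSummary:
    """Summarize (sample, consequence) mutation calls over a cohort.

    mutation_frequency = distinct mutated samples / n_samples;
    truncating_fraction = (nonsense + frameshift) / total mutations
    (``None`` when there are no mutations).
    """
    if n_samples <= 0:
        raise DomainError("n_samples must be positive")
    samples = {s for s, _c in mutations}
    if len(samples) > n_samples:
        raise DomainError(
            f"{len(samples)} distinct mutated samples exceed cohort size {n_samples}"
        )
    counts = Counter(c for _s, c in mutations)
    total = sum(counts.values())
    truncating = sum(counts[c] for c in TRUNCATING_CLASSES)
    return CohortSummary(
        n_samples=n_samples,
        n_mutated_samples=len(samples),
        mutation_frequency=len(samples) / n_samples,
        counts_by_consequence=dict(counts),
        truncating_fraction=(truncating / total) if total else None,
    )
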