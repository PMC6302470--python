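"""Multi-evidence prioritization of mutated candidate genes.

Four criteria are scored over the mutated-gene universe and candidates are
ranked by the number of criteria satisfied:

* **tissue**: the gene's expression in the target normal tissue(s)
  (colon/rectum) ranks in the top ``top_k`` of the multi-tissue panel
  (37 tissues by default), and — under the tumor-suppressor direction
  policy — the gene is consistently *down* in tumors;
* **early DEG**: called differentially expressed in at least ``min_series``
  independent adenoma/polyp series;
* **survival**: a best-separation expression cutoff (scanned over the
  20-80% quantile grid in 5% steps, as in the HPA convention, with no
  multiplicity correction) yields a log-rank p below alpha;
* **pathway**: membership in at least one curated pathway gene set.

Ties in the final ranking break lexicographically on gene id, making the
ordering fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import assoc_stats
from .assoc_stats import SurvivalRecord
from .errors import DegenerateDataError, DomainError, InsufficientDataError
from .io_formats import GeneSetCollection, LabeledMatrix

__all__ = [
    "TissueEnrichment",
    "DEGEvidence",
    "SurvivalEvidence",
    "tissue_enrichment",
    "deg_evidence",
    "survival_evidence",
    "pathway_evidence",
    "rank_candidates",
]

DEFAULT_CUTOFF_GRID = tuple(np.round(np.arange(0.20, 0.801, 0.05), 2))


@dataclass(frozen=True)
class TissueEnrichment:
    gene_id: str
    tissue_rank: int | None
    n_tissues: int
    enriched: bool
    detected: bool


@dataclass(frozen=True)
class DEGEvidence:
    gene_id: str
    series_calls: Mapping[str, str]          # series -> up | down | none
    n_significant_series: int
    direction: str                           # up | down | discordant | none


@dataclass(frozen=True)
class SurvivalEvidence:
    gene_id: str
    cutoff: float
    logrank_p: float
    direction: str                           # favourable | unfavourable
    n_cutoffs_tested: int
    satisfied: bool


def tissue_enrichment(
    expr: LabeledMatrix,
    target_tissues: Sequence[str],
    top_k: int = 7,
) -> list[TissueEnrichment]:
    """Rank each gene's best target-tissue expression among all tissues.

    Rank 1 is the highest-expressing tissue; ties take the best (minimum)
    rank.  A gene is *detected* when some target tissue has expression > 0
    and *enriched* when detected with rank <= top_k.  Being rank-based, the
    call is invariant under strictly monotone transforms of a gene's
    expression vector.
    """
    unknown = set(target_tissues) - set(expr.col_ids)
    if unknown:
        raise DomainError(f"unknown target tissue(s): {sorted(unknown)}")
    if len(expr.col_ids) < top_k:
        raise DomainError(f"need >= {top_k} tissues, got {len(expr.col_ids)}")
    values = expr.values.to_numpy(dtype=float)
    target_idx = [expr.col_ids.index(t) for t in target_tissues]
    out = []
    for i, gene in enumerate(expr.row_ids):
        row = values[i]
        best_target = row[target_idx].max()
        detected = bool(best_target > 0)
        if detected:
            rank = int((row > best_target).sum()) + 1   # min rank on ties
            enriched = rank <= top_k
        else:
            rank, enriched = None, False
        out.append(
            TissueEnrichment(
                gene_id=gene, tissue_rank=rank, n_tissues=len(expr.col_ids),
                enriched=enriched, detected=detected,
            )
        )
    return out


def deg_evidence(
    series_tables: Mapping[str, Mapping[str, str]],
    min_series: int = 2,
) -> list[DEGEvidence]:
    """Combine per-series differential-expression calls per gene.

    ``series_tables`` maps series name -> {gene -> 'up' | 'down' | 'none'}.
    A gene's criterion counts the series with a non-'none' call; the
    consensus direction is the common direction when all significant calls
    agree, 'discordant' otherwise, 'none' with no significant call.
    """
    if not series_tables:
        raise DomainError("at least one series table is required")
    genes = sorted({g for calls in series_tables.values() for g in calls})
    out = []
    for gene in genes:
        calls = {
            series: table.get(gene, "none") for series, table in series_tables.items()
        }
        significant = [d for d in calls.values() if d in ("up", "down")]
        n_sig = len(significant)
        if n_sig == 0:
            direction = "none"
        elif len(set(significant)) == 1:
            direction = significant[0]
        else:
            direction = "discordant"
        out.append(
            DEGEvidence(
                gene_id=gene, series_calls=calls,
                n_significant_series=n_sig, direction=direction,
            )
        )
    return out


def survival_evidence(
    gene_id: str,
    expression: Sequence[float],
    records: Sequence[SurvivalRecord],
    cutoff_grid: Sequence[float] = DEFAULT_CUTOFF_GRID,
    alpha: float = 0.05,
    min_group: int = 2,
) -> SurvivalEvidence:
    """Best-separation survival screen for one gene.

    Expression values are aligned positionally with ``records``.  Each grid
    quantile of expression splits patients into high/low arms; the log-rank
    p is computed for every admissible split (both arms non-empty with at
    least ``min_group`` subjects) and the cutoff minimizing p is reported
    — the raw minimum, with the number of cutoffs actually tested, so the
    caller can correct for the implicit multiplicity.  Direction compares
    restricted mean survival: 'favourable' when the high-expression arm
    survives longer.
    """
    expr = np.asarray(expression, dtype=float)
    if len(expr) != len(records):
        raise DomainError("expression and survival records must align")
    if np.all(expr == expr[0]):
        raise DegenerateDataError(f"{gene_id}: all expression values identical")
    if len(records) < 10:
        raise InsufficientDataError("best-separation screen needs >= 10 patients")

    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)

    best = None   # (p, cutoff, high_mask)
    n_tested = 0
    for q in cutoff_grid:
        cutoff = float(np.quantile(expr, q))
        high = expr > cutoff
        if high.sum() < min_group or (~high).sum() < min_group:
            continue
        if events[high].sum() + events[~high].sum() == 0:
            continue
        result = assoc_stats.logrank_arrays(
            times[high], events[high], times[~high], events[~high]
        )
        n_tested += 1
        if best is None or result.p_value < best[0]:
            best = (result.p_value, cutoff, high)
    if best is None:
        raise DegenerateDataError(f"{gene_id}: no admissible split on the grid")

    p_min, cutoff, high = best
    horizon = float(times.max())
    rm_high = assoc_stats.restricted_mean(times[high], events[high], horizon)
    rm_low = assoc_stats.restricted_mean(times[~high], events[~high], horizon)
    return SurvivalEvidence(
        gene_id=gene_id, cutoff=cutoff, logrank_p=p_min,
        direction="favourable" if rm_high >= rm_low else "unfavourable",
        n_cutoffs_tested=n_tested, satisfied=p_min < alpha,
    )


def pathway_evidence(
    genes: Iterable[str], collection: GeneSetCollection
) -> dict[str, list[str]]:
    """Map each gene to the gene sets containing it (empty list = criterion
    unsatisfied)."""
    return {gene: collection.sets_for(gene) for gene in genes}


def rank_candidates(
    tissue: Sequence[TissueEnrichment],
    deg: Sequence[DEGEvidence],
    survival: Sequence[SurvivalEvidence],
    pathways: Mapping[str, Sequence[str]],
    min_series: int = 2,
    direction_policy: bool = True,
) -> pd.DataFrame:
    """Combine the four evidence tracks into a scored, ranked table.

    The gene universe is the union of all evidence inputs; a gene missing
    from a track simply fails that criterion.  Under ``direction_policy``
    (the tumor-suppressor reading), the tissue criterion additionally
    requires the consensus DEG direction to be 'down'.  Score = number of
    satisfied criteria; rank orders by descending score, ties by ascending
    gene id.
    """
    tissue_by = {t.gene_id: t for t in tissue}
    deg_by = {d.gene_id: d for d in deg}
    surv_by = {s.gene_id: s for s in survival}
    universe = sorted(
        set(tissue_by) | set(deg_by) | set(surv_by) | set(pathways)
    )
    rows = []
    for gene in universe:
        t = tissue_by.get(gene)
        d = deg_by.get(gene)
        s = surv_by.get(gene)
        enriched = bool(t and t.enriched)
        down = bool(d and d.direction == "down")
        tissue_ok = enriched and (down if direction_policy else True)
        deg_ok = bool(d and d.n_significant_series >= min_series)
        surv_ok = bool(s and s.satisfied)
        path_ok = bool(pathways.get(gene))
        score = sum((tissue_ok, deg_ok, surv_ok, path_ok))
        rows.append(
            {
                "gene_id": gene,
                "tissue_criterion": tissue_ok,
                "deg_criterion": deg_ok,
                "survival_criterion": surv_ok,
                "pathway_criterion": path_ok,
                "score": score,
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    table = table.sort_values(["score"], ascending=False, kind="stable")
    table = table.loc[
        sorted(table.index, key=lambda g: (-table.loc[g, "score"], g))
    ]
    table["rank"] = np.arange(1, len(table) + 1)
    return table
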