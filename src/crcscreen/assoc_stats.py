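"""Statistical kernel: contingency tests, paired tests, correlations,
Kaplan-Meier / log-rank, Benjamini-Hochberg FDR, and the xenograft
volume formula.

Conventions fixed here (and relied on elsewhere in the package):

* the 2x2 chi-square applies the Yates continuity correction by default;
* the two-sided Fisher exact p sums hypergeometric probabilities of all
  tables with the observed margins whose probability does not exceed the
  observed table's;
* the Wilcoxon signed-rank test is exact for n <= 25 (no ties/zeros),
  normal-approximate with continuity correction otherwise;
* log-rank handles tied event times with the hypergeometric variance at
  each distinct time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from lifelines.utils import restricted_mean_survival_time
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, DomainError, InsufficientDataError
from .io_formats import LabeledMatrix

__all__ = [
    "ContingencyTable2x2",
    "SurvivalRecord",
    "TestResult",
    "chisq_2x2",
    "fisher_exact_2x2",
    "paired_tests",
    "pearson_r",
    "log2fc_correlation",
    "km_logrank",
    "bh_fdr",
    "tumor_volume",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 cell counts: rows = groups, columns = positive/negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DomainError("cell counts must be non-negative")
        if self.total < 1:
            raise DomainError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return np.inf if self.a * self.d > 0 else np.nan
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class SurvivalRecord:
    """Follow-up time, event indicator, and a grouping label or
    expression value."""

    time: float
    event: bool
    group: str | float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DomainError(f"negative follow-up time {self.time}")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    estimate: float | None = None
    df: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise DomainError(f"p-value {self.p_value} outside [0, 1]")


def chisq_2x2(table: ContingencyTable2x2, continuity: bool = True) -> TestResult:
    """Pearson chi-square on a 2x2 table (Yates-corrected by default), df 1,
    two-sided; the sample odds ratio ad/bc is reported as the estimate."""
    arr = table.as_array
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateDataError("a row or column marginal is zero")
    stat, p, dof, _exp = stats.chi2_contingency(arr, correction=continuity)
    return TestResult(
        statistic=float(stat), p_value=float(p), estimate=table.odds_ratio,
        df=float(dof), n=table.total,
    )


def fisher_exact_2x2(table: ContingencyTable2x2) -> TestResult:
    """Fisher exact test, two-sided by the 'sum of tables at most as
    probable as observed' convention."""
    res = stats.fisher_exact(table.as_array, alternative="two-sided")
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        estimate=table.odds_ratio, n=table.total,
    )


def paired_tests(x, y, method: str = "paired_t") -> TestResult:
    """Two-sided paired t-test or Wilcoxon signed-rank on matched samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise InsufficientDataError("paired tests need n >= 3 pairs")
    d = x - y
    if method == "paired_t":
        if np.allclose(d, d[0]):
            raise DegenerateDataError("differences have zero variance")
        res = stats.ttest_rel(x, y)
        return TestResult(
            statistic=float(res.statistic), p_value=float(res.pvalue),
            estimate=float(d.mean()), df=float(n - 1), n=n,
        )
    if method == "wilcoxon_signed_rank":
        if np.all(d == 0):
            return TestResult(statistic=0.0, p_value=1.0, estimate=0.0, n=n)
        nz = d[d != 0]
        mode = "exact" if len(nz) <= 25 else "approx"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(x, y, zero_method="wilcox", correction=True, method=mode)
        return TestResult(
            statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
            estimate=float(np.median(d)), n=n,
        )
    raise DomainError(f"unknown method {method!r}")


def pearson_r(x, y) -> TestResult:
    """Pearson correlation with two-sided p via the t-transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InsufficientDataError("pearson_r needs >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        estimate=float(res.statistic), df=float(len(x) - 2), n=len(x),
    )


def log2fc_correlation(
    tumor: LabeledMatrix, normal: LabeledMatrix, gene_a: str, gene_b: str
) -> TestResult:
    """Correlate per-pair expression fold changes log2(tumor/normal) of two
    genes across matched tumor/normal sample pairs.

    Columns of the two matrices are matched positionally (pair i = column i
    of each).  Pairs where either gene has a non-positive value in either
    tissue are dropped with a warning.
    """
    if tumor.shape[1] != normal.shape[1]:
        raise DomainError("tumor and normal matrices must have matched columns")
    t = tumor.values.loc[[gene_a, gene_b]].to_numpy(dtype=float)
    n = normal.values.loc[[gene_a, gene_b]].to_numpy(dtype=float)
    usable = (t > 0).all(axis=0) & (n > 0).all(axis=0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} pair(s) dropped for non-positive expression")
    if usable.sum() < 3:
        raise InsufficientDataError(
            f"only {int(usable.sum())} usable pairs after exclusions"
        )
    fc = np.log2(t[:, usable] / n[:, usable])
    return pearson_r(fc[0], fc[1])


def logrank_arrays(times_a, events_a, times_b, events_b) -> TestResult:
    """Two-group log-rank test on raw arrays (the array-level kernel behind
    :func:`km_logrank`, also used by the best-separation survival scan).
    O-E statistic with the hypergeometric variance at each distinct event
    time (standard handling of ties), chi-square 1 df."""
    times = np.concatenate([times_a, times_b]).astype(float)
    events = np.concatenate([events_a, events_b]).astype(bool)
    group_a = np.zeros(len(times), dtype=bool)
    group_a[: len(times_a)] = True

    event_times = np.unique(times[events])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & group_a).sum()
        d = (events & (times == t)).sum()
        d_a = (events & (times == t) & group_a).sum()
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    stat = (o_minus_e**2 / var) if var > 0 else 0.0
    p = float(stats.chi2.sf(stat, df=1)) if var > 0 else 1.0
    return TestResult(statistic=float(stat), p_value=p, df=1.0, n=len(times))


def km_logrank(records) -> tuple[TestResult, dict]:
    """Kaplan-Meier curves per group and the log-rank test across groups.

    Returns ``(TestResult, curves)`` where ``curves`` maps each group label
    to a DataFrame with columns ``time`` and ``survival`` (the product-limit
    step function, starting at S(0) = 1).  Two groups use the standard
    O-E / hypergeometric-variance statistic; >= 3 groups the multivariate
    extension (df = k - 1).
    """
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    groups = np.array([r.group for r in records], dtype=object)
    labels = sorted(set(groups), key=str)
    if len(labels) < 2:
        raise DomainError("log-rank needs at least two groups")
    for lab in labels:
        if (groups == lab).sum() == 0:
            raise DomainError(f"group {lab!r} has zero subjects")
    if events.sum() == 0:
        raise DegenerateDataError("no events observed in any group")

    curves = {}
    for lab in labels:
        mask = groups == lab
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(lab))
        sf = kmf.survival_function_
        curves[lab] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )

    if len(labels) == 2:
        m0 = groups == labels[0]
        result = logrank_arrays(times[m0], events[m0], times[~m0], events[~m0])
    else:
        res = multivariate_logrank_test(times, groups.astype(str), events)
        result = TestResult(
            statistic=float(res.test_statistic), p_value=float(res.p_value),
            df=float(len(labels) - 1), n=len(records),
        )
    return (result, curves)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tumor_volume(a: float, b: float) -> float:
    """Xenograft tumor volume 0.5 * a * b^2 from the two caliper diameters;
    ``a`` is the longer diameter (swapped with a warning if given reversed)."""
    if a <= 0 or b <= 0:
        raise DomainError("diameters must be positive")
    if a < b:
        warnings.warn("a < b: diameters swapped (a is defined as the longer)")
        a, b = b, a
    return 0.5 * a * b * b


def restricted_mean(times, events, horizon: float | None = None) -> float:
    """Restricted mean survival time of one arm (area under its KM curve
    up to ``horizon``, default the largest observed time)."""
    kmf = KaplanMeierFitter().fit(np.asarray(times, float), np.asarray(events, bool))
    t_max = horizon if horizon is not None else float(np.max(times))
    return float(restricted_mean_survival_time(kmf, t=t_max))
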