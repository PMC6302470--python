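import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcscreen.assoc_stats import (
    ContingencyTable2x2,
    SurvivalRecord,
    bh_fdr,
    chisq_2x2,
    fisher_exact_2x2,
    km_logrank,
    log2fc_correlation,
    logrank_arrays,
    paired_tests,
    pearson_r,
    tumor_volume,
)
from crcscreen.datasets import IHC_BREAST, IHC_COLORECTAL
from crcscreen.errors import DegenerateDataError, DomainError, InsufficientDataError
from crcscreen.io_formats import LabeledMatrix


class TestChisq:
    def test_breast_ihc_matches_printed_p(self):
        """Yates-corrected chi-square on the breast tissue-microarray counts
        (21/40 carcinoma vs 5/40 normal positive) prints P = 0.0003."""
        res = chisq_2x2(IHC_BREAST, continuity=True)
        assert float(f"{res.p_value:.1g}") == 0.0003

    def test_colorectal_ihc_below_headline_bound(self):
        assert chisq_2x2(IHC_COLORECTAL).p_value < 0.0001

    def test_no_association(self):
        res = chisq_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert res.statistic == 0 and res.p_value == 1

    def test_zero_marginal_rejected(self):
        with pytest.raises(DegenerateDataError):
            chisq_2x2(ContingencyTable2x2(0, 0, 5, 5))

    def test_invariant_under_row_and_column_swap(self):
        t = ContingencyTable2x2(21, 19, 5, 35)
        swapped = ContingencyTable2x2(35, 5, 19, 21)   # both rows and columns
        assert chisq_2x2(t).p_value == pytest.approx(chisq_2x2(swapped).p_value)


def enumerate_fisher(a, b, c, d):
    """Oracle: full enumeration over all tables with the observed margins."""
    from scipy.stats import hypergeom

    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, n, r1, c1)
    return float(pmf[pmf <= pmf[a - lo] * (1 + 1e-9)].sum())


class TestFisher:
    def test_diagonal_two_by_two(self):
        # enumeration: a in {0,1,2} with probs 1/6, 4/6, 1/6; two-sided 2/6
        assert fisher_exact_2x2(ContingencyTable2x2(2, 0, 0, 2)).p_value \
            == pytest.approx(1 / 3)

    def test_antidiagonal_matches_enumeration(self):
        res = fisher_exact_2x2(ContingencyTable2x2(0, 5, 5, 0))
        assert res.p_value == pytest.approx(enumerate_fisher(0, 5, 5, 0))

    def test_balanced_table_is_mode(self):
        assert fisher_exact_2x2(ContingencyTable2x2(3, 3, 3, 3)).p_value == 1

    @given(st.tuples(*[st.integers(0, 8)] * 4).filter(lambda t: sum(t) >= 1))
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d)).p_value
        assert min(p, 1.0) == pytest.approx(enumerate_fisher(a, b, c, d), abs=1e-12)

    def test_invariant_under_simultaneous_swap(self):
        p1 = fisher_exact_2x2(ContingencyTable2x2(7, 2, 3, 9)).p_value
        p2 = fisher_exact_2x2(ContingencyTable2x2(9, 3, 2, 7)).p_value
        assert p1 == pytest.approx(p2)


class TestPairedTests:
    def test_constant_shift(self):
        x = np.arange(5.0)
        with pytest.raises(DegenerateDataError):
            paired_tests(x + 1, x, method="paired_t")
        res = paired_tests(x + 1, x, method="wilcoxon_signed_rank")
        assert res.p_value == pytest.approx(0.0625)   # exact minimum at n = 5

    def test_identical_samples_signed_rank(self):
        x = np.arange(6.0)
        assert paired_tests(x, x, method="wilcoxon_signed_rank").p_value == 1.0

    def test_paired_t_matches_closed_form(self, rng):
        x = rng.normal(1, 1, size=10)
        y = rng.normal(0, 1, size=10)
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        res = paired_tests(x, y, method="paired_t")
        assert res.statistic == pytest.approx(t_hand, abs=1e-10)
        from scipy.stats import t as tdist

        assert res.p_value == pytest.approx(2 * tdist.sf(abs(t_hand), 9), abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            paired_tests([1, 2], [2, 3])


class TestPearson:
    def test_perfect_positive_and_negative(self, rng):
        x = rng.normal(size=10)
        assert pearson_r(x, 2 * x).estimate == pytest.approx(1.0)
        assert pearson_r(x, -x).estimate == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            pearson_r([1, 1, 1, 1], [1, 2, 3, 4])


class TestLog2fcCorrelation:
    def make(self, t_a, n_a, t_b, n_b):
        import pandas as pd

        cols = [f"p{i}" for i in range(len(t_a))]
        t = LabeledMatrix(values=pd.DataFrame([t_a, t_b], index=["A", "B"], columns=cols))
        n = LabeledMatrix(values=pd.DataFrame([n_a, n_b], index=["A", "B"], columns=cols))
        return t, n

    def test_proportional_fold_changes_correlate_perfectly(self, rng):
        normal = rng.uniform(5, 10, size=10)
        fa = rng.normal(0, 1, size=10)
        t, n = self.make(normal * 2.0**fa, normal, normal * 2.0 ** (0.5 * fa), normal)
        res = log2fc_correlation(t, n, "A", "B")
        assert res.estimate == pytest.approx(1.0)

    def test_zero_expression_pair_dropped(self, rng):
        normal = rng.uniform(5, 10, size=10)
        tumor = rng.uniform(5, 10, size=10)
        n_b = normal.copy()
        n_b[0] = 0.0
        t, n = self.make(tumor, normal, tumor, n_b)
        with pytest.warns(UserWarning, match="dropped"):
            res = log2fc_correlation(t, n, "A", "B")
        assert res.n == 9

    def test_too_few_usable_pairs(self):
        t, n = self.make([1, 2, 3], [1, 1, 1], [1, 2, 3], [0, 0, 1])
        with pytest.warns(UserWarning):
            with pytest.raises(InsufficientDataError):
                log2fc_correlation(t, n, "A", "B")


class TestKmLogrank:
    def test_identical_groups_null(self):
        base = [(1.0, True), (2.0, True), (3.0, False), (4.0, True)]
        records = [
            SurvivalRecord(time=t, event=e, group=g)
            for g in ("a", "b") for t, e in base
        ]
        res, curves = km_logrank(records)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        for curve in curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] <= 1.0 and np.all(np.diff(s) <= 1e-12)

    def test_textbook_hand_computation(self):
        """6-subject example, no censoring, all event times distinct:
        O-E and the hypergeometric variance accumulated by hand."""
        records = [
            SurvivalRecord(1.0, True, "a"), SurvivalRecord(2.0, True, "a"),
            SurvivalRecord(4.0, True, "a"), SurvivalRecord(3.0, True, "b"),
            SurvivalRecord(5.0, True, "b"), SurvivalRecord(6.0, True, "b"),
        ]
        # time 1: n=6, na=3, d=1 -> e=0.5, v=0.25      (O_a=1)
        # time 2: n=5, na=2, d=1 -> e=0.4, v=0.24      (O_a=1)
        # time 3: n=4, na=1, d=1 -> e=0.25, v=0.1875   (O_a=0)
        # time 4: n=3, na=1, d=1 -> e=1/3, v=2/9       (O_a=1)
        # time 5: n=2, na=0, d=1 -> e=0,   v=0
        # time 6: n=1, na=0, d=1 -> e=0,   v=0
        o_minus_e = (1 - 0.5) + (1 - 0.4) + (0 - 0.25) + (1 - 1 / 3)
        var = 0.25 + 0.24 + 0.1875 + 2 / 9
        res, _ = km_logrank(records)
        assert res.statistic == pytest.approx(o_minus_e**2 / var, abs=1e-10)

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines.statistics import logrank_test

        ta, tb = rng.exponential(10, 30), rng.exponential(15, 25)
        ea, eb = rng.random(30) < 0.7, rng.random(25) < 0.7
        mine = logrank_arrays(ta, ea, tb, eb)
        ref = logrank_test(ta, tb, ea, eb)
        assert mine.statistic == pytest.approx(float(ref.test_statistic), abs=1e-9)
        assert mine.p_value == pytest.approx(float(ref.p_value), abs=1e-12)

    def test_curves_start_at_one_nonincreasing(self, rng):
        records = [
            SurvivalRecord(float(t), bool(e), "a" if i % 2 else "b")
            for i, (t, e) in enumerate(zip(rng.exponential(5, 40), rng.random(40) < 0.6))
        ]
        _res, curves = km_logrank(records)
        for curve in curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0) or curve["time"].iloc[0] == 0
            assert np.all(np.diff(s) <= 1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(DomainError):
            km_logrank([SurvivalRecord(1.0, True, "a")])


class TestBhFdr:
    def test_hand_computed_step_up(self):
        # 0.01*3/1, 0.02*3/2, 0.03*3/3 then monotonized -> all 0.03
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.42]) == pytest.approx([0.42])

    def test_domain_check(self):
        with pytest.raises(DomainError):
            bh_fdr([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_at_least_raw_and_capped(self, ps):
        adj = bh_fdr(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_permutation_equivariant(self, ps):
        perm = np.random.RandomState(0).permutation(len(ps))
        adj = bh_fdr(ps)
        adj_perm = bh_fdr(np.asarray(ps)[perm])
        assert adj_perm == pytest.approx(adj[perm])


class TestTumorVolume:
    def test_formula(self):
        assert tumor_volume(10, 6) == pytest.approx(180.0)

    def test_swapped_diameters_warn(self):
        with pytest.warns(UserWarning, match="swapped"):
            assert tumor_volume(6, 10) == pytest.approx(180.0)

    def test_equal_diameters(self):
        assert tumor_volume(4, 4) == pytest.approx(0.5 * 4**3)

    def test_non_positive_rejected(self):
        with pytest.raises(DomainError):
            tumor_volume(0, 1)


def test_p_value_domain_enforced():
    from crcscreen import assoc_stats

    with pytest.raises(DomainError):
        assoc_stats.TestResult(statistic=1.0, p_value=1.5)
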