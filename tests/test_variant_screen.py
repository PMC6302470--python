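import numpy as np
import pytest
from Bio.Seq import Seq

from crcscreen.errors import (
    DegenerateDataError,
    DomainError,
    PairingError,
    ParseError,
)
from crcscreen.io_formats import TranscriptModel, VariantRecord
from crcscreen.variant_screen import (
    Consequence,
    FilterConfig,
    TranscriptIndex,
    apply_lof_filters,
    call_somatic,
    cds_position,
    classify_consequence,
    parse_protein_change,
    summarize_cohort,
)

from conftest import make_variant


class TestProteinChange:
    @pytest.mark.parametrize(
        "notation,ref,pos,alt,kind",
        [
            ("p. R174*", "R", 174, "*", Consequence.NONSENSE),
            ("p. D183G", "D", 183, "G", Consequence.MISSENSE),
            ("p. G384G", "G", 384, "G", Consequence.SYNONYMOUS),
            ("p. V289 M", "V", 289, "M", Consequence.MISSENSE),
            ("p.K223D", "K", 223, "D", Consequence.MISSENSE),
            ("p.E179*", "E", 179, "*", Consequence.NONSENSE),
        ],
    )
    def test_parses_printed_notation(self, notation, ref, pos, alt, kind):
        pc = parse_protein_change(notation)
        assert (pc.ref_aa, pc.position, pc.alt_aa, pc.kind) == (ref, pos, alt, kind)

    @pytest.mark.parametrize("bad", ["R174*", "p.174R*", "p.R*", "p. Rx74G"])
    def test_unparseable_echoes_input(self, bad):
        with pytest.raises(ParseError, match="parse"):
            parse_protein_change(bad)


class TestCdsPosition:
    def test_first_base_plus_strand(self, plus_model):
        pos, frac = cds_position(make_variant(pos=101), plus_model)
        assert pos == 1 and frac == pytest.approx(0.01)

    def test_minus_strand_counts_from_high_coordinate(self, minus_model):
        pos, _ = cds_position(make_variant(pos=200), minus_model)
        assert pos == 1
        pos, frac = cds_position(make_variant(pos=101), minus_model)
        assert pos == 100 and frac == pytest.approx(1.0)

    def test_hand_count_across_intron(self, two_segment_model):
        # segment 101-160 contributes 60 coding bases; 301 is base 61
        pos, frac = cds_position(make_variant(pos=301), two_segment_model)
        assert pos == 61 and frac == pytest.approx(0.61)

    def test_outside_cds_is_absent(self, two_segment_model):
        assert cds_position(make_variant(pos=250), two_segment_model) == (None, None)

    def test_empty_cds_is_degenerate(self):
        m = TranscriptModel(gene_id="g", transcript_id="t", chrom="chr1",
                            strand="+", cds_segments=())
        with pytest.raises(DegenerateDataError):
            cds_position(make_variant(pos=5), m)

    def test_strand_symmetry(self, plus_model, minus_model):
        """- strand position equals L + 1 - (+ strand position) at every base."""
        for g in range(101, 201):
            p_plus, _ = cds_position(make_variant(pos=g), plus_model)
            p_minus, _ = cds_position(make_variant(pos=g), minus_model)
            assert p_minus == plus_model.cds_length + 1 - p_plus


def brute_force_consequence(cds, cds_pos, alt_base):
    """Oracle: mutate the full CDS, translate both proteins entirely, and
    compare — independent of the codon-local classifier path."""
    mutated = cds[: cds_pos - 1] + alt_base + cds[cds_pos:]
    p_ref = str(Seq(cds).translate())
    p_alt = str(Seq(mutated).translate())
    if p_ref == p_alt:
        return Consequence.SYNONYMOUS
    i = next(k for k in range(len(p_ref)) if p_ref[k] != p_alt[k])
    return Consequence.NONSENSE if p_alt[i] == "*" else Consequence.MISSENSE


class TestClassifyConsequence:
    def test_stop_gain(self, plus_model, rng):
        cds = "ATG" + "CGA" * 32 + "TAA"   # length 102? -> use model of length 100
        model = TranscriptModel(gene_id="g", transcript_id="t", chrom="chr1",
                                strand="+", cds_segments=((101, 202),))
        # codon 2 is CGA (Arg); C->T at its first base gives TGA (stop)
        v = make_variant(pos=104, ref="C", alt="T")
        assert classify_consequence(v, model, cds) == Consequence.NONSENSE

    def test_one_bp_deletion_is_frameshift(self, plus_model):
        cds = "A" * 100
        v = make_variant(pos=150, ref="AA", alt="A")
        assert classify_consequence(v, plus_model, cds) == Consequence.FRAMESHIFT

    def test_inframe_deletion_is_other(self, plus_model):
        cds = "A" * 100
        v = make_variant(pos=150, ref="AAAA", alt="A")
        assert classify_consequence(v, plus_model, cds) == Consequence.OTHER

    def test_splice_window_boundary(self, two_segment_model):
        cds = "A" * 100
        one_past = make_variant(pos=161, ref="G", alt="A")
        three_past = make_variant(pos=163, ref="G", alt="A")
        assert classify_consequence(one_past, two_segment_model, cds) \
            == Consequence.CANONICAL_SPLICE
        assert classify_consequence(three_past, two_segment_model, cds) \
            == Consequence.NONCODING

    def test_length_mismatch_rejected(self, plus_model):
        with pytest.raises(DomainError):
            classify_consequence(make_variant(), plus_model, "ATG")

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_agrees_with_whole_protein_oracle(self, strand, rng):
        """Every substitution of a 300-bp CDS matches translate-and-compare,
        on both strands (two-segment model)."""
        from crcscreen.synthetic_data import _NONSTOP_CODONS

        idx = rng.integers(0, len(_NONSTOP_CODONS), size=100)
        cds = "".join(_NONSTOP_CODONS[i] for i in idx)
        model = TranscriptModel(
            gene_id="g", transcript_id="t", chrom="chr1", strand=strand,
            cds_segments=((1001, 1150), (2001, 2150)),
        )
        comp = str.maketrans("ACGT", "TGCA")
        checked = 0
        for cds_pos in range(1, 301):
            ref_cds = cds[cds_pos - 1]
            from crcscreen.synthetic_data import _cds_to_genomic, _genomic_base

            gpos = _cds_to_genomic(model, cds_pos)
            for alt_cds in "ACGT":
                if alt_cds == ref_cds:
                    continue
                g_ref = ref_cds if strand == "+" else ref_cds.translate(comp)
                g_alt = alt_cds if strand == "+" else alt_cds.translate(comp)
                v = make_variant(pos=gpos, ref=g_ref, alt=g_alt)
                got = classify_consequence(v, model, cds)
                assert got == brute_force_consequence(cds, cds_pos, alt_cds)
                checked += 1
        assert checked == 900


class TestFilters:
    def make_index(self, plus_model):
        return TranscriptIndex([plus_model])

    def test_quality_boundary(self, plus_model):
        idx = self.make_index(plus_model)
        fail, ok = apply_lof_filters(
            [make_variant(quality=99.0), make_variant(quality=100.0)], idx
        )
        assert fail.failed_criteria == {"quality"} and not fail.retained
        assert ok.retained

    def test_depth_closed_interval(self, plus_model):
        idx = self.make_index(plus_model)
        decisions = apply_lof_filters(
            [make_variant(depth=d) for d in (9, 10, 200, 201, None)], idx
        )
        assert [d.retained for d in decisions] == [False, True, True, False, False]
        assert decisions[0].failed_criteria == {"depth"}

    def test_cds_tail_strict_boundary(self, plus_model):
        idx = self.make_index(plus_model)
        at_95 = make_variant(pos=195)     # fraction exactly 0.95 -> kept
        past_95 = make_variant(pos=196)   # fraction 0.96 -> removed
        keep, drop = apply_lof_filters([at_95, past_95], idx)
        assert keep.retained
        assert drop.failed_criteria == {"cds_tail"}

    def test_all_failures_accumulate(self, plus_model):
        idx = self.make_index(plus_model)
        v = make_variant(pos=196, quality=10.0, depth=5, is_known=True)
        (d,) = apply_lof_filters([v], idx)
        assert d.failed_criteria == {"known_variant", "quality", "depth", "cds_tail"}

    def test_no_covering_model_fails_positional_criterion(self, plus_model):
        idx = self.make_index(plus_model)
        (d,) = apply_lof_filters([make_variant(chrom="chrX")], idx)
        assert d.failed_criteria == {"cds_tail"}

    def test_longest_cds_model_selected(self):
        short = TranscriptModel(gene_id="g", transcript_id="t.short", chrom="chr1",
                                strand="+", cds_segments=((101, 150),))
        long = TranscriptModel(gene_id="g", transcript_id="t.long", chrom="chr1",
                               strand="+", cds_segments=((101, 300),))
        # pos 149 is fraction 0.98 under the short model but 0.245 under the
        # long one; the longest-CDS policy keeps the variant
        (d,) = apply_lof_filters([make_variant(pos=149)], TranscriptIndex([short, long]))
        assert d.retained

    def test_idempotent_on_retained_set(self, plus_model, rng):
        idx = self.make_index(plus_model)
        variants = [
            make_variant(
                pos=int(rng.integers(101, 201)),
                quality=float(rng.integers(50, 200)),
                depth=int(rng.integers(1, 300)),
                is_known=bool(rng.random() < 0.3),
            )
            for _ in range(100)
        ]
        retained = [d.variant for d in apply_lof_filters(variants, idx) if d.retained]
        again = [d.variant for d in apply_lof_filters(retained, idx) if d.retained]
        assert again == retained

    def test_config_validation(self):
        with pytest.raises(DomainError):
            FilterConfig(cds_tail_fraction=1.5)
        with pytest.raises(DomainError):
            FilterConfig(depth_min=50, depth_max=10)


class TestSomatic:
    def test_germline_excluded_somatic_kept(self):
        shared = make_variant(pos=110)
        tumor_only = make_variant(pos=120)
        out = call_somatic([shared, tumor_only], [shared])
        assert out == [tumor_only]

    def test_somatic_set_algebra(self):
        t = [make_variant(pos=p) for p in (110, 120, 130)]
        assert call_somatic(t, []) == t
        assert call_somatic(t, t) == []
        assert call_somatic([], t) == []

    def test_subset_and_order_preserved(self, rng):
        t = [make_variant(pos=int(p)) for p in rng.choice(range(101, 200), 30, replace=False)]
        n = t[::3]
        out = call_somatic(t, n)
        assert set(v.key for v in out) <= set(v.key for v in t)
        assert out == [v for v in t if v not in n]

    def test_mismatched_individuals_rejected(self):
        t = [make_variant(sample_id="P1-T")]
        n = [make_variant(sample_id="P2-N")]
        with pytest.raises(PairingError):
            call_somatic(t, n)

    def test_tumor_normal_suffixes_accepted(self):
        t = [make_variant(pos=110, sample_id="P1-T")]
        n = [make_variant(pos=120, sample_id="P1-N")]
        assert call_somatic(t, n) == t


class TestCohortSummary:
    def test_printed_case_series(self):
        """3 nonsense + 4 missense + 1 synonymous in 8 of 104 samples gives
        7.7% frequency and 37.5% truncating fraction."""
        from crcscreen.datasets import BMP5_COHORT_SIZE, BMP5_MUTATIONS

        mutations = [
            (sample, parse_protein_change(notation).kind)
            for sample, notation in BMP5_MUTATIONS
        ]
        s = summarize_cohort(mutations, BMP5_COHORT_SIZE)
        assert s.n_mutated_samples == 8
        assert s.mutation_frequency == pytest.approx(8 / 104)
        assert round(100 * s.mutation_frequency, 1) == 7.7
        assert s.truncating_fraction == pytest.approx(0.375)

    def test_empty_cohort(self):
        s = summarize_cohort([], 10)
        assert s.mutation_frequency == 0 and s.truncating_fraction is None

    def test_two_frameshifts_one_sample(self):
        s = summarize_cohort(
            [("s1", Consequence.FRAMESHIFT), ("s1", Consequence.FRAMESHIFT)], 10
        )
        assert s.mutation_frequency == pytest.approx(0.10)
        assert s.truncating_fraction == 1.0

    def test_zero_samples_rejected(self):
        with pytest.raises(DomainError):
            summarize_cohort([], 0)
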