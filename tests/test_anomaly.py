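from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endosift.anomaly import (
    FeatureTestResult,
    fdr_adjust,
    feature_tables,
    fisher_exact,
    partition_reads,
    run_battery,
)
from endosift.calling import SampleCounts, VariantCandidate
from endosift.io_core import SymbiontGenome
from tests.conftest import reads_from_specs


def _rational_fisher(a, b, c, d):
    """Exact two-sided Fisher by full enumeration with integer weights."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return Fraction(1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = comb(r1, a) * comb(r2, c)
    total = sum(
        comb(r1, x) * comb(r2, c1 - x)
        for x in range(lo, hi + 1)
        if comb(r1, x) * comb(r2, c1 - x) <= obs
    )
    return Fraction(total, comb(n, c1))


class TestFisherExact:
    def test_balanced_table_is_one(self):
        assert fisher_exact(((5, 5), (5, 5))) == 1.0

    def test_fully_separated_table(self):
        # 2 equally extreme tables out of C(20,10) with all margins 10
        expected = Fraction(2, 184756)
        assert fisher_exact(((10, 0), (0, 10))) == pytest.approx(float(expected), rel=1e-9)

    def test_zero_margin_convention(self):
        assert fisher_exact(((0, 0), (3, 7))) == 1.0
        assert fisher_exact(((0, 3), (0, 7))) == 1.0

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(*[st.integers(0, 10)] * 4))
    def test_matches_rational_enumeration(self, cells):
        a, b, c, d = cells
        p = fisher_exact(((a, b), (c, d)))
        exact = float(_rational_fisher(a, b, c, d))
        assert p == pytest.approx(exact, rel=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_group_swap_symmetry(self, cells):
        a, b, c, d = cells
        assert fisher_exact(((a, b), (c, d))) == pytest.approx(
            fisher_exact(((c, d), (a, b))), rel=1e-12
        )

    def test_agrees_with_scipy_on_random_tables(self):
        from scipy.stats import fisher_exact as scipy_fisher

        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 50, 4)
            ours = fisher_exact(((a, b), (c, d)))
            theirs = scipy_fisher([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(theirs, rel=1e-8)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(((-1, 2), (3, 4)))


class TestFdrAdjust:
    def test_step_up_worked_example(self):
        out = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert np.allclose(fdr_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_single_value_unchanged(self):
        assert fdr_adjust([0.03]) == pytest.approx([0.03])

    def test_empty_input(self):
        assert fdr_adjust([]).size == 0

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.random(100)
        assert np.all(fdr_adjust(p) >= p - 1e-12)


def _snp(genome, pos, ref, alt):
    c = VariantCandidate(genome.name, pos, ref, alt, {"t": SampleCounts(10, 5)})
    c.record("called", True)
    return c


class TestPartitionReads:
    def test_plain_reference_read(self, flat_genome):
        pos = 100
        ref = flat_genome.sequence[pos]
        alt = "A" if ref != "A" else "C"
        rs = reads_from_specs(flat_genome, [(50, flat_genome.sequence[50:150])])
        part = partition_reads({"t": rs}, _snp(flat_genome, pos, ref, alt), flat_genome)
        g = part.ref_group
        assert (g.n, g.clipped, g.proper, g.mismatch_bases) == (1, 0, 1, 0)
        assert part.alt_group.n == 0 and not part.testable

    def test_clipped_alt_read_excludes_focal_mismatch(self, flat_genome):
        pos = 100
        ref = flat_genome.sequence[pos]
        alt = "A" if ref != "A" else "C"
        # 10S90M read carrying the alt plus two extra mismatches
        seq = list(flat_genome.sequence[40:140])
        seq[pos - 40] = alt
        for off in (70, 80):  # inside the aligned segment
            seq[off] = "A" if seq[off] != "A" else "G"
        rs = reads_from_specs(flat_genome, [(40, "".join(seq), {"left_clip": 10})])
        part = partition_reads({"t": rs}, _snp(flat_genome, pos, ref, alt), flat_genome)
        g = part.alt_group
        assert g.n == 1 and g.clipped == 1
        assert g.mismatch_bases == 2  # focal site excluded

    def test_deletion_spanning_site_is_unassigned(self, flat_genome):
        pos = 100
        ref = flat_genome.sequence[pos]
        alt = "A" if ref != "A" else "C"
        # reference projection pads deleted columns, so the read has no
        # base at the focal site
        seq = flat_genome.sequence[90:100] + "N" + flat_genome.sequence[101:120]
        rs = reads_from_specs(flat_genome, [(90, seq)])
        rs.codes[0, 10] = 255  # deleted column
        part = partition_reads({"t": rs}, _snp(flat_genome, pos, ref, alt), flat_genome)
        assert part.ref_group.n == 0 and part.alt_group.n == 0

    def test_third_allele_belongs_to_neither_group(self, flat_genome):
        pos = 100
        ref = flat_genome.sequence[pos]
        others = [b for b in "ACGT" if b != ref]
        seq = list(flat_genome.sequence[80:130])
        seq[20] = others[1]
        rs = reads_from_specs(flat_genome, [(80, "".join(seq))])
        part = partition_reads({"t": rs}, _snp(flat_genome, pos, ref, others[0]), flat_genome)
        assert part.ref_group.n == 0 and part.alt_group.n == 0


class TestDecision:
    def _run(self, ps, alpha=0.05):
        results = [
            FeatureTestResult("c", f, ((1, 1), (1, 1)), p, p_adjusted=p)
            for f, p in zip(("clipped", "proper_pair", "mismatch"), ps)
        ]
        return [r.feature for r in results if r.p_adjusted < alpha]

    def test_any_feature_rule(self):
        assert self._run((0.2, 0.9, 0.7)) == []
        assert self._run((0.2, 0.04, 0.7)) == ["proper_pair"]

    def test_battery_excludes_biased_artifact_and_keeps_true_variant(self, small_result):
        from endosift.calling import naive_call, support_filter

        res = small_result
        cands = naive_call(res.tissues, res.genome)
        live = support_filter(cands)
        truth = res.truth
        intervals = truth.insert_intervals()
        live = [
            c for c in live
            if not any(s <= c.position < e for s, e in intervals)
        ]
        retained, results = run_battery(live, res.tissues, res.genome)
        retained_pos = {c.position for c in retained}
        assert truth.true_variants[0].position in retained_pos
        assert truth.artifacts[0].position not in retained_pos

    def test_untestable_candidate_retained_with_flag(self, flat_genome):
        # site with zero coverage: neither group populated
        from endosift.alignments import ReadSet

        rs = ReadSet.empty("ref", len(flat_genome))
        rs.ref_codes = flat_genome.codes
        c = _snp(flat_genome, 10, flat_genome.sequence[10], "A" if flat_genome.sequence[10] != "A" else "C")
        retained, results = run_battery([c], {"t": rs}, flat_genome)
        assert retained == [c]
        assert "untestable" in c.flags
        assert results == []

    def test_mismatch_read_mode_table(self):
        from endosift.anomaly import AlleleGroup, AllelePartition

        part = AllelePartition(
            "c",
            AlleleGroup(10, 1, 10, 5, 900, 4),
            AlleleGroup(5, 2, 5, 30, 450, 5),
        )
        base = feature_tables(part, "base")["mismatch"]
        read = feature_tables(part, "read")["mismatch"]
        assert base == ((5, 895), (30, 420))
        assert read == ((4, 6), (5, 0))
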