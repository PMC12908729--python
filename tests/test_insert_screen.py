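import numpy as np
import pytest
from scipy.stats import binom

from endosift.calling import SampleCounts, VariantCandidate
from endosift.insert_screen import (
    apply_exclusion_list,
    count_uninfected_reads,
    screen,
    screen_window,
)
from tests.conftest import reads_from_specs


def _cand(pos, ref="A", alt="C"):
    c = VariantCandidate("ref", pos, ref, alt, {"t": SampleCounts(500, 50)})
    c.record("called", True)
    c.record("support_filter", True)
    return c


class TestCountUninfectedReads:
    def test_no_reads_anywhere(self, flat_genome):
        from endosift.alignments import ReadSet

        empty = ReadSet.empty("ref", len(flat_genome))
        assert count_uninfected_reads((0, 300), [empty]) == 0

    def test_read_abutting_window_not_counted(self, flat_genome):
        # aligned end == window start: zero overlap under half-open logic
        rs = reads_from_specs(flat_genome, [(250, flat_genome.sequence[250:300])])
        assert count_uninfected_reads((300, 600), [rs]) == 0
        assert count_uninfected_reads((299, 599), [rs]) == 1

    def test_pooled_across_samples(self, flat_genome):
        r1 = reads_from_specs(flat_genome, [(100, flat_genome.sequence[100:150])])
        r2 = reads_from_specs(flat_genome, [(120, flat_genome.sequence[120:170])])
        assert count_uninfected_reads((90, 390), [r1, r2]) == 2

    def test_simulated_insert_occupancy_within_binomial_bounds(self, small_result):
        ins = small_result.truth.inserts[0]
        pos = (ins.start + ins.end) // 2
        design = small_result.design
        win = screen_window(pos, len(small_result.genome), True)
        count = count_uninfected_reads(win, small_result.uninfected.values())
        # oracle recount from the simulated read coordinates
        oracle = 0
        for rs in small_result.uninfected.values():
            starts, spans = rs.aligned_start, rs.span
            oracle += int(((starts < win[1]) & (starts + spans > win[0])).sum())
        assert count == oracle
        # expected reads in a 300-bp window at the design's uninfected coverage
        rate = design.uninfected_coverage * design.uninfected_sample_count
        n_expected = rate * (win[1] - win[0] + design.read_length) / design.read_length
        assert binom.ppf(5e-4, int(3 * n_expected), 1 / 3) <= count
        assert count <= binom.ppf(1 - 5e-4, int(3 * n_expected), 1 / 3)


class TestScreen:
    @pytest.mark.parametrize("n_reads,kept", [(0, True), (1, True), (2, False), (5, False)])
    def test_threshold_of_two_reads(self, flat_genome, n_reads, kept):
        reads = [(140, flat_genome.sequence[140:190])] * n_reads
        rs = reads_from_specs(flat_genome, reads) if reads else None
        readsets = {"u": rs} if rs else {}
        out = screen([_cand(150)], readsets)
        assert (len(out) == 1) is kept

    def test_monotone_in_threshold(self, flat_genome):
        rs = reads_from_specs(flat_genome, [(140, flat_genome.sequence[140:190])] * 3)
        for lo, hi in [(2, 3), (3, 4), (4, 10)]:
            out_lo = screen([_cand(150)], {"u": rs}, threshold=lo)
            out_hi = screen([_cand(150)], {"u": rs}, threshold=hi)
            # increasing the threshold never excludes more candidates
            assert len(out_hi) >= len(out_lo)

    def test_circular_window_wraps(self, small_result):
        # a candidate near the origin still sees reads on the other side
        start, end = screen_window(10, len(small_result.genome), True)
        assert start < 0 and end - start == 300


class TestExclusionList:
    def test_empty_list_is_identity(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("reference\tposition\tref\talt\n")
        cands = [_cand(5), _cand(9)]
        for c in cands:
            c.record("insert_screen", True)
        kept, unmatched = apply_exclusion_list(cands, path)
        assert len(kept) == 2 and unmatched == []

    def test_named_candidate_is_excluded(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("ref\t10\tA\tC\n")  # 1-based position 10 = 0-based 9
        cands = [_cand(5), _cand(9), _cand(20)]
        for c in cands:
            c.record("insert_screen", True)
        kept, unmatched = apply_exclusion_list(cands, path)
        assert [c.position for c in kept] == [5, 20]
        assert unmatched == []

    def test_unmatched_row_reported_not_fatal(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("ref\t999\tA\tC\n")
        c = _cand(5)
        c.record("insert_screen", True)
        kept, unmatched = apply_exclusion_list([c], path)
        assert len(kept) == 1 and len(unmatched) == 1

    def test_malformed_row_rejected(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("ref\tnot_a_number\tA\tC\n")
        with pytest.raises(ValueError, match="not an integer"):
            apply_exclusion_list([], path)
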