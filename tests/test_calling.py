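import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endosift.calling import (
    SampleCounts,
    VariantCandidate,
    naive_call,
    support_filter,
)
from endosift.io_core import SymbiontGenome
from endosift.synthetic_data import SimulationDesign, TissueSpec, simulate
from tests.conftest import reads_from_specs


def _column_readset(genome, position, depth, alt, alt_base):
    """Reads of length 1 covering one column with given ref/alt split."""
    ref_base = genome.sequence[position]
    specs = [(position, ref_base) for _ in range(depth - alt)]
    specs += [(position, alt_base) for _ in range(alt)]
    return reads_from_specs(genome, specs)


class TestNaiveCall:
    @pytest.mark.parametrize(
        "depth,alt,expected",
        [
            (500, 0, 0),    # nothing but reference
            (500, 25, 1),   # fraction 0.05 >= F
            (500, 10, 0),   # fraction 0.02 < F
        ],
    )
    def test_minimum_fraction_threshold(self, flat_genome, depth, alt, expected):
        ref = flat_genome.sequence[100]
        alt_base = "A" if ref != "A" else "C"
        rs = _column_readset(flat_genome, 100, depth, alt, alt_base)
        cands = naive_call({"s": rs}, flat_genome, min_fraction=0.03)
        assert len(cands) == expected
        if expected:
            c = cands[0]
            assert (c.position, c.ref, c.alt) == (100, ref, alt_base)
            assert c.samples["s"].depth == depth and c.samples["s"].alt == alt

    def test_any_sample_suffices(self, flat_genome):
        ref = flat_genome.sequence[50]
        alt_base = "G" if ref != "G" else "T"
        high = _column_readset(flat_genome, 50, 200, 20, alt_base)
        low = _column_readset(flat_genome, 50, 200, 1, alt_base)
        cands = naive_call({"a": low, "b": high}, flat_genome)
        assert len(cands) == 1
        assert cands[0].samples["a"].alt == 1  # counts reported for all samples

    def test_matches_brute_force_pileup_oracle(self):
        design = SimulationDesign(
            seed=21, genome_length=4_000, homolog_separation=1_000,
            homolog_length=200, insert_count=0, uninfected_sample_count=0,
            host_contamination_coverage=0.0,
            tissues=(TissueSpec("t1", 80.0),),
            true_variants=(), artifacts=(), base_error_rate=0.01,
        )
        res = simulate(design)
        rs = res.tissues["t1"]
        genome = res.genome
        # brute force: count bases per column read by read
        L = len(genome)
        counts = np.zeros((4, L), dtype=np.int64)
        for i in range(rs.n):
            lo, hi = int(rs.left_clip[i]), int(rs.qlen[i] - rs.right_clip[i])
            for j in range(lo, hi):
                pos = int((rs.qstart[i] + j) % L)
                code = int(rs.codes[i, j])
                if code <= 3:
                    counts[code, pos] += 1
        depth = counts.sum(axis=0)
        expected = set()
        for pos in range(L):
            if depth[pos] == 0:
                continue
            for code in range(4):
                if code == genome.codes[pos]:
                    continue
                if counts[code, pos] > 0 and counts[code, pos] / depth[pos] >= 0.03:
                    expected.add((pos, code))
        got = {(c.position, "ACGT".index(c.alt)) for c in naive_call({"t1": rs}, genome)}
        assert got == expected

    def test_error_floor_produces_no_candidates(self):
        # at depth ~300 and error rate 1e-3, per-base alt counts stay far
        # below the 3% floor, so a variant-free genome yields no calls
        design = SimulationDesign(
            seed=22, genome_length=20_000, homolog_separation=3_000,
            homolog_length=300, insert_count=0, uninfected_sample_count=0,
            host_contamination_coverage=0.0,
            tissues=(TissueSpec("t1", 300.0),),
            true_variants=(), artifacts=(),
        )
        res = simulate(design)
        assert naive_call(res.tissues, res.genome) == []


def _cand(per_sample):
    c = VariantCandidate(
        "sym", 10, "A", "C", {k: SampleCounts(d, a) for k, (d, a) in per_sample.items()}
    )
    c.record("called", True)
    return c


class TestSupportFilter:
    def test_retained_when_one_tissue_passes(self):
        kept = support_filter([_cand({"t1": (250, 12), "t2": (50, 1)})])
        assert len(kept) == 1

    def test_depth_exactly_200_is_excluded(self):
        # the depth requirement is strictly "over 200"
        assert support_filter([_cand({"t1": (200, 50)})]) == []

    def test_insufficient_alt_reads_everywhere(self):
        assert support_filter([_cand({"t1": (1000, 9), "t2": (900, 9)})]) == []

    def test_all_tissue_scope(self):
        c = _cand({"t1": (250, 12), "t2": (250, 2)})
        assert support_filter([c], scope="all_tissues") == []

    @settings(max_examples=50, deadline=None)
    @given(
        depth=st.integers(0, 400),
        alt_frac=st.floats(0, 1),
        d_depth=st.integers(0, 100),
        d_alt=st.integers(0, 10),
    )
    def test_monotone_in_thresholds(self, depth, alt_frac, d_depth, d_alt):
        alt = int(depth * alt_frac)
        base = support_filter([_cand({"t": (depth, alt)})], 200, 10)
        stricter = support_filter([_cand({"t": (depth, alt)})], 200 + d_depth, 10 + d_alt)
        # raising thresholds never retains a previously excluded candidate
        assert len(stricter) <= len(base)

    def test_trail_is_append_only(self):
        c = _cand({"t1": (250, 12)})
        support_filter([c])
        with pytest.raises(ValueError):
            # once excluded, later stages must not touch the candidate
            excluded = _cand({"t1": (10, 1)})
            support_filter([excluded])
            excluded.record("insert_screen", True)
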