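import dataclasses

import numpy as np
import pytest

from endosift.conversion import (
    DiagnosticSite,
    HomologousPair,
    detect,
    diagnostic_allele_profile,
    find_pairs,
    read_pairs_tsv,
    unpaired_remap_check,
    write_pairs_tsv,
)
from endosift.io_core import SymbiontGenome
from endosift.synthetic_data import (
    ConversionSpec,
    SimulationDesign,
    TissueSpec,
    build_genome,
    simulate,
)


def _conv_design(seed, converted=True, **kwargs):
    base = dict(
        seed=seed,
        genome_length=30_000,
        homolog_separation=4_000,
        homolog_length=600,
        insert_count=0,
        uninfected_sample_count=0,
        host_contamination_coverage=0.0,
        tissues=(TissueSpec("pool", 400.0),),
        true_variants=(),
        artifacts=(),
        conversion=ConversionSpec(samples=("pool",)) if converted else None,
    )
    base.update(kwargs)
    return SimulationDesign(**base)


class TestFindPairs:
    def test_recovers_planted_pair_with_its_diagnostics(self):
        genome, pair, layout = build_genome(SimulationDesign(seed=31))
        found = find_pairs(genome)
        assert len(found) == 1
        p = found[0]
        # the recovered tract covers the planted one at the same offset
        assert p.b_start - p.a_start == pair.b_start - pair.a_start
        assert p.a_start <= pair.a_start and p.a_end >= pair.a_end
        planted = {(pair.a_start + s.offset, s.allele_a, s.allele_b) for s in pair.sites}
        got = {(p.a_start + s.offset, s.allele_a, s.allele_b) for s in p.sites}
        assert planted <= got
        assert len(got - planted) <= 2  # boundary context may add a difference

    def test_no_duplication_no_pairs(self):
        rng = np.random.default_rng(8)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 30_000))
        assert find_pairs(SymbiontGenome("g", seq, True)) == []

    def test_identical_tracts_reported_undetectable(self):
        rng = np.random.default_rng(9)
        codes = rng.integers(0, 4, 8_000)
        codes[5_000:5_200] = codes[1_000:1_200]
        seq = "".join("ACGT"[i] for i in codes)
        found = find_pairs(SymbiontGenome("g", seq, True))
        assert len(found) == 1
        p = found[0]
        assert p.sites == () and not p.detectable
        assert p.identity == 1.0

    def test_agrees_with_exhaustive_window_oracle(self):
        design = SimulationDesign(
            seed=33, genome_length=3_000, homolog_separation=800,
            homolog_length=400, insert_count=0,
        )
        genome, pair, layout = build_genome(design)
        found = find_pairs(genome, min_tract=100, min_identity=0.95)
        # oracle: scan every offset's mismatch track exhaustively for
        # match-bounded windows of identity >= 0.95 and length >= 100
        codes = genome.codes
        L = len(codes)
        oracle_hits = []
        for d in range(1, L):
            m = codes[: L - d] == codes[d:]
            if len(m) < 100:
                continue
            csum = np.concatenate([[0], np.cumsum(~m)])
            for s in range(len(m) - 100 + 1):
                e = s + 100
                if m[s] and m[e - 1] and (csum[e] - csum[s]) <= 5 and e - s <= d:
                    oracle_hits.append((d, s, e))
        # every oracle window overlaps a reported pair with the same offset
        # (one canonical tract is reported per overlapping cluster)
        for d, s, e in oracle_hits:
            assert any(
                p.b_start - p.a_start == d and p.a_start < e and s < p.a_end
                for p in found
            ), (d, s, e)
        # and every reported pair is corroborated by oracle windows
        for p in found:
            d = p.b_start - p.a_start
            assert any(
                hd == d and p.a_start < e and s < p.a_end for hd, s, e in oracle_hits
            )

    def test_pairs_tsv_round_trip(self, tmp_path):
        genome, pair, _ = build_genome(SimulationDesign(seed=34))
        path = tmp_path / "pairs.tsv"
        write_pairs_tsv([pair], path)
        (back,) = read_pairs_tsv(path)
        assert back == pair


class TestAlleleProfile:
    def test_unconverted_partner_fraction_bounded_by_errors(self):
        res = simulate(_conv_design(41, converted=False))
        prof = diagnostic_allele_profile(res.tissues["pool"], res.pair, "A")
        assert prof.defined
        # a partner allele can only arise from a base error hitting the
        # diagnostic site (one of three wrong bases)
        assert prof.partner_fraction <= 3 * res.design.base_error_rate

    def test_converted_partner_fraction_high(self):
        res = simulate(_conv_design(42, converted=True))
        prof = diagnostic_allele_profile(res.tissues["pool"], res.pair, "A")
        assert prof.partner_fraction >= 0.95

    def test_no_reads_flagged_undefined(self):
        from endosift.alignments import ReadSet

        res = simulate(_conv_design(43, converted=False))
        empty = ReadSet.empty(res.genome.name, len(res.genome), True)
        prof = diagnostic_allele_profile(empty, res.pair, "A")
        assert not prof.defined and prof.partner_fraction is None


class TestDetect:
    def test_planted_conversion_detected_with_direction(self):
        res = simulate(_conv_design(44, converted=True))
        (call,) = detect(res.tissues["pool"], [res.pair])
        assert call.verdict == "conversion"
        assert call.direction == res.truth.conversion.direction
        assert call.acceptor_ratio <= 0.5 and call.donor_ratio >= 1.5
        assert call.donor_allele_fraction >= 0.9

    def test_unconverted_sample_no_call(self):
        res = simulate(_conv_design(45, converted=False))
        (call,) = detect(res.tissues["pool"], [res.pair])
        assert call.verdict == "none"

    def test_deletion_without_allele_switch_is_not_conversion(self):
        # drop the reads over the acceptor tract: coverage criterion (i)
        # fires, but there is no donor rise and no allele switching
        res = simulate(_conv_design(46, converted=False))
        rs = res.tissues["pool"]
        over = rs.reads_overlapping(res.pair.a_start, res.pair.a_end)
        keep = np.setdiff1d(np.arange(rs.n), over)
        (call,) = detect(rs.subset(keep), [res.pair])
        assert call.verdict == "none"
        assert call.criteria["acceptor_drop"] is True
        assert call.criteria["donor_rise"] is False
        assert call.criteria["allele_switch"] is False

    def test_pair_without_diagnostics_undetectable(self):
        res = simulate(_conv_design(47, converted=False))
        blind = dataclasses.replace(res.pair, sites=(), identity=1.0)
        (call,) = detect(res.tissues["pool"], [blind])
        assert call.verdict == "undetectable"

    def test_reciprocal_depth_shift(self):
        # acceptor deficit and donor excess mirror each other
        res = simulate(_conv_design(48, converted=True))
        (call,) = detect(res.tissues["pool"], [res.pair])
        deficit = 1.0 - call.acceptor_ratio
        excess = call.donor_ratio - 1.0
        assert excess == pytest.approx(deficit, rel=0.25)


class TestRemapCheck:
    def test_converted_reads_reassign_to_donor(self):
        res = simulate(_conv_design(49, converted=True))
        chk = unpaired_remap_check(res.tissues["pool"], res.pair, "A")
        assert chk.better_acceptor == 0
        assert chk.fraction_reassigned >= 0.99

    def test_unconverted_reads_stay(self):
        res = simulate(_conv_design(50, converted=False))
        chk = unpaired_remap_check(res.tissues["pool"], res.pair, "A")
        assert chk.better_donor <= max(3, 0.01 * chk.n_reads)

    def test_read_without_diagnostic_is_unresolved(self):
        res = simulate(_conv_design(51, converted=True))
        chk = unpaired_remap_check(res.tissues["pool"], res.pair, "A")
        # tract-overlapping reads that cover no diagnostic site exist and
        # are reported as unresolved rather than assigned
        assert chk.unresolved > 0
        assert chk.n_reads == chk.better_donor + chk.better_acceptor + chk.ties + chk.unresolved
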