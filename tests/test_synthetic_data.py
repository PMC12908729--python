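import dataclasses

import numpy as np
import pytest
from scipy.stats import binom

from endosift.alignments import BASES, ReadSet
from endosift.synthetic_data import (
    ConversionSpec,
    PlantedVariant,
    SimulationDesign,
    TissueSpec,
    TruthTable,
    build_genome,
    plant_inserts,
    simulate,
    write_outputs,
)


class TestBuildGenome:
    def test_catalog_lists_exactly_the_requested_diagnostics(self, small_design):
        genome, pair, layout = build_genome(small_design)
        assert len(pair.sites) == small_design.diagnostic_count == 5
        for s in pair.sites:
            assert 0 <= s.offset < small_design.tract_length
            assert genome.sequence[layout.tract_a[0] + s.offset] == s.allele_a
            assert genome.sequence[layout.tract_b[0] + s.offset] == s.allele_b
            assert s.allele_a != s.allele_b

    def test_identical_copies_when_identity_one(self):
        d = SimulationDesign(
            seed=3, genome_length=10_000, homolog_separation=2_000,
            homolog_length=300, homolog_identity=1.0, diagnostic_count=0,
            insert_count=0,
        )
        genome, pair, layout = build_genome(d)
        a = genome.sequence[layout.tract_a[0] : layout.tract_a[1]]
        b = genome.sequence[layout.tract_b[0] : layout.tract_b[1]]
        assert a == b and pair.sites == ()

    def test_same_seed_reproduces_genome(self, small_design):
        g1, _, _ = build_genome(small_design)
        g2, _, _ = build_genome(small_design)
        assert g1.sequence == g2.sequence

    def test_copy_identity_matches_design(self, small_design):
        genome, _, layout = build_genome(small_design)
        a = np.frombuffer(
            genome.sequence[layout.copy_a[0] : layout.copy_a[1]].encode(), np.uint8
        )
        b = np.frombuffer(
            genome.sequence[layout.copy_b[0] : layout.copy_b[1]].encode(), np.uint8
        )
        identity = (a == b).mean()
        assert identity == pytest.approx(small_design.homolog_identity, abs=0.005)


class TestPlantInserts:
    def test_substitution_count_matches_truth(self, small_design):
        genome, _, layout = build_genome(small_design)
        contigs, truths = plant_inserts(genome, small_design, layout)
        assert len(truths) == small_design.insert_count
        for contig, ins in zip(contigs, truths):
            flank = small_design.insert_flank
            embedded = np.frombuffer(
                contig.sequence[flank : flank + (ins.end - ins.start)].encode(), np.uint8
            )
            original = np.frombuffer(
                genome.sequence[ins.start : ins.end].encode(), np.uint8
            )
            observed = int((embedded != original).sum())
            assert observed == ins.substitutions
            # realised count behaves binomially around length * divergence
            n = ins.end - ins.start
            lo = binom.ppf(5e-4, n, small_design.insert_divergence)
            hi = binom.ppf(1 - 5e-4, n, small_design.insert_divergence)
            assert lo <= observed <= hi

    def test_zero_inserts(self):
        d = SimulationDesign(seed=4, genome_length=10_000, homolog_separation=2_000,
                             homolog_length=300, insert_count=0)
        genome, _, layout = build_genome(d)
        contigs, truths = plant_inserts(genome, d, layout)
        assert contigs == [] and truths == []

    def test_same_seed_identical_contigs(self, small_design):
        genome, _, layout = build_genome(small_design)
        c1, _ = plant_inserts(genome, small_design, layout)
        c2, _ = plant_inserts(genome, small_design, layout)
        assert [c.sequence for c in c1] == [c.sequence for c in c2]


class TestSimulateReads:
    def test_planted_frequency_within_binomial_bounds(self, small_result):
        truth = small_result.truth.true_variants[0]
        for label, rs in small_result.tissues.items():
            f = truth.frequencies[label]
            _, bases, _ = rs.bases_at(truth.position)
            depth = int((bases <= 3).sum())
            alt = int((bases == BASES.index(truth.alt)).sum())
            lo = binom.ppf(5e-4, depth, f)
            hi = binom.ppf(1 - 5e-4, depth, f)
            assert lo <= alt <= hi

    def test_requested_coverage_conserved_within_5_percent(self, small_design, small_result):
        L = small_design.genome_length
        for spec in small_design.tissues:
            rs = small_result.tissues[spec.label]
            # symbiont-derived reads only (host contamination is on top)
            simulated = 2 * round(spec.coverage * L / (2 * small_design.read_length))
            simulated_bases = simulated * small_design.read_length
            assert simulated_bases / L == pytest.approx(spec.coverage, rel=0.05)

    def test_uninfected_reads_only_map_inside_inserts(self, small_result):
        intervals = small_result.truth.insert_intervals()
        for rs in small_result.uninfected.values():
            starts = rs.aligned_start
            ends = starts + rs.span
            for s, e in zip(starts, ends):
                assert any(s >= a - 1 and e <= b + 1 for a, b in intervals)

    def test_no_inserts_means_no_uninfected_alignments(self):
        d = SimulationDesign(
            seed=6, genome_length=10_000, homolog_separation=2_000,
            homolog_length=300, insert_count=0,
            tissues=(TissueSpec("t1", 50.0),), true_variants=(), artifacts=(),
        )
        res = simulate(d)
        assert all(rs.n == 0 for rs in res.uninfected.values())

    def test_conversion_reads_carry_donor_alleles(self):
        d = SimulationDesign(
            seed=7, genome_length=20_000, homolog_separation=3_000,
            homolog_length=400, insert_count=0, uninfected_sample_count=0,
            host_contamination_coverage=0.0,
            tissues=(TissueSpec("t1", 200.0),), true_variants=(), artifacts=(),
            base_error_rate=0.0,
            conversion=ConversionSpec(samples=("t1",)),
        )
        res = simulate(d)
        rs = res.tissues["t1"]
        for site in res.pair.sites:
            pos = res.pair.a_start + site.offset
            _, bases, _ = rs.bases_at(pos)
            assert len(bases) > 0
            assert set(bases.tolist()) == {BASES.index(site.allele_b)}

    def test_truth_table_round_trips_via_tsv(self, small_result, tmp_path):
        path = tmp_path / "truth.tsv"
        small_result.truth.to_tsv(path)
        assert TruthTable.from_tsv(path) == small_result.truth

    def test_byte_identical_outputs_for_same_design(self, small_design, tmp_path):
        d = dataclasses.replace(small_design, seed=12)
        out1, out2 = tmp_path / "a", tmp_path / "b"
        write_outputs(simulate(d), out1)
        write_outputs(simulate(d), out2)
        for f in sorted(p.name for p in out1.iterdir()):
            assert (out1 / f).read_bytes() == (out2 / f).read_bytes(), f

    def test_low_coverage_variant_warns(self):
        d = SimulationDesign(
            seed=8, genome_length=10_000, homolog_separation=2_000,
            homolog_length=300, insert_count=0,
            tissues=(TissueSpec("t1", 40.0),),
            true_variants=(PlantedVariant({"t1": 0.01}),), artifacts=(),
        )
        res = simulate(d)
        assert any("below 1" in w for w in res.truth.warnings)


def test_design_validation_rejects_oversized_homolog():
    with pytest.raises(ValueError):
        SimulationDesign(seed=1, genome_length=5_000, homolog_separation=4_000,
                         homolog_length=1_500)
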