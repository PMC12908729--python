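import numpy as np
import pytest

from endosift.alignments import PAD, ReadSet, encode_sequence
from endosift.io_core import SymbiontGenome
from endosift.synthetic_data import (
    ArtifactSpec,
    PlantedVariant,
    SimulationDesign,
    TissueSpec,
    simulate,
)


def reads_from_specs(genome: SymbiontGenome, specs, circular=None):
    """Build a ReadSet from (start, sequence, options) tuples.

    ``start`` is the reference coordinate of query index 0; options may
    set left_clip/right_clip/proper/reverse/mate2.
    """
    circular = genome.circular if circular is None else circular
    n = len(specs)
    maxlen = max(len(s[1]) for s in specs)
    codes = np.full((n, maxlen), PAD, dtype=np.uint8)
    qstart = np.zeros(n, dtype=np.int64)
    qlen = np.zeros(n, dtype=np.int64)
    lclip = np.zeros(n, dtype=np.int64)
    rclip = np.zeros(n, dtype=np.int64)
    proper = np.ones(n, dtype=bool)
    reverse = np.zeros(n, dtype=bool)
    for i, spec in enumerate(specs):
        start, seq = spec[0], spec[1]
        opts = spec[2] if len(spec) > 2 else {}
        qstart[i] = start
        qlen[i] = len(seq)
        codes[i, : len(seq)] = encode_sequence(seq)
        lclip[i] = opts.get("left_clip", 0)
        rclip[i] = opts.get("right_clip", 0)
        proper[i] = opts.get("proper", True)
        reverse[i] = opts.get("reverse", False)
    return ReadSet(
        genome.name, len(genome), circular, qstart, qlen, lclip, rclip,
        codes, reverse, proper, ref_codes=genome.codes,
    )


@pytest.fixture(scope="session")
def small_design():
    return SimulationDesign(
        seed=11,
        genome_length=12_000,
        homolog_separation=2_500,
        homolog_length=400,
        insert_count=1,
        insert_length=1_000,
        insert_flank=1_500,
        tissues=(TissueSpec("t1", 300.0), TissueSpec("t2", 260.0)),
        true_variants=(PlantedVariant({"t1": 0.4, "t2": 0.25}),),
        artifacts=(ArtifactSpec(alt_fraction=0.12, clip_probability=0.5, mismatch_rate=3.0),),
        uninfected_sample_count=1,
        uninfected_coverage=25.0,
        host_contamination_coverage=25.0,
    )


@pytest.fixture(scope="session")
def small_result(small_design):
    return simulate(small_design)


@pytest.fixture()
def flat_genome():
    rng = np.random.default_rng(0)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
    return SymbiontGenome("ref", seq, False)
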