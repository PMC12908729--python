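"""Synthetic endosymbiont resequencing data with a machine-readable truth table.

The generator emulates the study conditions the pipeline was built for:

* a circular symbiont genome (desk-scale default 100 kb) carrying a pair
  of homologous regions whose final ~104-bp tract is near-identical with
  a handful of diagnostic differences;
* host-nuclear inserts of diverged symbiont DNA embedded in host
  background sequence, which contaminate infected-tissue libraries and
  attract reads from uninfected lines;
* three tissue read sets at per-sample symbiont coverages around
  500-770x, with planted true SNPs at tissue-specific frequencies;
* planted artifact variants whose alternative-allele reads carry excess
  soft-clipping and mismatches;
* an optional gene-conversion event realised both in the read sequences
  (donor alleles over the acceptor tract) and in the mapping (most
  diagnostic-carrying acceptor reads re-placed at the donor, emulating
  what an aligner does when the acceptor no longer matches the
  reference).

Reads are emitted as directly-constructed alignments (:class:`ReadSet`),
so every downstream stage is testable without an aligner; SAM and FASTQ
renditions are available for interoperability.  Identical designs give
byte-identical outputs.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .alignments import BASES, ReadSet, decode_codes
from .conversion import DiagnosticSite, HomologousPair
from .io_core import SymbiontGenome

_DEFAULT_FREQS = {"haemolymph": 0.466, "nerve_chain": 0.584, "ovaries": 0.239}


@dataclass(frozen=True)
class TissueSpec:
    label: str
    coverage: float


@dataclass(frozen=True)
class PlantedVariant:
    """A true within-host SNP at tissue-specific frequencies."""

    frequencies: Mapping[str, float]
    position: int | None = None  # None: placed by the generator


@dataclass(frozen=True)
class ArtifactSpec:
    """A spurious variant whose alt-allele reads carry alignment anomalies.

    Alternative-allele reads are soft-clipped with probability
    ``clip_probability`` and receive Poisson(``mismatch_rate``) extra
    mismatches; reference-allele reads keep the baseline rates.
    """

    alt_fraction: float = 0.1
    clip_probability: float = 0.5
    mismatch_rate: float = 3.0
    improper_probability: float = 0.0
    position: int | None = None


@dataclass(frozen=True)
class ConversionSpec:
    """A gene-conversion event planted in a subset of samples.

    ``retained_fraction`` is the share of diagnostic-carrying acceptor
    reads that the paired-end constraint keeps anchored at the acceptor
    despite matching the donor better.
    """

    samples: tuple[str, ...]
    direction: str = "B_to_A"
    retained_fraction: float = 0.2


@dataclass(frozen=True)
class SimulationDesign:
    """Full description of one synthetic dataset; seed-determined."""

    seed: int
    genome_length: int = 100_000
    circular: bool = True
    # homologous pair: two copies `homolog_separation` apart whose final
    # `tract_length` bases differ at exactly `diagnostic_count` sites
    homolog_separation: int = 8_000
    homolog_length: int = 800
    homolog_identity: float = 0.92
    tract_length: int = 104
    diagnostic_count: int = 5
    # host-nuclear inserts
    insert_count: int = 3
    insert_length: int = 2_000
    insert_divergence: float = 0.03
    insert_flank: int = 5_000
    # samples
    tissues: tuple[TissueSpec, ...] = (
        TissueSpec("haemolymph", 533.7),
        TissueSpec("nerve_chain", 769.8),
        TissueSpec("ovaries", 723.9),
    )
    true_variants: tuple[PlantedVariant, ...] = (PlantedVariant(_DEFAULT_FREQS),)
    artifacts: tuple[ArtifactSpec, ...] = (ArtifactSpec(), ArtifactSpec())
    uninfected_sample_count: int = 2
    uninfected_coverage: float = 15.0
    host_contamination_coverage: float = 30.0
    conversion: ConversionSpec | None = None
    # read model
    read_length: int = 150
    fragment_mean: float = 350.0
    fragment_sd: float = 50.0
    base_error_rate: float = 0.001
    baseline_clip_probability: float = 0.02
    min_anchor: int = 50  # bp of insert overlap for a host read to map

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome length must be positive")
        if not 0 < self.homolog_identity <= 1:
            raise ValueError("homolog identity must be in (0, 1]")
        if self.tract_length > self.homolog_length:
            raise ValueError("tract length exceeds homolog length")
        if self.homolog_separation < self.homolog_length:
            raise ValueError("homologous copies would overlap")
        if self.homolog_separation + self.homolog_length >= self.genome_length:
            raise ValueError("separation plus homolog length exceeds the genome")
        if self.insert_count and self.insert_length >= self.genome_length:
            raise ValueError("insert length must be shorter than the genome")
        total_diffs = round((1 - self.homolog_identity) * self.homolog_length)
        if self.diagnostic_count > total_diffs:
            raise ValueError("diagnostic count exceeds total homolog differences")
        if self.diagnostic_count > self.tract_length:
            raise ValueError("more diagnostic sites than tract positions")
        for t in self.tissues:
            if t.coverage <= 0:
                raise ValueError(f"tissue {t.label}: coverage must be positive")
        for v in self.true_variants:
            for label, f in v.frequencies.items():
                if not 0 < f <= 1:
                    raise ValueError(f"variant frequency {f} for {label} outside (0, 1]")
        for a in self.artifacts:
            if not 0 < a.alt_fraction < 1:
                raise ValueError("artifact alt fraction must be in (0, 1)")
        if not 0 <= self.base_error_rate < 1:
            raise ValueError("base error rate must be in [0, 1)")
        if self.conversion is not None:
            labels = {t.label for t in self.tissues}
            unknown = set(self.conversion.samples) - labels
            if unknown:
                raise ValueError(f"conversion samples not among tissues: {sorted(unknown)}")
            if self.conversion.direction not in ("B_to_A", "A_to_B"):
                raise ValueError("conversion direction must be B_to_A or A_to_B")

    @classmethod
    def from_toml(cls, path) -> "SimulationDesign":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data = data.get("design", data)
        if "tissues" in data:
            data["tissues"] = tuple(TissueSpec(**t) for t in data["tissues"])
        if "true_variants" in data:
            data["true_variants"] = tuple(PlantedVariant(**v) for v in data["true_variants"])
        if "artifacts" in data:
            data["artifacts"] = tuple(ArtifactSpec(**a) for a in data["artifacts"])
        if "conversion" in data and data["conversion"] is not None:
            conv = dict(data["conversion"])
            conv["samples"] = tuple(conv["samples"])
            data["conversion"] = ConversionSpec(**conv)
        return cls(**data)


# ----------------------------------------------------------------------
# truth table
# ----------------------------------------------------------------------

@dataclass
class TrueVariantTruth:
    position: int
    ref: str
    alt: str
    frequencies: dict[str, float]


@dataclass
class ArtifactTruth:
    position: int
    ref: str
    alt: str
    alt_fraction: float
    clip_probability: float
    mismatch_rate: float
    improper_probability: float


@dataclass
class InsertTruth:
    start: int
    end: int
    substitutions: int
    contig: str


@dataclass
class ConversionTruth:
    direction: str
    acceptor_start: int
    acceptor_end: int
    donor_start: int
    donor_end: int
    samples: tuple[str, ...]


@dataclass
class TruthTable:
    """Ground truth for every planted event; TSV round-trips losslessly."""

    true_variants: list[TrueVariantTruth] = field(default_factory=list)
    artifacts: list[ArtifactTruth] = field(default_factory=list)
    inserts: list[InsertTruth] = field(default_factory=list)
    conversion: ConversionTruth | None = None
    warnings: list[str] = field(default_factory=list)

    def insert_intervals(self) -> list[tuple[int, int]]:
        return [(i.start, i.end) for i in self.inserts]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tstart\tend\tpayload\n")
            for v in self.true_variants:
                payload = {"ref": v.ref, "alt": v.alt, "frequencies": v.frequencies}
                fh.write(f"true_variant\t{v.position}\t{v.position + 1}\t{json.dumps(payload, sort_keys=True)}\n")
            for a in self.artifacts:
                payload = {
                    "ref": a.ref, "alt": a.alt, "alt_fraction": a.alt_fraction,
                    "clip_probability": a.clip_probability,
                    "mismatch_rate": a.mismatch_rate,
                    "improper_probability": a.improper_probability,
                }
                fh.write(f"artifact\t{a.position}\t{a.position + 1}\t{json.dumps(payload, sort_keys=True)}\n")
            for i in self.inserts:
                payload = {"substitutions": i.substitutions, "contig": i.contig}
                fh.write(f"insert\t{i.start}\t{i.end}\t{json.dumps(payload, sort_keys=True)}\n")
            if self.conversion is not None:
                c = self.conversion
                payload = {
                    "direction": c.direction, "donor_start": c.donor_start,
                    "donor_end": c.donor_end, "samples": list(c.samples),
                }
                fh.write(f"conversion\t{c.acceptor_start}\t{c.acceptor_end}\t{json.dumps(payload, sort_keys=True)}\n")
            for w in self.warnings:
                fh.write(f"warning\t-1\t-1\t{json.dumps({'message': w})}\n")

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        table = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("kind\t"):
                raise ValueError("not a truth-table TSV")
            for line in fh:
                kind, start, end, payload = line.rstrip("\n").split("\t", 3)
                data = json.loads(payload)
                start, end = int(start), int(end)
                if kind == "true_variant":
                    table.true_variants.append(
                        TrueVariantTruth(start, data["ref"], data["alt"], data["frequencies"])
                    )
                elif kind == "artifact":
                    table.artifacts.append(
                        ArtifactTruth(
                            start, data["ref"], data["alt"], data["alt_fraction"],
                            data["clip_probability"], data["mismatch_rate"],
                            data["improper_probability"],
                        )
                    )
                elif kind == "insert":
                    table.inserts.append(InsertTruth(start, end, data["substitutions"], data["contig"]))
                elif kind == "conversion":
                    table.conversion = ConversionTruth(
                        data["direction"], start, end, data["donor_start"],
                        data["donor_end"], tuple(data["samples"]),
                    )
                elif kind == "warning":
                    table.warnings.append(data["message"])
                else:
                    raise ValueError(f"unknown truth record kind {kind!r}")
        return table


@dataclass
class GenomeLayout:
    copy_a: tuple[int, int]
    copy_b: tuple[int, int]
    tract_a: tuple[int, int]
    tract_b: tuple[int, int]


@dataclass
class SimulationResult:
    design: SimulationDesign
    genome: SymbiontGenome
    pair: HomologousPair
    layout: GenomeLayout
    host_contigs: list[SymbiontGenome]
    tissues: dict[str, ReadSet]
    uninfected: dict[str, ReadSet]
    truth: TruthTable


# ----------------------------------------------------------------------
# genome construction
# ----------------------------------------------------------------------

def _rng(design: SimulationDesign, stream: int) -> np.random.Generator:
    return np.random.default_rng([design.seed, stream])


def _spread_positions(rng, count: int, length: int) -> np.ndarray:
    """`count` distinct positions spread quasi-uniformly over [0, length)."""
    if count == 0:
        return np.zeros(0, dtype=np.int64)
    spacing = length / count
    jitter = rng.integers(-int(spacing // 4), int(spacing // 4) + 1, size=count)
    pos = np.clip(((np.arange(count) + 0.5) * spacing).astype(np.int64) + jitter, 0, length - 1)
    return np.unique(pos)


def _substitute(rng, codes: np.ndarray, positions: np.ndarray) -> None:
    codes[positions] = (codes[positions] + rng.integers(1, 4, size=len(positions))) % 4


def build_genome(design: SimulationDesign) -> tuple[SymbiontGenome, HomologousPair, GenomeLayout]:
    """Random circular genome containing the planted homologous pair.

    Copy B is copy A mutated so that the overall copy identity matches
    the design and the final ``tract_length`` bases differ at exactly
    ``diagnostic_count`` positions.  Outside the tract, the differences
    are spread quasi-uniformly along the copy — the uniform-divergence
    model of an anciently duplicated paralog — so the tract is the only
    segment whose local identity exceeds the copy-wide level.
    """
    rng = _rng(design, 0)
    L = design.genome_length
    hl = design.homolog_length
    tl = design.tract_length
    codes = rng.integers(0, 4, size=L, dtype=np.uint8)
    ca_start = int(rng.integers(0, L - design.homolog_separation - hl))
    cb_start = ca_start + design.homolog_separation
    copy_b = codes[ca_start : ca_start + hl].copy()
    total_diffs = round((1 - design.homolog_identity) * hl)
    # diagnostic differences inside the tract
    diag_off = _spread_positions(rng, design.diagnostic_count, tl)
    while len(diag_off) < design.diagnostic_count:  # collision fallback
        extra = rng.integers(0, tl)
        diag_off = np.unique(np.append(diag_off, extra))
    diag_abs = (hl - tl) + diag_off
    _substitute(rng, copy_b, diag_abs)
    # remaining differences spread over the non-tract part
    n_outside = total_diffs - len(diag_off)
    if n_outside > 0:
        outside = _spread_positions(rng, n_outside, hl - tl)
        _substitute(rng, copy_b, outside)
    codes[cb_start : cb_start + hl] = copy_b
    genome = SymbiontGenome("symbiont", decode_codes(codes), design.circular)
    ta = (ca_start + hl - tl, ca_start + hl)
    tb = (cb_start + hl - tl, cb_start + hl)
    sites = tuple(
        DiagnosticSite(int(o), BASES[genome.codes[ta[0] + o]], BASES[genome.codes[tb[0] + o]])
        for o in diag_off
    )
    identity = 1.0 - len(sites) / tl
    pair = HomologousPair(genome.name, ta[0], ta[1], tb[0], tb[1], identity, sites)
    layout = GenomeLayout((ca_start, ca_start + hl), (cb_start, cb_start + hl), ta, tb)
    return genome, pair, layout


def plant_inserts(
    genome: SymbiontGenome, design: SimulationDesign, layout: GenomeLayout
) -> tuple[list[SymbiontGenome], list[InsertTruth]]:
    """Embed diverged symbiont fragments into host background contigs.

    Each insert is a symbiont subsequence mutated at the design
    divergence (per-site Bernoulli, exact realised count recorded in the
    truth), flanked by random host sequence.  Intervals are reported in
    symbiont coordinates.  Zero divergence with a positive count is
    permitted but flagged in the truth warnings, since such inserts are
    indistinguishable from symbiont reads except by sample of origin.
    """
    rng = _rng(design, 1)
    L = len(genome)
    contigs: list[SymbiontGenome] = []
    truths: list[InsertTruth] = []
    forbidden = [layout.copy_a, layout.copy_b]
    ilen = design.insert_length
    for k in range(design.insert_count):
        for _attempt in range(1000):
            s = int(rng.integers(0, L - ilen))
            interval = (s - 1000, s + ilen + 1000)
            if all(interval[1] <= fs or interval[0] >= fe for fs, fe in forbidden):
                break
        else:
            raise ValueError("could not place inserts away from homologous copies")
        forbidden.append((s - 1000, s + ilen + 1000))
        fragment = genome.codes[s : s + ilen].copy()
        mask = rng.random(ilen) < design.insert_divergence
        positions = np.flatnonzero(mask)
        _substitute(rng, fragment, positions)
        flank = design.insert_flank
        left = rng.integers(0, 4, size=flank, dtype=np.uint8)
        right = rng.integers(0, 4, size=flank, dtype=np.uint8)
        contig_codes = np.concatenate([left, fragment, right])
        name = f"host_contig_{k + 1}"
        contigs.append(SymbiontGenome(name, decode_codes(contig_codes), False))
        truths.append(InsertTruth(s, s + ilen, int(len(positions)), name))
    return contigs, truths


# ----------------------------------------------------------------------
# read simulation
# ----------------------------------------------------------------------

def _paired_arrays(rng, n_pairs: int, rl: int, L: int, fragment_mean, fragment_sd, circular=True):
    frag = np.rint(rng.normal(fragment_mean, fragment_sd, n_pairs)).astype(np.int64)
    frag = np.maximum(frag, rl)
    if circular:
        start = rng.integers(0, L, n_pairs)
    else:
        start = rng.integers(0, np.maximum(L - frag, 1))
    n = 2 * n_pairs
    qstart = np.empty(n, dtype=np.int64)
    qstart[0::2] = start
    qstart[1::2] = start + frag - rl
    if circular:
        qstart[1::2] %= L
    reverse = np.zeros(n, dtype=bool)
    reverse[1::2] = True
    mate2 = reverse.copy()
    return qstart, reverse, mate2


def _gather_reads(template: np.ndarray, qstart: np.ndarray, rl: int, L: int, circular: bool) -> np.ndarray:
    """Chunked gather of read base codes from a template sequence."""
    n = len(qstart)
    codes = np.empty((n, rl), dtype=np.uint8)
    ext = np.concatenate([template, template[:rl]]) if circular else template
    ar = np.arange(rl, dtype=np.int32)
    qs = (qstart % L if circular else qstart).astype(np.int32)
    step = 131072
    for lo in range(0, n, step):
        hi = min(lo + step, n)
        codes[lo:hi] = ext[qs[lo:hi, None] + ar]
    return codes


def _apply_errors(rng, codes: np.ndarray, rate: float) -> None:
    if rate <= 0:
        return
    total = codes.size
    n_err = int(rng.poisson(rate * total))
    if n_err == 0:
        return
    idx = rng.integers(0, total, n_err)
    flat = codes.reshape(-1)
    flat[idx] = (flat[idx] + rng.integers(1, 4, n_err).astype(np.uint8)) % 4


def _covering_offsets(qstart: np.ndarray, position: int, rl: int, L: int, circular: bool):
    off = position - qstart
    if circular:
        off %= L
    cover = (off >= 0) & (off < rl)
    return off, cover


def _simulate_tissue(
    design: SimulationDesign,
    tissue: TissueSpec,
    genome: SymbiontGenome,
    layout: GenomeLayout,
    pair: HomologousPair,
    host_contigs: list[SymbiontGenome],
    insert_truths: list[InsertTruth],
    truth: TruthTable,
    rng: np.random.Generator,
) -> ReadSet:
    L = len(genome)
    rl = design.read_length
    converted = design.conversion is not None and tissue.label in design.conversion.samples
    template = genome.codes.copy()
    if converted:
        conv = design.conversion
        if conv.direction == "B_to_A":
            acc_t, don_t = layout.tract_a, layout.tract_b
            donor_alleles = [s.allele_b for s in pair.sites]
        else:
            acc_t, don_t = layout.tract_b, layout.tract_a
            donor_alleles = [s.allele_a for s in pair.sites]
        for site, allele in zip(pair.sites, donor_alleles):
            template[acc_t[0] + site.offset] = BASES.index(allele)
    n_pairs = max(1, int(round(tissue.coverage * L / (2 * rl))))
    qstart, reverse, mate2 = _paired_arrays(
        rng, n_pairs, rl, L, design.fragment_mean, design.fragment_sd, design.circular
    )
    n = len(qstart)
    codes = _gather_reads(template, qstart, rl, L, design.circular)
    left_clip = np.zeros(n, dtype=np.int64)
    right_clip = np.zeros(n, dtype=np.int64)
    proper = np.ones(n, dtype=bool)
    # baseline soft-clipping (library/alignment noise common to all reads)
    if design.baseline_clip_probability > 0:
        sel = np.flatnonzero(rng.random(n) < design.baseline_clip_probability)
        lengths = rng.integers(5, 31, size=len(sel))
        sides = rng.random(len(sel)) < 0.5
        left_clip[sel[sides]] = lengths[sides]
        right_clip[sel[~sides]] = lengths[~sides]
    # true variants: per-read Bernoulli at the tissue frequency
    for v in truth.true_variants:
        f = v.frequencies.get(tissue.label, 0.0)
        if f <= 0:
            continue
        off, cover = _covering_offsets(qstart, v.position, rl, L, design.circular)
        sel = cover & (rng.random(n) < f)
        codes[sel, off[sel]] = BASES.index(v.alt)
    # artifact variants: alt reads receive clipping and mismatch excess
    for a in truth.artifacts:
        off, cover = _covering_offsets(qstart, a.position, rl, L, design.circular)
        alt_sel = np.flatnonzero(cover & (rng.random(n) < a.alt_fraction))
        if len(alt_sel) == 0:
            continue
        codes[alt_sel, off[alt_sel]] = BASES.index(a.alt)
        clip_sel = alt_sel[rng.random(len(alt_sel)) < a.clip_probability]
        for r in clip_sel:
            o = int(off[r])
            length = int(rng.integers(15, 41))
            if o >= rl // 2:  # clip the far end, keeping the focal base aligned
                left_clip[r] = max(left_clip[r], min(length, o))
            else:
                right_clip[r] = max(right_clip[r], min(length, rl - 1 - o))
        extra = rng.poisson(a.mismatch_rate, size=len(alt_sel))
        for r, k in zip(alt_sel, extra):
            if k == 0:
                continue
            cols = rng.integers(0, rl, size=k)
            cols = cols[cols != off[r]]
            codes[r, cols] = (codes[r, cols] + rng.integers(1, 4, len(cols)).astype(np.uint8)) % 4
        if a.improper_probability > 0:
            improper = alt_sel[rng.random(len(alt_sel)) < a.improper_probability]
            proper[improper] = False
    # conversion: aligner re-places most diagnostic-carrying acceptor reads
    if converted:
        conv = design.conversion
        if conv.direction == "B_to_A":
            acc_t = layout.tract_a
            donor_copy = layout.copy_b
            delta = layout.tract_b[0] - layout.tract_a[0]
        else:
            acc_t = layout.tract_b
            donor_copy = layout.copy_a
            delta = layout.tract_a[0] - layout.tract_b[0]
        cover_any = np.zeros(n, dtype=bool)
        for site in pair.sites:
            _, cov = _covering_offsets(qstart, acc_t[0] + site.offset, rl, L, design.circular)
            cover_any |= cov
        moved = cover_any & (rng.random(n) >= conv.retained_fraction)
        qstart[moved] += delta
        # clip overhangs past the donor copy, as an aligner would
        a_end = qstart + rl - right_clip
        over_r = np.where(moved, a_end - donor_copy[1], 0)
        right_clip += np.maximum(over_r, 0)
        a_start = qstart + left_clip
        over_l = np.where(moved, donor_copy[0] - a_start, 0)
        left_clip += np.maximum(over_l, 0)
        # a read left with no anchored bases is fully clipped, not negative
        left_clip = np.minimum(left_clip, rl)
        right_clip = np.minimum(right_clip, rl - left_clip)
    _apply_errors(rng, codes, design.base_error_rate)
    symbiont = ReadSet(
        genome.name, L, design.circular, qstart, np.full(n, rl, dtype=np.int64),
        left_clip, right_clip, codes, reverse, proper, mate2, sample=tissue.label,
        ref_codes=genome.codes,
    )
    parts = [symbiont]
    if design.host_contamination_coverage > 0 and host_contigs:
        host = _host_reads(
            design, genome, host_contigs, insert_truths,
            design.host_contamination_coverage, rng, tissue.label,
        )
        if host.n:
            parts.append(host)
    from .alignments import concatenate

    return concatenate(parts) if len(parts) > 1 else symbiont


def _host_reads(
    design: SimulationDesign,
    genome: SymbiontGenome,
    host_contigs: list[SymbiontGenome],
    insert_truths: list[InsertTruth],
    coverage: float,
    rng: np.random.Generator,
    sample: str,
) -> ReadSet:
    """Reads from host contigs, mapped onto the symbiont reference.

    A host read is placed on the symbiont iff it overlaps the embedded
    insert by at least ``min_anchor`` bp; portions extending into host
    background are soft-clipped, and a read whose mate fails to map is
    flagged as not properly paired — the behaviour of a paired-end
    aligner encountering an insert boundary.
    """
    rl = design.read_length
    L = len(genome)
    flank = design.insert_flank
    parts = []
    for contig, ins in zip(host_contigs, insert_truths):
        clen = len(contig)
        ccodes = contig.codes
        ilen = ins.end - ins.start
        n_pairs = max(1, int(round(coverage * clen / (2 * rl))))
        qstart_c, reverse, mate2 = _paired_arrays(
            rng, n_pairs, rl, clen, design.fragment_mean, design.fragment_sd, circular=False
        )
        qstart_c = np.clip(qstart_c, 0, clen - rl)
        read_end = qstart_c + rl
        ov = np.minimum(read_end, flank + ilen) - np.maximum(qstart_c, flank)
        mapped = ov >= design.min_anchor
        mate_mapped = mapped.copy()
        mate_mapped[0::2] = mapped[1::2]
        mate_mapped[1::2] = mapped[0::2]
        keep = np.flatnonzero(mapped)
        if len(keep) == 0:
            continue
        qs = qstart_c[keep]
        codes = _gather_reads(ccodes, qs, rl, clen, False)
        sym_qstart = ins.start + (qs - flank)
        lclip = np.maximum(flank - qs, 0)
        rclip = np.maximum((qs + rl) - (flank + ilen), 0)
        rs = ReadSet(
            genome.name, L, design.circular, sym_qstart, np.full(len(keep), rl, np.int64),
            lclip, rclip, codes, reverse[keep], mate_mapped[keep] & mapped[keep],
            mate2[keep], sample=sample, ref_codes=genome.codes,
        )
        parts.append(rs)
    if not parts:
        return ReadSet.empty(genome.name, L, design.circular, sample=sample)
    from .alignments import concatenate

    out = concatenate(parts) if len(parts) > 1 else parts[0]
    _apply_errors(rng, out.codes, design.base_error_rate)
    return out


def _resolve_positions(design: SimulationDesign, genome, layout, insert_truths, rng):
    """Assign generator-chosen positions and alleles for planted events."""
    L = len(genome)
    margin = 500
    taken: list[tuple[int, int]] = [
        (layout.copy_a[0] - margin, layout.copy_a[1] + margin),
        (layout.copy_b[0] - margin, layout.copy_b[1] + margin),
    ]
    taken += [(i.start - margin, i.end + margin) for i in insert_truths]

    def place(requested: int | None) -> int:
        if requested is not None:
            return requested
        for _ in range(10_000):
            p = int(rng.integers(0, L))
            if all(not (s <= p < e) for s, e in taken):
                taken.append((p - 400, p + 400))
                return p
        raise ValueError("could not place planted events on the genome")

    true_truths = []
    for v in design.true_variants:
        p = place(v.position)
        ref = BASES[genome.codes[p]]
        alt = BASES[(genome.codes[p] + rng.integers(1, 4)) % 4]
        true_truths.append(TrueVariantTruth(p, ref, alt, dict(v.frequencies)))
    artifact_truths = []
    for a in design.artifacts:
        p = place(a.position)
        ref = BASES[genome.codes[p]]
        alt = BASES[(genome.codes[p] + rng.integers(1, 4)) % 4]
        artifact_truths.append(
            ArtifactTruth(p, ref, alt, a.alt_fraction, a.clip_probability,
                          a.mismatch_rate, a.improper_probability)
        )
    return true_truths, artifact_truths


def simulate(design: SimulationDesign) -> SimulationResult:
    """Run the full generator: genome, inserts, tissue and uninfected reads.

    Every planted event appears in the returned truth table exactly
    once; identical designs produce identical results.
    """
    genome, pair, layout = build_genome(design)
    contigs, insert_truths = plant_inserts(genome, design, layout)
    rng_place = _rng(design, 2)
    true_truths, artifact_truths = _resolve_positions(design, genome, layout, insert_truths, rng_place)
    truth = TruthTable(true_truths, artifact_truths, insert_truths)
    if design.insert_count and design.insert_divergence == 0:
        truth.warnings.append(
            "insert divergence is 0: inserts are indistinguishable from the symbiont "
            "except by sample of origin"
        )
    for v in true_truths:
        for t in design.tissues:
            f = v.frequencies.get(t.label, 0.0)
            if 0 < t.coverage * f < 1:
                truth.warnings.append(
                    f"expected alt read count below 1 for variant at {v.position} in {t.label}"
                )
    if design.conversion is not None:
        conv = design.conversion
        if conv.direction == "B_to_A":
            acc, don = layout.tract_a, layout.tract_b
        else:
            acc, don = layout.tract_b, layout.tract_a
        truth.conversion = ConversionTruth(
            conv.direction, acc[0], acc[1], don[0], don[1], tuple(conv.samples)
        )
    tissues: dict[str, ReadSet] = {}
    for k, t in enumerate(design.tissues):
        rng = _rng(design, 10 + k)
        tissues[t.label] = _simulate_tissue(
            design, t, genome, layout, pair, contigs, insert_truths, truth, rng
        )
    uninfected: dict[str, ReadSet] = {}
    for k in range(design.uninfected_sample_count):
        rng = _rng(design, 100 + k)
        name = f"uninfected_{k + 1}"
        rs = _host_reads(design, genome, contigs, insert_truths, design.uninfected_coverage, rng, name)
        uninfected[name] = rs
    return SimulationResult(design, genome, pair, layout, contigs, tissues, uninfected, truth)


# ----------------------------------------------------------------------
# interchange
# ----------------------------------------------------------------------

def to_fastq(readset: ReadSet, path_r1, path_r2) -> None:
    """Write a paired FASTQ rendition (reverse reads are back-complemented)."""
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for i in range(readset.n):
            qlen = int(readset.qlen[i])
            codes = readset.codes[i, :qlen]
            if readset.reverse[i]:
                codes = comp[np.where(codes > 4, 4, codes)][::-1]
            name = readset.names[i] if readset.names else f"r{i:09d}"
            out = f2 if readset.mate2[i] else f1
            qual = "I" * qlen
            out.write(f"@{name}\n{decode_codes(codes)}\n+\n{qual}\n")


def write_outputs(result: SimulationResult, outdir) -> None:
    """Materialise a simulation as FASTA + SAM + TSV files under ``outdir``."""
    import os

    from .conversion import write_pairs_tsv
    from .io_core import write_fasta

    os.makedirs(outdir, exist_ok=True)
    write_fasta([result.genome], os.path.join(outdir, "reference.fa"))
    if result.host_contigs:
        write_fasta(result.host_contigs, os.path.join(outdir, "host_contigs.fa"))
    write_pairs_tsv([result.pair], os.path.join(outdir, "homolog_pairs.tsv"))
    result.truth.to_tsv(os.path.join(outdir, "truth.tsv"))
    for label, rs in {**result.tissues, **result.uninfected}.items():
        rs.to_sam(os.path.join(outdir, f"{label}.sam"), result.genome.codes)
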