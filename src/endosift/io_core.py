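"""Readers and writers for the standard formats the pipeline touches.

Internally every coordinate is 0-based, half-open.  The only 1-based
surfaces are VCF records and qPCR tables; conversion happens exactly at
those format boundaries.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .alignments import encode_sequence

IUPAC = set("ACGTRYSWKMBDHVN")

#: canonical pipeline stages, in the order candidates traverse them
STAGES = (
    "called",
    "support_filter",
    "insert_screen",
    "wet_lab_exclusion",
    "anomaly",
    "final",
)


@dataclass
class SymbiontGenome:
    """A (possibly circular) reference sequence.

    The sequence alphabet is restricted to ACGT for synthetic genomes and
    ACGTN for ingested ones; the encoded uint8 form used by numeric code
    is cached on first access.
    """

    name: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("genome name must be non-empty")
        if len(self.sequence) == 0:
            raise ValueError(f"genome {self.name!r} has an empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - IUPAC
        if bad:
            raise ValueError(f"genome {self.name!r} contains illegal characters: {sorted(bad)}")
        self._codes: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None:
            self._codes = encode_sequence(self.sequence)
        return self._codes


@dataclass(frozen=True)
class VariantRecordView:
    """A single-alt view of a called variant with per-sample support."""

    reference: str
    position: int  # 0-based
    ref: str
    alt: str
    depth: Mapping[str, int]
    alt_count: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        for s, d in self.depth.items():
            a = self.alt_count.get(s, 0)
            if not (d >= a >= 0):
                raise ValueError(f"sample {s}: depth {d} < alt count {a} or negative")


def read_fasta(path: str | os.PathLike) -> list[SymbiontGenome]:
    """Read a FASTA file into genomes, preserving record order.

    Sequences are uppercased; a ``circular=true`` token in the record
    description marks the genome as circular (the convention used by this
    package's own FASTA writer).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    genomes = []
    for rec in SeqIO.parse(path, "fasta"):
        circular = "circular=true" in rec.description.lower()
        genomes.append(SymbiontGenome(rec.id, str(rec.seq), circular))
    return genomes


def write_fasta(genomes: Sequence[SymbiontGenome], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            tag = " circular=true" if g.circular else ""
            fh.write(f">{g.name}{tag}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


def read_variants(path: str | os.PathLike, sample_names: Sequence[str] | None = None) -> list[VariantRecordView]:
    """Read a VCF into single-alt variant views.

    Multiallelic records are decomposed into one view per alternative
    allele; positions are converted to 0-based; output is sorted by
    (reference, position, alt).  Per-sample depth comes from ``DP`` and
    alt support from ``AD`` (or ``AO`` when ``AD`` is absent).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    views: list[VariantRecordView] = []
    with pysam.VariantFile(path) as vcf:
        file_samples = list(vcf.header.samples)
        if sample_names is None:
            sample_names = file_samples
        else:
            missing = [s for s in sample_names if s not in file_samples]
            if missing:
                raise ValueError(f"samples absent from VCF: {missing}")
        for line_no, rec in enumerate(vcf, start=1):
            try:
                alts = rec.alts or ()
                for ai, alt in enumerate(alts):
                    depth: dict[str, int] = {}
                    alt_count: dict[str, int] = {}
                    for s in sample_names:
                        fmt = rec.samples[s]
                        dp = fmt.get("DP")
                        depth[s] = int(dp) if dp is not None else 0
                        ad = fmt.get("AD")
                        if ad is not None:
                            alt_count[s] = int(ad[ai + 1])
                        else:
                            ao = fmt.get("AO")
                            if ao is None:
                                alt_count[s] = 0
                            elif isinstance(ao, tuple):
                                alt_count[s] = int(ao[ai])
                            else:
                                alt_count[s] = int(ao)
                    views.append(
                        VariantRecordView(rec.chrom, rec.pos - 1, rec.ref, alt, depth, alt_count)
                    )
            except (KeyError, IndexError, TypeError, ValueError) as exc:
                raise ValueError(f"malformed VCF record #{line_no} at {rec.chrom}:{rec.pos}: {exc}") from exc
    views.sort(key=lambda v: (v.reference, v.position, v.alt))
    return views


# ----------------------------------------------------------------------
# stage reports
# ----------------------------------------------------------------------

_REPORT_COLUMNS = [
    "reference", "position", "ref", "alt", "sample",
    "depth", "alt_count", "stage", "status", "reason",
]


def write_report(candidates, tsv_path, vcf_path=None, genome=None, stage_label: str | None = None) -> None:
    """Write the per-variant, per-stage decision trail as a TSV.

    One row per variant x sample x stage decision, in deterministic
    order, so identical inputs give byte-identical files.  When
    ``vcf_path`` and ``genome`` are given, surviving candidates are also
    written as a VCF annotated with the stages they passed.
    """
    rows = []
    for c in sorted(candidates, key=lambda c: (c.reference, c.position, c.alt)):
        samples = sorted(c.samples) or [""]
        for stage, status, reason in c.trail:
            if stage_label is not None and stage != stage_label:
                continue
            for s in samples:
                sc = c.samples.get(s)
                rows.append(
                    (
                        c.reference, c.position + 1, c.ref, c.alt, s,
                        sc.depth if sc else 0, sc.alt if sc else 0,
                        stage, status, reason,
                    )
                )
    frame = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    frame.to_csv(tsv_path, sep="\t", index=False, lineterminator="\n")
    if vcf_path is not None:
        if genome is None:
            raise ValueError("writing a VCF requires the reference genome")
        write_survivor_vcf([c for c in candidates if not c.excluded], vcf_path, genome)


def write_survivor_vcf(candidates, path, genome: SymbiontGenome) -> None:
    """Write surviving candidates as VCFv4.2 with stage annotations in INFO."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=STAGES,Number=.,Type=String,Description="Validation stages passed">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.contigs.add(genome.name, length=len(genome))
    samples = sorted({s for c in candidates for s in c.samples})
    for s in samples:
        header.add_sample(s)
    ordered = sorted(candidates, key=lambda c: (c.reference, c.position, c.alt))
    with pysam.VariantFile(path, "w", header=header) as out:
        for c in ordered:
            rec = out.new_record(
                contig=c.reference, start=c.position, alleles=(c.ref, c.alt)
            )
            rec.info["STAGES"] = ",".join(st for st, status, _ in c.trail if status == "retained")
            for s in samples:
                sc = c.samples.get(s)
                rec.samples[s]["DP"] = sc.depth if sc else 0
                rec.samples[s]["AD"] = (sc.depth - sc.alt, sc.alt) if sc else (0, 0)
            out.write(rec)


def read_report(tsv_path) -> pd.DataFrame:
    """Load a stage-report TSV back into a DataFrame (1-based positions kept)."""
    return pd.read_csv(tsv_path, sep="\t", dtype={"reason": str}, keep_default_na=False)


def read_exclusion_list(path) -> list[tuple[str, int, str, str]]:
    """Read a wet-lab exclusion list TSV of (reference, position, ref, alt).

    Positions in the file are 1-based (a lab-facing surface); the
    returned tuples are 0-based.  Lines starting with ``#`` are ignored.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[:4] == ["reference", "position", "ref", "alt"]:
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns (reference, position, ref, alt)")
            ref_name, pos, ref, alt = parts[:4]
            try:
                position = int(pos) - 1
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: position {pos!r} is not an integer") from exc
            rows.append((ref_name, position, ref.upper(), alt.upper()))
    return rows


def read_qpcr_table(path) -> pd.DataFrame:
    """Read a qPCR cycle table TSV with columns sample, locus, replicate, cp."""
    frame = pd.read_csv(path, sep="\t")
    required = {"sample", "locus", "cp"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    return frame
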