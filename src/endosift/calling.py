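"""Candidate variant production and the read-support filter.

Candidates come either from an external caller's VCF (via
:func:`candidates_from_views`) or from the built-in naive frequency
caller, which emits every non-reference base whose observation fraction
reaches a floor ``F`` in at least one sample.  The support filter then
keeps only sites with total depth strictly over 200 and at least 10
alternative-allele reads within a tissue (both configurable) — the
conservative entry criterion for all downstream validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignments import BASES, ReadSet
from .io_core import SymbiontGenome, VariantRecordView


@dataclass
class SampleCounts:
    depth: int
    alt: int

    @property
    def fraction(self) -> float:
        return self.alt / self.depth if self.depth > 0 else 0.0


@dataclass
class VariantCandidate:
    """A candidate site with per-sample support and a per-stage status trail.

    The trail grows monotonically: each stage appends one
    ``(stage, "retained"|"excluded", reason)`` decision and an excluded
    candidate is never evaluated at a later stage.
    """

    reference: str
    position: int
    ref: str
    alt: str
    samples: dict[str, SampleCounts]
    trail: list[tuple[str, str, str]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def id(self) -> str:
        return f"{self.reference}:{self.position + 1}:{self.ref}>{self.alt}"

    @property
    def excluded(self) -> bool:
        return any(status == "excluded" for _, status, _ in self.trail)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def record(self, stage: str, retained: bool, reason: str = "") -> None:
        if self.excluded:
            raise ValueError(f"{self.id}: candidate already excluded; trail is append-only")
        self.trail.append((stage, "retained" if retained else "excluded", reason))

    def exclusion_stage(self) -> str | None:
        for stage, status, _ in self.trail:
            if status == "excluded":
                return stage
        return None


def candidates_from_views(views: Sequence[VariantRecordView]) -> list[VariantCandidate]:
    """Wrap ingested VCF views as candidates entering the pipeline."""
    out = []
    for v in views:
        samples = {
            s: SampleCounts(int(v.depth.get(s, 0)), int(v.alt_count.get(s, 0)))
            for s in v.depth
        }
        c = VariantCandidate(v.reference, v.position, v.ref, v.alt, samples)
        c.record("called", True, "ingested")
        out.append(c)
    return out


def naive_call(
    samples: Mapping[str, ReadSet],
    genome: SymbiontGenome,
    min_fraction: float = 0.03,
    min_baseq: int = 0,
    min_mapq: int = 0,
) -> list[VariantCandidate]:
    """Frequency-based SNP caller over per-sample pileup columns.

    At each position, every non-reference base whose per-sample
    observation fraction is at least ``min_fraction`` in one or more
    samples becomes a candidate, with depth and alt counts recorded for
    all samples.  Substitutions only; indels are delegated to external
    VCF ingestion.  ``min_mapq`` is part of the contract for ingested
    alignments; the simulator emits uniquely-placed reads, which carry
    the maximum mapping quality.
    """
    del min_mapq  # all ReadSet reads are primary, uniquely-placed alignments
    if not samples:
        return []
    L = len(genome)
    names = list(samples)
    for name, rs in samples.items():
        if rs.reference != genome.name or rs.ref_length != L:
            raise ValueError(f"sample {name!r} aligned to a different reference")
    counts = {name: rs.base_counts(min_baseq)[:4] for name, rs in samples.items()}
    depth = {name: c.sum(axis=0) for name, c in counts.items()}
    ref_codes = genome.codes
    hit = np.zeros((4, L), dtype=bool)
    for name in names:
        d = depth[name]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = counts[name] / np.where(d > 0, d, 1)
        hit |= (frac >= min_fraction) & (counts[name] > 0)
    # reference base is never a variant of itself
    cols = np.arange(L)
    valid_ref = ref_codes < 4
    hit[ref_codes[valid_ref], cols[valid_ref]] = False
    hit[:, ~valid_ref] = False
    alt_codes, positions = np.nonzero(hit)
    order = np.lexsort((alt_codes, positions))
    out = []
    for alt_code, pos in zip(alt_codes[order], positions[order]):
        sample_counts = {
            name: SampleCounts(int(depth[name][pos]), int(counts[name][alt_code, pos]))
            for name in names
        }
        c = VariantCandidate(
            genome.name, int(pos), BASES[ref_codes[pos]], BASES[alt_code], sample_counts
        )
        c.record("called", True, f"F>={min_fraction}")
        out.append(c)
    return out


def support_filter(
    candidates: Sequence[VariantCandidate],
    min_depth: int = 200,
    min_alt_reads: int = 10,
    scope: str = "any_tissue",
) -> list[VariantCandidate]:
    """Keep candidates with depth strictly over ``min_depth`` and at least
    ``min_alt_reads`` alternative reads, in at least one tissue
    (``any_tissue``, default) or in every tissue (``all_tissues``).

    Returns the retained candidates; every candidate's trail records the
    decision.
    """
    if scope not in ("any_tissue", "all_tissues"):
        raise ValueError("scope must be any_tissue or all_tissues")
    retained = []
    for c in candidates:
        oks = [sc.depth > min_depth and sc.alt >= min_alt_reads for sc in c.samples.values()]
        ok = any(oks) if scope == "any_tissue" else bool(oks) and all(oks)
        if ok:
            c.record("support_filter", True, f"depth>{min_depth} and alt>={min_alt_reads}")
            retained.append(c)
        else:
            c.record(
                "support_filter", False,
                f"no tissue with depth>{min_depth} and alt>={min_alt_reads}",
            )
    return retained
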