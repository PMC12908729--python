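"""Funnel accounting, qPCR relative quantification, and summary tables."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import VariantCandidate
from .io_core import STAGES

#: stages at which candidates can be excluded, in pipeline order
FILTER_STAGES = ("support_filter", "insert_screen", "wet_lab_exclusion", "anomaly")


@dataclass
class StageCount:
    stage: str
    entering: int
    excluded: int

    @property
    def surviving(self) -> int:
        return self.entering - self.excluded


@dataclass
class FilterFunnel:
    """Ordered accounting of candidates entering/excluded/surviving each stage.

    Conservation holds by construction and is re-checked on build:
    ``surviving(k) == entering(k+1)`` and
    ``final == called - sum(excluded)``.
    """

    called: int
    stages: list[StageCount]

    @property
    def final(self) -> int:
        return self.stages[-1].surviving if self.stages else self.called

    @property
    def retention(self) -> float:
        return self.final / self.called if self.called else 0.0

    @property
    def retention_percent(self) -> float:
        return 100.0 * self.retention

    def retention_formatted(self) -> dict[str, str]:
        """Rounded (3 significant figures) and truncated (2 dp) renditions.

        Published retention percentages are sometimes truncated rather
        than rounded, so both are reported and neither is guessed.
        """
        pct = self.retention_percent
        rounded = f"{pct:.3g}%"
        truncated = f"{np.floor(pct * 100) / 100:.2f}%"
        return {"rounded": rounded, "truncated": truncated}

    def surviving_after(self, stage: str) -> int:
        for sc in self.stages:
            if sc.stage == stage:
                return sc.surviving
        raise KeyError(stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [s.stage for s in self.stages],
                "entering": [s.entering for s in self.stages],
                "excluded": [s.excluded for s in self.stages],
                "surviving": [s.surviving for s in self.stages],
            }
        )

    def summary(self) -> str:
        lines = [f"candidates called: {self.called}"]
        for s in self.stages:
            lines.append(f"  {s.stage}: {s.entering} entering, {s.excluded} excluded, {s.surviving} surviving")
        fmt = self.retention_formatted()
        lines.append(
            f"final survivors: {self.final} / {self.called} "
            f"({fmt['rounded']} rounded, {fmt['truncated']} truncated)"
        )
        return "\n".join(lines)


def build_funnel(candidates: Sequence[VariantCandidate], stages: Sequence[str] = FILTER_STAGES) -> FilterFunnel:
    """Build the filter funnel from candidate status trails.

    Every candidate's trail must start at ``called``; exclusions are
    attributed to the stage recorded in the trail.  Stages a retained
    candidate never reached (e.g., when a run skipped the wet-lab list)
    count zero exclusions.
    """
    known = set(STAGES) | set(stages)
    excluded_at: dict[str, int] = {s: 0 for s in stages}
    called = 0
    for c in candidates:
        if not c.trail or c.trail[0][0] != "called":
            raise ValueError(f"{c.id}: status trail does not start at 'called'")
        called += 1
        for stage, status, _ in c.trail:
            if stage not in known:
                raise ValueError(f"{c.id}: unknown stage {stage!r} in trail")
            if status == "excluded":
                excluded_at[stage] = excluded_at.get(stage, 0) + 1
    counts = []
    entering = called
    for stage in stages:
        exc = excluded_at.get(stage, 0)
        counts.append(StageCount(stage, entering, exc))
        entering -= exc
    funnel = FilterFunnel(called, counts)
    # conservation identity
    assert funnel.final == called - sum(s.excluded for s in counts)
    return funnel


# ----------------------------------------------------------------------
# qPCR relative quantification
# ----------------------------------------------------------------------

def rq(cp_target: Sequence[float], cp_reference: Sequence[float]) -> float:
    """Relative symbiont load from qPCR cycle thresholds.

    RQ = 2^-(mean CP(target) - mean CP(reference)), the delta-CP method
    with the target locus on the symbiont (*wsp*) and the reference on a
    single-copy host nuclear gene.  Replicate CPs are averaged before
    the difference is taken.
    """
    t = np.asarray(cp_target, dtype=np.float64)
    r = np.asarray(cp_reference, dtype=np.float64)
    if t.size == 0 or r.size == 0:
        raise ValueError("at least one replicate is required for each locus")
    return float(2.0 ** -(t.mean() - r.mean()))


def rq_table(qpcr: pd.DataFrame, target: str = "wsp", reference: str = "TLeu") -> pd.DataFrame:
    """Per-sample RQ values from a long-format qPCR cycle table."""
    rows = []
    for sample, group in qpcr.groupby("sample", sort=True):
        t = group.loc[group["locus"] == target, "cp"].to_numpy()
        r = group.loc[group["locus"] == reference, "cp"].to_numpy()
        if t.size == 0 or r.size == 0:
            raise ValueError(f"sample {sample!r} lacks replicates for {target} or {reference}")
        rows.append((sample, t.mean(), r.mean(), rq(t, r)))
    return pd.DataFrame(rows, columns=["sample", f"mean_cp_{target}", f"mean_cp_{reference}", "rq"])


def variant_frequency_table(survivors: Sequence[VariantCandidate]) -> pd.DataFrame:
    """Per-variant per-tissue alternative-allele frequency table.

    One row per variant x tissue with position (1-based), alleles,
    depth, alt count and frequency; a survivor without reads in a tissue
    reports frequency 0 there.  Functional-effect columns are left to
    external annotation tools.
    """
    rows = []
    for c in sorted(survivors, key=lambda c: (c.reference, c.position, c.alt)):
        for tissue in sorted(c.samples):
            sc = c.samples[tissue]
            rows.append(
                (
                    c.reference, c.position + 1, c.ref, c.alt, tissue,
                    sc.depth, sc.alt, sc.fraction,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["reference", "position", "ref", "alt", "tissue", "depth", "alt_count", "frequency"],
    )
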