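"""Window-based coverage profiles and depth review around candidate sites.

Coverage along the symbiont genome is summarised as mean per-base depth
over adjacent, non-overlapping windows (5 kb by default), and normalised
by dividing each window by the median over all windows, so a copy-neutral
region sits at 1.  Depth around validated sites is reviewed over 100-bp
windows to flag collapsed repeats and similar assembly anomalies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignments import ReadSet
from .io_core import SymbiontGenome


@dataclass
class WindowCoverageProfile:
    """Raw and median-normalised depth over adjacent windows.

    ``base_sums`` holds the exact integer number of aligned bases per
    window, so ``sum(base_sums) == total aligned bases`` holds as an
    integer identity.  ``normalized`` is NaN-free only when the median
    window depth is positive; otherwise ``normalization_defined`` is
    False and the profile is flagged.
    """

    sample: str | None
    reference: str
    window_size: int
    starts: np.ndarray
    ends: np.ndarray
    depth: np.ndarray          # mean per-base depth per window
    normalized: np.ndarray
    median: float
    base_sums: np.ndarray
    normalization_defined: bool = True

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "reference": self.reference,
                "start": self.starts,
                "end": self.ends,
                "depth": self.depth,
                "normalized": self.normalized,
            }
        )

    def to_bedgraph(self, path) -> None:
        """Write a BEDGRAPH-style TSV (reference, start, end, raw, normalized)."""
        self.to_frame().to_csv(path, sep="\t", index=False, header=True, lineterminator="\n")


def _window_profile(depth: np.ndarray, window_size: int, reference: str, sample=None) -> WindowCoverageProfile:
    L = len(depth)
    starts = np.arange(0, L, window_size, dtype=np.int64)
    ends = np.minimum(starts + window_size, L)
    edges = np.append(starts, L)
    base_sums = np.add.reduceat(depth, starts)
    lengths = (ends - starts).astype(np.float64)
    means = base_sums / lengths
    med = float(np.median(means))
    defined = med > 0
    normalized = means / med if defined else np.full_like(means, np.nan)
    return WindowCoverageProfile(
        sample, reference, window_size, starts, ends, means, normalized,
        med, base_sums.astype(np.int64), defined,
    )


def window_coverage(
    alignments: ReadSet,
    genome: SymbiontGenome,
    window_size: int = 5000,
    min_baseq: int = 0,
) -> WindowCoverageProfile:
    """Mean per-base depth over adjacent ``window_size`` windows.

    Depth counts reference-consuming called bases (deleted columns add
    span but no base).  The trailing partial window of a genome whose
    length is not a multiple of ``window_size`` is kept as its own,
    shorter window; because the statistic is per-base, this introduces
    no bias.  An all-zero profile is returned flagged, with the
    normalised track undefined.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if alignments.ref_length != len(genome):
        raise ValueError("alignment reference length does not match genome")
    depth = alignments.depth(min_baseq).astype(np.float64)
    return _window_profile(depth, window_size, genome.name, alignments.sample)


def normalize_profile(profile: WindowCoverageProfile) -> WindowCoverageProfile:
    """Median-normalise a profile's depth track (idempotent)."""
    med = float(np.median(profile.depth))
    if med <= 0:
        return profile
    normalized = profile.depth / med
    return WindowCoverageProfile(
        profile.sample, profile.reference, profile.window_size,
        profile.starts, profile.ends, normalized, normalized / float(np.median(normalized)),
        1.0, profile.base_sums, True,
    )


def depth_around(
    alignments: ReadSet,
    position: int,
    span: int,
    window_size: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean depth per adjacent ``window_size`` window across +/- ``span``.

    Returns ``(midpoints, values)``; the central window contains the
    site.  ``span == 0`` yields that single window.  On circular
    references the windows wrap; on linear ones a span that runs off the
    reference is an error.
    """
    L = alignments.ref_length
    if not 0 <= position < L:
        raise ValueError("position outside the reference")
    m = 2 * (span // window_size) + 1
    half = window_size // 2
    first = position - half - (m // 2) * window_size
    starts = first + np.arange(m, dtype=np.int64) * window_size
    if not alignments.circular:
        if starts[0] < 0 or starts[-1] + window_size > L:
            raise ValueError("review span exceeds the linear reference")
    depth = alignments.depth().astype(np.float64)
    values = np.empty(m)
    for i, s in enumerate(starts):
        idx = np.arange(s, s + window_size)
        if alignments.circular:
            idx %= L
        values[i] = depth[idx].mean()
    midpoints = starts + window_size // 2
    if alignments.circular:
        midpoints = midpoints % L
    return midpoints, values


def flag_depth_anomaly(values: np.ndarray, fold_threshold: float = 2.0) -> tuple[bool, str]:
    """Flag a depth series whose extremes depart from its median by a fold factor.

    Returns ``(anomalous, summary)``.  An all-zero series is anomalous
    by convention (nothing aligned where coverage was expected).
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty depth series")
    med = float(np.median(values))
    if med <= 0:
        return True, "all-zero or zero-median depth series"
    folds = values / med
    hi = float(folds.max())
    lo = float(folds.min())
    anomalous = hi >= fold_threshold or lo <= 1.0 / fold_threshold
    return anomalous, f"max fold {hi:.3g}, min fold {lo:.3g} vs threshold {fold_threshold:g}"
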