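"""Validation step 1: the uninfected-line window screen.

Endosymbiont DNA inserted into the host nuclear genome attracts reads
from symbiont-free host individuals.  A candidate variant whose
surrounding 300-bp window (starting 150 bp before the site) contains at
least two reads from uninfected lines is therefore best explained by a
nuclear insert, not by symbiont polymorphism, and is excluded.  A
wet-lab exclusion list (PCR amplification in uninfected hosts) can be
applied as a second, data-driven step.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignments import ReadSet
from .calling import VariantCandidate
from .io_core import read_exclusion_list


def screen_window(position: int, ref_length: int, circular: bool, flank: int = 150, window: int = 300) -> tuple[int, int]:
    """The half-open screen window around a candidate position.

    Starts ``flank`` bp before the site and spans ``window`` bp; wraps
    on circular references and is truncated at the edges of linear ones.
    """
    start = position - flank
    end = start + window
    if not circular:
        start = max(start, 0)
        end = min(end, ref_length)
    return start, end


def count_uninfected_reads(
    window: tuple[int, int],
    uninfected: Iterable[ReadSet],
    min_mapq: int = 0,
) -> int:
    """Number of distinct uninfected-line reads overlapping the window.

    Overlap of >= 1 aligned base suffices; counts are pooled across the
    uninfected samples.  Secondary and supplementary alignments are
    already excluded at load time, and the mapping-quality floor
    defaults to 0 — the most conservative setting toward exclusion.
    """
    del min_mapq  # ReadSet holds primary, uniquely-placed alignments only
    start, end = window
    total = 0
    for rs in uninfected:
        total += len(rs.reads_overlapping(start, end))
    return total


def screen(
    candidates: Sequence[VariantCandidate],
    uninfected: Mapping[str, ReadSet] | Sequence[ReadSet],
    threshold: int = 2,
    flank: int = 150,
    window: int = 300,
    min_mapq: int = 0,
    pooled: bool = True,
) -> list[VariantCandidate]:
    """Exclude candidates whose window holds >= ``threshold`` uninfected reads.

    With ``pooled`` (default, matching the published procedure) the
    count is summed over all uninfected samples; otherwise the threshold
    must be met within a single sample.
    """
    readsets = list(uninfected.values()) if isinstance(uninfected, Mapping) else list(uninfected)
    retained = []
    for c in candidates:
        if readsets:
            L = readsets[0].ref_length
            circular = readsets[0].circular
            if c.reference != readsets[0].reference:
                raise ValueError(
                    f"candidate reference {c.reference!r} absent from uninfected alignments"
                )
        else:
            L, circular = None, False
        if readsets:
            win = screen_window(c.position, L, circular, flank, window)
            if pooled:
                count = count_uninfected_reads(win, readsets, min_mapq)
                hit = count >= threshold
            else:
                counts = [count_uninfected_reads(win, [rs], min_mapq) for rs in readsets]
                count = max(counts)
                hit = any(n >= threshold for n in counts)
        else:
            count, hit = 0, False
        if hit:
            c.record("insert_screen", False, f"nuclear-insert evidence: {count} uninfected reads")
        else:
            c.record("insert_screen", True, f"{count} uninfected reads in window")
            retained.append(c)
    return retained


def apply_exclusion_list(
    candidates: Sequence[VariantCandidate], path
) -> tuple[list[VariantCandidate], list[tuple]]:
    """Exclude candidates named in a wet-lab exclusion TSV.

    Rows are (reference, 1-based position, ref, alt).  Returns the
    retained candidates and the rows that matched no candidate (reported
    rather than silently dropped).
    """
    rows = read_exclusion_list(path)
    keyed = {(r, p, a, b) for r, p, a, b in rows}
    matched = set()
    retained = []
    for c in candidates:
        key = (c.reference, c.position, c.ref, c.alt)
        if key in keyed:
            matched.add(key)
            c.record("wet_lab_exclusion", False, "wet-lab PCR evidence")
        else:
            c.record("wet_lab_exclusion", True, "")
            retained.append(c)
    unmatched = [row for row in rows if row not in matched]
    return retained, unmatched
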