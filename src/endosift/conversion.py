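"""Gene-conversion detection between homologous region pairs.

A conversion event copies one locus's sequence onto its paralog.  When
reads from a converted population are mapped against the unconverted
reference, reads drawn from the acceptor locus now match the donor and
are placed there by the aligner, leaving a sharp coverage deficit at the
acceptor, a matching excess at the donor, and — among the reads that
paired-end constraints keep anchored at the acceptor — donor alleles at
every diagnostic site.  The detector requires all three signals; generic
structural-variant calling is not reimplemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alignments import BASES, ReadSet
from .io_core import SymbiontGenome


@dataclass(frozen=True)
class DiagnosticSite:
    """A position at which the two homologous tracts carry different alleles."""

    offset: int    # offset within the tract
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError("diagnostic site alleles must differ")


@dataclass(frozen=True)
class HomologousPair:
    """Two equal-length, near-identical tracts on the same reference."""

    reference: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    identity: float
    sites: tuple[DiagnosticSite, ...]

    def __post_init__(self) -> None:
        if self.a_end - self.a_start != self.b_end - self.b_start:
            raise ValueError("homologous tracts must have equal lengths")

    @property
    def tract_length(self) -> int:
        return self.a_end - self.a_start

    @property
    def detectable(self) -> bool:
        return len(self.sites) > 0

    @property
    def pair_id(self) -> str:
        return f"{self.reference}:{self.a_start}-{self.a_end}~{self.b_start}-{self.b_end}"

    def site_positions(self, region: str) -> np.ndarray:
        start = self.a_start if region == "A" else self.b_start
        return np.array([start + s.offset for s in self.sites], dtype=np.int64)


@dataclass
class ConversionCall:
    """Evidence bundle for one sample x pair x direction."""

    sample: str | None
    pair_id: str
    direction: str               # "B_to_A" or "A_to_B" (donor -> acceptor)
    acceptor_ratio: float        # tract depth / flank depth at the acceptor
    donor_ratio: float
    donor_allele_fraction: float | None
    verdict: str                 # conversion | none | undetectable
    criteria: dict = field(default_factory=dict)


def write_pairs_tsv(pairs: Sequence[HomologousPair], path) -> None:
    rows = []
    for p in pairs:
        sites = ";".join(f"{s.offset}:{s.allele_a}:{s.allele_b}" for s in p.sites)
        rows.append((p.reference, p.a_start, p.a_end, p.b_start, p.b_end, p.identity, sites))
    pd.DataFrame(
        rows,
        columns=["reference", "a_start", "a_end", "b_start", "b_end", "identity", "sites"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_pairs_tsv(path) -> list[HomologousPair]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False, float_precision="round_trip")
    pairs = []
    for row in frame.itertuples(index=False):
        sites = tuple(
            DiagnosticSite(int(o), a, b)
            for o, a, b in (tok.split(":") for tok in str(row.sites).split(";") if tok)
        )
        pairs.append(
            HomologousPair(
                row.reference, int(row.a_start), int(row.a_end),
                int(row.b_start), int(row.b_end), float(row.identity), sites,
            )
        )
    return pairs


# ----------------------------------------------------------------------
# pair discovery
# ----------------------------------------------------------------------

def find_pairs(
    genome: SymbiontGenome,
    min_tract: int = 100,
    min_identity: float = 0.95,
    seed_k: int = 16,
) -> list[HomologousPair]:
    """Find non-overlapping near-identical tract pairs by seeded self-comparison.

    Exact ``seed_k``-mer matches between distinct positions seed
    candidate offsets; each offset's gap-free mismatch track is then
    scanned for maximal tracts with identity >= ``min_identity`` and
    length >= ``min_tract``, trimmed to end on matching bases.
    Diagnostic sites are the positionwise differences within a tract.
    Comparison is gap-free, which the >= 80%-identity regime justifies;
    the search does not cross the origin of circular genomes.
    """
    codes = genome.codes
    L = len(codes)
    if L < 2 * seed_k:
        return []
    # hash k-mers (only unambiguous ones)
    ar = np.arange(L - seed_k + 1)
    window = codes[ar[:, None] + np.arange(seed_k)]
    valid = (window <= 3).all(axis=1)
    key = np.zeros(len(ar), dtype=np.int64)
    for j in range(seed_k):
        key = key * 4 + window[:, j]
    order = np.argsort(key[valid], kind="stable")
    pos_valid = ar[valid][order]
    key_sorted = key[valid][order]
    # candidate offsets from duplicate k-mers
    deltas: dict[int, int] = {}
    start = 0
    n = len(key_sorted)
    while start < n:
        stop = start
        while stop + 1 < n and key_sorted[stop + 1] == key_sorted[start]:
            stop += 1
        if stop > start:
            group = np.sort(pos_valid[start : stop + 1])
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    d = int(group[j] - group[i])
                    if d >= seed_k:
                        deltas[d] = deltas.get(d, 0) + 1
        start = stop + 1
    pairs: list[HomologousPair] = []
    max_mismatch_frac = 1.0 - min_identity
    for d in sorted(deltas):
        match = codes[: L - d] == codes[d:]
        match &= (codes[: L - d] <= 3) & (codes[d:] <= 3)
        tracts = [
            (s, e) for s, e in _maximal_tracts(match, max_mismatch_frac, min_tract)
            if e - s <= d  # otherwise the two tracts would overlap each other
        ]
        for s, e in _merge_alternatives(tracts, match):
            diffs = np.flatnonzero(~match[s:e])
            identity = 1.0 - len(diffs) / (e - s)
            sites = tuple(
                DiagnosticSite(int(o), BASES[codes[s + o]], BASES[codes[s + d + o]])
                for o in diffs
            )
            pairs.append(HomologousPair(genome.name, s, e, s + d, e + d, identity, sites))
    pairs.sort(key=lambda p: (p.a_start, p.b_start))
    return pairs


def _merge_alternatives(tracts, match):
    """Collapse overlapping same-offset tracts to one representative.

    Greedy growth from different seed runs can stop at alternative
    boundaries of the same homologous tract; of each overlapping
    cluster, keep the interval with the sharpest boundary contrast —
    highest inside identity minus mean identity of the 30 bp just
    outside each end — so the reported tract is the near-identical core
    whose edges fall where homology actually collapses.
    """
    tracts = sorted(tracts)
    out = []
    cluster: list[tuple[int, int]] = []
    for s, e in tracts:
        if cluster and s < cluster[-1][1]:
            cluster.append((s, e))
        else:
            if cluster:
                out.append(_best_tract(cluster, match))
            cluster = [(s, e)]
    if cluster:
        out.append(_best_tract(cluster, match))
    return out


def _best_tract(cluster, match, context: int = 30):
    n = len(match)

    def score(t):
        s, e = t
        ident = match[s:e].mean()
        left = match[max(0, s - context) : s]
        right = match[e : min(n, e + context)]
        out = np.concatenate([left, right])
        contrast = ident - (out.mean() if len(out) else 0.0)
        return (contrast, ident, e - s, -s)

    return max(cluster, key=score)


def _maximal_tracts(match: np.ndarray, max_mismatch_frac: float, min_len: int):
    """Maximal match-bounded intervals with mismatch fraction <= threshold.

    Greedy closure: starting from each maximal exact run, repeatedly
    absorb the adjacent mismatch plus following/preceding run while the
    interval's overall mismatch fraction stays within budget; report an
    interval once, when it can no longer grow.
    """
    n = len(match)
    if n == 0:
        return []
    # exact runs of matches
    padded = np.concatenate(([False], match, [False]))
    diff = padded[1:].astype(np.int8) - padded[:-1].astype(np.int8)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    runs = list(zip(starts.tolist(), ends.tolist()))
    if not runs:
        return []
    results = []
    reported: set[tuple[int, int]] = set()
    i = 0
    while i < len(runs):
        li = ri = i
        s, e = runs[i]
        mism = 0
        grown = True
        while grown:
            grown = False
            # absorb the next run (the gap between runs costs mismatches)
            if ri + 1 < len(runs):
                ns, ne = runs[ri + 1]
                gap = ns - e
                if (mism + gap) / (ne - s) <= max_mismatch_frac:
                    mism += gap
                    e = ne
                    ri += 1
                    grown = True
                    continue
            # absorb the previous run
            if li > 0:
                ps, pe = runs[li - 1]
                gap = s - pe
                if (mism + gap) / (e - ps) <= max_mismatch_frac:
                    mism += gap
                    s = ps
                    li -= 1
                    grown = True
        if e - s >= min_len and (s, e) not in reported:
            reported.add((s, e))
            results.append((s, e))
        # a long exact run is itself a candidate boundary choice: for a
        # perfectly identical tract it is the natural report, undiluted
        # by absorbed context
        rs_, re_ = runs[i]
        if re_ - rs_ >= min_len and (rs_, re_) not in reported:
            reported.add((rs_, re_))
            results.append((rs_, re_))
        i += 1
    # overlapping alternatives are resolved downstream by boundary contrast
    results.sort()
    return results


# ----------------------------------------------------------------------
# evidence extraction
# ----------------------------------------------------------------------

@dataclass
class AlleleProfile:
    """Per-diagnostic-site allele counts at one region of a pair."""

    region: str
    positions: np.ndarray
    own_counts: np.ndarray
    partner_counts: np.ndarray
    other_counts: np.ndarray
    partner_fraction: float | None  # pooled; None when nothing is informative

    @property
    def defined(self) -> bool:
        return self.partner_fraction is not None


def diagnostic_allele_profile(
    alignments: ReadSet, pair: HomologousPair, region: str = "A"
) -> AlleleProfile:
    """Count region-own vs partner-region alleles at each diagnostic site.

    The pooled partner-allele fraction is
    ``partner / (own + partner)`` over all sites; bases matching neither
    allele (errors) are tallied separately.  Zero informative coverage
    yields an undefined fraction, flagged via :attr:`AlleleProfile.defined`.
    """
    if region not in ("A", "B"):
        raise ValueError("region must be 'A' or 'B'")
    if not pair.detectable:
        raise ValueError("pair has no diagnostic sites")
    positions = pair.site_positions(region)
    own_alleles = [s.allele_a if region == "A" else s.allele_b for s in pair.sites]
    partner_alleles = [s.allele_b if region == "A" else s.allele_a for s in pair.sites]
    own = np.zeros(len(positions), dtype=np.int64)
    partner = np.zeros(len(positions), dtype=np.int64)
    other = np.zeros(len(positions), dtype=np.int64)
    for i, (pos, oa, pa) in enumerate(zip(positions, own_alleles, partner_alleles)):
        _, bases, _ = alignments.bases_at(int(pos))
        oc = BASES.index(oa)
        pc = BASES.index(pa)
        own[i] = int((bases == oc).sum())
        partner[i] = int((bases == pc).sum())
        other[i] = int(((bases != oc) & (bases != pc) & (bases <= 3)).sum())
    informative = int(own.sum() + partner.sum())
    fraction = float(partner.sum() / informative) if informative > 0 else None
    return AlleleProfile(region, positions, own, partner, other, fraction)


def _interval_mean_depth(depth: np.ndarray, start: int, end: int, circular: bool) -> float:
    L = len(depth)
    idx = np.arange(start, end)
    if circular:
        idx %= L
    else:
        idx = idx[(idx >= 0) & (idx < L)]
    if len(idx) == 0:
        return float("nan")
    return float(depth[idx].mean())


def _flank_mean_depth(
    depth: np.ndarray,
    start: int,
    end: int,
    flank: int,
    circular: bool,
    exclude: Sequence[tuple[int, int]],
) -> float:
    """Mean depth over `flank` bp on each side, skipping excluded intervals."""
    L = len(depth)
    idx = np.concatenate([np.arange(start - flank, start), np.arange(end, end + flank)])
    if circular:
        idx %= L
    else:
        idx = idx[(idx >= 0) & (idx < L)]
    mask = np.ones(len(idx), dtype=bool)
    for (xs, xe) in exclude:
        mask &= ~((idx >= xs) & (idx < xe))
    idx = idx[mask]
    if len(idx) == 0:
        return float("nan")
    return float(depth[idx].mean())


def detect(
    alignments: ReadSet,
    pairs: Sequence[HomologousPair],
    drop_ratio: float = 0.5,
    rise_ratio: float = 1.5,
    allele_min: float = 0.9,
    flank: int = 2000,
    exclude_regions: Sequence[tuple[int, int]] | None = None,
) -> list[ConversionCall]:
    """Call gene conversion for one sample over a catalog of pairs.

    For direction donor->acceptor, a ``conversion`` verdict requires all
    three criteria: (i) acceptor tract depth / flank depth <= ``drop_ratio``,
    (ii) donor tract depth / flank depth >= ``rise_ratio``, and (iii)
    donor-allele fraction >= ``allele_min`` at the acceptor's diagnostic
    sites among reads still anchored there.  Tract and flank statistics
    are means of per-base depth over the exact intervals (windows finer
    than half the tract, as required to resolve it).  Partial evidence
    is recorded on ``none`` verdicts; a pair with no diagnostic site is
    ``undetectable``.
    """
    depth = alignments.depth().astype(np.float64)
    calls: list[ConversionCall] = []
    catalog_intervals = [(p.a_start, p.a_end) for p in pairs] + [(p.b_start, p.b_end) for p in pairs]
    if exclude_regions:
        catalog_intervals += list(exclude_regions)
    for pair in pairs:
        if not pair.detectable:
            calls.append(
                ConversionCall(alignments.sample, pair.pair_id, "B_to_A",
                               float("nan"), float("nan"), None, "undetectable")
            )
            continue
        ratio = {}
        for region, (s, e) in (("A", (pair.a_start, pair.a_end)), ("B", (pair.b_start, pair.b_end))):
            tract = _interval_mean_depth(depth, s, e, alignments.circular)
            fl = _flank_mean_depth(depth, s, e, flank, alignments.circular, catalog_intervals)
            ratio[region] = tract / fl if fl > 0 else float("nan")
        profiles = {r: diagnostic_allele_profile(alignments, pair, r) for r in ("A", "B")}
        best = None
        for direction, acceptor, donor in (("B_to_A", "A", "B"), ("A_to_B", "B", "A")):
            prof = profiles[acceptor]
            crit = {
                "acceptor_drop": bool(np.isfinite(ratio[acceptor]) and ratio[acceptor] <= drop_ratio),
                "donor_rise": bool(np.isfinite(ratio[donor]) and ratio[donor] >= rise_ratio),
                "allele_switch": bool(prof.defined and prof.partner_fraction >= allele_min),
            }
            call = ConversionCall(
                alignments.sample, pair.pair_id, direction,
                ratio[acceptor], ratio[donor], prof.partner_fraction,
                "conversion" if all(crit.values()) else "none", crit,
            )
            if best is None or sum(call.criteria.values()) > sum(best.criteria.values()):
                best = call
            if call.verdict == "conversion":
                best = call
                break
        calls.append(best)
    return calls


@dataclass
class RemapCheck:
    """Outcome of single-end best-placement rescoring of acceptor reads."""

    n_reads: int
    better_donor: int
    better_acceptor: int
    ties: int
    unresolved: int  # reads covering no diagnostic site

    @property
    def fraction_reassigned(self) -> float | None:
        resolved = self.better_donor + self.better_acceptor + self.ties
        return self.better_donor / resolved if resolved else None


def unpaired_remap_check(
    alignments: ReadSet, pair: HomologousPair, acceptor: str = "A"
) -> RemapCheck:
    """Rescore reads anchored at the acceptor tract against both copies.

    Emulates realigning without the paired-end constraint: each read
    overlapping the acceptor tract is scored by match/mismatch against
    the acceptor and donor tract sequences at its mapped offset.  The
    two tracts are identical away from the diagnostic sites, so the
    placement is decided by the diagnostic alleles the read carries; a
    read covering none of them is a tie, counted as unresolved.
    """
    if not pair.detectable:
        raise ValueError("pair has no diagnostic sites")
    if acceptor == "A":
        t_start, t_end = pair.a_start, pair.a_end
        acc_alleles = [s.allele_a for s in pair.sites]
        don_alleles = [s.allele_b for s in pair.sites]
    else:
        t_start, t_end = pair.b_start, pair.b_end
        acc_alleles = [s.allele_b for s in pair.sites]
        don_alleles = [s.allele_a for s in pair.sites]
    idx = alignments.reads_overlapping(t_start, t_end)
    if len(idx) == 0:
        raise ValueError("no reads over the acceptor tract")
    acc_score = np.zeros(len(idx), dtype=np.int64)
    don_score = np.zeros(len(idx), dtype=np.int64)
    covered = np.zeros(len(idx), dtype=np.int64)
    lookup = {int(r): k for k, r in enumerate(idx)}
    for site, oa, ob in zip(pair.sites, acc_alleles, don_alleles):
        pos = t_start + site.offset
        rid, bases, _ = alignments.bases_at(int(pos))
        oc = BASES.index(oa)
        dc = BASES.index(ob)
        for r, b in zip(rid, bases):
            k = lookup.get(int(r))
            if k is None:
                continue
            covered[k] += 1
            if b == oc:
                acc_score[k] += 1
            elif b == dc:
                don_score[k] += 1
    has_diag = covered > 0
    better_d = int(((don_score > acc_score) & has_diag).sum())
    better_a = int(((acc_score > don_score) & has_diag).sum())
    ties = int(((acc_score == don_score) & has_diag).sum())
    unresolved = int((~has_diag).sum())
    return RemapCheck(len(idx), better_d, better_a, ties, unresolved)
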