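"""Validation step 3: allele-partitioned alignment-anomaly tests.

Reads covering a candidate SNP are split by the allele they carry.  If
the alternative-allele reads come from a diverged sequence (a nuclear
insert missed by the window screen, or a related bacterium), they tend
to show a higher proportion of clipped reads, a lower proportion of
properly paired reads, and more mismatches against the reference.  For
each candidate, three Fisher exact tests compare these features between
the reference-allele and alternative-allele read groups; after
Benjamini-Hochberg FDR correction, a candidate with any adjusted
p-value below the significance level is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .alignments import BASES, ReadSet
from .calling import VariantCandidate
from .io_core import SymbiontGenome

FEATURES = ("clipped", "proper_pair", "mismatch")


@dataclass
class AlleleGroup:
    """Per-read alignment features for one allele group at a site."""

    n: int
    clipped: int
    proper: int
    mismatch_bases: int      # mismatches vs reference, excluding the focal site
    aligned_bases: int       # aligned called bases, excluding the focal column
    reads_with_mismatch: int

    @property
    def matching_bases(self) -> int:
        return self.aligned_bases - self.mismatch_bases


@dataclass
class AllelePartition:
    candidate_id: str
    ref_group: AlleleGroup
    alt_group: AlleleGroup

    @property
    def testable(self) -> bool:
        return self.ref_group.n > 0 and self.alt_group.n > 0


@dataclass
class FeatureTestResult:
    candidate_id: str
    feature: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    p_adjusted: float | None = None
    excluded: bool = False


def partition_reads(
    samples: Mapping[str, ReadSet] | ReadSet,
    candidate: VariantCandidate,
    genome: SymbiontGenome,
    min_baseq: int = 13,
) -> AllelePartition:
    """Split the reads covering a candidate SNP by carried allele.

    Reads are pooled across the provided samples.  A read joins the
    reference or alternative group according to its base at the site
    (quality floor applied when qualities are available); reads carrying
    a third allele, a deleted column, or a sub-threshold base belong to
    neither group.  The per-read mismatch count excludes the focal site:
    alternative-allele reads have one mismatch subtracted.
    """
    if not candidate.is_snp:
        raise ValueError(f"{candidate.id}: allele partitioning requires a SNP")
    readsets = [samples] if isinstance(samples, ReadSet) else list(samples.values())
    ref_code = BASES.index(candidate.ref)
    alt_code = BASES.index(candidate.alt)
    groups = {ref_code: [], alt_code: []}
    stats = {ref_code: np.zeros(6, dtype=np.int64), alt_code: np.zeros(6, dtype=np.int64)}
    for rs in readsets:
        idx, bases, quals = rs.bases_at(candidate.position)
        if len(idx) == 0:
            continue
        if quals is not None and min_baseq > 0:
            keep = quals >= min_baseq
            idx, bases = idx[keep], bases[keep]
        nm = rs.nm_array(genome.codes)
        span = rs.span
        for code in (ref_code, alt_code):
            sel = idx[bases == code]
            if len(sel) == 0:
                continue
            is_alt = code == alt_code
            mism = nm[sel] - (1 if is_alt else 0)
            mism = np.maximum(mism, 0)
            s = stats[code]
            s[0] += len(sel)
            s[1] += int(rs.clipped[sel].sum())
            s[2] += int(rs.proper[sel].sum())
            s[3] += int(mism.sum())
            s[4] += int((span[sel] - 1).sum())
            s[5] += int((mism > 0).sum())

    def group(code) -> AlleleGroup:
        s = stats[code]
        return AlleleGroup(int(s[0]), int(s[1]), int(s[2]), int(s[3]), int(s[4]), int(s[5]))

    return AllelePartition(candidate.id, group(ref_code), group(alt_code))


# ----------------------------------------------------------------------
# Fisher exact test
# ----------------------------------------------------------------------

_TIE_EPS = 1e-11  # relative slack when comparing floating-point pmf values


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table.

    Sums, over the hypergeometric support with the observed margins, the
    probabilities of all tables no more probable than the observed one
    (probabilities computed in log space; ties detected with a relative
    tolerance well below the spacing of distinct hypergeometric
    probabilities).  A zero margin leaves a single possible table, so
    p = 1 by convention.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("contingency table cells must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    x = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
        + gammaln(r2 + 1) - gammaln(c1 - x + 1) - gammaln(r2 - c1 + x + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    obs = logpmf[a - lo]
    mask = logpmf <= obs + _TIE_EPS
    return float(min(1.0, np.exp(logsumexp(logpmf[mask]))))


def fdr_adjust(p_values: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def feature_tables(partition: AllelePartition, mismatch_mode: str = "base"):
    """The three 2x2 tables (ref group vs alt group) for one candidate."""
    r, a = partition.ref_group, partition.alt_group
    tables = {
        "clipped": ((r.clipped, r.n - r.clipped), (a.clipped, a.n - a.clipped)),
        "proper_pair": ((r.proper, r.n - r.proper), (a.proper, a.n - a.proper)),
    }
    if mismatch_mode == "base":
        tables["mismatch"] = (
            (r.mismatch_bases, r.matching_bases),
            (a.mismatch_bases, a.matching_bases),
        )
    elif mismatch_mode == "read":
        tables["mismatch"] = (
            (r.reads_with_mismatch, r.n - r.reads_with_mismatch),
            (a.reads_with_mismatch, a.n - a.reads_with_mismatch),
        )
    else:
        raise ValueError("mismatch_mode must be 'base' or 'read'")
    return tables


def run_battery(
    candidates: Sequence[VariantCandidate],
    samples: Mapping[str, ReadSet],
    genome: SymbiontGenome,
    alpha: float = 0.05,
    fdr_scope: str = "global",
    mismatch_mode: str = "base",
    min_baseq: int = 13,
) -> tuple[list[VariantCandidate], list[FeatureTestResult]]:
    """Run the three-feature anomaly battery and record exclusion decisions.

    Indel candidates are skipped (carried through untested); SNP
    candidates whose site is uncovered, or where one allele group is
    empty, are untestable and retained with an ``untestable`` flag that
    marks them for manual review.  FDR correction is applied either over
    the pooled candidate x feature family (``global``, default) or
    within each candidate (``per_candidate``).  A candidate is excluded
    iff any adjusted p-value is strictly below ``alpha``.
    """
    for rs in samples.values():
        rs.nm_array(genome.codes)  # ensure mismatch counts exist before pooling
    results: list[FeatureTestResult] = []
    per_candidate: dict[str, list[FeatureTestResult]] = {}
    testable_candidates = []
    for c in candidates:
        if not c.is_snp:
            c.flags.append("anomaly_skipped_indel")
            continue
        part = partition_reads(samples, c, genome, min_baseq)
        if not part.testable:
            c.flags.append("untestable")
            continue
        tests = []
        for feature, table in feature_tables(part, mismatch_mode).items():
            res = FeatureTestResult(c.id, feature, table, fisher_exact(table))
            tests.append(res)
        per_candidate[c.id] = tests
        results.extend(tests)
        testable_candidates.append(c)
    if fdr_scope == "global":
        if results:
            adjusted = fdr_adjust([r.p_value for r in results])
            for r, q in zip(results, adjusted):
                r.p_adjusted = float(q)
    elif fdr_scope == "per_candidate":
        for tests in per_candidate.values():
            adjusted = fdr_adjust([r.p_value for r in tests])
            for r, q in zip(tests, adjusted):
                r.p_adjusted = float(q)
    else:
        raise ValueError("fdr_scope must be 'global' or 'per_candidate'")
    retained = []
    for c in candidates:
        tests = per_candidate.get(c.id)
        if tests is None:
            # untestable or indel: retained, flagged for manual review
            c.record("anomaly", True, ";".join(c.flags) or "untested")
            retained.append(c)
            continue
        offending = [r.feature for r in tests if r.p_adjusted is not None and r.p_adjusted < alpha]
        for r in tests:
            r.excluded = bool(offending)
        if offending:
            c.record("anomaly", False, "anomalous features: " + ",".join(offending))
        else:
            c.record("anomaly", True, "no significant feature difference")
            retained.append(c)
    return retained, results


def results_frame(results: Sequence[FeatureTestResult]):
    """Per-candidate per-feature tables and p-values as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "candidate": [r.candidate_id for r in results],
            "feature": [r.feature for r in results],
            "table": [str(r.table) for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "excluded": [r.excluded for r in results],
        }
    )
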