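"""Planted-truth recovery and oracle-agreement evaluations.

These routines validate the pipeline against independent references: a
funnel rebuilt from published stage counts, exact-arithmetic references
for the Fisher test and the Benjamini-Hochberg adjustment, and
planted-truth recovery rates measured on the synthetic generator's
study conditions.  They are used by the test suite and by the
reproduction script; every quantity is recomputed from scratch at call
time.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

from . import calling, conversion, coverage, insert_screen, pipeline
from .anomaly import fdr_adjust, fisher_exact
from .calling import SampleCounts, VariantCandidate
from .reporting import FilterFunnel, build_funnel
from .synthetic_data import (
    ArtifactSpec,
    ConversionSpec,
    PlantedVariant,
    SimulationDesign,
    TissueSpec,
    simulate,
)


def _child_seed(base_seed: int, k: int) -> int:
    return int((base_seed * 100_003 + 7919 * (k + 1)) % (2**31 - 1))


# ----------------------------------------------------------------------
# funnel arithmetic from published stage counts
# ----------------------------------------------------------------------

def funnel_from_counts(called: int, excluded_by_stage: dict[str, int]) -> FilterFunnel:
    """Rebuild the filter funnel from per-stage exclusion counts.

    Constructs one candidate trail per called variant, excluding the
    stated number at each stage in pipeline order, and runs the regular
    funnel accounting over them — so the stage bookkeeping itself is
    exercised, not just arithmetic.
    """
    from .reporting import FILTER_STAGES

    candidates = []
    budget = dict(excluded_by_stage)
    for i in range(called):
        c = VariantCandidate("ref", i, "A", "C", {"s": SampleCounts(1000, 100)})
        c.record("called", True)
        for stage in FILTER_STAGES:
            if budget.get(stage, 0) > 0:
                budget[stage] -= 1
                c.record(stage, False, "reported exclusion")
                break
            c.record(stage, True)
        else:
            c.record("final", True)
        candidates.append(c)
    remaining = {k: v for k, v in budget.items() if v}
    if remaining:
        raise ValueError(f"more exclusions than candidates: {remaining}")
    return build_funnel(candidates)


# ----------------------------------------------------------------------
# Fisher / BH reference agreement
# ----------------------------------------------------------------------

def fisher_reference_sweep(max_total: int = 40) -> dict:
    """Compare :func:`fisher_exact` with exact rational enumeration.

    Enumerates every 2x2 table whose cell total is at most ``max_total``
    (grouped by margins, so each hypergeometric support is enumerated
    once) and computes the two-sided p-value with exact integer
    arithmetic: the observed table's probability weight is
    ``C(r1, a) * C(r2, c)`` over the common denominator ``C(n, c1)``,
    and the p-value sums the weights of support tables no more probable
    than the observed.  Returns the maximum relative error and the
    number of tables checked.
    """
    max_rel = 0.0
    n_tables = 0
    for n in range(1, max_total + 1):
        for r1 in range(n + 1):
            r2 = n - r1
            for c1 in range(n + 1):
                lo = max(0, c1 - r2)
                hi = min(r1, c1)
                weights = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
                denom = comb(n, c1)
                for a in range(lo, hi + 1):
                    c = c1 - a
                    b = r1 - a
                    d = r2 - c
                    obs = weights[a - lo]
                    exact = Fraction(sum(w for w in weights if w <= obs), denom)
                    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
                        exact = Fraction(1)
                    p = fisher_exact(((a, b), (c, d)))
                    err = abs(p - float(exact)) / float(exact)
                    max_rel = max(max_rel, err)
                    n_tables += 1
    return {"max_relative_error": max_rel, "n_tables": n_tables}


def _bh_direct(p: np.ndarray) -> np.ndarray:
    """Direct step-up formula: q(i) = min over j >= i of p(j) * m / j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def bh_reference_check(n_vectors: int = 1000, max_len: int = 200, seed: int = 0) -> dict:
    """Compare :func:`fdr_adjust` with the direct step-up formula."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, max_len + 1))
        p = rng.random(m)
        if rng.random() < 0.3:  # exercise ties
            p = np.round(p, 2)
        err = float(np.abs(fdr_adjust(p) - _bh_direct(p)).max())
        max_err = max(max_err, err)
    return {"max_abs_error": max_err, "n_vectors": n_vectors}


# ----------------------------------------------------------------------
# insert-screen recovery on the default study conditions
# ----------------------------------------------------------------------

def insert_screen_recovery(n_seeds: int = 20, base_seed: int = 1) -> dict:
    """Planted-truth recovery of the uninfected-line window screen.

    On the default design (100 kb genome, three tissues, three 2-kb
    inserts at 3% divergence, uninfected lines at pooled 30x), calls
    candidates, applies the support filter and the window screen, and
    measures: the fraction of candidates inside insert intervals that
    the screen excluded (recall), and the fraction of planted true
    variants it wrongly excluded.
    """
    inside_total = inside_excluded = 0
    true_total = true_excluded = 0
    for k in range(n_seeds):
        design = SimulationDesign(seed=_child_seed(base_seed, k))
        res = simulate(design)
        cands = calling.naive_call(res.tissues, res.genome)
        live = calling.support_filter(cands)
        insert_screen.screen(live, res.uninfected)
        intervals = res.truth.insert_intervals()
        true_positions = {v.position for v in res.truth.true_variants}
        for c in cands:
            if any(s <= c.position < e for s, e in intervals):
                inside_total += 1
                if c.exclusion_stage() == "insert_screen":
                    inside_excluded += 1
            if c.position in true_positions:
                true_total += 1
                if c.exclusion_stage() == "insert_screen":
                    true_excluded += 1
    return {
        "recall": inside_excluded / inside_total if inside_total else float("nan"),
        "false_exclusion_rate": true_excluded / true_total if true_total else float("nan"),
        "n_insert_candidates": inside_total,
        "n_true_variants": true_total,
        "n_seeds": n_seeds,
    }


# ----------------------------------------------------------------------
# anomaly-battery error control and power
# ----------------------------------------------------------------------

def _anomaly_design(seed: int) -> SimulationDesign:
    """Study conditions for the battery: 50 unbiased SNPs plus three
    clip-biased artifacts at the minimum stated bias, no inserts."""
    freqs = {"haemolymph": 0.3, "nerve_chain": 0.3, "ovaries": 0.3}
    return SimulationDesign(
        seed=seed,
        true_variants=tuple(PlantedVariant(freqs) for _ in range(50)),
        artifacts=tuple(
            ArtifactSpec(alt_fraction=0.1, clip_probability=0.3, mismatch_rate=0.0)
            for _ in range(3)
        ),
        insert_count=0,
        uninfected_sample_count=0,
        host_contamination_coverage=0.0,
    )


def anomaly_error_control(n_seeds: int = 20, base_seed: int = 1) -> dict:
    """Type-I error and power of the allele-partitioned battery.

    Measures, over seeds: the fraction of planted unbiased variants
    excluded at alpha = 0.05 with global FDR (should not exceed the
    nominal level by more than discreteness allows), and the fraction
    of seeds in which every planted clip-biased artifact (excess clip
    0.3, >= 50 alternative reads pooled) was excluded.
    """
    null_total = null_excluded = 0
    seeds_all_artifacts = 0
    artifact_total = artifact_excluded = 0
    for k in range(n_seeds):
        design = _anomaly_design(_child_seed(base_seed, 1000 + k))
        res = simulate(design)
        cands = calling.naive_call(res.tissues, res.genome)
        live = calling.support_filter(cands)
        for c in live:
            c.record("insert_screen", True)
            c.record("wet_lab_exclusion", True)
        from .anomaly import run_battery

        run_battery(live, res.tissues, res.genome)
        true_pos = {v.position for v in res.truth.true_variants}
        art_pos = {a.position for a in res.truth.artifacts}
        all_art = True
        for c in cands:
            if c.position in true_pos:
                null_total += 1
                if c.exclusion_stage() == "anomaly":
                    null_excluded += 1
            elif c.position in art_pos:
                artifact_total += 1
                if c.exclusion_stage() == "anomaly":
                    artifact_excluded += 1
                else:
                    all_art = False
        if all_art:
            seeds_all_artifacts += 1
    return {
        "null_exclusion_rate": null_excluded / null_total if null_total else float("nan"),
        "artifact_seed_rate": seeds_all_artifacts / n_seeds,
        "artifact_exclusion_rate": artifact_excluded / artifact_total if artifact_total else float("nan"),
        "n_null_variants": null_total,
        "n_artifacts": artifact_total,
        "n_seeds": n_seeds,
    }


# ----------------------------------------------------------------------
# conversion recovery
# ----------------------------------------------------------------------

def _conversion_design(seed: int, converted: bool) -> SimulationDesign:
    """One 500x sample over the default genome, with or without the event."""
    return SimulationDesign(
        seed=seed,
        tissues=(TissueSpec("pool", 500.0),),
        true_variants=(),
        artifacts=(),
        insert_count=0,
        uninfected_sample_count=0,
        host_contamination_coverage=0.0,
        conversion=ConversionSpec(samples=("pool",)) if converted else None,
    )


def conversion_recovery(n_seeds: int = 20, base_seed: int = 1) -> dict:
    """Detection of planted conversions and specificity on unconverted data.

    Converted runs must yield a ``conversion`` verdict with the planted
    direction; unconverted runs must yield none.  The unpaired remap
    check is pooled over the converted runs: among acceptor reads
    covering at least one diagnostic site, the fraction re-placed at
    the donor under single-end rescoring.
    """
    detected = 0
    false_calls = 0
    remap_better = remap_resolved = 0
    for k in range(n_seeds):
        res = simulate(_conversion_design(_child_seed(base_seed, 2000 + k), True))
        rs = res.tissues["pool"]
        calls = conversion.detect(rs, [res.pair])
        truth_dir = res.truth.conversion.direction
        if any(c.verdict == "conversion" and c.direction == truth_dir for c in calls):
            detected += 1
        acceptor = "A" if truth_dir == "B_to_A" else "B"
        chk = conversion.unpaired_remap_check(rs, res.pair, acceptor)
        remap_better += chk.better_donor
        remap_resolved += chk.better_donor + chk.better_acceptor + chk.ties
    for k in range(n_seeds):
        res = simulate(_conversion_design(_child_seed(base_seed, 3000 + k), False))
        calls = conversion.detect(res.tissues["pool"], [res.pair])
        false_calls += sum(1 for c in calls if c.verdict == "conversion")
    return {
        "detection_rate": detected / n_seeds,
        "false_call_count": false_calls,
        "remap_reassigned_fraction": remap_better / remap_resolved if remap_resolved else float("nan"),
        "n_seeds": n_seeds,
    }


# ----------------------------------------------------------------------
# coverage contracts
# ----------------------------------------------------------------------

def coverage_oracle_check(seed: int = 1, genome_length: int = 10_000, window: int = 500) -> dict:
    """Window profile versus a brute-force per-base depth oracle.

    Simulates a small single-tissue dataset, recomputes per-base depth
    by walking every read's aligned interval in a plain loop, and
    compares window means, the normalised median, and the integer
    conservation identity (window base sums equal total aligned bases).
    """
    design = SimulationDesign(
        seed=seed,
        genome_length=genome_length,
        homolog_separation=2000,
        homolog_length=400,
        insert_count=0,
        uninfected_sample_count=0,
        host_contamination_coverage=0.0,
        tissues=(TissueSpec("pool", 120.0),),
        true_variants=(),
        artifacts=(),
    )
    res = simulate(design)
    rs = res.tissues["pool"]
    L = len(res.genome)
    oracle = np.zeros(L, dtype=np.int64)
    starts = rs.aligned_start
    spans = rs.span
    for s, sp in zip(starts, spans):
        idx = np.arange(s, s + sp)
        if rs.circular:
            idx %= L
        np.add.at(oracle, idx, 1)
    profile = coverage.window_coverage(rs, res.genome, window)
    edges = np.append(profile.starts, L)
    oracle_means = np.array(
        [oracle[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
    )
    max_abs = float(np.abs(profile.depth - oracle_means).max())
    norm_median = float(np.median(profile.normalized))
    conserved = int(profile.base_sums.sum()) == int(oracle.sum()) == rs.total_aligned_bases()
    return {
        "max_abs_error": max_abs,
        "normalized_median": norm_median,
        "conservation_holds": bool(conserved),
        "n_windows": len(profile.depth),
    }


# ----------------------------------------------------------------------
# headline end-to-end run
# ----------------------------------------------------------------------

def default_pipeline_run(seed: int = 1) -> dict:
    """Full cascade on the default design: the desk-scale headline run.

    Returns the funnel and, for the surviving variants, the recovered
    per-tissue frequencies alongside the planted ones.
    """
    res = simulate(SimulationDesign(seed=seed))
    result = pipeline.run(res.tissues, res.genome, res.uninfected)
    survivors = {}
    for c in result.survivors:
        survivors[c.id] = {s: sc.fraction for s, sc in c.samples.items()}
    truth_positions = {v.position: v.frequencies for v in res.truth.true_variants}
    true_survivors = [
        c for c in result.survivors if c.position in truth_positions
    ]
    return {
        "funnel": result.funnel,
        "survivor_frequencies": survivors,
        "n_true_recovered": len(true_survivors),
        "truth_frequencies": truth_positions,
    }
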