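"""End-to-end orchestration of the validation pipeline.

calling -> support filter -> uninfected-line window screen -> optional
wet-lab exclusion list -> alignment-anomaly battery -> funnel + final
depth review.  Thin glue over the stage modules; each stage records its
decision on every candidate's status trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import anomaly, calling, coverage, insert_screen, reporting
from .alignments import ReadSet
from .calling import VariantCandidate
from .config import PipelineConfig
from .io_core import SymbiontGenome


@dataclass
class PipelineResult:
    candidates: list[VariantCandidate]
    survivors: list[VariantCandidate]
    funnel: reporting.FilterFunnel
    anomaly_results: list[anomaly.FeatureTestResult]
    depth_reviews: dict[str, tuple[bool, str]] = field(default_factory=dict)


def run(
    samples: Mapping[str, ReadSet],
    genome: SymbiontGenome,
    uninfected: Mapping[str, ReadSet] | None = None,
    exclusion_list_path=None,
    config: PipelineConfig = PipelineConfig(),
    candidates: Sequence[VariantCandidate] | None = None,
    review_span: int = 500,
) -> PipelineResult:
    """Run every validation stage over one set of tissue alignments.

    ``candidates`` may be supplied from an external caller's VCF (via
    :func:`endosift.calling.candidates_from_views`); otherwise the naive
    frequency caller produces them.  The final survivors get a 100-bp
    window depth review around the site, flagging collapsed-repeat-like
    anomalies for manual inspection.
    """
    if candidates is None:
        candidates = calling.naive_call(
            samples, genome,
            min_fraction=config.min_fraction,
            min_baseq=config.min_baseq,
            min_mapq=config.min_mapq,
        )
    else:
        candidates = list(candidates)
    live = calling.support_filter(
        candidates, config.min_depth, config.min_alt_reads, config.depth_scope
    )
    live = insert_screen.screen(
        live, uninfected or {},
        threshold=config.screen_threshold,
        flank=config.screen_flank,
        window=config.screen_window,
        min_mapq=config.screen_min_mapq,
        pooled=config.screen_pooled,
    )
    if exclusion_list_path is not None:
        live, _unmatched = insert_screen.apply_exclusion_list(live, exclusion_list_path)
    else:
        for c in live:
            c.record("wet_lab_exclusion", True, "no exclusion list provided")
    live, results = anomaly.run_battery(
        live, samples, genome,
        alpha=config.alpha,
        fdr_scope=config.fdr_scope,
        mismatch_mode=config.mismatch_mode,
        min_baseq=config.min_baseq,
    )
    reviews: dict[str, tuple[bool, str]] = {}
    for c in live:
        c.record("final", True, "validated")
        for label, rs in samples.items():
            span = min(review_span, rs.ref_length // 2 - 1) if not rs.circular else review_span
            try:
                _, values = coverage.depth_around(rs, c.position, span, config.review_window)
            except ValueError:
                continue
            reviews[f"{c.id}:{label}"] = coverage.flag_depth_anomaly(values, config.anomaly_fold)
    funnel = reporting.build_funnel(candidates)
    return PipelineResult(list(candidates), live, funnel, results, reviews)
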