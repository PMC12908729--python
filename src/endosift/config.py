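"""Pipeline configuration.

A single declarative object holds every threshold used by the stages,
with the published filtering values as defaults.  Configurations can be
loaded from a TOML file whose keys mirror the field names (optionally
nested under an ``[endosift]`` table).
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass


@dataclass(frozen=True)
class PipelineConfig:
    # naive caller
    min_fraction: float = 0.03       # minimum alt observation fraction F
    min_baseq: int = 13              # base-quality floor for pileup/partition
    min_mapq: int = 0
    # support filter: depth strictly over min_depth and >= min_alt_reads
    # alternative-allele reads, within at least one tissue by default
    min_depth: int = 200
    min_alt_reads: int = 10
    depth_scope: str = "any_tissue"  # any_tissue | all_tissues
    # uninfected-line window screen
    screen_flank: int = 150          # window starts this far before the site
    screen_window: int = 300
    screen_threshold: int = 2        # reads from uninfected lines that exclude
    screen_min_mapq: int = 0
    screen_pooled: bool = True       # pool uninfected samples before counting
    # alignment-anomaly battery
    alpha: float = 0.05
    fdr_scope: str = "global"        # global | per_candidate
    mismatch_mode: str = "base"      # base | read
    # coverage review
    coverage_window: int = 5000
    review_window: int = 100
    anomaly_fold: float = 2.0
    # gene-conversion detector
    conversion_drop_ratio: float = 0.5
    conversion_rise_ratio: float = 1.5
    conversion_allele_min: float = 0.9
    conversion_flank: int = 2000
    find_pairs_min_tract: int = 100
    find_pairs_min_identity: float = 0.95

    def __post_init__(self) -> None:
        if self.depth_scope not in ("any_tissue", "all_tissues"):
            raise ValueError("depth_scope must be any_tissue or all_tissues")
        if self.fdr_scope not in ("global", "per_candidate"):
            raise ValueError("fdr_scope must be global or per_candidate")
        if self.mismatch_mode not in ("base", "read"):
            raise ValueError("mismatch_mode must be base or read")
        if not 0 <= self.min_fraction <= 1:
            raise ValueError("min_fraction must be in [0, 1]")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data = data.get("endosift", data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
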