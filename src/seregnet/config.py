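"""Run configuration: every numeric parameter of the analysis in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    """Tunable parameters with their field-standard defaults.

    Lengths are in bp.  ``stitch_distance``/``tss_exclusion`` drive
    super-enhancer calling; ``promoter_halfwidth``/``upstream_max`` the
    feature hierarchy; ``overlap_window`` the peak-center co-occupancy
    window; ``network_window`` the ±window-plus-gene-body target rule;
    ``ma_window`` is a gene count (moving-average window); the profiling
    pair sets the metaprofile extent and bin size.
    """

    stitch_distance: int = 12_500
    tss_exclusion: int = 2_500
    promoter_halfwidth: int = 2_000
    upstream_max: int = 20_000
    overlap_window: int = 500
    ma_window: int = 100
    profile_halfwidth: int = 3_000
    profile_bin: int = 100
    network_window: int = 20_000
    extreme_fraction: float = 0.10
    min_dataset_hits: int = 3
    cooccupancy_gene_threshold: int = 22
    cooccupancy_se_threshold: int = 8
    n_classes: int = 4
    pseudocount: float = 1.0
    min_peak_signal: float = 0.0  # optional weak-peak filter, default off
    timecourse_metric: str = "euclidean"  # or "correlation"
    rng_seed: int = 0

    def __post_init__(self):
        for name in (
            "stitch_distance", "tss_exclusion", "promoter_halfwidth",
            "upstream_max", "overlap_window", "ma_window",
            "profile_halfwidth", "profile_bin", "network_window",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0 < self.extreme_fraction < 0.5:
            raise ConfigurationError("extreme_fraction must be in (0, 0.5)")
        if self.min_dataset_hits < 1:
            raise ConfigurationError("min_dataset_hits must be >= 1")
        if self.pseudocount <= 0:
            raise ConfigurationError("pseudocount must be > 0")
        if self.profile_halfwidth % self.profile_bin:
            raise ConfigurationError("profile_halfwidth must be a multiple of profile_bin")
        if self.timecourse_metric not in ("euclidean", "correlation"):
            raise ConfigurationError("timecourse_metric must be 'euclidean' or 'correlation'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
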