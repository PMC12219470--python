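"""Experiment and analysis configuration."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import ConfigError

__all__ = ["ExperimentConfig", "AnalysisConfig", "load_config"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of a simulated multi-session dual-channel experiment.

    Defaults are desk-scale (5-min sessions at 15 fps); ``paper_scale`` gives
    the full 15-min / 30 fps schedule.
    """

    n_sessions: int = 7
    session_interval_days: int = 2
    session_duration_s: float = 300.0
    fps: float = 15.0
    n_cells: int = 150
    fov_shape: tuple[int, int] = (200, 200)
    track_length_cm: float = 100.0
    place_cell_fraction: float = 0.5
    field_width_cm: float = 10.0
    activity_prob: float = 0.7
    crosstalk_alpha: float = 0.05
    fov_jitter_px: float = 2.0
    noise_sd: float = 0.05
    seed: int = 0

    # behaviour generator
    run_speed_cm_s: float = 45.0
    run_speed_sd_cm_s: float = 5.0
    pause_s: float = 3.0
    px_per_cm: float = 5.0
    # probability of a partial mid-track excursion before a full traversal;
    # needed so odd/even trial splits share spatial coverage in both directions
    turnaround_prob: float = 0.3

    # indicator / footprint model
    kernel_rise_s: float = 0.05
    kernel_decay_s: float = 0.4
    peak_rate_hz: float = 8.0
    untuned_rate_hz: float = 0.5
    tuned_baseline_frac: float = 0.05  # off-field rate as a fraction of peak
    footprint_sigma_px: float = 3.0
    static_sigma_px: float = 2.5
    min_separation_px: float = 10.0
    static_baseline: float = 1.0
    static_baseline_sd: float = 0.1
    static_drift_frac: float = 0.02

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ConfigError("n_sessions must be >= 1")
        if not 0.0 <= self.activity_prob <= 1.0:
            raise ConfigError("activity_prob must be in [0, 1]")
        if not 0.0 <= self.crosstalk_alpha < 1.0:
            raise ConfigError("crosstalk_alpha must be in [0, 1)")
        if not 0.0 <= self.place_cell_fraction <= 1.0:
            raise ConfigError("place_cell_fraction must be in [0, 1]")
        if self.fps <= 0 or self.session_duration_s <= 0:
            raise ConfigError("fps and session_duration_s must be positive")
        for name in ("track_length_cm", "field_width_cm", "px_per_cm",
                     "footprint_sigma_px", "static_sigma_px", "min_separation_px"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        if self.fov_jitter_px < 0 or self.noise_sd < 0:
            raise ConfigError("fov_jitter_px and noise_sd must be non-negative")
        object.__setattr__(self, "fov_shape", tuple(int(v) for v in self.fov_shape))

    @property
    def n_frames(self) -> int:
        return int(round(self.session_duration_s * self.fps))

    @property
    def day_indices(self) -> list[int]:
        return [s * self.session_interval_days for s in range(self.n_sessions)]

    @classmethod
    def paper_scale(cls, **overrides) -> "ExperimentConfig":
        base = dict(session_duration_s=900.0, fps=30.0)
        base.update(overrides)
        return cls(**base)

    def replace(self, **changes) -> "ExperimentConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fov_shape"] = list(d["fov_shape"])
        return d


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the analysis stages (detection through drift)."""

    # detection
    smoothing_sigma: float = 1.5
    min_distance: int = 7
    threshold_quantile: float = 0.95
    radius_bounds: tuple[float, float] = (2.0, 8.0)
    roundness_min: float = 0.7

    # registration
    max_dist_px: float = 5.0

    # cross-talk
    n_crosstalk_shuffles: int = 100
    crosstalk_min_shift_s: float = 30.0

    # spatial
    speed_threshold_cm_s: float = 3.0
    speed_smooth_frames: int = 5
    end_zone_cm: float = 10.0
    kde_bandwidth_cm: float = 5.0
    n_spatial_bins: int = 200
    occupancy_floor: float = 1e-4
    n_place_shuffles: int = 100
    place_min_shift_s: float = 30.0
    place_percentile: float = 95.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["radius_bounds"] = list(d["radius_bounds"])
        return d


def load_config(path: str | Path) -> tuple[ExperimentConfig, AnalysisConfig]:
    """Load a YAML config with optional ``experiment:`` / ``analysis:`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    exp = raw.get("experiment", {})
    ana = raw.get("analysis", {})
    if "fov_shape" in exp:
        exp["fov_shape"] = tuple(exp["fov_shape"])
    if "radius_bounds" in ana:
        ana["radius_bounds"] = tuple(ana["radius_bounds"])
    try:
        return ExperimentConfig(**exp), AnalysisConfig(**ana)
    except TypeError as err:
        raise ConfigError(str(err)) from err
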