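"""Shared domain types and error hierarchy."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "DuoscopeError",
    "ConfigError",
    "PackingError",
    "GeometryError",
    "DegenerateDataError",
    "Footprint",
    "TraceSet",
    "Trajectory",
]


class DuoscopeError(Exception):
    """Base class for all duoscope errors."""


class ConfigError(DuoscopeError, ValueError):
    """Invalid configuration value."""


class PackingError(DuoscopeError, RuntimeError):
    """Could not place the requested number of cells at the requested separation."""


class GeometryError(DuoscopeError, ValueError):
    """Spatial object does not fit the field of view."""


class DegenerateDataError(DuoscopeError, ValueError):
    """Input data is degenerate for the requested computation."""


TRACE_KINDS = ("raw-projected", "denoised", "deconvolved")


@dataclass
class Footprint:
    """One cell's 2D spatial weight map within a field of view.

    Parameters
    ----------
    cell_id : int
        Identifier, unique within one session/channel.
    weights : ndarray of shape (H, W)
        Non-negative pixel weights; at least one positive entry.
    centroid : (float, float), optional
        Weight-weighted (row, col) centroid. Computed from ``weights``
        when omitted.
    """

    cell_id: int
    weights: np.ndarray
    centroid: tuple[float, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.ndim != 2:
            raise GeometryError("footprint weights must be 2D")
        if np.any(w < 0):
            raise GeometryError("footprint weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise DegenerateDataError("footprint has no positive weight")
        if self.centroid is None:
            rows, cols = np.nonzero(w)
            vals = w[rows, cols]
            self.centroid = (
                float(np.dot(rows, vals) / total),
                float(np.dot(cols, vals) / total),
            )
        r, c = self.centroid
        if not (0 <= r < w.shape[0] and 0 <= c < w.shape[1]):
            raise GeometryError("footprint centroid outside field of view")

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.weights.shape)  # type: ignore[return-value]


@dataclass
class TraceSet:
    """Cells x frames temporal signals with a kind tag."""

    values: np.ndarray
    kind: str
    fps: float

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.kind not in TRACE_KINDS:
            raise ConfigError(f"unknown trace kind {self.kind!r}; expected one of {TRACE_KINDS}")
        if not np.all(np.isfinite(self.values)):
            raise DegenerateDataError("trace values must be finite")
        if self.kind == "deconvolved" and np.any(self.values < 0):
            raise DegenerateDataError("deconvolved traces must be non-negative")
        if self.fps <= 0:
            raise ConfigError("fps must be positive")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class Trajectory:
    """Frame-indexed animal position on a linear track.

    ``speed``, ``behavior``, ``linpos`` and ``trial_id`` are filled in by
    :func:`duoscope.spatial.segment_trajectory`; ``behavior`` uses the codes
    ``0`` idle, ``1`` running left (linearized range [0, 100)), ``2`` running
    right (range [100, 200)).
    """

    x_px: np.ndarray
    y_px: np.ndarray
    fps: float
    track_length_cm: float
    px_per_cm: float
    speed: Optional[np.ndarray] = None
    behavior: Optional[np.ndarray] = None
    linpos: Optional[np.ndarray] = None
    trial_id: Optional[np.ndarray] = None
    n_trials: Optional[int] = None
    running_speed: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        if self.x_px.shape != self.y_px.shape or self.x_px.ndim != 1:
            raise ConfigError("x_px and y_px must be 1D arrays of equal length")
        if self.fps <= 0 or self.track_length_cm <= 0 or self.px_per_cm <= 0:
            raise ConfigError("fps, track_length_cm and px_per_cm must be positive")

    @property
    def n_frames(self) -> int:
        return self.x_px.size

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


IDLE, LEFT, RIGHT = 0, 1, 2
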