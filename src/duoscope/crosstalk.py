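"""Channel cross-talk quantification.

The static channel should carry no activity dynamics, so the linear
coefficient of static-on-dynamic is an estimate of the bleed-through
fraction. A circular-shuffle null breaks temporal alignment while keeping
both marginals; the spectrally expected ratio integrates the dynamic
fluorophore's emission against each channel filter's transmission.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ConfigError, DegenerateDataError, Footprint, GeometryError, TraceSet

__all__ = [
    "SpectraSet",
    "CrosstalkEstimate",
    "CrosstalkSummary",
    "project_traces",
    "fit_crosstalk",
    "shuffled_null",
    "expected_crosstalk_ratio",
    "summarize_crosstalk",
]


@dataclass
class SpectraSet:
    """Emission spectrum plus per-channel filter transmission on one grid."""

    wavelengths: np.ndarray
    emission: np.ndarray
    transmission_green: np.ndarray
    transmission_red: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or np.any(np.diff(wl) <= 0):
            raise ConfigError("wavelength grid must be 1D strictly increasing")
        for name in ("emission", "transmission_green", "transmission_red"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != wl.shape:
                raise ConfigError(f"{name} must share the wavelength grid")
            setattr(self, name, arr)
        if np.any(self.emission < 0) or self.emission.sum() <= 0:
            raise DegenerateDataError("emission must be non-negative with positive total")
        for name in ("transmission_green", "transmission_red"):
            t = getattr(self, name)
            if np.any((t < 0) | (t > 1)):
                raise ConfigError(f"{name} must lie in [0, 1]")
        self.wavelengths = wl


@dataclass
class CrosstalkEstimate:
    """Observed coefficients, shuffle null and spectrally expected ratio."""

    coefficients: np.ndarray            # (n_cells,)
    null_coefficients: np.ndarray       # (n_cells, n_shuffles)
    expected_ratio: float | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.null_coefficients = np.atleast_2d(np.asarray(self.null_coefficients, dtype=float))
        if self.null_coefficients.shape[0] != self.coefficients.size:
            raise ConfigError("null array must have one row per cell")
        if self.expected_ratio is not None and not 0.0 <= self.expected_ratio <= 1.0:
            raise ConfigError("expected_ratio must lie in [0, 1]")


@dataclass
class CrosstalkSummary:
    observed_mean: float
    observed_sd: float
    null_mean: float
    null_sd: float
    paired_t: float
    paired_p: float
    one_sample_t: float | None
    one_sample_p: float | None


def project_traces(movie: np.ndarray, footprints: list[Footprint], fps: float = 1.0) -> TraceSet:
    """Weight-normalized projection of raw pixels onto spatial footprints.

    trace[c, t] = sum_px(weights_c * frame_t) / sum_px(weights_c)
    """
    movie = np.asarray(movie)
    if movie.ndim != 3:
        raise GeometryError("movie must be a (frames, H, W) stack")
    n_frames = movie.shape[0]
    flat = movie.reshape(n_frames, -1)
    values = np.empty((len(footprints), n_frames))
    for i, fp in enumerate(footprints):
        if fp.weights.shape != movie.shape[1:]:
            raise GeometryError("footprint shape does not match movie frames")
        total = fp.weights.sum()
        if total <= 0:
            raise DegenerateDataError(f"footprint {fp.cell_id} has zero weight")
        rows, cols = np.nonzero(fp.weights)
        idx = rows * movie.shape[2] + cols
        values[i] = flat[:, idx] @ (fp.weights[rows, cols] / total)
    return TraceSet(values, "raw-projected", fps)


def _validate_pair(gcamp: np.ndarray, static: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(gcamp, dtype=float).ravel()
    s = np.asarray(static, dtype=float).ravel()
    if g.size != s.size:
        raise ConfigError("traces must have equal length")
    if g.size < 10:
        raise ConfigError("need at least 10 frames to fit")
    if np.var(g) == 0:
        raise DegenerateDataError("dynamic trace has zero variance; fit undefined")
    return g, s


def fit_crosstalk(gcamp: np.ndarray, static: np.ndarray) -> float:
    """OLS slope of static ~ intercept + beta * gcamp."""
    g, s = _validate_pair(gcamp, static)
    gc = g - g.mean()
    return float(np.dot(gc, s - s.mean()) / np.dot(gc, gc))


def shuffled_null(
    gcamp: np.ndarray,
    static: np.ndarray,
    n_shuffles: int = 100,
    seed: int = 0,
    min_shift_s: float = 30.0,
    fps: float = 15.0,
) -> np.ndarray:
    """Refit beta after circular shifts of the static trace.

    Shift offsets are uniform integers in [min_shift, T - min_shift] frames,
    drawn from a stream keyed by ``seed``.
    """
    g, s = _validate_pair(gcamp, static)
    t = g.size
    min_shift = int(round(min_shift_s * fps))
    if t <= 2 * min_shift:
        raise ConfigError(
            f"trace of {t} frames too short for min shift of {min_shift} frames"
        )
    rng = np.random.default_rng(seed)
    offsets = rng.integers(min_shift, t - min_shift + 1, size=n_shuffles)
    gc = g - g.mean()
    denom = np.dot(gc, gc)
    sc = s - s.mean()
    out = np.empty(n_shuffles)
    for k, off in enumerate(offsets):
        out[k] = np.dot(gc, np.roll(sc, int(off))) / denom
    return out


def expected_crosstalk_ratio(spectra: SpectraSet) -> float:
    """Emission passed by the red filter over emission passed by the green.

    Trapezoidal integration of emission x transmission on the common grid.
    """
    wl = spectra.wavelengths
    red = np.trapezoid(spectra.emission * spectra.transmission_red, wl)
    green = np.trapezoid(spectra.emission * spectra.transmission_green, wl)
    if green <= 0:
        raise DegenerateDataError("no emission passes the green filter; ratio undefined")
    return float(red / green)


def summarize_crosstalk(est: CrosstalkEstimate) -> CrosstalkSummary:
    """Observed vs null (paired t) and observed vs expected (one-sample t)."""
    obs = est.coefficients
    if obs.size < 2:
        raise DegenerateDataError("need at least 2 cells to summarize")
    per_cell_null = est.null_coefficients.mean(axis=1)
    diff = obs - per_cell_null
    mean_diff = float(diff.mean())
    if np.allclose(diff, mean_diff):  # constant difference: t-test degenerate
        if np.isclose(mean_diff, 0.0):
            paired_t, paired_p = 0.0, 1.0
        else:
            paired_t, paired_p = np.inf * np.sign(mean_diff), 0.0
    else:
        paired_t, paired_p = stats.ttest_rel(obs, per_cell_null)
    if est.expected_ratio is None:
        one_t = one_p = None
    elif np.allclose(obs, est.expected_ratio):
        one_t, one_p = 0.0, 1.0
    else:
        one_t, one_p = stats.ttest_1samp(obs, est.expected_ratio)
        one_t, one_p = float(one_t), float(one_p)
    return CrosstalkSummary(
        observed_mean=float(obs.mean()),
        observed_sd=float(obs.std(ddof=1)),
        null_mean=float(est.null_coefficients.mean()),
        null_sd=float(est.null_coefficients.std(ddof=1)),
        paired_t=float(paired_t),
        paired_p=float(paired_p),
        one_sample_t=one_t,
        one_sample_p=one_p,
    )
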