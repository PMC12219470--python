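"""Linear-track behaviour segmentation, rate maps, place cells and PV drift.

Positions are projected onto the track axis and linearized to [0, 100) cm,
with the two running directions mapped to disjoint halves of a 0-200 range
(left [0, 100), right [100, 200)). Occupancy and event-weighted firing
densities are cosine-kernel KDEs sampled on 200 one-cm bins; spatial
information is the Skaggs sum I = sum_i p_i (l_i/l̄) log2(l_i/l̄).
Place cells are classified against circular-shuffle nulls of the
deconvolved trace, requiring both information and stability to exceed the
95th null percentile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    ConfigError,
    DegenerateDataError,
    TraceSet,
    Trajectory,
    IDLE,
    LEFT,
    RIGHT,
)

__all__ = [
    "RateMap",
    "PlaceCellResult",
    "compute_speed",
    "classify_behavior",
    "detect_trials",
    "linearize_position",
    "segment_trajectory",
    "estimate_density",
    "compute_rate_map",
    "spatial_information",
    "normalized_rate_map",
    "session_stability",
    "cross_session_stability",
    "place_cell_test",
    "pv_correlation",
    "activity_quantile",
]

N_BINS = 200
TRACK_RANGE = 200.0


# ---------------------------------------------------------------------------
# behaviour segmentation
# ---------------------------------------------------------------------------

def _project_position(traj: Trajectory) -> np.ndarray:
    """Project (x, y) onto the principal track axis; returns px along axis."""
    xy = np.stack([traj.x_px, traj.y_px], axis=1)
    centered = xy - xy.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis  # orient along increasing x for a reproducible sign
    return centered @ axis + (xy.mean(axis=0) @ axis)


def _smoothed(values: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return values
    kernel = np.ones(n) / n
    pad = n // 2
    padded = np.pad(values, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad:pad + values.size]
    return out


def compute_speed(traj: Trajectory, smooth_frames: int = 5) -> Trajectory:
    """Per-frame speed (cm/s) from the position gradient; 95th pct = running speed."""
    if traj.n_frames < 2:
        raise DegenerateDataError("need at least 2 frames to compute speed")
    pos = _project_position(traj)
    grad_px = np.gradient(pos)  # px per frame
    speed = np.abs(grad_px) / traj.px_per_cm * traj.fps
    traj.speed = speed
    traj.running_speed = float(np.percentile(speed, 95))
    traj.meta["pos_axis_px"] = pos
    traj.meta["speed_smooth"] = _smoothed(speed, smooth_frames)
    traj.meta["grad_smooth"] = _smoothed(grad_px, smooth_frames)
    return traj


def classify_behavior(
    traj: Trajectory, threshold_cm_s: float = 3.0, smooth_frames: int = 5
) -> Trajectory:
    """idle iff smoothed speed <= threshold; else left/right by motion sign."""
    if traj.speed is None:
        compute_speed(traj, smooth_frames)
    smooth = traj.meta["speed_smooth"]
    grad = traj.meta["grad_smooth"]
    behavior = np.full(traj.n_frames, IDLE, dtype=int)
    # epsilon so smoothing round-off cannot flip the at-threshold convention
    moving = smooth > threshold_cm_s + 1e-9
    behavior[moving & (grad > 0)] = RIGHT
    behavior[moving & (grad <= 0)] = LEFT
    traj.behavior = behavior
    return traj


def detect_trials(traj: Trajectory, end_zone_cm: float = 10.0) -> Trajectory:
    """A trial completes at each entry into the end zone opposite the last one."""
    pos = traj.meta.get("pos_axis_px")
    if pos is None:
        compute_speed(traj)
        pos = traj.meta["pos_axis_px"]
    lo, hi = pos.min(), pos.max()
    span = hi - lo
    if span <= 0:
        traj.trial_id = np.zeros(traj.n_frames, dtype=int)
        traj.n_trials = 0
        return traj
    frac = (pos - lo) / span * traj.track_length_cm
    in_a = frac <= end_zone_cm
    in_b = frac >= traj.track_length_cm - end_zone_cm
    trial_id = np.zeros(traj.n_frames, dtype=int)
    count = 0
    last: int | None = None
    for t in range(traj.n_frames):
        zone = 0 if in_a[t] else 1 if in_b[t] else None
        if zone is not None and zone != last:
            if last is not None:
                count += 1
            last = zone
        trial_id[t] = count
    traj.trial_id = trial_id
    traj.n_trials = count
    return traj


def linearize_position(traj: Trajectory) -> Trajectory:
    """Map track position to [0, 100); offset rightward frames by +100."""
    if traj.behavior is None:
        classify_behavior(traj)
    pos = traj.meta["pos_axis_px"]
    lo, hi = pos.min(), pos.max()
    if hi <= lo:  # stationary recording: everything idle, position undefined
        traj.linpos = np.full(traj.n_frames, np.nan)
        return traj
    lin01 = np.minimum((pos - lo) / (hi - lo) * 100.0, np.nextafter(100.0, 0.0))
    linpos = np.where(traj.behavior == RIGHT, lin01 + 100.0, lin01)
    linpos[traj.behavior == IDLE] = np.nan
    traj.linpos = linpos
    return traj


def segment_trajectory(
    traj: Trajectory,
    speed_threshold_cm_s: float = 3.0,
    smooth_frames: int = 5,
    end_zone_cm: float = 10.0,
) -> Trajectory:
    """Speed, behaviour labels, linearized position and trial ids in one pass."""
    compute_speed(traj, smooth_frames)
    classify_behavior(traj, speed_threshold_cm_s, smooth_frames)
    detect_trials(traj, end_zone_cm)
    linearize_position(traj)
    return traj


# ---------------------------------------------------------------------------
# rate maps and spatial information
# ---------------------------------------------------------------------------

def _bin_centers(n_bins: int = N_BINS) -> np.ndarray:
    return (np.arange(n_bins) + 0.5) * (TRACK_RANGE / n_bins)


def _cosine_kernel(u: np.ndarray) -> np.ndarray:
    out = np.zeros_like(u)
    inside = np.abs(u) <= 1.0
    out[inside] = (np.pi / 4.0) * np.cos(np.pi * u[inside] / 2.0)
    return out


def estimate_density(
    samples: np.ndarray,
    weights: np.ndarray | None = None,
    bandwidth: float = 5.0,
    n_bins: int = N_BINS,
) -> np.ndarray:
    """Cosine-kernel KDE on ``n_bins`` one-cm bins, normalized to sum 1.

    K(u) = (pi/4) cos(pi u / 2) for |u| <= 1, u = (x - x_s) / bandwidth.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if weights is None:
        weights = np.ones_like(samples)
    else:
        weights = np.asarray(weights, dtype=float).ravel()
        if weights.shape != samples.shape:
            raise ConfigError("weights must match samples")
        if np.any(weights < 0):
            raise ConfigError("weights must be non-negative")
    keep = np.isfinite(samples)
    samples, weights = samples[keep], weights[keep]
    if samples.size == 0 or weights.sum() <= 0:
        raise DegenerateDataError("no samples (or all-zero weights) for density")
    centers = _bin_centers(n_bins)
    u = (centers[:, None] - samples[None, :]) / bandwidth
    density = _cosine_kernel(u) @ weights
    total = density.sum()
    if total <= 0:
        raise DegenerateDataError("density collapsed to zero on the bin grid")
    return density / total


@dataclass
class RateMap:
    """Occupancy and firing densities on the 200-bin linearized track."""

    occupancy: np.ndarray       # sums to 1 over all bins
    firing: np.ndarray          # sums to 1 over all bins (zero for silent cells)
    valid_mask: np.ndarray      # occupancy above floor
    bandwidth: float = 5.0

    def __post_init__(self) -> None:
        for name in ("occupancy", "firing"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr < 0):
                raise ConfigError(f"{name} must be non-negative")
            setattr(self, name, arr)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if not (self.occupancy.shape == self.firing.shape == self.valid_mask.shape):
            raise ConfigError("rate map components must share shape")

    @property
    def n_bins(self) -> int:
        return self.occupancy.size


def compute_rate_map(
    linpos: np.ndarray,
    event_weights: np.ndarray,
    bandwidth: float = 5.0,
    n_bins: int = N_BINS,
    occupancy_floor: float = 1e-4,
) -> RateMap:
    """Occupancy from non-idle frames; firing from event frames, amplitude-weighted."""
    linpos = np.asarray(linpos, dtype=float)
    w = np.asarray(event_weights, dtype=float)
    if linpos.shape != w.shape:
        raise ConfigError("linpos and event weights must be frame-aligned")
    occupancy = estimate_density(linpos, bandwidth=bandwidth, n_bins=n_bins)
    ev = np.isfinite(linpos) & (w > 0)
    if ev.any():
        firing = estimate_density(linpos[ev], w[ev], bandwidth=bandwidth, n_bins=n_bins)
    else:
        firing = np.zeros(n_bins)
    return RateMap(occupancy, firing, occupancy >= occupancy_floor, bandwidth)


def spatial_information(rm: RateMap, mean_mode: str = "occupancy") -> float:
    """Skaggs information I = sum_i p_i (l_i/l̄) log2(l_i/l̄), in bits.

    ``mean_mode='occupancy'`` uses the occupancy-weighted mean rate
    l̄ = sum_i p_i l_i (guarantees I >= 0); ``'plain'`` uses the unweighted
    mean over valid bins.
    """
    valid = rm.valid_mask
    if not valid.any():
        raise DegenerateDataError("no valid bins")
    p = rm.occupancy[valid]
    p = p / p.sum()
    lam = rm.firing[valid]
    if mean_mode == "occupancy":
        lam_bar = float(np.dot(p, lam))
    elif mean_mode == "plain":
        lam_bar = float(lam.mean())
    else:
        raise ConfigError(f"unknown mean_mode {mean_mode!r}")
    if lam_bar <= 0:
        raise DegenerateDataError("cell is silent; spatial information undefined")
    ratio = lam / lam_bar
    pos = ratio > 0
    return float(np.sum(p[pos] * ratio[pos] * np.log2(ratio[pos])))


def normalized_rate_map(rm: RateMap) -> np.ndarray:
    """Firing over occupancy on valid bins; masked (NaN) elsewhere."""
    if not rm.valid_mask.any():
        raise DegenerateDataError("all bins below occupancy floor")
    out = np.full(rm.n_bins, np.nan)
    v = rm.valid_mask
    out[v] = rm.firing[v] / rm.occupancy[v]
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 2:
        raise DegenerateDataError("fewer than 2 jointly valid bins")
    x, y = x[keep], y[keep]
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan")
    return float((xc @ yc) / denom)


def _split_masks(trial_id: np.ndarray, which: str) -> tuple[np.ndarray, np.ndarray]:
    max_id = int(trial_id.max())
    if which == "odd-even":
        return trial_id % 2 == 1, trial_id % 2 == 0
    if which == "halves":
        cut = (max_id + 1) / 2.0
        return trial_id < cut, trial_id >= cut
    raise ConfigError(f"unknown split {which!r}")


def session_stability(
    event_weights: np.ndarray,
    traj: Trajectory,
    split: str = "both",
    bandwidth: float = 5.0,
    n_bins: int = N_BINS,
    occupancy_floor: float = 1e-4,
) -> float:
    """Pearson r of normalized maps across within-session trial splits.

    ``split='both'`` returns the mean of the odd-even and first/second-half
    correlations, matching the within-session stability definition.
    """
    if traj.linpos is None or traj.trial_id is None:
        segment_trajectory(traj)
    if traj.n_trials is not None and traj.n_trials < 4:
        raise DegenerateDataError("need >= 4 trials for within-session splits")
    splits = ("odd-even", "halves") if split == "both" else (split,)
    rs = []
    for which in splits:
        m1, m2 = _split_masks(traj.trial_id, which)
        maps = []
        for m in (m1, m2):
            lin = np.where(m, traj.linpos, np.nan)
            rm = compute_rate_map(lin, np.where(m, event_weights, 0.0),
                                  bandwidth, n_bins, occupancy_floor)
            maps.append(normalized_rate_map(rm))
        rs.append(_pearson(maps[0], maps[1]))
    return float(np.mean(rs))


def cross_session_stability(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Pearson r of two sessions' normalized maps over jointly valid bins."""
    return _pearson(np.asarray(map_a, float), np.asarray(map_b, float))


# ---------------------------------------------------------------------------
# place-cell classification (vectorized over circular shuffles)
# ---------------------------------------------------------------------------

@dataclass
class PlaceCellResult:
    spatial_information: float
    stability: float
    null_si: np.ndarray
    null_stability: np.ndarray
    si_p95: float
    stab_p95: float
    is_place_cell: bool
    silent: bool = False


def _kernel_matrix(
    linpos: np.ndarray, mask: np.ndarray, bandwidth: float, n_bins: int
) -> np.ndarray:
    """(n_bins, T) cosine-kernel weights; zero columns outside ``mask``."""
    k = np.zeros((n_bins, linpos.size))
    use = mask & np.isfinite(linpos)
    if not use.any():
        return k
    centers = _bin_centers(n_bins)
    u = (centers[:, None] - linpos[None, use]) / bandwidth
    k[:, use] = _cosine_kernel(u)
    return k


def _si_columns(p: np.ndarray, firing: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Spatial information per column of a (bins, n) firing-density stack."""
    pv = p[valid]
    pv = pv / pv.sum()
    f = firing[valid]
    totals = f.sum(axis=0)
    out = np.full(firing.shape[1], np.nan)
    ok = totals > 0
    if not ok.any():
        return out
    lam = f[:, ok] / totals[ok]
    lam_bar = pv @ lam
    ratio = lam / lam_bar
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(ratio > 0, ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    out[ok] = pv @ terms
    return out


def _corr_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r of two (bins, n) stacks."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    denom = np.sqrt((ac * ac).sum(axis=0) * (bc * bc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (ac * bc).sum(axis=0) / denom, np.nan)


def _session_kernels(
    traj: Trajectory, bandwidth: float, n_bins: int, occupancy_floor: float
) -> dict:
    """Kernel matrices and occupancies shared by every cell of a session.

    Cached on ``traj.meta`` — the trajectory is identical across cells, so
    recomputing the (bins x frames) kernel per cell would dominate runtime.
    """
    cache = traj.meta.setdefault("_kde_cache", {})
    key = (bandwidth, n_bins, occupancy_floor, int(traj.trial_id is not None))
    if key in cache:
        return cache[key]
    valid_frames = np.isfinite(traj.linpos)
    k_all = _kernel_matrix(traj.linpos, valid_frames, bandwidth, n_bins)
    occ = k_all.sum(axis=1)
    total = occ.sum()
    if total <= 0:
        raise DegenerateDataError("no non-idle frames")
    p = occ / total
    valid = p >= occupancy_floor
    if not valid.any():
        raise DegenerateDataError("no valid occupancy bins")
    out = {"k_all": k_all, "p": p, "valid": valid}
    for which in ("odd-even", "halves"):
        m1, m2 = _split_masks(traj.trial_id, which)
        parts = []
        for m in (m1, m2):
            k = _kernel_matrix(traj.linpos, m & valid_frames, bandwidth, n_bins)
            o = k.sum(axis=1)
            tot = o.sum()
            ps = o / tot if tot > 0 else np.zeros_like(o)
            parts.append((k, ps, ps >= occupancy_floor))
        out[which] = parts
    cache[key] = out
    return out


def place_cell_test(
    event_weights: np.ndarray,
    traj: Trajectory,
    n_shuffles: int = 500,
    percentile: float = 95.0,
    seed: int = 0,
    min_shift_s: float = 30.0,
    bandwidth: float = 5.0,
    n_bins: int = N_BINS,
    occupancy_floor: float = 1e-4,
) -> PlaceCellResult:
    """Classify a cell by circular-shuffle nulls of information and stability.

    The deconvolved trace is circularly shifted ``n_shuffles`` times by a
    uniform offset in [min_shift, T - min_shift] frames; spatial information
    and within-session stability are recomputed for every shift, and the
    cell is a place cell iff both observed values exceed the requested null
    percentile. Deterministic for a given ``seed``.
    """
    w = np.asarray(event_weights, dtype=float).ravel()
    if traj.linpos is None or traj.trial_id is None:
        segment_trajectory(traj)
    if w.size != traj.n_frames:
        raise ConfigError("trace and trajectory must be frame-aligned")
    empty_null = np.full(n_shuffles, np.nan)
    if w.sum() <= 0:
        return PlaceCellResult(np.nan, np.nan, empty_null, empty_null,
                               np.nan, np.nan, False, silent=True)

    t = w.size
    min_shift = int(round(min_shift_s * traj.fps))
    if t <= 2 * min_shift:
        raise ConfigError("trace too short for the minimum circular shift")
    rng = np.random.default_rng(seed)
    offsets = rng.integers(min_shift, t - min_shift + 1, size=n_shuffles)

    # column 0 = observed, then one column per shuffle
    stack = np.empty((t, n_shuffles + 1))
    stack[:, 0] = w
    for j, off in enumerate(offsets):
        stack[:, j + 1] = np.roll(w, int(off))

    kern = _session_kernels(traj, bandwidth, n_bins, occupancy_floor)
    p, valid = kern["p"], kern["valid"]
    si = _si_columns(p, kern["k_all"] @ stack, valid)

    split_rs = []
    for which in ("odd-even", "halves"):
        joint = valid.copy()
        norm_maps = []
        for k, ps, v in kern[which]:
            joint &= v
            f = k @ stack
            totals = f.sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                dens = np.where(totals > 0, f / totals, np.nan)
                nm = dens / ps[:, None]
            norm_maps.append(nm)
        if joint.sum() < 2:
            split_rs.append(np.full(n_shuffles + 1, np.nan))
        else:
            split_rs.append(_corr_columns(norm_maps[0][joint], norm_maps[1][joint]))
    stability = np.mean(split_rs, axis=0)

    null_si, null_stab = si[1:], stability[1:]
    si_thr = float(np.nanpercentile(null_si, percentile)) if np.isfinite(null_si).any() else np.nan
    stab_thr = (float(np.nanpercentile(null_stab, percentile))
                if np.isfinite(null_stab).any() else np.nan)
    obs_si, obs_stab = float(si[0]), float(stability[0])
    is_pc = bool(
        np.isfinite(obs_si) and np.isfinite(obs_stab)
        and np.isfinite(si_thr) and np.isfinite(stab_thr)
        and obs_si > si_thr and obs_stab > stab_thr
    )
    return PlaceCellResult(obs_si, obs_stab, null_si, null_stab, si_thr, stab_thr, is_pc)


# ---------------------------------------------------------------------------
# population vectors and activity level
# ---------------------------------------------------------------------------

def pv_correlation(maps_a: np.ndarray, maps_b: np.ndarray, mode: str = "zero-fill") -> float:
    """Mean per-bin Pearson correlation of population vectors across cells.

    ``maps_a`` / ``maps_b`` are (n_cells, n_bins) normalized rate maps with
    all-NaN rows marking cells inactive in that session. ``zero-fill``
    substitutes zeros for inactive cells; ``intersect`` drops them.
    """
    a = np.atleast_2d(np.asarray(maps_a, dtype=float))
    b = np.atleast_2d(np.asarray(maps_b, dtype=float))
    if a.shape != b.shape:
        raise ConfigError("map stacks must have equal shape")
    inactive_a = ~np.isfinite(a).any(axis=1)
    inactive_b = ~np.isfinite(b).any(axis=1)
    if mode == "zero-fill":
        pass
    elif mode == "intersect":
        keep = ~(inactive_a | inactive_b)
        a, b = a[keep], b[keep]
    else:
        raise ConfigError(f"unknown mode {mode!r}")
    if a.shape[0] < 2:
        raise DegenerateDataError("need >= 2 cells in the population vector")
    a = np.nan_to_num(a, nan=0.0)
    b = np.nan_to_num(b, nan=0.0)
    rs = _corr_columns(a, b)
    rs = rs[np.isfinite(rs)]
    if rs.size == 0:
        raise DegenerateDataError("no bin had variance across cells in both sessions")
    return float(rs.mean())


def activity_quantile(traces: TraceSet | np.ndarray) -> np.ndarray:
    """Quantile of each cell's temporal-mean activity among all cells.

    Mid-rank convention: quantile = (n_smaller + (n_ties - 1)/2) / n, so
    distinct means give 0, 1/n, ..., (n-1)/n and full ties give
    (n - 1) / (2 n) for every cell.
    """
    values = traces.values if isinstance(traces, TraceSet) else np.atleast_2d(traces)
    if values.shape[0] < 2:
        raise DegenerateDataError("need >= 2 cells for a relative quantile")
    means = values.mean(axis=1)
    n = means.size
    smaller = (means[:, None] > means[None, :]).sum(axis=1)
    ties = (means[:, None] == means[None, :]).sum(axis=1)  # includes self
    return (smaller + 0.5 * (ties - 1)) / n
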