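"""Synthetic multi-session dual-channel datasets with known ground truth.

Generates linear-track behaviour, a population of round cells visible in a
static (nuclear) channel, direction-specific place-field activity in a
dynamic channel, planted channel cross-talk, rigid field-of-view jitter
across sessions, and per-session activity dropout. Every quantity the
downstream analysis estimates (cross-talk coefficient, field centres,
activity schedule, cell identities) is recorded in :class:`GroundTruth`.

Seeding: every cell/session gets its own :func:`numpy.random.default_rng`
stream keyed by ``(seed, stage, session, cell)``, so adding cells or
sessions never reshuffles the draws of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .config import ExperimentConfig
from .core import (
    ConfigError,
    Footprint,
    GeometryError,
    PackingError,
    TraceSet,
    Trajectory,
    IDLE,
    LEFT,
    RIGHT,
)

__all__ = [
    "GroundTruth",
    "SyntheticSession",
    "simulate_trajectory",
    "simulate_population",
    "simulate_session_traces",
    "simulate_experiment",
    "simulate_crosstalk_pairs",
    "render_movies",
    "render_static_summary",
    "calcium_kernel",
    "gaussian_footprint",
]

# rng stream tags
_TRAJ, _POP, _TRACE, _MOVIE, _STATIC_IMG = 1, 2, 3, 4, 5


@dataclass
class GroundTruth:
    """Planted parameters of a simulated experiment."""

    base_centroids: np.ndarray          # (n_cells, 2) row/col px, session-0 frame
    session_shifts: np.ndarray          # (n_sessions, 2) rigid FOV shift px
    field_centers: np.ndarray           # (n_cells,) linearized cm in [0, 200); NaN if untuned
    tuned_mask: np.ndarray              # (n_cells,) bool
    active_matrix: np.ndarray           # (n_cells, n_sessions) bool
    crosstalk_alpha: float
    static_levels: np.ndarray           # (n_cells,) baseline static fluorescence

    @property
    def n_cells(self) -> int:
        return self.base_centroids.shape[0]

    @property
    def n_sessions(self) -> int:
        return self.session_shifts.shape[0]

    @property
    def cell_centroids(self) -> np.ndarray:
        """Per-session centroids after jitter, shape (n_sessions, n_cells, 2)."""
        return self.base_centroids[None, :, :] + self.session_shifts[:, None, :]


@dataclass
class SyntheticSession:
    """One simulated recording session (both channels)."""

    session: int
    day: int
    trajectory: Trajectory
    gcamp_events: TraceSet              # deconvolved; rows follow gcamp_cells
    gcamp_fluor: TraceSet               # denoised fluorescence; rows follow gcamp_cells
    static_traces: TraceSet             # raw-projected; one row per ground-truth cell
    gcamp_cells: np.ndarray             # truth cell index per gcamp trace row
    footprints_gcamp: list[Footprint]
    footprints_static: list[Footprint]
    movies: Optional[dict] = None

    def __post_init__(self) -> None:
        t = self.trajectory.n_frames
        for ts in (self.gcamp_events, self.gcamp_fluor, self.static_traces):
            if ts.n_frames != t:
                raise ConfigError("all frame-indexed members must share frame count")


def simulate_trajectory(config: ExperimentConfig, seed: int | None = None) -> Trajectory:
    """Back-and-forth runs on a linear track with pauses at the ends.

    Run speeds are drawn around ``config.run_speed_cm_s``; pause durations are
    jittered around ``config.pause_s``. The generated ground-truth behaviour
    labels and linearized positions are stashed in ``Trajectory.meta`` — the
    analysis recomputes its own from raw positions.
    """
    if config.session_duration_s <= 0 or config.fps <= 0:
        raise ConfigError("duration and fps must be positive")
    rng = np.random.default_rng([_TRAJ, config.seed if seed is None else seed])
    n_frames = config.n_frames
    length = config.track_length_cm
    fps = config.fps

    pos: list[np.ndarray] = []
    behavior: list[np.ndarray] = []
    frames_done = 0
    at = 0.0              # current position, cm
    heading_right = True  # next run direction (toward track_length)
    n_laps = 0

    def draw_speed() -> float:
        if config.run_speed_sd_cm_s > 0:
            return float(np.clip(
                rng.normal(config.run_speed_cm_s, config.run_speed_sd_cm_s), 5.0, None
            ))
        return config.run_speed_cm_s

    def run_segment(start: float, stop: float) -> None:
        nonlocal frames_done
        v = draw_speed()
        step = v / fps
        dist = abs(stop - start)
        n_run = int(np.ceil(dist / step))
        ramp = step * np.arange(1, n_run + 1)
        going_right = stop > start
        seg = np.clip(start + ramp, 0.0, length) if going_right else np.clip(start - ramp, 0.0, length)
        seg[-1] = stop
        pos.append(seg)
        behavior.append(np.full(n_run, RIGHT if going_right else LEFT, dtype=int))
        frames_done += n_run

    while frames_done < n_frames:
        if config.pause_s > 0:
            n_pause = int(round(config.pause_s * fps * rng.uniform(0.5, 1.5)))
        else:
            n_pause = 0
        if n_pause:
            pos.append(np.full(n_pause, at))
            behavior.append(np.full(n_pause, IDLE, dtype=int))
            frames_done += n_pause
        # occasional partial excursion: out to mid-track and back, no lap
        if config.turnaround_prob > 0 and rng.random() < config.turnaround_prob:
            frac = rng.uniform(0.3, 0.8)
            target = at + frac * length if heading_right else at - frac * length
            target = float(np.clip(target, 0.0, length))
            run_segment(at, target)
            run_segment(target, at)
        run_segment(at, length if heading_right else 0.0)
        if frames_done <= n_frames:
            n_laps += 1
        at = length if heading_right else 0.0
        heading_right = not heading_right

    pos_cm = np.concatenate(pos)[:n_frames]
    beh = np.concatenate(behavior)[:n_frames]

    frac = pos_cm / length
    true_lin = np.where(beh == RIGHT, 100.0 + frac * 100.0, frac * 100.0)
    true_lin[beh == IDLE] = np.nan

    traj = Trajectory(
        x_px=pos_cm * config.px_per_cm,
        y_px=np.full(n_frames, 50.0),
        fps=fps,
        track_length_cm=length,
        px_per_cm=config.px_per_cm,
    )
    traj.meta.update(
        n_laps=n_laps,
        true_behavior=beh,
        true_linpos=true_lin,
        run_speed_cm_s=config.run_speed_cm_s,
    )
    return traj


def simulate_population(config: ExperimentConfig, seed: int | None = None) -> GroundTruth:
    """Sample cell positions, tuning, activity schedule and FOV jitter.

    Centroids are placed by dart-throwing with a minimum pairwise separation
    of ``config.min_separation_px``; a :class:`PackingError` is raised when
    the requested count cannot be placed.
    """
    rng = np.random.default_rng([_POP, config.seed if seed is None else seed])
    h, w = config.fov_shape
    margin = 3.0 * config.footprint_sigma_px + config.fov_jitter_px + 1.0
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise PackingError("field of view too small for footprint margin")

    min_sep = config.min_separation_px
    centroids = np.empty((config.n_cells, 2))
    placed = 0
    max_tries = 200_000
    for _ in range(max_tries):
        cand = rng.uniform([margin, margin], [h - margin, w - margin])
        if placed == 0 or cdist(cand[None], centroids[:placed]).min() >= min_sep:
            centroids[placed] = cand
            placed += 1
            if placed == config.n_cells:
                break
    if placed < config.n_cells:
        raise PackingError(
            f"placed only {placed}/{config.n_cells} cells at separation {min_sep} px"
        )

    n = config.n_cells
    tuned = rng.random(n) < config.place_cell_fraction
    direction = rng.integers(0, 2, size=n)  # 0 left, 1 right
    centers = rng.uniform(10.0, 90.0, size=n) + 100.0 * direction
    centers = np.where(tuned, centers, np.nan)

    active = rng.random((n, config.n_sessions)) < config.activity_prob

    shifts = np.zeros((config.n_sessions, 2))
    if config.fov_jitter_px > 0 and config.n_sessions > 1:
        shifts[1:] = rng.uniform(
            -config.fov_jitter_px, config.fov_jitter_px, size=(config.n_sessions - 1, 2)
        )

    levels = config.static_baseline + config.static_baseline_sd * rng.standard_normal(n)
    levels = np.clip(levels, 0.2 * config.static_baseline, None)

    return GroundTruth(
        base_centroids=centroids,
        session_shifts=shifts,
        field_centers=centers,
        tuned_mask=tuned,
        active_matrix=active,
        crosstalk_alpha=config.crosstalk_alpha,
        static_levels=levels,
    )


def calcium_kernel(fps: float, rise_s: float = 0.05, decay_s: float = 0.4) -> np.ndarray:
    """Unit-peak double-exponential indicator kernel sampled at ``fps``."""
    t = np.arange(0.0, 5.0 * decay_s, 1.0 / fps)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = k.max()
    if peak <= 0:  # decay faster than rise; degenerate but keep a delta
        k = np.zeros_like(t)
        k[0] = 1.0
        return k
    return k / peak


def gaussian_footprint(
    shape: tuple[int, int], center: tuple[float, float], sigma: float, cell_id: int = 0
) -> Footprint:
    """Isotropic Gaussian footprint truncated at 3 sigma."""
    h, w = shape
    r0, c0 = center
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise GeometryError(f"footprint centre {center} outside FOV {shape}")
    rad = int(np.ceil(3.0 * sigma))
    rlo, rhi = max(0, int(np.floor(r0)) - rad), min(h, int(np.ceil(r0)) + rad + 1)
    clo, chi = max(0, int(np.floor(c0)) - rad), min(w, int(np.ceil(c0)) + rad + 1)
    rr, cc = np.meshgrid(np.arange(rlo, rhi), np.arange(clo, chi), indexing="ij")
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    patch = np.exp(-d2 / (2.0 * sigma**2))
    patch[d2 > (3.0 * sigma) ** 2] = 0.0
    weights = np.zeros(shape, dtype=np.float32)
    weights[rlo:rhi, clo:chi] = patch
    return Footprint(cell_id=cell_id, weights=weights, centroid=(float(r0), float(c0)))


def _place_field_rate(linpos: np.ndarray, center: float, width_cm: float,
                      peak_hz: float) -> np.ndarray:
    sigma = width_cm / 2.0
    rate = np.zeros_like(linpos)
    ok = np.isfinite(linpos)
    rate[ok] = peak_hz * np.exp(-((linpos[ok] - center) ** 2) / (2.0 * sigma**2))
    return rate


def simulate_session_traces(
    truth: GroundTruth,
    traj: Trajectory,
    config: ExperimentConfig,
    session: int,
    seed: int | None = None,
) -> SyntheticSession:
    """Generate both channels' traces and footprints for one session.

    Tuned active cells emit Poisson events along a Gaussian tuning curve of
    the linearized position (direction-specific by construction of the
    0–200 range); untuned active cells emit homogeneously. The static trace
    is baseline + slow sinusoidal drift + ``crosstalk_alpha`` x the clean
    dynamic fluorescence + sensor noise.
    """
    if not 0 <= session < truth.n_sessions:
        raise IndexError(f"session {session} out of range 0..{truth.n_sessions - 1}")
    base_seed = config.seed if seed is None else seed
    n_frames = traj.n_frames
    fps = traj.fps
    kernel = calcium_kernel(fps, config.kernel_rise_s, config.kernel_decay_s)
    linpos = traj.meta.get("true_linpos")
    if linpos is None:
        raise ConfigError("trajectory lacks generator metadata (true_linpos)")

    active = truth.active_matrix[:, session]
    shift = truth.session_shifts[session]
    events_rows, fluor_rows, static_rows = [], [], []
    fp_gcamp, fp_static = [], []
    gcamp_cells = []
    t_grid = np.arange(n_frames)

    for cell in range(truth.n_cells):
        rng = np.random.default_rng([_TRACE, base_seed, session, cell])
        clean = np.zeros(n_frames)
        if active[cell]:
            if truth.tuned_mask[cell]:
                rate = _place_field_rate(
                    linpos, float(truth.field_centers[cell]),
                    config.field_width_cm, config.peak_rate_hz,
                )
                rate += config.tuned_baseline_frac * config.peak_rate_hz
            else:
                rate = np.full(n_frames, config.untuned_rate_hz)
            counts = rng.poisson(rate / fps)
            amps = rng.standard_gamma(counts.astype(float))
            clean = np.convolve(amps, kernel)[:n_frames]
            noise = rng.standard_normal(n_frames) * config.noise_sd
            events_rows.append(amps)
            fluor_rows.append(clean + noise)
            gcamp_cells.append(cell)
            cen = truth.base_centroids[cell] + shift
            fp_gcamp.append(
                gaussian_footprint(config.fov_shape, tuple(cen),
                                   config.footprint_sigma_px, cell_id=len(gcamp_cells) - 1)
            )
        # static channel: present for every cell
        level = truth.static_levels[cell]
        phase = rng.uniform(0.0, 2.0 * np.pi)
        drift = (config.static_drift_frac * level
                 * np.sin(2.0 * np.pi * 1.5 * t_grid / n_frames + phase))
        static = (level + drift + truth.crosstalk_alpha * clean
                  + rng.standard_normal(n_frames) * config.noise_sd)
        static_rows.append(static)
        cen = truth.base_centroids[cell] + shift
        fp_static.append(
            gaussian_footprint(config.fov_shape, tuple(cen),
                               config.static_sigma_px, cell_id=cell)
        )

    if events_rows:
        ev = np.asarray(events_rows)
        fl = np.asarray(fluor_rows)
    else:
        ev = np.zeros((0, n_frames))
        fl = np.zeros((0, n_frames))
    day = session * config.session_interval_days
    return SyntheticSession(
        session=session,
        day=day,
        trajectory=traj,
        gcamp_events=TraceSet(ev, "deconvolved", fps),
        gcamp_fluor=TraceSet(fl, "denoised", fps),
        static_traces=TraceSet(np.asarray(static_rows), "raw-projected", fps),
        gcamp_cells=np.asarray(gcamp_cells, dtype=int),
        footprints_gcamp=fp_gcamp,
        footprints_static=fp_static,
    )


def simulate_experiment(
    config: ExperimentConfig,
) -> tuple[list[SyntheticSession], GroundTruth]:
    """Full experiment: one session per scheduled day, shared ground truth."""
    truth = simulate_population(config)
    sessions = []
    for s in range(config.n_sessions):
        traj = simulate_trajectory(config, seed=config.seed * 10_000 + s)
        sessions.append(simulate_session_traces(truth, traj, config, s))
    return sessions, truth


def render_movies(
    session: SyntheticSession,
    config: ExperimentConfig,
    seed: int | None = None,
    noise_sd: float | None = None,
) -> dict[str, np.ndarray]:
    """Render per-channel frame stacks: frame_t = sum_c footprint_c * trace_c[t] + noise."""
    noise = config.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng([_MOVIE, config.seed if seed is None else seed,
                                 session.session])
    h, w = config.fov_shape
    n_frames = session.trajectory.n_frames
    out = {}
    for name, fps_, traces in (
        ("gcamp", session.footprints_gcamp, session.gcamp_fluor.values),
        ("static", session.footprints_static, session.static_traces.values),
    ):
        movie = np.zeros((n_frames, h, w), dtype=np.float32)
        for fp, trace in zip(fps_, traces):
            if fp.weights.shape != (h, w):
                raise GeometryError("footprint shape does not match FOV")
            rows, cols = np.nonzero(fp.weights)
            movie[:, rows, cols] += np.outer(trace, fp.weights[rows, cols]).astype(np.float32)
        if noise > 0:
            movie += rng.standard_normal(movie.shape).astype(np.float32) * noise
        out[name] = movie
    return out


def render_static_summary(
    session: SyntheticSession, config: ExperimentConfig, seed: int | None = None
) -> np.ndarray:
    """Mean-projection image of the static channel without materializing a movie.

    Pixel noise scales as noise_sd / sqrt(n_frames), matching the mean of a
    noisy movie.
    """
    rng = np.random.default_rng([_STATIC_IMG, config.seed if seed is None else seed,
                                 session.session])
    h, w = config.fov_shape
    image = np.zeros((h, w))
    means = session.static_traces.values.mean(axis=1)
    for fp, m in zip(session.footprints_static, means):
        image += fp.weights * m
    if config.noise_sd > 0:
        image += rng.standard_normal((h, w)) * (
            config.noise_sd / np.sqrt(session.trajectory.n_frames)
        )
    return image


def simulate_crosstalk_pairs(
    n_cells: int,
    duration_s: float,
    fps: float,
    alpha: float,
    snr: float = 5.0,
    rate_hz: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (dynamic, static) traces with planted cross-talk ``alpha``.

    The dynamic trace is homogeneous-Poisson transients plus sensor noise at
    sd(clean)/``snr``; the static trace is baseline + ``alpha`` x clean
    dynamic + independent noise at the same level. Returns two arrays of
    shape (n_cells, n_frames).
    """
    n_frames = int(round(duration_s * fps))
    kernel = calcium_kernel(fps)
    gcamp = np.empty((n_cells, n_frames))
    static = np.empty((n_cells, n_frames))
    for c in range(n_cells):
        rng = np.random.default_rng([7, seed, c])
        counts = rng.poisson(rate_hz / fps, size=n_frames)
        amps = rng.standard_gamma(counts.astype(float))
        clean = np.convolve(amps, kernel)[:n_frames]
        sd = clean.std()
        noise = sd / snr if sd > 0 else 0.0
        gcamp[c] = clean + rng.standard_normal(n_frames) * noise
        static[c] = (1.0 + alpha * clean
                     + rng.standard_normal(n_frames) * noise)
    return gcamp, static
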