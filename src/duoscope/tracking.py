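"""Longitudinal tracking statistics over a boolean activity matrix.

Given which globally registered cells are present in which sessions, this
module computes the per-session tracking probability

    p_m = (1/k) * sum_i N_mi / N_i

(N_i cells present in session i, N_mi those of them present in exactly m
sessions total), the pairwise reactivation rate

    p_AB = 1/2 (N_2/N_A + N_2/N_B),

raw activity-pattern proportions, and OLS slopes of a metric against the
day interval between session pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ConfigError, DegenerateDataError
from .registration import RegistrationMap

__all__ = [
    "ActivityMatrix",
    "build_activity_matrix",
    "per_session_tracking_probability",
    "tracking_probabilities",
    "reactivation_rate",
    "combination_proportions",
    "slope_vs_interval",
]


@dataclass
class ActivityMatrix:
    """Boolean cells x sessions presence matrix with session day indices."""

    matrix: np.ndarray
    day_index: np.ndarray
    global_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.ndim != 2:
            raise ConfigError("activity matrix must be 2D")
        self.day_index = np.asarray(self.day_index, dtype=int)
        if self.day_index.size != self.matrix.shape[1]:
            raise ConfigError("one day index per session required")
        if np.any(np.diff(self.day_index) <= 0):
            raise ConfigError("sessions must be ordered by strictly increasing day")
        if self.matrix.shape[0] and not self.matrix.any(axis=1).all():
            raise ConfigError("every cell must be active in at least one session")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sessions(self) -> int:
        return self.matrix.shape[1]


def build_activity_matrix(
    reg_map: RegistrationMap, channel: str, subset=None
) -> ActivityMatrix:
    """Presence matrix for one channel, optionally restricted to a global-id subset."""
    presence = reg_map.presence(channel)
    if subset is not None:
        subset = sorted(int(g) for g in subset)
        presence = presence.loc[presence.index.intersection(subset)]
    presence = presence.loc[presence.any(axis=1)]
    if presence.shape[0] == 0:
        raise DegenerateDataError("no cells present for the requested channel/subset")
    return ActivityMatrix(
        matrix=presence.to_numpy(),
        day_index=reg_map.day_index,
        global_ids=presence.index.to_numpy(),
    )


def _session_counts(am: ActivityMatrix) -> tuple[np.ndarray, np.ndarray]:
    n_i = am.matrix.sum(axis=0)
    if np.any(n_i == 0):
        empty = np.nonzero(n_i == 0)[0].tolist()
        raise DegenerateDataError(f"sessions {empty} have no active cells")
    row_totals = am.matrix.sum(axis=1)
    return n_i, row_totals


def per_session_tracking_probability(am: ActivityMatrix, m: int) -> float:
    """p_m = (1/k) sum_i N_mi / N_i."""
    k = am.n_sessions
    if not 1 <= m <= k:
        raise ConfigError(f"m must be in 1..{k}")
    n_i, row_totals = _session_counts(am)
    is_m = row_totals == m
    n_mi = (am.matrix & is_m[:, None]).sum(axis=0)
    return float(np.mean(n_mi / n_i))


def tracking_probabilities(am: ActivityMatrix) -> np.ndarray:
    """All p_m for m = 1..k; sums to 1."""
    return np.array([per_session_tracking_probability(am, m)
                     for m in range(1, am.n_sessions + 1)])


def reactivation_rate(am: ActivityMatrix, a: int, b: int) -> float:
    """p_AB = 1/2 (N_2/N_A + N_2/N_B) for sessions ``a`` and ``b``."""
    if a == b:
        raise ConfigError("sessions A and B must differ")
    col_a, col_b = am.matrix[:, a], am.matrix[:, b]
    n_a, n_b = int(col_a.sum()), int(col_b.sum())
    if n_a == 0 or n_b == 0:
        raise DegenerateDataError("both sessions must have active cells")
    n_2 = int((col_a & col_b).sum())
    return 0.5 * (n_2 / n_a + n_2 / n_b)


def combination_proportions(am: ActivityMatrix) -> dict[tuple[int, ...], float]:
    """Fraction of cells showing each exact activity pattern (keys: session tuples)."""
    if am.n_cells == 0:
        raise DegenerateDataError("empty activity matrix")
    patterns: dict[tuple[int, ...], int] = {}
    for row in am.matrix:
        key = tuple(int(s) for s in np.nonzero(row)[0])
        patterns[key] = patterns.get(key, 0) + 1
    return {k: v / am.n_cells for k, v in sorted(patterns.items())}


@dataclass
class SlopeFit:
    slope: float
    intercept: float
    p_value: float
    stderr: float
    r_value: float


def slope_vs_interval(intervals, values) -> SlopeFit:
    """OLS of a session-pair metric on the day interval; exact-t p-value."""
    x = np.asarray(intervals, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ConfigError("need at least 3 (interval, value) points")
    if np.ptp(x) == 0:
        raise DegenerateDataError("all intervals equal; slope is rank-deficient")
    res = stats.linregress(x, y)
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
        r_value=float(res.rvalue),
    )
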