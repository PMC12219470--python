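"""Centroid-distance cell registration across channels and sessions.

Within-session cross-channel matching and session-to-session tracking both
reduce to mutual-nearest-neighbour matching of centroid sets under a
distance threshold. Cross-session identities are chained against a running
reference whose centroids are updated to the mean of their matched members,
and a dynamic-channel (GCaMP) mapping is obtained by propagating identities
through the static-channel landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import ConfigError, DuoscopeError, Footprint, GeometryError

__all__ = [
    "MatchPairs",
    "RegistrationMap",
    "match_centroids",
    "register_cross_channel",
    "register_cross_session",
    "propagate_gcamp_map",
]

STATIC, GCAMP = "static", "gcamp"


class RegistrationConflictError(DuoscopeError, RuntimeError):
    """Two local cells claimed the same global identity in one session."""


@dataclass
class MatchPairs:
    """One-to-one matches between two centroid sets."""

    pairs: list[tuple[int, int, float]]  # (index_a, index_b, distance px)
    unmatched_a: list[int]
    unmatched_b: list[int]

    @property
    def a_to_b(self) -> dict[int, int]:
        return {a: b for a, b, _ in self.pairs}

    @property
    def b_to_a(self) -> dict[int, int]:
        return {b: a for a, b, _ in self.pairs}


@dataclass
class RegistrationMap:
    """Global cell identities linking per-session, per-channel local indices.

    ``table`` has columns ``global_id, session, channel, local_index`` with at
    most one row per (global_id, session, channel) and per
    (session, channel, local_index).
    """

    table: pd.DataFrame
    day_index: np.ndarray
    stable_ids: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.day_index = np.asarray(self.day_index, dtype=int)
        if np.any(np.diff(self.day_index) <= 0):
            raise ConfigError("day indices must be strictly increasing")
        dup = self.table.duplicated(subset=["global_id", "session", "channel"])
        if dup.any():
            raise RegistrationConflictError("global_id appears twice in a session+channel")
        dup = self.table.duplicated(subset=["session", "channel", "local_index"])
        if dup.any():
            raise RegistrationConflictError("local cell maps to two global ids")

    @property
    def n_sessions(self) -> int:
        return self.day_index.size

    def global_ids(self, channel: str | None = None) -> np.ndarray:
        t = self.table if channel is None else self.table[self.table.channel == channel]
        return np.sort(t.global_id.unique())

    def presence(self, channel: str) -> pd.DataFrame:
        """Boolean frame indexed by global_id with one column per session."""
        t = self.table[self.table.channel == channel]
        mat = pd.crosstab(t.global_id, t.session).astype(bool)
        return mat.reindex(columns=range(self.n_sessions), fill_value=False)

    def local_to_global(self, session: int, channel: str) -> dict[int, int]:
        t = self.table[(self.table.session == session) & (self.table.channel == channel)]
        return dict(zip(t.local_index.astype(int), t.global_id.astype(int)))


def _as_centroids(items) -> np.ndarray:
    if len(items) == 0:
        return np.zeros((0, 2))
    if isinstance(items[0], Footprint):
        return np.asarray([fp.centroid for fp in items], dtype=float)
    arr = np.asarray(items, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ConfigError("centroids must be an (n, 2) array or list of Footprints")
    return arr


def match_centroids(centroids_a, centroids_b, max_dist: float) -> MatchPairs:
    """Mutual-nearest-neighbour pairs with distance <= ``max_dist``.

    Pairs are reported in ascending distance order (ties broken by the lower
    index pair); the matching is symmetric in A and B.
    """
    if max_dist <= 0:
        raise ConfigError("max_dist must be positive")
    a = _as_centroids(centroids_a)
    b = _as_centroids(centroids_b)
    if a.shape[0] == 0 or b.shape[0] == 0:
        return MatchPairs([], list(range(a.shape[0])), list(range(b.shape[0])))
    d = cdist(a, b)
    nn_a = d.argmin(axis=1)
    nn_b = d.argmin(axis=0)
    pairs = []
    for i, j in enumerate(nn_a):
        if nn_b[j] == i and d[i, j] <= max_dist:
            pairs.append((i, int(j), float(d[i, j])))
    pairs.sort(key=lambda p: (p[2], p[0], p[1]))
    matched_a = {p[0] for p in pairs}
    matched_b = {p[1] for p in pairs}
    return MatchPairs(
        pairs,
        [i for i in range(a.shape[0]) if i not in matched_a],
        [j for j in range(b.shape[0]) if j not in matched_b],
    )


def register_cross_channel(
    gcamp_fps: list[Footprint], static_fps: list[Footprint], max_dist: float = 5.0
) -> MatchPairs:
    """Match dynamic-channel cells to static-channel cells within one session."""
    return match_centroids(gcamp_fps, static_fps, max_dist)


def register_cross_session(
    footprints_by_session: list,
    max_dist: float = 5.0,
    day_index=None,
    channel: str = STATIC,
) -> RegistrationMap:
    """Chain session-to-session matches into global identities.

    The first session seeds the reference set; each later session is matched
    against the running reference and matched reference centroids are updated
    to the mean over all matched members. Unmatched cells start new ids.
    """
    if len(footprints_by_session) < 1:
        raise ConfigError("need at least one session")
    per_session = [_as_centroids(fps) for fps in footprints_by_session]
    shapes = {
        fps[0].shape
        for fps in footprints_by_session
        if len(fps) and isinstance(fps[0], Footprint)
    }
    if len(shapes) > 1:
        raise GeometryError(f"inconsistent FOV shapes across sessions: {shapes}")
    if day_index is None:
        day_index = np.arange(len(per_session))

    ref_centroids: list[np.ndarray] = []   # running mean per global id
    ref_counts: list[int] = []
    rows = []
    next_gid = 0
    for s, cents in enumerate(per_session):
        if ref_centroids:
            mp = match_centroids(np.asarray(ref_centroids), cents, max_dist)
        else:
            mp = MatchPairs([], [], list(range(cents.shape[0])))
        for gid, j, _ in mp.pairs:
            rows.append((gid, s, channel, int(j)))
            k = ref_counts[gid]
            ref_centroids[gid] = (ref_centroids[gid] * k + cents[j]) / (k + 1)
            ref_counts[gid] += 1
        for j in mp.unmatched_b:
            rows.append((next_gid, s, channel, int(j)))
            ref_centroids.append(cents[j].copy())
            ref_counts.append(1)
            next_gid += 1
    table = pd.DataFrame(rows, columns=["global_id", "session", "channel", "local_index"])
    return RegistrationMap(table=table, day_index=day_index)


def propagate_gcamp_map(
    static_map: RegistrationMap, cross_channel: dict[int, MatchPairs]
) -> RegistrationMap:
    """Give each dynamic-channel cell the identity of its static landmark.

    ``cross_channel[s]`` holds the session-``s`` matches with A = GCaMP local
    index and B = static local index. GCaMP cells with no static partner are
    dropped. ``stable_ids`` is the subset of global ids whose static landmark
    is present in every session.
    """
    rows = []
    for s in range(static_map.n_sessions):
        mp = cross_channel.get(s)
        if mp is None:
            raise ConfigError(f"missing cross-channel matching for session {s}")
        static_l2g = static_map.local_to_global(s, STATIC)
        seen: dict[int, int] = {}
        for ig, istatic, _ in mp.pairs:
            gid = static_l2g.get(istatic)
            if gid is None:
                continue
            if gid in seen:
                raise RegistrationConflictError(
                    f"session {s}: GCaMP cells {seen[gid]} and {ig} share landmark {gid}"
                )
            seen[gid] = ig
            rows.append((gid, s, GCAMP, int(ig)))
    gtable = pd.DataFrame(rows, columns=["global_id", "session", "channel", "local_index"])
    presence = static_map.presence(STATIC)
    stable = frozenset(int(g) for g in presence.index[presence.all(axis=1)])
    table = pd.concat([static_map.table, gtable], ignore_index=True)
    return RegistrationMap(table=table, day_index=static_map.day_index, stable_ids=stable)
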