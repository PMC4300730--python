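"""Linking of cells and interfaces across time-lapse frames.

Cells link by nearest-neighbour assignment of footprint centres; upon a
division only the closest daughter continues the parent track and the
other daughter starts a new one.  Interfaces link by an optimal
assignment over a cost combining the two proximal endpoint distances and
the centre-of-mass distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

log = logging.getLogger(__name__)

__all__ = ["TrackSet", "track_cells", "track_interfaces", "interface_link_cost"]

_BIG = 1e9


@dataclass
class TrackSet:
    """Per-entity track assignments.

    ``tracks`` maps track id -> {frame index: entity id}; ``divisions``
    records (parent_track, new_track, frame) triples where an unmatched
    entity appeared next to a linked one.
    """

    tracks: dict[int, dict[int, int]] = field(default_factory=dict)
    divisions: list[tuple[int, int, int]] = field(default_factory=list)

    def as_dataframe(self):
        import pandas as pd

        rows = [
            {"track_id": tid, "frame": f, "entity_id": e}
            for tid, tr in self.tracks.items()
            for f, e in sorted(tr.items())
        ]
        return pd.DataFrame(rows)


def _assign(cost: np.ndarray, gate: float) -> list[tuple[int, int]]:
    """Optimal one-to-one assignment with a gating distance.

    Pads the matrix so unmatched rows/columns are allowed, then solves
    the global assignment; pairs whose cost exceeds the gate stay
    unlinked.  Deterministic: scipy's solver breaks ties by index order
    (lower id wins), which we log when it happens.
    """
    n, m = cost.shape
    padded = np.full((n + m, n + m), gate, dtype=float)
    padded[:n, :m] = np.where(cost <= gate, cost, _BIG)
    rows, cols = linear_sum_assignment(padded)
    out = []
    for r, c in zip(rows, cols):
        if r < n and c < m and padded[r, c] <= gate:
            out.append((r, c))
    return out


def track_cells(
    frames_centers: list[np.ndarray],
    gate_um: float = 20.0,
) -> TrackSet:
    """Track cells by nearest-neighbour centre assignment.

    ``frames_centers`` is a list of (n_i, 2) centre arrays (um) per
    frame.  Links minimize the summed centre-to-centre distance
    globally; entities beyond ``gate_um`` of any partner start or end
    tracks.  After a division both daughters compete for the parent:
    the assignment links the closest daughter, the other becomes a new
    track recorded as a division event.
    """
    if len(frames_centers) < 2:
        raise ValueError("need at least 2 frames to track")
    ts = TrackSet()
    next_track = 0
    current: dict[int, int] = {}  # entity idx in prev frame -> track id
    for i in range(len(frames_centers[0])):
        ts.tracks[next_track] = {0: i}
        current[i] = next_track
        next_track += 1
    for f in range(1, len(frames_centers)):
        prev = np.asarray(frames_centers[f - 1], dtype=float)
        cur = np.asarray(frames_centers[f], dtype=float)
        cost = np.linalg.norm(prev[:, None, :] - cur[None, :, :], axis=2)
        ties = np.sum(np.abs(cost - cost.min(axis=1, keepdims=True)) < 1e-12, axis=1)
        if np.any(ties > 1):
            log.info("distance tie during cell linking; lower index wins")
        links = _assign(cost, gate_um)
        new_current: dict[int, int] = {}
        matched_cur = set()
        for r, c in links:
            tid = current[r]
            ts.tracks[tid][f] = c
            new_current[c] = tid
            matched_cur.add(c)
        for c in range(len(cur)):
            if c in matched_cur:
                continue
            tid = next_track
            next_track += 1
            ts.tracks[tid] = {f: c}
            new_current[c] = tid
            # division bookkeeping: a new entity near a linked parent
            if len(prev):
                parent_prev = int(np.argmin(np.linalg.norm(prev - cur[c], axis=1)))
                if np.linalg.norm(prev[parent_prev] - cur[c]) <= gate_um:
                    ts.divisions.append((current.get(parent_prev, -1), tid, f))
        current = new_current
    return ts


def interface_link_cost(
    end_a1: np.ndarray, end_a2: np.ndarray, com_a: np.ndarray,
    end_b1: np.ndarray, end_b2: np.ndarray, com_b: np.ndarray,
) -> float:
    """Cost of linking two interfaces: sum of the two proximal endpoint
    distances plus the centre-of-mass distance."""
    direct = np.linalg.norm(end_a1 - end_b1) + np.linalg.norm(end_a2 - end_b2)
    crossed = np.linalg.norm(end_a1 - end_b2) + np.linalg.norm(end_a2 - end_b1)
    return float(min(direct, crossed) + np.linalg.norm(com_a - com_b))


def track_interfaces(
    frames_interfaces: list[list[dict]],
    gate_um: float = 20.0,
) -> TrackSet:
    """Track interfaces by optimal assignment of the endpoint/centroid cost.

    Each frame is a list of dicts with ``end1``, ``end2``, ``com`` (um).
    The pairing minimizing the total cost among all possible pairings is
    chosen per frame pair; unmatched interfaces start or end tracks.
    """
    if len(frames_interfaces) < 2:
        raise ValueError("need at least 2 frames to track")
    ts = TrackSet()
    next_track = 0
    current: dict[int, int] = {}
    for i in range(len(frames_interfaces[0])):
        ts.tracks[next_track] = {0: i}
        current[i] = next_track
        next_track += 1
    for f in range(1, len(frames_interfaces)):
        prev = frames_interfaces[f - 1]
        cur = frames_interfaces[f]
        cost = np.zeros((len(prev), len(cur)))
        for r, a in enumerate(prev):
            for c, b in enumerate(cur):
                cost[r, c] = interface_link_cost(
                    np.asarray(a["end1"]), np.asarray(a["end2"]), np.asarray(a["com"]),
                    np.asarray(b["end1"]), np.asarray(b["end2"]), np.asarray(b["com"]),
                )
        links = _assign(cost, 3 * gate_um)
        new_current: dict[int, int] = {}
        matched = set()
        for r, c in links:
            tid = current[r]
            ts.tracks[tid][f] = c
            new_current[c] = tid
            matched.add(c)
        for c in range(len(cur)):
            if c not in matched:
                ts.tracks[next_track] = {f: c}
                new_current[c] = next_track
                next_track += 1
        current = new_current
    return ts
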