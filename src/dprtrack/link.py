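"""Two-pass LAP particle linking with gap closing.

Pass 1 links detections between consecutive frames by solving, per frame
pair, an optimal bipartite assignment on squared displacement with a
non-link alternative costing ``linking_max_distance**2`` (the augmented-cost
construction of LAP tracking).  Pass 2 joins the resulting track-segment
ends to later segment starts, again by optimal assignment on squared
distance, when the frame gap is at most ``max_frame_gap`` and the bridge
distance at most ``gap_closing_max_distance``.  Each detection belongs to at
most one trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detect import SpotDetection
from .simulate import Trajectory

__all__ = ["LinkingConfig", "link_points", "link_tracks", "filter_trajectories"]

_INF = 1e30


@dataclass(frozen=True)
class LinkingConfig:
    """Linking parameters (all in µm and frames)."""

    linking_max_distance: float = 1.0
    gap_closing_max_distance: float = 1.0
    max_frame_gap: int = 5

    def __post_init__(self) -> None:
        if (self.linking_max_distance < 0 or self.gap_closing_max_distance < 0
                or self.max_frame_gap < 0):
            raise ValueError("linking parameters must be >= 0")


def _lap_pair(cost: np.ndarray, alt_cost: float) -> list[tuple[int, int]]:
    """Solve one frame-to-frame LAP with per-item non-link alternatives.

    ``cost`` is (n1, n2) with infeasible entries >= _INF.  Returns the list
    of (i, j) real links in the optimal solution.
    """
    n1, n2 = cost.shape
    big = np.full((n1 + n2, n2 + n1), _INF)
    big[:n1, :n2] = cost
    idx1 = np.arange(n1)
    idx2 = np.arange(n2)
    big[idx1, n2 + idx1] = alt_cost  # source drops out
    big[n1 + idx2, idx2] = alt_cost  # target starts fresh
    # lower-right slack block: feasible wherever the real block is
    lr = np.where(cost.T < _INF, 0.0, _INF)
    big[n1:, n2:] = lr
    rows, cols = linear_sum_assignment(big)
    return [(r, c) for r, c in zip(rows, cols)
            if r < n1 and c < n2 and cost[r, c] < _INF]


def link_points(points_by_frame: list[np.ndarray],
                cfg: LinkingConfig) -> list[list[tuple[int, int]]]:
    """Link per-frame point sets into tracks of (frame, index) pairs.

    ``points_by_frame[f]`` is an (n_f, 2) array of positions (µm) for frame
    ``f``; empty frames are allowed.  Returns one list of (frame,
    within-frame index) per trajectory, frames strictly increasing.
    """
    n_frames = len(points_by_frame)
    pts = [np.asarray(p, dtype=float).reshape(-1, 2) for p in points_by_frame]
    # pass 1: frame-to-frame
    segments: list[list[tuple[int, int]]] = []
    open_by_index: dict[int, int] = {}  # detection idx in prev frame -> segment
    max2 = cfg.linking_max_distance ** 2
    for f in range(n_frames):
        cur = pts[f]
        new_open: dict[int, int] = {}
        if f > 0 and len(open_by_index) and len(cur):
            prev_idx = sorted(open_by_index)
            prev_pts = pts[f - 1][prev_idx]
            d2 = ((prev_pts[:, None, :] - cur[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(d2 <= max2, d2, _INF)
            for i, j in _lap_pair(cost, max2):
                seg = open_by_index[prev_idx[i]]
                segments[seg].append((f, j))
                new_open[j] = seg
        for j in range(len(cur)):
            if j not in new_open:
                segments.append([(f, j)])
                new_open[j] = len(segments) - 1
        open_by_index = new_open
    if cfg.max_frame_gap < 1 or not segments:
        return segments
    # pass 2: gap closing (segment end -> later segment start)
    ends = np.array([s[-1][0] for s in segments])
    starts = np.array([s[0][0] for s in segments])
    end_pos = np.array([pts[f][j] for f, j in (s[-1] for s in segments)])
    start_pos = np.array([pts[f][j] for f, j in (s[0] for s in segments)])
    gap = starts[None, :] - ends[:, None]
    d2 = ((end_pos[:, None, :] - start_pos[None, :, :]) ** 2).sum(axis=2)
    gmax2 = cfg.gap_closing_max_distance ** 2
    feasible = (gap >= 2) & (gap <= cfg.max_frame_gap + 1) & (d2 <= gmax2)
    cost = np.where(feasible, d2, _INF)
    links = _lap_pair(cost, gmax2)
    successor = dict(links)
    merged_into = set(j for _, j in links)
    out = []
    for i, seg in enumerate(segments):
        if i in merged_into:
            continue
        chain = list(seg)
        k = i
        while k in successor:
            k = successor[k]
            chain.extend(segments[k])
        out.append(chain)
    return out


def link_tracks(detections_by_frame: list[list[SpotDetection]],
                cfg: LinkingConfig, dt: float) -> list[Trajectory]:
    """Link per-frame spot detections into :class:`Trajectory` objects."""
    points = [np.array([[d.x, d.y] for d in dets]).reshape(-1, 2)
              for dets in detections_by_frame]
    tracks = link_points(points, cfg)
    out = []
    for tid, chain in enumerate(tracks):
        frames = np.array([f for f, _ in chain])
        xy = np.array([points[f][j] for f, j in chain])
        out.append(Trajectory(track_id=tid, frames=frames,
                              t=frames * dt, xy=xy))
    return out


def filter_trajectories(tracks: list[Trajectory],
                        min_duration: float) -> list[Trajectory]:
    """Keep tracks whose duration is strictly greater than ``min_duration``.

    Duration is the elapsed time between the first and last observed frame;
    order is preserved.
    """
    if min_duration < 0:
        raise ValueError("min_duration must be >= 0")
    return [t for t in tracks if t.duration > min_duration]
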