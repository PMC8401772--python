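"""Maximum-probability trajectory linking with gap closing.

For noninteracting Brownian particles the probability of a set of
frame-to-frame displacements {δᵢ} factorises into a product of Gaussians, so
the most likely assignment of particle labels between consecutive frames is
the one minimising Σδᵢ² subject to a hard displacement gate.  We solve this
exactly as a linear assignment problem (LAP) with birth/death dummy entries
at cost ``max_disp²``, then run a second LAP over (track end, track start)
pairs to re-join tracks fragmented by emitter blinking (gap closing).
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator

from .types import Detection, Trajectory

__all__ = [
    "LAPLinker",
    "link_cw",
    "filter_tracks",
    "detections_from_trajectories",
    "group_detections_by_frame",
]

_BIG = 1e15  # forbidden-assignment cost; large vs any gated d² but finite


def detections_from_trajectories(
    trajs: Sequence[Trajectory], pixel_size: float = 1.0
) -> List[List[Detection]]:
    """Explode trajectories into per-frame detection lists (pixels).

    Utility for closed-loop tests: ground-truth simulator trajectories (μm)
    become the linker's input, divided by ``pixel_size``.
    """
    n_frames = 1 + max((int(t.frames[-1]) for t in trajs), default=-1)
    out: List[List[Detection]] = [[] for _ in range(n_frames)]
    for t in trajs:
        inten = t.intensities if t.intensities is not None else np.ones(t.n_points)
        for i, f in enumerate(t.frames):
            out[int(f)].append(
                Detection(frame=int(f), x=t.xy[i, 0] / pixel_size,
                          y=t.xy[i, 1] / pixel_size, intensity=float(inten[i]))
            )
    return out


def group_detections_by_frame(detections: Sequence[Detection]) -> List[List[Detection]]:
    """Group a flat detection list into per-frame lists indexed by frame."""
    if not detections:
        return []
    n_frames = 1 + max(d.frame for d in detections)
    out: List[List[Detection]] = [[] for _ in range(n_frames)]
    for d in detections:
        out[d.frame].append(d)
    return out


def _solve_gated_lap(cost: np.ndarray, gate_cost: float) -> List[Tuple[int, int]]:
    """Solve an n×m assignment with per-item opt-out at ``gate_cost``.

    ``cost`` entries above ``gate_cost`` are treated as forbidden.  Returns
    the list of (row, col) pairs actually linked.
    """
    n, m = cost.shape
    if n == 0 or m == 0:
        return []
    C = np.full((n + m, n + m), _BIG)
    tl = np.where(cost <= gate_cost, cost, _BIG)
    C[:n, :m] = tl
    C[np.arange(n), m + np.arange(n)] = gate_cost  # deaths
    C[n + np.arange(m), np.arange(m)] = gate_cost  # births
    C[n:, m:] = 0.0  # complementary block
    rows, cols = linear_sum_assignment(C)
    return [(r, c) for r, c in zip(rows, cols) if r < n and c < m and tl[r, c] < _BIG]


class LAPLinker(BaseEstimator):
    """Frame-to-frame LAP linker with second-pass gap closing.

    Parameters
    ----------
    max_disp : float, default 5.0
        Maximum frame-to-frame displacement in pixels; also the gap-closing
        distance gate.
    max_gap : int, default 10
        Maximum number of consecutive missing frames bridged by gap closing.
        0 disables gap closing.
    pixel_size : float, default 0.225
        μm per pixel; output trajectories are stored in μm.

    Attributes
    ----------
    trajectories_ : list of Trajectory
        Linked trajectories, each detection used exactly once.
    n_gaps_closed_ : int
        Number of end→start joins made by the second pass.
    """

    def __init__(self, max_disp: float = 5.0, max_gap: int = 10, pixel_size: float = 0.225):
        self.max_disp = max_disp
        self.max_gap = max_gap
        self.pixel_size = pixel_size

    def fit(self, detections: Sequence[Sequence[Detection]]):
        """Link per-frame detection lists into trajectories."""
        if self.max_disp <= 0:
            raise ValueError("max_disp must be > 0")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        segments = self._link_frames(detections)
        segments, self.n_gaps_closed_ = self._close_gaps(segments)
        self.trajectories_ = self._to_trajectories(segments)
        return self

    def fit_predict(self, detections: Sequence[Sequence[Detection]]) -> List[Trajectory]:
        return self.fit(detections).trajectories_

    # -- first pass ---------------------------------------------------------
    def _link_frames(self, detections) -> List[List[Detection]]:
        gate2 = float(self.max_disp) ** 2
        segments: List[List[Detection]] = []
        active: List[int] = []  # segment indices with a detection in frame f
        prev_frame = None
        for dets in detections:
            dets = list(dets)
            if not dets:
                active = []
                prev_frame = None
                continue
            f = dets[0].frame
            linked_to: Dict[int, int] = {}
            if active and prev_frame is not None and f == prev_frame + 1:
                last = np.array([[segments[s][-1].x, segments[s][-1].y] for s in active])
                cur = np.array([[d.x, d.y] for d in dets])
                cost = ((last[:, None, :] - cur[None, :, :]) ** 2).sum(axis=2)
                for r, c in _solve_gated_lap(cost, gate2):
                    linked_to[c] = active[r]
            new_active = []
            for j, d in enumerate(dets):
                if j in linked_to:
                    s = linked_to[j]
                    segments[s].append(d)
                else:
                    s = len(segments)
                    segments.append([d])
                new_active.append(s)
            active = new_active
            prev_frame = f
        return segments

    # -- second pass --------------------------------------------------------
    def _close_gaps(self, segments):
        if self.max_gap == 0 or len(segments) < 2:
            return segments, 0
        gate2 = float(self.max_disp) ** 2
        ends = [(i, seg[-1]) for i, seg in enumerate(segments)]
        starts = [(i, seg[0]) for i, seg in enumerate(segments)]
        cost = np.full((len(ends), len(starts)), _BIG)
        for r, (ei, e) in enumerate(ends):
            for c, (si, s) in enumerate(starts):
                if si == ei:
                    continue
                gap = s.frame - e.frame - 1
                if 1 <= gap <= self.max_gap:
                    cost[r, c] = (e.x - s.x) ** 2 + (e.y - s.y) ** 2
        joins = _solve_gated_lap(cost, gate2)
        succ = {ends[r][0]: starts[c][0] for r, c in joins}
        consumed = {starts[c][0] for _, c in joins}
        merged: List[List[Detection]] = []
        for i, seg in enumerate(segments):
            if i in consumed:
                continue
            chain = list(seg)
            j = i
            while j in succ:
                j = succ[j]
                chain.extend(segments[j])
            merged.append(chain)
        return merged, len(joins)

    def _to_trajectories(self, segments) -> List[Trajectory]:
        segments = sorted(segments, key=lambda s: (s[0].frame, s[0].y, s[0].x))
        out = []
        for tid, seg in enumerate(segments):
            frames = np.array([d.frame for d in seg])
            xy = np.array([[d.x, d.y] for d in seg]) * self.pixel_size
            inten = np.array([d.intensity for d in seg])
            out.append(Trajectory(track_id=tid, frames=frames, xy=xy, intensities=inten))
        return out


def link_cw(
    detections: Sequence[Sequence[Detection]],
    max_disp: float = 5.0,
    max_gap: int = 10,
    pixel_size: float = 0.225,
) -> List[Trajectory]:
    """Link per-frame detections into trajectories (see :class:`LAPLinker`)."""
    return LAPLinker(max_disp=max_disp, max_gap=max_gap, pixel_size=pixel_size).fit_predict(detections)


def filter_tracks(
    trajs: Sequence[Trajectory],
    min_duration: int = 50,
    require_blinking: bool = True,
) -> Tuple[List[Trajectory], Dict[str, int]]:
    """Retain analysable trajectories.

    Keeps trajectories spanning at least ``min_duration`` frames and, when
    ``require_blinking``, containing at least one internal gap (the signature
    of a single blinking emitter rather than an aggregate or stuck spot).

    Returns the retained list and per-filter rejection counts.
    """
    kept: List[Trajectory] = []
    rejected = {"too_short": 0, "no_blinking": 0}
    for t in trajs:
        if t.duration < min_duration:
            rejected["too_short"] += 1
        elif require_blinking and not t.has_gaps:
            rejected["no_blinking"] += 1
        else:
            kept.append(t)
    return kept, rejected
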