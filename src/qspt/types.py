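"""Core data containers shared across the tracking pipeline.

Conventions
-----------
* Trajectory positions are stored in micrometres (μm); detection positions in
  pixels (0-based, pixel-centre origin); localization maps in nanometres (nm).
* Frames are integer indices; a trajectory's ``frames`` array is strictly
  increasing and gaps are represented by missing frame indices, never by NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Detection",
    "Trajectory",
    "MSDCurve",
    "DiffusionEstimate",
    "MergeSplitRecord",
    "LocalizationMap",
    "Tessellation",
    "Cluster",
]


@dataclass
class Detection:
    """A single sub-pixel spot detection in one frame.

    Positions are in pixels; ``intensity`` is the summed brightness over the
    refinement window and ``size`` a radius-of-gyration proxy in pixels.
    """

    frame: int
    x: float
    y: float
    intensity: float = 0.0
    size: float = 0.0


@dataclass
class Trajectory:
    """One particle's time-ordered 2D path with explicit blink gaps.

    Parameters
    ----------
    track_id : int
        Identifier, unique within one linking run.
    frames : ndarray of int, shape (n,)
        Strictly increasing frame indices of the observed positions.
    xy : ndarray of float, shape (n, 2)
        Positions in μm, aligned with ``frames``.
    intensities : ndarray of float, shape (n,), optional
        Spot brightness per observation.
    """

    track_id: int
    frames: np.ndarray
    xy: np.ndarray
    intensities: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=np.float64)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must have shape (n, 2)")
        if self.frames.shape[0] != self.xy.shape[0]:
            raise ValueError("frames and xy must have equal length")
        if self.frames.size > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if self.intensities is not None:
            self.intensities = np.asarray(self.intensities, dtype=np.float64)
            if self.intensities.shape[0] != self.frames.shape[0]:
                raise ValueError("intensities must align with frames")

    @property
    def n_points(self) -> int:
        return int(self.frames.size)

    @property
    def duration(self) -> int:
        """Span in frames, last − first + 1 (counts gap frames)."""
        if self.frames.size == 0:
            return 0
        return int(self.frames[-1] - self.frames[0] + 1)

    @property
    def n_gaps(self) -> int:
        """Number of internal missing frames."""
        return self.duration - self.n_points

    @property
    def has_gaps(self) -> bool:
        return self.n_gaps > 0


@dataclass
class MSDCurve:
    """Mean-square displacement versus lag time for one trajectory.

    ``lags`` are in seconds (multiples of the frame interval), ``msd`` in μm²,
    ``n_pairs`` the number of displacement pairs averaged at each lag.
    ``gap_mode`` records whether blink gaps were reindexed away or respected.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    gap_mode: str
    dt: float

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=np.float64)
        self.msd = np.asarray(self.msd, dtype=np.float64)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)


@dataclass
class DiffusionEstimate:
    """Output of one diffusion estimator on one trajectory.

    ``D`` is in μm²/s.  For the MSD-line method ``intercept`` holds the
    ordinate at the origin (4σₓ² for a Brownian walker with static noise σₓ);
    for the likelihood method ``sigma_est`` holds the fitted static noise in μm
    and ``R`` the motion-blur coefficient used.  ``valid`` is False when the
    fit was impossible or unreliable (too few points, non-convergence).
    """

    D: float
    method: str
    track_id: int = -1
    intercept: float = np.nan
    sigma_est: float = np.nan
    R: float = np.nan
    n_points_used: int = 0
    valid: bool = True
    on_boundary: bool = False


@dataclass
class MergeSplitRecord:
    """One detected merge or split event.

    ``kind`` is ``"merge"`` or ``"split"``; ``frame`` is the frame at which
    the trunk carries the fused spot adjacent to the branch's end/start;
    ``displacement`` is the bridged distance in μm.
    """

    kind: str
    frame: int
    trunk_track: int
    branch_tracks: tuple
    displacement: float


@dataclass
class LocalizationMap:
    """A set of super-resolved (x, y) localizations in nm.

    ``frame`` is optional per-point acquisition frame; ``fov_bounds`` is
    (xmin, ymin, xmax, ymax) in nm; ``source`` tags the acquisition modality.
    """

    points: np.ndarray
    fov_bounds: tuple
    frame: Optional[np.ndarray] = None
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must have shape (n, 2)")
        if self.frame is not None:
            self.frame = np.asarray(self.frame, dtype=np.int64)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


@dataclass
class Tessellation:
    """Voronoï tessellation of a localization map, clipped to the FOV.

    One cell per (deduplicated) localization.  ``areas`` are clipped cell
    areas in nm²; ``neighbors`` maps cell id -> set of adjacent cell ids
    (cells sharing a Voronoï edge); ``boundary`` flags cells whose unclipped
    region was unbounded; ``multiplicity`` counts duplicate localizations
    collapsed into each cell.
    """

    points: np.ndarray
    areas: np.ndarray
    neighbors: list
    boundary: np.ndarray
    multiplicity: np.ndarray
    fov_bounds: tuple
    polygons: list = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return int(self.points.shape[0])


@dataclass
class Cluster:
    """A nanocluster: a connected component of dense Voronoï cells.

    ``radius = sqrt(area / π)`` in nm; ``density`` is localizations per
    100 nm².
    """

    member_cells: np.ndarray
    n_locs: int
    area: float
    radius: float
    density: float
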