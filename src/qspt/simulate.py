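"""Synthetic data generators with known ground truth.

The generators embody the statistical structure the downstream analysis
assumes: free 2D Brownian diffusion sampled at the camera frame rate, static
Gaussian localization noise, optional within-frame exposure averaging (motion
blur), two-state Markov blinking of quantum-dot emitters, engineered
merge-and-split encounters, rendered image stacks, and clustered localization
maps over a uniform background.

Every generator draws all of its randomness from a single integer seed via
independent per-particle child streams, so identical seeds produce
bit-identical outputs and individual particles are reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.special import erf

from .types import Detection, LocalizationMap, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "ClusterSimConfig",
    "simulate_brownian",
    "apply_noise_and_blinking",
    "simulate_encounter_pair",
    "encounter_pair_detections",
    "render_movie",
    "simulate_clustered_localizations",
    "implied_blur_coefficient",
]

#: number of within-frame sub-steps used for exposure (motion-blur) averaging
N_BLUR_SUBSTEPS = 32


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated quantum-dot tracking experiment.

    Attributes
    ----------
    D_true : float
        Ground-truth diffusion coefficient, μm²/s.
    dt : float
        Frame interval in seconds (default 0.032 s, ~30 Hz).
    n_frames : int
        Number of camera frames.
    sigma_loc : float
        Static localization noise per axis, μm.
    exposure_fraction : float
        Fraction of ``dt`` the shutter is open. 0 means instantaneous
        sampling (blur coefficient R = 0); 1 means full-frame uniform
        exposure (R = 1/6).
    p_off, p_on : float
        Per-frame blink transition probabilities (on→off and off→on).
    fov : float
        Field-of-view side length, μm.
    pixel_size : float
        μm per pixel.
    seed : int
        RNG seed; all randomness derives from it.
    """

    D_true: float = 0.1
    dt: float = 0.032
    n_frames: int = 200
    sigma_loc: float = 0.02
    exposure_fraction: float = 0.0
    p_off: float = 0.1
    p_on: float = 0.5
    fov: float = 20.0
    pixel_size: float = 0.225
    seed: int = 0

    def validate(self) -> None:
        if not self.D_true >= 0:
            raise ValueError("SimConfig.D_true must be >= 0")
        if not self.dt > 0:
            raise ValueError("SimConfig.dt must be > 0")
        if not self.n_frames >= 2:
            raise ValueError("SimConfig.n_frames must be >= 2")
        if not self.sigma_loc >= 0:
            raise ValueError("SimConfig.sigma_loc must be >= 0")
        if not 0.0 <= self.exposure_fraction <= 1.0:
            raise ValueError("SimConfig.exposure_fraction must be in [0, 1]")
        for name in ("p_off", "p_on"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"SimConfig.{name} must be in [0, 1]")
        if not self.fov > 0:
            raise ValueError("SimConfig.fov must be > 0")
        if not self.pixel_size > 0:
            raise ValueError("SimConfig.pixel_size must be > 0")


@dataclass(frozen=True)
class ClusterSimConfig:
    """Parameters of a synthetic clustered localization map.

    ``background_density`` is in localizations/μm²; spatial quantities in nm.
    Cluster centres are placed at least ``2 * cluster_radius`` from the FOV
    edge and at least ``4 * cluster_radius`` apart (centre to centre).

    Defaults emulate a nanocluster validation map at 10× intra-cluster to
    background density contrast, with the FOV sized so background and
    clustered localization counts are roughly balanced — the operating
    regime of a relative (percentile-threshold) cluster search.
    """

    n_clusters: int = 10
    cluster_radius: float = 60.0
    locs_per_cluster: int = 100
    background_density: float = 884.0
    fov: float = 1100.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 0:
            raise ValueError("ClusterSimConfig.n_clusters must be >= 0")
        if self.cluster_radius <= 0:
            raise ValueError("ClusterSimConfig.cluster_radius must be > 0")
        if self.locs_per_cluster < 0:
            raise ValueError("ClusterSimConfig.locs_per_cluster must be >= 0")
        if self.background_density < 0:
            raise ValueError("ClusterSimConfig.background_density must be >= 0")
        if self.n_clusters > 0 and self.fov < 4 * self.cluster_radius:
            raise ValueError("FOV too small to hold a cluster away from edges")


def implied_blur_coefficient(exposure_fraction: float) -> float:
    """Motion-blur coefficient R implied by a uniform shutter.

    For a shutter uniformly open during a fraction *f* of the frame the
    time-averaged position carries blur coefficient R = f/6: R = 0 for
    instantaneous sampling and 1/6 for full-frame exposure.
    """
    return exposure_fraction / 6.0


def _particle_rng(seed: int, particle_index: int = 0) -> np.random.Generator:
    """Independent child stream for one particle of one simulation."""
    ss = np.random.SeedSequence(seed, spawn_key=(particle_index,))
    return np.random.Generator(np.random.PCG64(ss))


def _brownian_path(
    config: SimConfig, rng: np.random.Generator, start: np.ndarray
) -> np.ndarray:
    """Reported (possibly blur-averaged) positions, shape (n_frames, 2)."""
    n = config.n_frames
    if config.exposure_fraction > 0.0 and config.D_true > 0.0:
        # subdivide the open-shutter window into sub-steps, average them,
        # then jump across the closed remainder of the frame in one step
        m = N_BLUR_SUBSTEPS
        t_open = config.exposure_fraction * config.dt
        t_closed = config.dt - t_open
        sub_sd = np.sqrt(2.0 * config.D_true * (t_open / m))
        closed_sd = np.sqrt(2.0 * config.D_true * t_closed)
        pos = np.asarray(start, dtype=np.float64).copy()
        out = np.empty((n, 2))
        for i in range(n):
            subs = rng.normal(0.0, sub_sd, size=(m, 2)).cumsum(axis=0) + pos
            out[i] = subs.mean(axis=0)
            pos = subs[-1]
            if t_closed > 0:
                pos = pos + rng.normal(0.0, closed_sd, size=2)
        return out
    step_sd = np.sqrt(2.0 * config.D_true * config.dt)
    steps = rng.normal(0.0, step_sd, size=(n - 1, 2))
    return np.vstack([start, start + steps.cumsum(axis=0)])


def simulate_brownian(config: SimConfig, particle_index: int = 0) -> Trajectory:
    """Simulate one gap-free Brownian trajectory.

    Per-axis increments over one frame are independent zero-mean Gaussians
    with variance ``2 * D_true * dt``.  With ``exposure_fraction > 0`` the
    reported position of each frame is the average of 32 within-frame
    sub-steps over the open-shutter window, reproducing camera motion blur.

    Returns a :class:`Trajectory` with consecutive frames starting at 0 and
    constant unit intensity.
    """
    config.validate()
    rng = _particle_rng(config.seed, particle_index)
    start = rng.uniform(0.25 * config.fov, 0.75 * config.fov, size=2)
    xy = _brownian_path(config, rng, start)
    frames = np.arange(config.n_frames)
    return Trajectory(
        track_id=particle_index,
        frames=frames,
        xy=xy,
        intensities=np.ones(config.n_frames),
    )


def apply_noise_and_blinking(
    traj: Trajectory, config: SimConfig, particle_index: int = 0
) -> Tuple[Trajectory, np.ndarray]:
    """Overlay static localization noise and two-state Markov blinking.

    Adds i.i.d. Gaussian noise (std ``sigma_loc`` per axis) to every observed
    position and deletes positions during the off state of a two-state Markov
    chain with per-frame transition probabilities ``p_off`` (on→off) and
    ``p_on`` (off→on).  The first frame always starts in the on state.

    Returns
    -------
    observed : Trajectory
        Noisy trajectory containing only on-state frames (gaps implicit).
    on_mask : ndarray of bool
        Ground-truth on-state mask aligned with ``traj.frames`` — on-state
        observed positions equal the input positions plus noise only.
    """
    if traj.has_gaps:
        raise ValueError("apply_noise_and_blinking expects a gap-free input")
    config.validate()
    # separate child stream: noise/blink draws never perturb the path stream
    rng = _particle_rng(config.seed ^ 0x5EED5EED, particle_index)
    n = traj.n_points
    on = np.empty(n, dtype=bool)
    on[0] = True
    u = rng.uniform(size=n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        on[i] = (u[i - 1] >= config.p_off) if on[i - 1] else (u[i - 1] < config.p_on)
    noise = rng.normal(0.0, config.sigma_loc, size=(n, 2)) if config.sigma_loc > 0 else np.zeros((n, 2))
    observed = Trajectory(
        track_id=traj.track_id,
        frames=traj.frames[on],
        xy=traj.xy[on] + noise[on],
        intensities=None if traj.intensities is None else traj.intensities[on],
    )
    return observed, on


def simulate_encounter_pair(
    config: SimConfig,
    t_merge: int,
    t_split: int,
    spot_intensity: float = 100.0,
    offset_scale: float = 0.5,
    particle_index: int = 0,
) -> Tuple[Trajectory, Trajectory]:
    """Engineer two trajectories that transiently co-diffuse.

    Particles A and B diffuse independently, share identical positions on
    frames ``[t_merge, t_split)`` and then separate again.  B's approach and
    departure are Brownian bridges ending/starting within ``offset_scale``
    linking radii of A, so a linker at the usual displacement gate sees a
    clean merge at ``t_merge`` and a split at ``t_split``.  During the merged
    interval each trajectory carries intensity ``2 * spot_intensity`` (the
    fused diffraction-limited spot sums both emitters); outside it each
    carries ``spot_intensity``.
    """
    config.validate()
    if not (0 < t_merge < t_split < config.n_frames):
        raise ValueError("require 0 < t_merge < t_split < n_frames")
    rng = _particle_rng(config.seed ^ 0x0E0C0A0, particle_index)
    start = rng.uniform(0.25 * config.fov, 0.75 * config.fov, size=2)
    a_xy = _brownian_path(config, rng, start)

    step_sd = np.sqrt(2.0 * config.D_true * config.dt)
    # typical one-frame excursion used as the approach/departure offset
    off_sd = max(offset_scale * step_sd, 1e-3)
    b_xy = np.empty_like(a_xy)
    b_xy[t_merge:t_split] = a_xy[t_merge:t_split]
    # approach: diffuse backwards in time from just next to A at t_merge
    pos = a_xy[t_merge] + rng.normal(0.0, off_sd, size=2)
    for t in range(t_merge - 1, -1, -1):
        b_xy[t] = pos
        pos = pos + rng.normal(0.0, step_sd, size=2)
    # departure: diffuse forwards from just next to A at t_split - 1
    pos = a_xy[t_split - 1] + rng.normal(0.0, off_sd, size=2)
    for t in range(t_split, config.n_frames):
        b_xy[t] = pos
        pos = pos + rng.normal(0.0, step_sd, size=2)

    frames = np.arange(config.n_frames)
    merged = (frames >= t_merge) & (frames < t_split)
    inten = np.where(merged, 2.0 * spot_intensity, spot_intensity)
    a = Trajectory(track_id=0, frames=frames, xy=a_xy, intensities=inten.copy())
    b = Trajectory(track_id=1, frames=frames, xy=b_xy, intensities=inten.copy())
    return a, b


def encounter_pair_detections(
    a: Trajectory, b: Trajectory, t_merge: int, t_split: int, pixel_size: float = 1.0
) -> List[List[Detection]]:
    """Per-frame detection lists for an encounter pair.

    During the merged interval the pair appears as a single fused detection
    at the shared position with the summed intensity; outside it, as two
    separate detections.  Positions are converted to pixels by ``pixel_size``
    (μm/px) so the lists feed the linker directly.
    """
    out: List[List[Detection]] = []
    for i, f in enumerate(a.frames):
        dets: List[Detection] = []
        if t_merge <= f < t_split:
            dets.append(
                Detection(frame=int(f), x=a.xy[i, 0] / pixel_size, y=a.xy[i, 1] / pixel_size,
                          intensity=float(a.intensities[i]))
            )
        else:
            for tr in (a, b):
                dets.append(
                    Detection(frame=int(f), x=tr.xy[i, 0] / pixel_size, y=tr.xy[i, 1] / pixel_size,
                              intensity=float(tr.intensities[i]) )
                )
        out.append(dets)
    return out


def render_movie(
    trajs: List[Trajectory],
    shape: Tuple[int, int],
    pixel_size: float,
    psf_sigma: float = 1.2,
    photons: float = 500.0,
    background: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Render trajectories into a noisy image stack.

    Each observed position is drawn as an integrated 2D Gaussian PSF of width
    ``psf_sigma`` pixels carrying ``photons`` total counts (scaled by the
    trajectory's per-frame intensity if present, relative to 1.0), on a
    constant ``background``; Poisson shot noise is applied to signal plus
    background.  Positions are in μm and converted with ``pixel_size``.
    Particles outside the field of view are skipped with a logged warning.

    Returns a float array of shape (n_frames, H, W); frame count is the
    largest frame index across trajectories plus one.
    """
    H, W = shape
    n_frames = 1 + max((int(t.frames[-1]) for t in trajs), default=0)
    stack = np.full((n_frames, H, W), float(background))
    yy = np.arange(H)
    xx = np.arange(W)
    s2 = psf_sigma * np.sqrt(2.0)
    for traj in trajs:
        inten = traj.intensities if traj.intensities is not None else np.ones(traj.n_points)
        for i, f in enumerate(traj.frames):
            cx = traj.xy[i, 0] / pixel_size
            cy = traj.xy[i, 1] / pixel_size
            if not (0 <= cx < W and 0 <= cy < H):
                logger.warning(
                    "particle %d at frame %d outside FOV (%.1f, %.1f px); skipped",
                    traj.track_id, int(f), cx, cy,
                )
                continue
            gx = 0.5 * (erf((xx + 0.5 - cx) / s2) - erf((xx - 0.5 - cx) / s2))
            gy = 0.5 * (erf((yy + 0.5 - cy) / s2) - erf((yy - 0.5 - cy) / s2))
            stack[int(f)] += photons * float(inten[i]) * np.outer(gy, gx)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(0xF11A,))))
    return rng.poisson(stack).astype(np.float64)


def simulate_clustered_localizations(config: ClusterSimConfig) -> Tuple[LocalizationMap, np.ndarray]:
    """Simulate a clustered localization map over a Poisson background.

    Cluster members are drawn uniformly in a disk of ``cluster_radius`` nm
    around each centre; the background is a homogeneous Poisson process over
    the FOV at ``background_density`` localizations/μm².

    Returns
    -------
    loc_map : LocalizationMap
    labels : ndarray of int
        Ground-truth cluster id per localization (−1 for background).
    """
    config.validate()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed, spawn_key=(0xC1,))))
    L = config.fov
    r = config.cluster_radius

    centers = []
    margin = 2.0 * r
    guard = 0
    while len(centers) < config.n_clusters:
        c = rng.uniform(margin, L - margin, size=2)
        if all(np.hypot(*(c - np.asarray(o))) >= 2.0 * margin for o in centers):
            centers.append(c)
        guard += 1
        if guard > 10000 * max(config.n_clusters, 1):
            raise ValueError("could not place cluster centres; FOV too crowded")

    pts = []
    labels = []
    for k, c in enumerate(centers):
        u = rng.uniform(size=config.locs_per_cluster)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=config.locs_per_cluster)
        rad = r * np.sqrt(u)
        pts.append(c + np.column_stack([rad * np.cos(theta), rad * np.sin(theta)]))
        labels.append(np.full(config.locs_per_cluster, k))

    # background: homogeneous Poisson; density is per μm², FOV is in nm
    lam = config.background_density * (L / 1000.0) ** 2
    n_bg = rng.poisson(lam)
    if n_bg > 0:
        pts.append(rng.uniform(0.0, L, size=(n_bg, 2)))
        labels.append(np.full(n_bg, -1))

    if pts:
        points = np.vstack(pts)
        lab = np.concatenate(labels)
    else:
        points = np.empty((0, 2))
        lab = np.empty(0, dtype=int)
    loc_map = LocalizationMap(points=points, fov_bounds=(0.0, 0.0, L, L), source="synthetic")
    return loc_map, lab.astype(np.int64)
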