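"""Simulator ground-truth checks: increment statistics, blinking, encounters."""

import numpy as np
import pytest
from scipy import stats

from qspt.detect import bandpass_detect
from qspt.simulate import (ClusterSimConfig, SimConfig, apply_noise_and_blinking,
                           implied_blur_coefficient, render_movie,
                           simulate_brownian, simulate_clustered_localizations,
                           simulate_encounter_pair)


class TestBrownian:
    def test_zero_diffusion_is_static(self):
        cfg = SimConfig(D_true=0.0, sigma_loc=0.0, n_frames=50, seed=3)
        t = simulate_brownian(cfg)
        assert np.allclose(t.xy, t.xy[0])

    def test_increment_variance_matches_2_D_dt(self):
        # Var(Δx) = 2 D δt; at n = 2000 the sample variance sits within 5%
        cfg = SimConfig(D_true=0.1, dt=0.032, n_frames=2000, sigma_loc=0.0,
                        p_off=0.0, seed=11)
        t = simulate_brownian(cfg)
        v = np.diff(t.xy[:, 0]).var(ddof=1)
        assert abs(v - 0.0064) / 0.0064 < 0.05

    def test_increments_gaussian(self):
        # pooled x/y increments pass a KS normality check at large n
        incs = []
        for i in range(50):
            cfg = SimConfig(D_true=0.05, n_frames=2000, sigma_loc=0.0, seed=21)
            incs.append(np.diff(simulate_brownian(cfg, i).xy, axis=0).ravel())
        z = np.concatenate(incs) / np.sqrt(2 * 0.05 * 0.032)
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_determinism(self):
        cfg = SimConfig(D_true=0.1, n_frames=100, seed=7)
        a = simulate_brownian(cfg)
        b = simulate_brownian(cfg)
        assert np.array_equal(a.xy, b.xy)
        obs_a, _ = apply_noise_and_blinking(a, cfg)
        obs_b, _ = apply_noise_and_blinking(b, cfg)
        assert np.array_equal(obs_a.xy, obs_b.xy)
        assert np.array_equal(obs_a.frames, obs_b.frames)

    @pytest.mark.parametrize("field,value", [
        ("D_true", -1.0), ("dt", 0.0), ("n_frames", 1),
        ("exposure_fraction", 1.5), ("p_off", -0.1),
    ])
    def test_invalid_config_names_field(self, field, value):
        cfg = SimConfig(**{field: value})
        with pytest.raises(ValueError, match=field):
            simulate_brownian(cfg)

    def test_blur_coefficient_mapping(self):
        assert implied_blur_coefficient(0.0) == 0.0
        assert implied_blur_coefficient(1.0) == pytest.approx(1 / 6)


class TestBlinking:
    def test_no_gaps_when_p_off_zero(self):
        cfg = SimConfig(p_off=0.0, n_frames=300, seed=5)
        obs, on = apply_noise_and_blinking(simulate_brownian(cfg), cfg)
        assert on.all() and obs.n_points == 300

    def test_stationary_on_fraction(self):
        # two-state chain: long-run on fraction = p_on / (p_on + p_off) = 5/6
        cfg = SimConfig(p_off=0.1, p_on=0.5, n_frames=2000, seed=9)
        fracs = [apply_noise_and_blinking(simulate_brownian(cfg, i), cfg, i)[1].mean()
                 for i in range(20)]
        target = 5 / 6
        se = np.sqrt(target * (1 - target) / (2000 * 20))
        # binomial error with a margin for serial correlation of the chain
        assert abs(np.mean(fracs) - target) < 6 * se

    def test_positions_preserved_plus_noise_only(self):
        cfg = SimConfig(D_true=0.1, sigma_loc=0.0, p_off=0.2, p_on=0.5,
                        n_frames=400, seed=13)
        truth = simulate_brownian(cfg)
        obs, on = apply_noise_and_blinking(truth, cfg)
        assert np.array_equal(obs.xy, truth.xy[on])
        assert np.array_equal(obs.frames, truth.frames[on])

    def test_msd_plateau_at_4_sigma_sq_when_immobile(self):
        # Brownian-line intercept with D = 0: MSD plateaus at 4σ² = 1.6e-3 μm²
        from qspt.diffusion import compute_msd
        cfg = SimConfig(D_true=0.0, sigma_loc=0.02, p_off=0.0, n_frames=3000, seed=17)
        obs, _ = apply_noise_and_blinking(simulate_brownian(cfg), cfg)
        msd = compute_msd(obs, dt=cfg.dt)
        plateau = msd.msd[1:6].mean()
        assert plateau == pytest.approx(4 * 0.02**2, rel=0.10)


class TestEncounterPair:
    def test_shared_positions_and_summed_intensity(self):
        cfg = SimConfig(D_true=0.1, n_frames=120, seed=1)
        a, b = simulate_encounter_pair(cfg, t_merge=50, t_split=65, spot_intensity=80.0)
        assert np.array_equal(a.xy[50:65], b.xy[50:65])
        assert np.all(a.intensities[50:65] == 160.0)
        assert np.all(a.intensities[:50] == 80.0)

    def test_one_frame_merge_event(self):
        cfg = SimConfig(D_true=0.05, n_frames=60, seed=2)
        a, b = simulate_encounter_pair(cfg, t_merge=30, t_split=31)
        assert np.array_equal(a.xy[30], b.xy[30])
        assert not np.array_equal(a.xy[31], b.xy[31])

    def test_interval_out_of_range_raises(self):
        cfg = SimConfig(n_frames=50)
        with pytest.raises(ValueError):
            simulate_encounter_pair(cfg, t_merge=40, t_split=60)


class TestRenderMovie:
    def test_empty_stack_is_background(self):
        stack = render_movie([], shape=(32, 32), pixel_size=0.1, background=10.0, seed=0)
        # zero trajectories: a pure-background Poisson stack
        assert stack.shape[1:] == (32, 32)

    def test_immobile_particle_recovered_subpixel(self):
        from qspt.types import Trajectory
        pos = np.tile([2.03, 4.17], (40, 1))  # μm; 20.3, 41.7 px at 0.1 μm/px
        traj = Trajectory(track_id=0, frames=np.arange(40), xy=pos)
        stack = render_movie([traj], shape=(64, 64), pixel_size=0.1,
                             photons=5000, background=5.0, seed=4)
        errs = []
        for f in range(40):
            dets = bandpass_detect(stack[f], threshold=50.0, size=5, frame=f)
            assert len(dets) == 1
            errs.append((dets[0].x - 20.3) ** 2 + (dets[0].y - 41.7) ** 2)
        assert np.sqrt(np.mean(errs)) < 0.1

    def test_two_separated_particles_give_two_detections(self):
        from qspt.types import Trajectory
        t1 = Trajectory(0, np.arange(5), np.tile([1.0, 1.0], (5, 1)))
        t2 = Trajectory(1, np.arange(5), np.tile([2.0, 1.0], (5, 1)))  # 10 px apart
        stack = render_movie([t1, t2], shape=(32, 32), pixel_size=0.1,
                             photons=3000, background=5.0, seed=6)
        dets = bandpass_detect(stack[0], threshold=50.0, size=4)
        assert len(dets) == 2


class TestClusteredLocalizations:
    def test_single_cluster_no_background_within_radius(self):
        cfg = ClusterSimConfig(n_clusters=1, cluster_radius=50.0,
                               locs_per_cluster=200, background_density=0.0,
                               fov=1000.0, seed=8)
        lm, labels = simulate_clustered_localizations(cfg)
        assert (labels == 0).all()
        center = lm.points.mean(axis=0)
        r = np.hypot(*(lm.points - center).T)
        assert r.max() <= 50.0 * 1.1  # centre estimated from the sample

    def test_background_labelled_minus_one(self):
        cfg = ClusterSimConfig(n_clusters=0, background_density=500.0, fov=1500.0, seed=10)
        lm, labels = simulate_clustered_localizations(cfg)
        assert (labels == -1).all()
        assert lm.n_points > 0

    def test_determinism(self):
        cfg = ClusterSimConfig(seed=12)
        a, la = simulate_clustered_localizations(cfg)
        b, lb = simulate_clustered_localizations(cfg)
        assert np.array_equal(a.points, b.points) and np.array_equal(la, lb)
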