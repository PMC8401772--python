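"""Diffusion estimators: MSD oracle equivalence, recovery, classification."""

import numpy as np
import pytest

from qspt.diffusion import (IMMOBILE_THRESHOLD, MLEDiffusionEstimator,
                            MSDDiffusionEstimator, classify_mobility,
                            compare_distributions, compute_msd, fit_d25,
                            fit_mle)
from qspt.simulate import SimConfig, apply_noise_and_blinking, simulate_brownian
from qspt.types import DiffusionEstimate, MSDCurve, Trajectory

from conftest import make_ensemble


def naive_msd(traj, gap_mode, dt):
    """Independent double-loop MSD oracle (both gap modes)."""
    frames = np.arange(traj.n_points) if gap_mode == "reindexed" else traj.frames - traj.frames[0]
    lookup = {int(f): traj.xy[i] for i, f in enumerate(frames)}
    span = int(frames[-1]) + 1
    lags, msd, n_pairs = [], [], []
    for n in range(1, span):
        acc, k = 0.0, 0
        for j in range(span - n):
            if j in lookup and j + n in lookup:
                d = lookup[j + n] - lookup[j]
                acc += d[0] ** 2 + d[1] ** 2
                k += 1
        if k:
            lags.append(n * dt)
            msd.append(acc / k)
            n_pairs.append(k)
    return np.array(lags), np.array(msd), np.array(n_pairs)


class TestComputeMSD:
    @pytest.mark.parametrize("gap_mode", ["gap_aware", "reindexed"])
    def test_matches_double_loop_oracle(self, gap_mode, blinking_ensemble):
        for traj in blinking_ensemble[:10]:
            got = compute_msd(traj, gap_mode=gap_mode, dt=0.032)
            lags, msd, n_pairs = naive_msd(traj, gap_mode, 0.032)
            assert np.array_equal(got.n_pairs, n_pairs)
            np.testing.assert_allclose(got.msd, msd, rtol=1e-12)
            np.testing.assert_allclose(got.lags, lags, rtol=1e-12)

    def test_constant_trajectory_zero_msd(self):
        t = Trajectory(0, np.arange(20), np.ones((20, 2)))
        assert np.all(compute_msd(t).msd == 0.0)

    def test_ballistic_msd_analytic(self):
        # x = v t with v = 1 μm/s, δt = 0.1 s: MSD(nδt) = (0.1 n)²
        frames = np.arange(30)
        xy = np.column_stack([0.1 * frames, np.zeros(30)])
        msd = compute_msd(Trajectory(0, frames, xy), dt=0.1)
        np.testing.assert_allclose(msd.msd, (msd.lags) ** 2, rtol=1e-12)

    def test_single_point_raises(self):
        with pytest.raises(ValueError):
            compute_msd(Trajectory(0, np.array([0]), np.zeros((1, 2))))

    def test_reindexing_inflates_lag1_msd(self, blinking_ensemble):
        # gap-crossing displacements become apparent single-frame steps
        diffs = []
        for traj in blinking_ensemble:
            if not traj.has_gaps:
                continue
            r = compute_msd(traj, "reindexed").msd[0]
            g = compute_msd(traj, "gap_aware").msd[0]
            diffs.append(r - g)
        assert np.mean(diffs) > 0


class TestFitD25:
    def test_exact_line_recovery(self):
        # MSD(t) = 4·0.05·t + 4·(0.02)² recovers D = 0.05, intercept = 1.6e-3
        dt = 0.032
        lags = np.arange(1, 8) * dt
        curve = MSDCurve(lags=lags, msd=4 * 0.05 * lags + 4 * 0.02**2,
                         n_pairs=np.full(7, 10), gap_mode="gap_aware", dt=dt)
        est = fit_d25(curve)
        assert est.D == pytest.approx(0.05, rel=1e-12)
        assert est.intercept == pytest.approx(1.6e-3, rel=1e-9)
        assert est.n_points_used == 4

    def test_too_few_lags_invalid(self):
        curve = MSDCurve(lags=np.array([0.032]), msd=np.array([0.01]),
                         n_pairs=np.array([5]), gap_mode="gap_aware", dt=0.032)
        est = fit_d25(curve)
        assert not est.valid


class TestFitMLE:
    def test_noiseless_recovery(self):
        # long noiseless tracks: ensemble-median D̂ within 5% of truth
        ds = []
        for i in range(40):
            cfg = SimConfig(D_true=0.1, n_frames=2000, sigma_loc=0.0, p_off=0.0, seed=31)
            ds.append(fit_mle(simulate_brownian(cfg, i), R=0.0).D)
        assert abs(np.median(ds) - 0.1) / 0.1 < 0.05

    def test_gap_free_rmse_beats_msd_line(self):
        # likelihood uses all displacements: lower RMSE than the 4-point line fit
        trajs = make_ensemble(150, D_true=0.1, n_frames=200, sigma_loc=0.02,
                              p_off=0.0, base_seed=77)
        d_mle = MLEDiffusionEstimator(R=0.0).fit_predict(trajs)
        d_msd = MSDDiffusionEstimator().fit_predict(trajs)
        rmse = lambda d: np.sqrt(np.mean((np.asarray(d) - 0.1) ** 2))
        assert rmse(d_mle) <= rmse(d_msd)

    def test_invalid_R_raises(self):
        t = Trajectory(0, np.arange(20), np.zeros((20, 2)))
        with pytest.raises(ValueError):
            fit_mle(t, R=0.5)

    def test_short_track_flagged_invalid(self):
        t = Trajectory(0, np.arange(5), np.zeros((5, 2)))
        assert not fit_mle(t).valid

    def test_gap_policies_agree_on_gap_free_tracks(self):
        cfg = SimConfig(D_true=0.05, n_frames=300, sigma_loc=0.02, p_off=0.0, seed=55)
        obs, _ = apply_noise_and_blinking(simulate_brownian(cfg), cfg)
        a = fit_mle(obs, gap_policy="reindexed")
        b = fit_mle(obs, gap_policy="contiguous")
        assert a.D == pytest.approx(b.D, abs=1e-9)


class TestMobilityClassification:
    @pytest.mark.parametrize("d,expected", [
        (5e-4, "immobile"),     # threshold is strict: "greater than"
        (0.084, "mobile"),
        (-1e-5, "immobile"),    # noise-dominated negative fit
    ])
    def test_threshold_rule(self, d, expected):
        est = DiffusionEstimate(D=d, method="d25")
        assert classify_mobility(est) == expected

    def test_invalid_estimate_raises(self):
        with pytest.raises(ValueError):
            classify_mobility(DiffusionEstimate(D=np.nan, method="d25", valid=False))


class TestCompareDistributions:
    def test_identical_samples_ks_zero(self):
        a = np.linspace(0.01, 0.2, 50)
        rep = compare_distributions(a, a)
        assert rep["ks_stat"] == 0.0

    def test_separated_ensembles_detected(self):
        # medians 0.084 vs 0.097 at a few hundred tracks: both tests significant
        a = make_ensemble(150, D_true=0.084, n_frames=200, sigma_loc=0.02,
                          p_off=0.0, base_seed=5)
        b = make_ensemble(150, D_true=0.097, n_frames=200, sigma_loc=0.02,
                          p_off=0.0, base_seed=6)
        da = MSDDiffusionEstimator().fit_predict(a)
        db = MSDDiffusionEstimator().fit_predict(b)
        rep = compare_distributions(da, db)
        assert rep["mannwhitney_p"] < 0.05
        assert rep["median_a"] < rep["median_b"]

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            compare_distributions([], [0.1, 0.2])
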