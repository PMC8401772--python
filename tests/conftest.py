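"""Shared fixtures: small simulated ensembles with known ground truth."""

import numpy as np
import pytest

from qspt.simulate import SimConfig, apply_noise_and_blinking, simulate_brownian


def make_ensemble(n_tracks, base_seed=0, **cfg_kwargs):
    """Simulate n blinking/noisy observed trajectories (one stream each)."""
    out = []
    for i in range(n_tracks):
        cfg = SimConfig(seed=base_seed, **cfg_kwargs)
        traj = simulate_brownian(cfg, particle_index=i)
        obs, _ = apply_noise_and_blinking(traj, cfg, particle_index=i)
        obs.track_id = i
        out.append(obs)
    return out


@pytest.fixture(scope="session")
def blinking_ensemble():
    """100 blinking noisy tracks at the default acquisition conditions."""
    return make_ensemble(100, D_true=0.1, n_frames=200, sigma_loc=0.02,
                         p_off=0.1, p_on=0.5, base_seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
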