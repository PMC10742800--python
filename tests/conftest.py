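import numpy as np
import pytest

from pairturn import (
    ArenaConfig,
    SimConfig,
    build_pair_state_series,
    simulate_pair,
    smooth_trajectory,
)


@pytest.fixture(scope="session")
def arena():
    return ArenaConfig()


@pytest.fixture(scope="session")
def clean_sim():
    """One noise-free recording with two dominated and two non-dominated turns."""
    cfg = SimConfig(noise_sigma_m=0.0, spike_prob=0.0, seed=1)
    ta, tb, gt = simulate_pair(cfg)
    return cfg, ta, tb, gt


@pytest.fixture(scope="session")
def clean_series(clean_sim):
    cfg, ta, tb, gt = clean_sim
    series = build_pair_state_series(
        smooth_trajectory(ta), smooth_trajectory(tb), cfg.arena)
    return cfg, series, gt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
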