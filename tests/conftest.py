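import numpy as np
import pytest

from ubidia.config import RunConfig
from ubidia.pipeline import build_benchmark_space, simulate_experiment


@pytest.fixture(scope="session")
def cfg():
    return RunConfig().replace(precursor_charges=(2,))


@pytest.fixture(scope="session")
def small_space(cfg):
    """Search space over a small random proteome, shared across tests."""
    proteins, space = build_benchmark_space(20, cfg, seed=11)
    return proteins, space


@pytest.fixture(scope="session")
def noisefree_experiment(cfg, small_space):
    """Two noise-free runs, 40 present / 40 absent, run2 doubled in abundance."""
    _, space = small_space
    truth, pairs, runs = simulate_experiment(
        space, n_present=40, n_absent=40, n_runs=2, config=cfg, seed=5,
        noise_cv=0.0, baseline=0.0, interference_rate=0.0,
        abundance_scales=[1.0, 2.0],
    )
    return truth, pairs, runs


@pytest.fixture(scope="session")
def noisy_experiment(cfg, small_space):
    """Two runs at default noise with a linear RT shift on run 2."""
    _, space = small_space
    truth, pairs, runs = simulate_experiment(
        space, n_present=150, n_absent=150, n_runs=2, config=cfg, seed=3,
        rt_shifts=[(0.0, 1.0), (4.0, 1.02)],
    )
    return truth, pairs, runs
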