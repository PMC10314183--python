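"""Shared fixtures: small simulated experiments generated at test time."""

import numpy as np
import pytest

from flicrhythm.synth import SimulationParams, simulate_experiment


@pytest.fixture(scope="session")
def sim_small():
    """3 wells, 1 LD day, 500 ms sampling — quick but realistic."""
    params = SimulationParams(
        n_wells=3, n_ld_days=1, n_dd_days=0, sample_interval_ms=500, seed=11
    )
    return simulate_experiment(params)


@pytest.fixture(scope="session")
def sim_week():
    """12 wells, 3 LD + 4 DD days at 1 s sampling: the full assay layout."""
    params = SimulationParams(
        n_wells=12, n_ld_days=3, n_dd_days=4, sample_interval_ms=1000, seed=7
    )
    return simulate_experiment(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
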