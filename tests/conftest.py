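import numpy as np
import pytest

import percgen as pg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def exp1_schedule():
    return pg.make_schedule(1, seed=7)


@pytest.fixture(scope="session")
def exp2_schedule():
    return pg.make_schedule(2, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """Four perceptual-generalizer participants, point-metric generative path."""
    spec = pg.SimSpec(
        experiment=1, n_participants=4, seed=99,
        group_weights=(0.0, 0.0, 0.0, 1.0),
        perceptual_metric=pg.Metric.POINT,
    )
    return pg.simulate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_config():
    """A few-second MCMC configuration for smoke tests."""
    return pg.MCMCConfig(chains=2, iterations=120, burn_in=60, seed=5)
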