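import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import statewalk as sw
from statewalk.fit import MCMCConfig, PriorSpec, run_chain
from statewalk.preprocess import SubsampleSpec, steps_from_positions

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def traj():
    """Default two-regime synthetic trajectory (487 points)."""
    return sw.simulate_trajectory(sw.default_generator_config(seed=11))


@pytest.fixture(scope="session")
def steps_f1(traj):
    """Step series of the synthetic trajectory at the original resolution."""
    return steps_from_positions(traj.xy, traj.t, SubsampleSpec(base_interval=1.0, factor=1))


@pytest.fixture(scope="session")
def chain_f1(steps_f1):
    """A short but usable two-state chain on the synthetic step series."""
    return run_chain(
        steps_f1, 2, PriorSpec(),
        MCMCConfig(n_iter=4000, burn_in=800, thin=10, seed=7),
    )
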