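import numpy as np
import pytest

from brachyqa.phantom import PhantomConfig, generate_plan
from brachyqa.pipeline import run_experiment, simulate_cohort


@pytest.fixture(scope="session")
def default_frame():
    """Feature/target table for the full default synthetic cohort
    (200 plans, documented seed)."""
    return simulate_cohort(PhantomConfig())


@pytest.fixture(scope="session")
def default_experiment(default_frame):
    """160/40 split + grid-searched per-organ SVR fits on the default cohort."""
    return run_experiment(default_frame)


@pytest.fixture(scope="session")
def small_plans():
    """A handful of fully materialized phantom plans for unit tests."""
    cfg = PhantomConfig(n_plans=3)
    return [generate_plan(cfg, i, keep_volumes=True) for i in range(3)]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
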