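"""Shared fixtures: small synthetic cohorts and a fitted ensemble, reused
across test modules to keep the suite fast."""

import numpy as np
import pytest

from omicsurv import (
    RunConfig,
    SyntheticCohortSpec,
    fit_ensemble,
    generate_cohort,
)
from omicsurv.data_model import SurvivalTable


def make_survival(n, seed=0, censor=0.3, rng=None):
    """Random survival table with continuous times."""
    rng = rng or np.random.default_rng(seed)
    time = rng.exponential(1000, n)
    event = (rng.random(n) >= censor).astype(int)
    return SurvivalTable([f"s{i:03d}" for i in range(n)], time, event)


@pytest.fixture(scope="session")
def strong_cohort():
    """Well-separated 2-subtype cohort with survival signal (n=120)."""
    return generate_cohort(
        SyntheticCohortSpec(n_samples=120, hazard_ratio=3.0, seed=7)
    )


@pytest.fixture(scope="session")
def fast_config():
    """Scaled-down model hyperparameters for mechanism tests."""
    return RunConfig(hidden_size=16, gmm_n_init=10)


@pytest.fixture(scope="session")
def tiny_ensemble(strong_cohort, fast_config):
    """A small fitted ensemble shared by serialization/prediction tests."""
    return fit_ensemble(
        strong_cohort.dataset, n_models=3, K=2, seed=11, config=fast_config
    )
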