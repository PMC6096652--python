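"""Shared fixtures: small synthetic datasets and session-scoped fits.

Expensive posterior fits are session-scoped so that several tests can read
different properties off the same draws.
"""

import warnings

import numpy as np
import pytest

import shootddm as S

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_trials():
    """Small uncensored race-by-object dataset with default ground truth."""
    trials, truth = S.generate_dataset(
        S.TruthConfig(), n_subjects=10, trials_per_cell=10,
        window_ms=None, censor_mode="none", seed=101)
    return trials, truth


@pytest.fixture(scope="session")
def study4_scale_fit():
    """One study-4-like fit (40 subjects x 160 trials, race x context design).

    Used for parameter recovery, convergence diagnostics and posterior
    predictive self-consistency.
    """
    trials, truth = S.generate_preset(
        "study4", seed=202, n_subjects=40, trials_per_cell=20)
    model = S.HierarchicalDDM(trials, windows_ms={"study4": 630.0})
    draws = S.sample_posterior(model, chains=2, iterations=600, warmup=600, seed=303)
    return trials, truth, model, draws


@pytest.fixture(scope="session")
def small_fit(small_trials):
    trials, truth = small_trials
    model = S.HierarchicalDDM(trials)
    draws = S.sample_posterior(model, chains=2, iterations=300, warmup=300, seed=99)
    return model, draws


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
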