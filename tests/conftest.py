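"""Shared fixtures: scaled-down synthetic cohorts and posterior fits.

Session-scoped fits are reused across test modules to keep the suite fast;
all randomness is fixed by explicit seeds so the suite is deterministic.
"""
from dataclasses import replace

import numpy as np
import pytest

from gonogo_ddm import (McmcConfig, ModelSpec, fit_hierarchical, generate_cohort,
                        preset_cohorts)


def scaled_truth(preset: str, n_per_group: int, n_trials: int, **kw):
    truth = preset_cohorts(preset)
    return replace(truth,
                   n_participants={g: n_per_group for g in truth.n_participants},
                   n_trials=n_trials, **kw)


@pytest.fixture(scope="session")
def small_cohort():
    """paper_like cohort scaled to 3 groups x 4 participants x 150 trials."""
    truth = scaled_truth("paper_like", 4, 150)
    ds, params = generate_cohort(truth, seed=11)
    return truth, ds, params


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """Variant-4 fit of the small cohort at a reduced chain length."""
    _, ds, _ = small_cohort
    return fit_hierarchical(ds, ModelSpec.variant(4),
                            McmcConfig(n_samples=1500, n_burnin=500), seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
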