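"""Shared fixtures: observed group parameters and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from axondd import GroupParams, default_config, simulate_study

# Observed per-group ADD features (GM μm, GSD, skewness, P90 μm, mode μm)
# used throughout as ground truth for internal-consistency checks.
OBSERVED = {
    "sham": {"gm": 0.69, "gsd": 2.10, "skewness": 3.21, "p90": 1.79, "mode": 0.40},
    "day7": {"gm": 0.65, "gsd": 2.03, "skewness": 2.94, "p90": 1.61, "mode": 0.39},
    "day21": {"gm": 0.51, "gsd": 1.97, "skewness": 2.72, "p90": 1.22, "mode": 0.32},
}

GROUP_N_ANIMALS = {"sham": 7, "day7": 7, "day21": 6}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220702)


@pytest.fixture(scope="session")
def small_study():
    """Three-group study at reduced per-animal axon counts (fast)."""
    groups = [
        GroupParams(
            name=g.name,
            gm=g.gm,
            gsd=g.gsd,
            n_animals=g.n_animals,
            axons_per_animal=400,
            survival_mean=g.survival_mean,
        )
        for g in default_config()
    ]
    return simulate_study(groups, seed=11)


@pytest.fixture(scope="session")
def sham_sample(rng):
    """Large single-animal sham draw for estimator checks."""
    return np.exp(rng.normal(np.log(0.69), np.log(2.10), size=50_000))
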