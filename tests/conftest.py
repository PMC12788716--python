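"""Shared fixtures: compact truth configurations and small cohorts.

The compact configurations keep the covariate space small so that repeated
Cox fits stay fast while preserving the structure under study (pattern main
effects, stroke/diabetes/age-driven interactions, ~15% event fraction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pa_optim.synthetic import TruthConfig, generate_cohort

COMPACT_COVARIATES = {
    "age": ("normal", 62.0, 8.0),
    "sex_male": ("binary", 0.48),
    "stroke": ("binary", 0.10),
    "diabetes": ("binary", 0.06),
}

COMPACT_BETA_MAIN = {
    "active_lpa": -0.30,
    "active_regular": -0.70,
    "active_ww": -0.50,
    "age": 0.07,
    "sex_male": 0.45,
    "stroke": 0.80,
    "diabetes": 0.50,
}

COMPACT_BETA_INTERACTION = {
    ("active_lpa", "stroke"): 0.50,
    ("active_regular", "stroke"): 1.20,
    ("active_ww", "stroke"): 1.20,
    ("active_ww", "age"): -0.030,
}

COMPACT_ASSIGNMENT = {
    "active_lpa": {"intercept": 0.01, "sex_male": -0.30},
    "active_regular": {"intercept": 0.18, "age": -0.10},
    "active_ww": {"intercept": 0.90, "age": 0.10, "sex_male": 0.30},
}


def compact_config(**kwargs) -> TruthConfig:
    """A four-covariate truth with well-separated pattern contrasts."""
    base = TruthConfig(
        covariate_spec=COMPACT_COVARIATES,
        beta_main=COMPACT_BETA_MAIN,
        beta_interaction=COMPACT_BETA_INTERACTION,
        pattern_assignment=COMPACT_ASSIGNMENT,
        confounding_strength=0.5,
        weibull_scale=75.0,
    )
    return base.with_(**kwargs) if kwargs else base


@pytest.fixture(scope="session")
def small_cohort():
    """A 4,000-participant compact cohort shared across tests."""
    table, truth = generate_cohort(compact_config(n=4000, seed=11))
    return table, truth


@pytest.fixture(scope="session")
def censored_fixture():
    """A 50-row censored survival fixture for metric oracles."""
    rng = np.random.default_rng(7)
    n = 50
    T = rng.exponential(10, n)
    C = rng.exponential(14, n)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    pred = rng.uniform(0.2, 0.99, n)
    return pd.DataFrame({"time": time, "event": event, "surv_prob": pred})
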