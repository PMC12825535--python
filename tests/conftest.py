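import numpy as np
import pandas as pd
import pytest

from prediagprot.synthetic_cohort import (
    MediationSpec,
    SimConfig,
    simulate_cohort,
    study_like_config,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort with planted signal, archetypes, and mediation."""
    cfg = study_like_config(
        n_participants=4000, n_proteins=60, n_hits=12, event_rate=0.02, seed=11
    )
    cfg.missing_rate = 0.0
    cohort, matrix, truth = simulate_cohort(cfg)
    return cohort, matrix, truth


@pytest.fixture(scope="session")
def null_cohort():
    """No protein-hazard association at all; modest covariate effects."""
    cfg = SimConfig(
        n_participants=3000,
        n_proteins=40,
        event_rate=0.03,
        covariate_log_hr={"age": 0.4, "sex": 0.5},
        missing_rate=0.0,
        seed=23,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def mediation_cohort():
    """Known mediation structure through one BMI-driven protein."""
    cfg = SimConfig(
        n_participants=12000,
        n_proteins=4,
        event_rate=0.02,
        mediation_spec=MediationSpec(
            exposure="bmi", mediators={"P0001": 0.5}, theta1=0.2, theta2=0.4, theta3=0.0
        ),
        missing_rate=0.0,
        seed=31,
    )
    return simulate_cohort(cfg)


def make_survival(rng, n, beta, event_rate=0.1, p=None):
    """Plain exponential PH data for direct model tests."""
    beta = np.asarray(beta, dtype=float)
    p = p if p is not None else beta.size
    X = rng.standard_normal((n, p))
    eta = X[:, : beta.size] @ beta
    lam0 = event_rate / 10.0
    T = rng.standard_exponential(n) / (lam0 * np.exp(eta))
    C = rng.uniform(8.0, 14.0, n)
    t = np.minimum(T, C)
    e = (T <= C).astype(int)
    return X, t, e
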