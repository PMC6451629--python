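"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest

from bmicost.config import SimulationConfig
from bmicost.simulate import generate_cohort, generate_panel, generate_population_table


@pytest.fixture(scope="session")
def base_config():
    """Small default-parameter cohort used by most unit tests."""
    return SimulationConfig(n_women=900, years=5, seed=123)


@pytest.fixture(scope="session")
def cohort_small(base_config):
    return generate_cohort(base_config)


@pytest.fixture(scope="session")
def panel_small(base_config, cohort_small):
    return generate_panel(cohort_small, base_config)


@pytest.fixture(scope="session")
def population():
    return generate_population_table()


def newton_poisson_mle(y, X, tol=1e-12, maxiter=200):
    """Independent Newton-Raphson maximiser of the Poisson log-likelihood.

    Deliberately implemented from the score and Hessian directly (no IRLS,
    no statsmodels) to serve as an oracle for the quasi-Poisson point
    estimates, which solve the same score equations.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-8))
    for _ in range(maxiter):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        score = X.T @ (y - mu)
        H = X.T @ (X * mu[:, None])
        step = np.linalg.solve(H, score)
        # damped Newton for stability on poorly scaled problems
        lam = 1.0
        def negll(b):
            m = np.exp(np.clip(X @ b, -30, 30))
            return float(np.sum(m) - np.sum(y * (X @ b)))
        f0 = negll(beta)
        while lam > 1e-8 and negll(beta + lam * step) > f0 + 1e-12:
            lam /= 2.0
        beta = beta + lam * step
        if np.max(np.abs(step)) * lam < tol:
            break
    return beta


@pytest.fixture(scope="session")
def poisson_oracle():
    return newton_poisson_mle


def quasi_variance_objective(v, contrast_cov):
    """Objective of the floating-CI construction, written independently.

    v has length K (reference first); contrast_cov is the (K-1)x(K-1)
    covariance of the non-reference log relative rates.
    """
    C = np.asarray(contrast_cov, dtype=float)
    Km1 = C.shape[0]
    total = 0.0
    for j in range(Km1):
        total += (np.log(v[0] + v[j + 1]) - np.log(C[j, j])) ** 2
    for i in range(Km1):
        for j in range(i + 1, Km1):
            t = C[i, i] + C[j, j] - 2 * C[i, j]
            total += (np.log(v[i + 1] + v[j + 1]) - np.log(t)) ** 2
    return total


@pytest.fixture(scope="session")
def qv_objective():
    return quasi_variance_objective


def simple_panel(mu_fn, bmi_values, years=1, seed=0, poisson=True):
    """Minimal hand-built person-year panel for closed-form GLM tests."""
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for b in bmi_values:
        pid += 1
        for t in range(years):
            mu = mu_fn(b)
            y = rng.poisson(mu) if poisson else mu
            rows.append(
                {
                    "person_id": pid,
                    "year_index": t,
                    "fraction_observed": 1.0,
                    "bmi": b,
                    "y": float(y),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def make_simple_panel():
    return simple_panel
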