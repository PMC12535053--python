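import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from cvtransport import CohortTable, CovariateSchema, CovariateSpec, default_schema


# ---------------------------------------------------------------------------
# independent estimation oracles (deliberately naive: explicit loops,
# generic optimizers — no shared code with the package's fitting paths)
# ---------------------------------------------------------------------------


def logistic_mle_oracle(X, y):
    """Brute-force logistic MLE via Nelder-Mead-refined BFGS on the
    hand-written log-likelihood. Returns (intercept, coefs)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)

    def negll(params):
        lp = params[0] + X @ params[1:]
        return float(np.sum(np.log1p(np.exp(lp)) - y * lp))

    x0 = np.zeros(X.shape[1] + 1)
    res = optimize.minimize(negll, x0, method="BFGS", options={"gtol": 1e-12})
    res = optimize.minimize(negll, res.x, method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-14})
    return res.x[0], res.x[1:]


def cox_partial_loglik_oracle(beta, X, time, event, weights=None):
    """Hand-written weighted Breslow log partial likelihood (pure loops)."""
    X = np.asarray(X, dtype=float)
    n = len(time)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    ll = 0.0
    for i in range(n):
        if event[i] != 1:
            continue
        risk = 0.0
        for j in range(n):
            if time[j] >= time[i]:
                risk += w[j] * np.exp(X[j] @ beta)
        ll += w[i] * (X[i] @ beta - np.log(risk))
    return ll


def cox_mle_oracle(X, time, event, weights=None):
    """Maximize the hand-written partial likelihood with a generic optimizer."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]

    def neg(beta):
        return -cox_partial_loglik_oracle(beta, X, time, event, weights)

    res = optimize.minimize(neg, np.zeros(X.shape[1]), method="BFGS", options={"gtol": 1e-12})
    res = optimize.minimize(neg, res.x, method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-14})
    return res.x


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture
def tiny_schema():
    return CovariateSchema(
        (
            CovariateSpec("age", "continuous", "years", 18, 110),
            CovariateSpec("prior_mi_stroke", "binary"),
        )
    )


def make_cohort(df: pd.DataFrame, schema) -> CohortTable:
    return CohortTable(df, schema)


@pytest.fixture
def toy_survival_cohort(tiny_schema):
    """8 subjects, distinct event times, both arms, for Cox oracles."""
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(8)],
            "source": "trial_1",
            "arm": ["treated", "control"] * 4,
            "age": [60.0, 65.0, 70.0, 55.0, 72.0, 68.0, 59.0, 61.0],
            "prior_mi_stroke": [1, 0, 1, 0, 0, 1, 0, 1],
            "time": [1.1, 0.8, 2.5, 3.0, 0.5, 1.9, 2.2, 3.4],
            "event": [1, 1, 0, 1, 1, 1, 0, 1],
        }
    )
    return CohortTable(df, tiny_schema)


@pytest.fixture
def covariate_cohort(tiny_schema):
    """Cross-sectional cohort (no follow-up), 6 subjects."""
    df = pd.DataFrame(
        {
            "subject_id": [f"t{i}" for i in range(6)],
            "source": "target",
            "arm": "none",
            "age": [55.0, 60.0, 65.0, 70.0, 75.0, 80.0],
            "prior_mi_stroke": [0, 1, 0, 1, 0, 1],
        }
    )
    return CohortTable(df, tiny_schema)
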