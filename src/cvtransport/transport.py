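"""Transposition of trial treatment effects to a target population.

Implements the inverse-odds-of-sampling-weights workflow: model the
probability p_i = P(S = trial | X_i) of trial membership in the stacked
trial + target sample (logistic regression or a discrete Bayesian
network), weight each trial participant by the inverse odds
w_i = (1 - p_i) / p_i, and re-estimate the treatment hazard ratio with a
weighted Cox model. The weighted estimate is the trial effect transported
to the covariate mix of the target population. Kish's effective sample
size (sum w)^2 / (sum w^2) quantifies how much information the weighting
retains, and a weight-by-treatment interaction test checks whether the
treatment effect varies with membership odds (which would undermine the
transport).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bayesnet import DiscreteBayesianNetwork, Discretizer, learn_structure
from .cohort import CohortTable
from .effects import EffectEstimate, weighted_cox_hr

SOURCE_NODE = "__source__"


# ---------------------------------------------------------------------------
# membership models
# ---------------------------------------------------------------------------


class SeparationError(ValueError):
    def __init__(self, covariates: list[str]):
        super().__init__(
            f"perfect separation between trial and target on: {covariates}"
        )
        self.covariates = covariates


@dataclass
class MembershipModel:
    """Fitted model of P(source = trial | X) on the stacked sample."""

    method: str  # "LR" | "BN"
    covariates: list[str]
    trial_fraction: float
    params: pd.Series | None = None  # LR coefficients (incl. const)
    network: DiscreteBayesianNetwork | None = None
    trial_probabilities: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.covariates].astype(float)
        if self.method == "LR":
            lp = self.params["const"] + X.to_numpy() @ self.params[self.covariates].to_numpy()
            return 1.0 / (1.0 + np.exp(-lp))
        post = self.network.posterior(SOURCE_NODE, X)
        return post[:, 1]

    @property
    def edges(self) -> list[tuple[str, str]]:
        if self.network is None:
            raise AttributeError("edge list only exists for BN membership models")
        return self.network.edges


def _stack(trial: CohortTable, target: CohortTable, covariates: list[str]) -> tuple[pd.DataFrame, np.ndarray]:
    Xt = trial.df[covariates].astype(float)
    Xg = target.df[covariates].astype(float)
    X = pd.concat([Xt, Xg], ignore_index=True)
    y = np.concatenate([np.ones(len(Xt)), np.zeros(len(Xg))])
    return X, y


def _separating_covariates(X: pd.DataFrame, y: np.ndarray) -> list[str]:
    out = []
    for col in X.columns:
        a, b = X[col][y == 1], X[col][y == 0]
        if a.min() > b.max() or b.min() > a.max():
            out.append(col)
    return out


def fit_membership_lr(
    trial: CohortTable, target: CohortTable, covariates: list[str]
) -> MembershipModel:
    """Maximum-likelihood logistic model of trial membership."""
    X, y = _stack(trial, target, covariates)
    sep = _separating_covariates(X, y)
    if sep:
        raise SeparationError(sep)
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", True):
        raise SeparationError(list(X.columns))
    p_trial = np.asarray(res.predict(Xc.iloc[: trial.n]))
    return MembershipModel(
        method="LR",
        covariates=list(covariates),
        trial_fraction=trial.n / (trial.n + target.n),
        params=res.params,
        trial_probabilities=p_trial,
    )


def fit_membership_bn(
    trial: CohortTable,
    target: CohortTable,
    covariates: list[str],
    bins: int = 5,
    max_indegree: int = 3,
    restarts: int = 5,
    seed: int = 0,
) -> MembershipModel:
    """Bayesian-network membership model on the stacked sample.

    Continuous covariates are discretized by quantile bins fitted on the
    stacked data; structure search is hill-climbing with BIC, seeded
    random restarts, and the source indicator forced to stay connected.
    Covariates with a single observed level are dropped with a warning.
    """
    X, y = _stack(trial, target, covariates)
    usable = []
    for col in covariates:
        if X[col].nunique() < 2:
            warnings.warn(f"covariate {col!r} has a single observed level; dropped")
        else:
            usable.append(col)
    schema_cont = [c for c in usable if X[c].nunique() > 2]
    disc = Discretizer.fit(X, schema_cont, bins=bins)
    coded = disc.transform(X[usable])
    coded[SOURCE_NODE] = y.astype(int)
    bn = learn_structure(
        coded,
        max_indegree=max_indegree,
        restarts=restarts,
        seed=seed,
        require_connected=SOURCE_NODE,
    )
    bn.discretizer = disc
    post = bn.posterior(SOURCE_NODE, X[usable])
    return MembershipModel(
        method="BN",
        covariates=usable,
        trial_fraction=trial.n / (trial.n + target.n),
        network=bn,
        trial_probabilities=post[: trial.n, 1],
    )


# ---------------------------------------------------------------------------
# inverse odds weights
# ---------------------------------------------------------------------------


@dataclass
class WeightSet:
    """Per-subject transportability weights for the trial members."""

    subject_ids: np.ndarray
    membership_probability: np.ndarray  # after clipping
    weights: np.ndarray  # (1 - p) / p
    clip: tuple[float, float] | None
    n_clipped: int

    @property
    def ess(self) -> float:
        return effective_sample_size(self.weights)

    def summary(self) -> dict:
        w = self.weights
        return {
            "n": len(w),
            "min": float(w.min()),
            "max": float(w.max()),
            "mean": float(w.mean()),
            "cv": float(w.std() / w.mean()),
            "ess": self.ess,
            "n_clipped": self.n_clipped,
        }


def inverse_odds_weights(
    model: MembershipModel,
    trial: CohortTable,
    clip: tuple[float, float] | None = (0.005, 0.995),
) -> WeightSet:
    """Inverse odds of sampling weights w = (1 - p) / p for trial members.

    Membership probabilities are clipped into `clip` before inversion;
    with clipping disabled any boundary probability is a hard error.
    Weights are deliberately not renormalized — the Cox partial
    likelihood is invariant to their scale.
    """
    p = np.asarray(model.trial_probabilities, dtype=float)
    if len(p) != trial.n:
        raise ValueError("membership model was not fitted with this trial cohort")
    if clip is None:
        if ((p <= 0) | (p >= 1)).any():
            raise ValueError("membership probability at 0 or 1 and clipping disabled")
        clipped = p
        n_clipped = 0
    else:
        lo, hi = clip
        clipped = np.clip(p, lo, hi)
        n_clipped = int(((p < lo) | (p > hi)).sum())
    w = (1.0 - clipped) / clipped
    return WeightSet(
        subject_ids=trial.df["subject_id"].to_numpy(),
        membership_probability=clipped,
        weights=w,
        clip=clip,
        n_clipped=n_clipped,
    )


def effective_sample_size(w: np.ndarray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(w, dtype=float)
    if len(w) == 0:
        raise ValueError("empty weight vector")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    return float(w.sum() ** 2 / (w**2).sum())


# ---------------------------------------------------------------------------
# diagnostics and the one-call workflow
# ---------------------------------------------------------------------------


def weight_treatment_interaction(
    cohort: CohortTable, weights: WeightSet | np.ndarray
) -> tuple[float, bool]:
    """Wald p for a treatment-by-weight product term in an (unweighted) Cox.

    Returns ``(p_value, degenerate)``; constant weights make the product
    collinear with treatment, reported as p = 1 with the degenerate flag.
    """
    w = weights.weights if isinstance(weights, WeightSet) else np.asarray(weights)
    if np.std(w) < 1e-12 * max(1.0, abs(np.mean(w))):
        return 1.0, True
    from lifelines import CoxPHFitter

    df = pd.DataFrame(
        {
            "time": cohort.df["time"].astype(float),
            "event": cohort.df["event"].astype(int),
            "treated": (cohort.df["arm"] == "treated").astype(int),
            "w": w,
        }
    )
    df["treated_x_w"] = df["treated"] * df["w"]
    cph = CoxPHFitter().fit(df, duration_col="time", event_col="event", fit_options={"precision": 1e-9})
    return float(cph.summary.loc["treated_x_w", "p"]), False


@dataclass
class TranspositionResults:
    """Output of :meth:`TranspositionModel.fit`: a Table-1-style row pair."""

    unweighted: EffectEstimate
    transposed: EffectEstimate
    weights: WeightSet
    membership: MembershipModel
    interaction_p: float
    interaction_degenerate: bool

    def summary(self) -> pd.DataFrame:
        rows = []
        for est in (self.unweighted, self.transposed):
            lo, hi = est.ci
            rows.append(
                {
                    "method": est.method,
                    "HR": est.hr,
                    "CI_low": lo,
                    "CI_high": hi,
                    "n": est.n,
                    "events": est.events,
                    "ESS": est.ess if est.ess is not None else est.n,
                }
            )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        out = [
            "Transposition analysis",
            f"  trial estimate:      {self.unweighted}",
            f"  transposed estimate: {self.transposed}",
            f"  effective sample size: {self.weights.ess:.1f} of {len(self.weights.weights)}",
            f"  weight x treatment interaction p = {self.interaction_p:.3f}"
            + (" (degenerate)" if self.interaction_degenerate else ""),
        ]
        return "\n".join(out)


class TranspositionModel:
    """Transposes a trial hazard ratio to a target population.

    Parameters
    ----------
    trial : CohortTable
        Randomized cohort with arms and follow-up.
    target : CohortTable
        Covariates-only cohort defining the reference population. Target
        rows never enter the Cox fit; they only inform the weights.
    covariates : list of str, optional
        Membership-model covariates (default: full schema).
    method : {"LR", "BN"}
    clip : (lo, hi) or None
        Membership-probability clipping bounds.
    """

    def __init__(
        self,
        trial: CohortTable,
        target: CohortTable,
        covariates: list[str] | None = None,
        method: str = "LR",
        clip: tuple[float, float] | None = (0.005, 0.995),
        adjustments: tuple[str, ...] = (),
        bn_settings: dict | None = None,
    ):
        if method not in ("LR", "BN"):
            raise ValueError(f"unknown membership method {method!r}")
        self.trial = trial
        self.target = target
        self.covariates = list(covariates) if covariates else trial.schema.names
        self.method = method
        self.clip = clip
        self.adjustments = tuple(adjustments)
        self.bn_settings = dict(bn_settings or {})

    def fit(self, seed: int = 0) -> TranspositionResults:
        if self.method == "LR":
            membership = fit_membership_lr(self.trial, self.target, self.covariates)
        else:
            membership = fit_membership_bn(
                self.trial, self.target, self.covariates, seed=seed, **self.bn_settings
            )
        ws = inverse_odds_weights(membership, self.trial, clip=self.clip)
        unweighted = weighted_cox_hr(
            self.trial, covariate_adjustments=self.adjustments, method="unweighted"
        )
        transposed = weighted_cox_hr(
            self.trial,
            weights=ws.weights,
            covariate_adjustments=self.adjustments,
            method=f"{self.method}-weighted",
        )
        p_int, degen = weight_treatment_interaction(self.trial, ws)
        return TranspositionResults(
            unweighted=unweighted,
            transposed=transposed,
            weights=ws,
            membership=membership,
            interaction_p=p_int,
            interaction_degenerate=degen,
        )


def transpose(
    trial: CohortTable,
    target: CohortTable,
    method: str = "LR",
    covariates: list[str] | None = None,
    clip: tuple[float, float] | None = (0.005, 0.995),
    seed: int = 0,
    **settings,
) -> TranspositionResults:
    """One-call transposition workflow (unweighted + transposed estimates)."""
    return TranspositionModel(
        trial, target, covariates=covariates, method=method, clip=clip, **settings
    ).fit(seed=seed)
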