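"""Hazard-ratio effect estimates via lifelines, with a shared result type."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError, StatisticalWarning

from .cohort import CohortTable


@dataclass(frozen=True)
class EffectEstimate:
    """Treatment log hazard ratio with its uncertainty and bookkeeping."""

    loghr: float
    se: float
    n: int
    events: int
    method: str = "unweighted"
    ess: float | None = None

    @property
    def hr(self) -> float:
        return float(np.exp(self.loghr))

    @property
    def ci(self) -> tuple[float, float]:
        """95% CI on the hazard-ratio scale."""
        return (
            float(np.exp(self.loghr - 1.96 * self.se)),
            float(np.exp(self.loghr + 1.96 * self.se)),
        )

    @property
    def p_value(self) -> float:
        from scipy import stats

        return float(2 * stats.norm.sf(abs(self.loghr) / self.se))

    def __str__(self) -> str:
        lo, hi = self.ci
        return f"HR {self.hr:.2f} (95% CI {lo:.2f}-{hi:.2f}) [{self.method}]"


def _treated_frame(
    cohort: CohortTable,
    adjustments: list[str] | tuple[str, ...] = (),
    treatment_col: str = "treated",
) -> pd.DataFrame:
    df = cohort.df
    if "time" not in df.columns:
        raise ValueError("cohort has no follow-up columns")
    out = pd.DataFrame(
        {
            "time": df["time"].astype(float),
            "event": df["event"].astype(int),
            treatment_col: (df["arm"] == "treated").astype(int),
        },
        index=df.index,
    )
    for name in adjustments:
        if name == "@source":
            # indicator covariates for every source beyond the first
            for s in sorted(df["source"].unique())[1:]:
                out[f"src_{s}"] = (df["source"] == s).astype(float)
        else:
            out[name] = df[name].astype(float)
    return out


def weighted_cox_hr(
    cohort: CohortTable,
    weights: np.ndarray | None = None,
    covariate_adjustments: list[str] | tuple[str, ...] = (),
    strata: str | None = None,
    method: str | None = None,
) -> EffectEstimate:
    """Treatment hazard ratio from a (weighted) Cox model.

    The fit uses Efron tie handling; when weights are supplied the
    variance is the robust sandwich estimator, since the weights are
    estimated and model-based variance would be anti-conservative. The
    point estimate is invariant to rescaling all weights by a constant
    (Cox partial likelihood property).
    """
    df = _treated_frame(cohort, covariate_adjustments)
    if df["event"].sum() == 0:
        raise ValueError("no events in cohort; cannot fit Cox model")
    if strata is not None:
        df[strata] = cohort.df[strata].to_numpy()
    kwargs: dict = {}
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(df):
            raise ValueError("weights not aligned with cohort")
        if (w <= 0).any():
            raise ValueError("weights must be positive")
        df["_w"] = w
        kwargs.update(weights_col="_w", robust=True)
    if strata is not None:
        kwargs["strata"] = [strata]
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", StatisticalWarning)
        try:
            cph.fit(
                df,
                duration_col="time",
                event_col="event",
                fit_options={"precision": 1e-9},
                **kwargs,
            )
        except ConvergenceError as exc:
            raise ValueError(f"Cox model did not converge: {exc}") from exc
    loghr = float(cph.params_["treated"])
    se = float(cph.standard_errors_["treated"])
    if method is None:
        method = "unweighted" if weights is None else "weighted"
    ess = None
    if weights is not None:
        ess = float(np.sum(w) ** 2 / np.sum(w**2))
    return EffectEstimate(
        loghr=loghr,
        se=se,
        n=len(df),
        events=int(df["event"].sum()),
        method=method,
        ess=ess,
    )
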