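"""Absolute-scale clinical benefit per subgroup, with interaction tests.

The workhorse is G-computation on a Cox proportional-hazards model fitted
to the pooled trial data (treatment, adjustment covariates and a trial
indicator): for a subgroup, set everyone's arm to "control", average the
predicted risk 1 - S(t* | x) at the landmark time t* (default 3.6 years),
repeat under "treated", and difference the two averages. That difference
is the absolute risk reduction (ARR); its reciprocal is the number needed
to treat (NNT). Uncertainty comes from a stratified nonparametric
bootstrap (resampling subjects within subgroup-by-arm cells, refitting
the model, recomputing every ARR), reported as percentile intervals.

Heterogeneity across subgroups is tested on two scales: the relative
scale with a Wald test of treatment-by-subgroup interaction terms in the
Cox model, and the absolute scale with the Gail-Simon tests — the
qualitative (crossover) statistic min(Q+, Q-) against its chi-square
mixture null, and a quantitative inverse-variance heterogeneity
chi-square for same-direction effects of different size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb

from ._cox import CoxFit, cox_fit
from .cohort import CohortTable
from .effects import EffectEstimate
from .subgroups import SubgroupTree, assign_subgroups


# ---------------------------------------------------------------------------
# combined Cox model with survival prediction
# ---------------------------------------------------------------------------


@dataclass
class CombinedCoxModel:
    """Cox fit on pooled trial data exposing counterfactual survival.

    With `subgroup_levels` set, the design additionally carries subgroup
    main effects and treatment-by-subgroup interactions, so counterfactual
    risks honor both subgroup-specific baseline risk and subgroup-specific
    treatment effects.
    """

    fit: CoxFit
    covariates: list[str]
    source_levels: list[str]
    subgroup_levels: list[str] = field(default_factory=list)

    def _design(self, df: pd.DataFrame, arm_counterfactual: str | None = None) -> np.ndarray:
        if arm_counterfactual is None:
            treated = (df["arm"] == "treated").to_numpy(dtype=float)
        elif arm_counterfactual == "treated":
            treated = np.ones(len(df))
        elif arm_counterfactual == "control":
            treated = np.zeros(len(df))
        else:
            raise ValueError(f"unknown counterfactual arm {arm_counterfactual!r}")
        cols = [treated[:, None]]
        if self.subgroup_levels:
            lab = df["subgroup"].to_numpy().astype(str)
            for g in self.subgroup_levels[1:]:
                ind = (lab == g).astype(float)
                cols.append(ind[:, None])
                cols.append((treated * ind)[:, None])
        if self.covariates:
            cols.append(df[self.covariates].astype(float).to_numpy())
        for s in self.source_levels[1:]:
            cols.append((df["source"] == s).to_numpy(dtype=float)[:, None])
        return np.hstack(cols)

    def predict_survival(
        self, df: pd.DataFrame, t_star: float, arm_counterfactual: str | None = None
    ) -> np.ndarray:
        return self.fit.predict_survival(self._design(df, arm_counterfactual), t_star)

    @property
    def max_event_time(self) -> float:
        return float(self.fit.baseline_times.max())


def _fit_frame(
    df: pd.DataFrame,
    covariates: list[str],
    source_levels: list[str],
    subgroup_levels: list[str] | None = None,
    weights: np.ndarray | None = None,
    init: np.ndarray | None = None,
    tol: float = 1e-9,
    prune: bool = True,
) -> CombinedCoxModel:
    model = CombinedCoxModel(
        fit=None,  # type: ignore[arg-type]
        covariates=list(covariates),
        source_levels=source_levels,
        subgroup_levels=list(subgroup_levels or []),
    )
    # drop adjustment covariates that are linearly dependent on the
    # structural columns or on earlier covariates (e.g. a covariate that
    # exactly defines a subgroup dummy); sequential Gram-Schmidt keeps the
    # structural part of the design intact and is deterministic
    if prune and covariates:
        struct = CombinedCoxModel(
            fit=None,  # type: ignore[arg-type]
            covariates=[],
            source_levels=source_levels,
            subgroup_levels=model.subgroup_levels,
        )._design(df)
        basis = np.hstack([np.ones((len(df), 1)), struct])
        Q, _ = np.linalg.qr(basis)
        kept: list[str] = []
        for c in model.covariates:
            x = df[c].to_numpy(dtype=float)[:, None]
            r = x - Q @ (Q.T @ x)
            norm = np.linalg.norm(r)
            if norm < 1e-8 * max(np.linalg.norm(x), 1.0):
                continue
            kept.append(c)
            Q = np.hstack([Q, r / norm])
        model.covariates = kept
    X = model._design(df)
    model.fit = cox_fit(
        X,
        df["time"].to_numpy(dtype=float),
        df["event"].to_numpy(dtype=float),
        weights=weights,
        init=init,
        tol=tol,
    )
    return model


def fit_combined_cox(
    cohort: CohortTable,
    covariates: list[str] | tuple[str, ...] = (),
    trial_indicator: bool = True,
    weights: np.ndarray | None = None,
    init: np.ndarray | None = None,
) -> CombinedCoxModel:
    """Cox model with treatment, adjustments and (optionally) a source
    indicator, exposing the Breslow baseline cumulative hazard."""
    df = cohort.df
    sources = sorted(df["source"].unique()) if trial_indicator else []
    return _fit_frame(df, list(covariates), sources, weights=weights, init=init)


def predicted_risk(
    model: CombinedCoxModel,
    cohort_subset: pd.DataFrame | CohortTable,
    t_star: float,
    arm_counterfactual: str,
) -> float:
    """G-computation risk: mean over subjects of 1 - S(t* | x, arm)."""
    df = cohort_subset.df if isinstance(cohort_subset, CohortTable) else cohort_subset
    if t_star > model.max_event_time:
        raise ValueError(
            f"t_star={t_star} beyond the last event time "
            f"{model.max_event_time:.3f}; refusing to extrapolate"
        )
    s = model.predict_survival(df, t_star, arm_counterfactual)
    return float(np.mean(1.0 - s))


# ---------------------------------------------------------------------------
# ARR / NNT with stratified bootstrap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BootstrapPlan:
    """Subject-level bootstrap, stratified by subgroup x arm."""

    n_resamples: int = 1000
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_resamples < 2:
            raise ValueError("bootstrap needs at least 2 resamples")


@dataclass
class BenefitEstimate:
    subgroup: str
    t_star: float
    risk_control: float
    risk_treated: float
    arr_ci: tuple[float, float]
    n: int
    events: int
    nnt_defined: bool
    bootstrap_arrs: np.ndarray = field(repr=False)

    @property
    def arr(self) -> float:
        return self.risk_control - self.risk_treated

    @property
    def nnt_raw(self) -> float:
        return float(np.inf) if self.arr == 0 else 1.0 / self.arr

    @property
    def nnt(self) -> int | None:
        """Reported NNT: 1/ARR rounded to the nearest integer."""
        return None if self.arr == 0 else nnt_from_arr(self.arr)

    def describe_nnt(self) -> str:
        if self.arr == 0:
            return "NNT undefined (ARR = 0)"
        if not self.nnt_defined:
            return f"NNT not defined (CI crosses 0); point estimate {self.nnt}"
        return str(self.nnt)


def nnt_from_arr(arr: float) -> int:
    """Number needed to treat: nearest integer to 1/ARR."""
    if arr == 0:
        raise ValueError("NNT undefined for ARR = 0")
    return int(round(1.0 / arr))


def _stratified_resample(
    rng: np.random.Generator, strata: np.ndarray
) -> np.ndarray:
    idx = np.arange(len(strata))
    out = []
    for s in np.unique(strata):
        members = idx[strata == s]
        out.append(rng.choice(members, size=len(members), replace=True))
    return np.concatenate(out)


def arr_nnt(
    model_cohort: CohortTable,
    subgroups: pd.Series | np.ndarray,
    t_star: float = 3.6,
    plan: BootstrapPlan = BootstrapPlan(),
    covariates: list[str] | tuple[str, ...] = (),
    trial_indicator: bool = True,
) -> dict[str, BenefitEstimate]:
    """ARR and NNT per subgroup with percentile bootstrap intervals.

    One model fit per resample serves every subgroup, which keeps the
    subgroup ARRs internally consistent and the bootstrap affordable.
    When there is more than one subgroup the model carries subgroup main
    effects and treatment-by-subgroup interactions, so each subgroup's
    ARR reflects its own baseline risk and its own treatment effect.
    """
    labels = np.asarray(subgroups).astype(str)
    df = model_cohort.df.copy()
    df["subgroup"] = labels
    uniq = sorted(pd.unique(labels))
    source_levels = (
        sorted(df["source"].unique()) if trial_indicator else []
    )
    subgroup_levels = uniq if len(uniq) > 1 else []
    model = _fit_frame(df, list(covariates), source_levels, subgroup_levels)

    def _arrs(m: CombinedCoxModel, frame: pd.DataFrame, labs: np.ndarray) -> dict[str, float]:
        out = {}
        s_c = m.predict_survival(frame, t_star, "control")
        s_t = m.predict_survival(frame, t_star, "treated")
        for g in uniq:
            mask = labs == g
            out[g] = float(np.mean(1 - s_c[mask]) - np.mean(1 - s_t[mask]))
        return out

    if t_star > model.max_event_time:
        raise ValueError(
            f"t_star={t_star} beyond the last event time "
            f"{model.max_event_time:.3f}; refusing to extrapolate"
        )

    rng = np.random.default_rng(plan.seed)
    strata = np.char.add(
        labels.astype(str), np.where(df["arm"] == "treated", "|t", "|c")
    )
    boot: dict[str, list[float]] = {g: [] for g in uniq}
    for _ in range(plan.n_resamples):
        take = _stratified_resample(rng, strata)
        sub = df.iloc[take]
        # looser Newton tolerance: percentile endpoints are insensitive to
        # 1e-6-level wiggle in each resample's coefficients
        m = _fit_frame(
            sub,
            model.covariates,
            model.source_levels,
            model.subgroup_levels,
            init=model.fit.beta,
            tol=1e-6,
            prune=False,
        )
        for g, v in _arrs(m, sub, labels[take]).items():
            boot[g].append(v)

    alpha = (1 - plan.ci_level) / 2
    s_c_all = model.predict_survival(df, t_star, "control")
    s_t_all = model.predict_survival(df, t_star, "treated")
    out: dict[str, BenefitEstimate] = {}
    for g in uniq:
        mask = labels == g
        arrs = np.asarray(boot[g])
        lo, hi = np.percentile(arrs, [100 * alpha, 100 * (1 - alpha)])
        out[g] = BenefitEstimate(
            subgroup=str(g),
            t_star=t_star,
            risk_control=float(np.mean(1 - s_c_all[mask])),
            risk_treated=float(np.mean(1 - s_t_all[mask])),
            arr_ci=(float(lo), float(hi)),
            n=int(mask.sum()),
            events=int(df.loc[mask, "event"].sum()),
            nnt_defined=bool(lo > 0 or hi < 0),
            bootstrap_arrs=arrs,
        )
    return out


# ---------------------------------------------------------------------------
# Gail-Simon interaction tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GailSimonResult:
    scale: str
    estimates: tuple[float, ...]
    standard_errors: tuple[float, ...]
    q_plus: float
    q_minus: float
    p_qualitative: float
    q_het: float
    p_quantitative: float

    @property
    def crossover(self) -> bool:
        return self.p_qualitative < 0.05


def gail_simon_test(
    estimates: list[tuple[float, float]], scale: str = "ARR"
) -> GailSimonResult:
    """Qualitative (crossover) and quantitative interaction tests.

    `estimates` is a list of (D_k, s_k) per subgroup. The crossover
    statistic is min(Q+, Q-) with Q+- the sums of squared standardized
    effects by sign; its p-value is the binomial mixture of chi-squares
    sum_{j=1}^{K-1} C(K-1, j) 2^{-(K-1)} P(chi2_j > min(Q+, Q-)). The
    quantitative test is the inverse-variance heterogeneity chi-square
    with K-1 degrees of freedom.
    """
    if len(estimates) < 2:
        raise ValueError("need at least two subgroups")
    D = np.array([d for d, _ in estimates], dtype=float)
    S = np.array([s for _, s in estimates], dtype=float)
    if (S <= 0).any():
        raise ValueError("standard errors must be positive")
    z2 = (D / S) ** 2
    q_plus = float(z2[D > 0].sum())
    q_minus = float(z2[D < 0].sum())
    q_min = min(q_plus, q_minus)
    K = len(D)
    p_qual = float(
        sum(
            comb(K - 1, j) * 0.5 ** (K - 1) * stats.chi2.sf(q_min, df=j)
            for j in range(1, K)
        )
    )
    p_qual = min(p_qual, 1.0)
    if q_min == 0.0:
        p_qual = 1.0
    w = 1.0 / S**2
    dbar = float(np.sum(w * D) / np.sum(w))
    q_het = float(np.sum((D - dbar) ** 2 * w))
    p_quant = float(stats.chi2.sf(q_het, df=K - 1))
    return GailSimonResult(
        scale=scale,
        estimates=tuple(D),
        standard_errors=tuple(S),
        q_plus=q_plus,
        q_minus=q_minus,
        p_qualitative=p_qual,
        q_het=q_het,
        p_quantitative=p_quant,
    )


def relative_scale_interaction(
    cohort: CohortTable,
    subgroups: pd.Series | np.ndarray,
    covariates: list[str] | tuple[str, ...] = (),
    trial_indicator: bool = True,
) -> float:
    """Wald p for joint nullity of treatment-by-subgroup interactions."""
    df = cohort.df
    labels = np.asarray(subgroups).astype(str)
    uniq = sorted(pd.unique(labels))
    if len(uniq) < 2:
        raise ValueError("need at least two subgroups")
    for g in uniq:
        if (labels == g).sum() == 0:
            raise ValueError(f"empty subgroup {g!r}")
    treated = (df["arm"] == "treated").to_numpy(dtype=float)
    cols = [treated[:, None]]
    names = ["treated"]
    for g in uniq[1:]:
        ind = (labels == g).astype(float)
        cols += [ind[:, None], (treated * ind)[:, None]]
        names += [f"grp_{g}", f"treated_x_{g}"]
    if covariates:
        cols.append(df[list(covariates)].astype(float).to_numpy())
        names += list(covariates)
    if trial_indicator:
        for s in sorted(df["source"].unique())[1:]:
            cols.append((df["source"] == s).to_numpy(dtype=float)[:, None])
            names.append(f"src_{s}")
    X = np.hstack(cols)
    fit = cox_fit(X, df["time"].to_numpy(dtype=float), df["event"].to_numpy(dtype=float))
    idx = [i for i, nm in enumerate(names) if nm.startswith("treated_x_")]
    b = fit.beta[idx]
    V = fit.cov[np.ix_(idx, idx)]
    w = float(b @ np.linalg.solve(V, b))
    return float(stats.chi2.sf(w, df=len(idx)))


# ---------------------------------------------------------------------------
# imbalance-triggered sensitivity adjustments
# ---------------------------------------------------------------------------


def imbalance_adjustments(
    df: pd.DataFrame, covariates: list[str], schema
) -> list[str]:
    """Covariates imbalanced across arms (SMD > 0.1 and p < 0.05)."""
    from .matching import standardized_mean_difference

    treated = df["arm"] == "treated"
    out = []
    for cov in covariates:
        xa = df.loc[treated, cov].to_numpy(dtype=float)
        xb = df.loc[~treated, cov].to_numpy(dtype=float)
        kind = schema[cov].kind
        smd = standardized_mean_difference(xa, xb, kind)
        if smd <= 0.1 or not np.isfinite(smd):
            continue
        if kind == "continuous":
            p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
        else:
            tab = np.array(
                [[xa.sum(), len(xa) - xa.sum()], [xb.sum(), len(xb) - xb.sum()]]
            )
            p = float(stats.chi2_contingency(tab, correction=False)[1])
        if p < 0.05:
            out.append(cov)
    return out


# ---------------------------------------------------------------------------
# model facade
# ---------------------------------------------------------------------------


@dataclass
class BenefitResults:
    t_star: float
    benefits: dict[str, BenefitEstimate]
    hazard_ratios: dict[str, EffectEstimate | None]
    gail_simon_arr: GailSimonResult | None
    relative_interaction_p: float | None
    adjustments: tuple[str, ...]
    sensitivity_adjustments: dict[str, list[str]]

    def summary(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.benefits):
            be = self.benefits[g]
            est = self.hazard_ratios.get(g)
            row = {
                "subgroup": g,
                "n": be.n,
                "events": be.events,
                "risk_control": be.risk_control,
                "risk_treated": be.risk_treated,
                "ARR": be.arr,
                "ARR_CI_low": be.arr_ci[0],
                "ARR_CI_high": be.arr_ci[1],
                "NNT": be.describe_nnt(),
            }
            if est is not None:
                lo, hi = est.ci
                row.update({"HR": est.hr, "HR_CI_low": lo, "HR_CI_high": hi})
            rows.append(row)
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        out = [f"Clinical benefit at t* = {self.t_star} years", self.summary().to_string(index=False)]
        if self.gail_simon_arr is not None:
            gs = self.gail_simon_arr
            out.append(
                f"Gail-Simon (ARR scale): quantitative p = {gs.p_quantitative:.4f}, "
                f"qualitative (crossover) p = {gs.p_qualitative:.4f}"
            )
        if self.relative_interaction_p is not None:
            out.append(f"Relative-scale interaction p = {self.relative_interaction_p:.4f}")
        return "\n".join(out)


class BenefitModel:
    """Subgroup benefit report on absolute and relative scales.

    Parameters
    ----------
    cohort : CohortTable
        Pooled longitudinal cohort (trial or matched real-world).
    tree : SubgroupTree or None
        Partition; ``None`` treats the cohort as a single group.
    t_star : float
        Landmark time in years (3.6 for the trial landscape; 2.1 is the
        natural choice for shorter-follow-up real-world cohorts).
    adjustments : covariate names entering the Cox model.
    auto_adjust : bool
        Re-fit each subgroup's hazard ratio adding covariates that are
        imbalanced across arms within the subgroup (SMD > 0.1, p < 0.05).
    """

    def __init__(
        self,
        cohort: CohortTable,
        tree: SubgroupTree | None = None,
        t_star: float = 3.6,
        adjustments: tuple[str, ...] = (),
        plan: BootstrapPlan = BootstrapPlan(),
        trial_indicator: bool = True,
        auto_adjust: bool = True,
    ):
        self.cohort = cohort
        self.tree = tree
        self.t_star = t_star
        self.adjustments = tuple(adjustments)
        self.plan = plan
        self.trial_indicator = trial_indicator and cohort.df["source"].nunique() > 1
        self.auto_adjust = auto_adjust

    def fit(self) -> BenefitResults:
        cohort = self.cohort
        if self.tree is not None:
            cohort = assign_subgroups(cohort, self.tree)
            labels = cohort.df["subgroup"].to_numpy()
        elif "subgroup" in cohort.df.columns:
            labels = cohort.df["subgroup"].to_numpy()
        else:
            labels = np.full(cohort.n, "A")

        benefits = arr_nnt(
            cohort,
            labels,
            t_star=self.t_star,
            plan=self.plan,
            covariates=self.adjustments,
            trial_indicator=self.trial_indicator,
        )

        hrs: dict[str, EffectEstimate | None] = {}
        sens: dict[str, list[str]] = {}
        schema = cohort.schema
        for g in sorted(benefits):
            sub = cohort.df[labels == g]
            extra: list[str] = []
            if self.auto_adjust:
                extra = imbalance_adjustments(sub, schema.names, schema)
            sens[g] = extra
            hrs[g] = self._subgroup_hr(sub, tuple(dict.fromkeys((*self.adjustments, *extra))))

        uniq = sorted(benefits)
        gs = None
        rel_p = None
        if len(uniq) >= 2:
            ests = []
            for g in uniq:
                be = benefits[g]
                se = float(np.std(be.bootstrap_arrs, ddof=1))
                ests.append((be.arr, max(se, 1e-12)))
            gs = gail_simon_test(ests, scale="ARR")
            rel_p = relative_scale_interaction(
                cohort, labels, covariates=self.adjustments, trial_indicator=self.trial_indicator
            )
        return BenefitResults(
            t_star=self.t_star,
            benefits=benefits,
            hazard_ratios=hrs,
            gail_simon_arr=gs,
            relative_interaction_p=rel_p,
            adjustments=self.adjustments,
            sensitivity_adjustments=sens,
        )

    def _subgroup_hr(self, sub: pd.DataFrame, adjustments: tuple[str, ...]) -> EffectEstimate | None:
        ev_by_arm = sub.groupby(sub["arm"] == "treated")["event"].sum()
        if len(ev_by_arm) < 2 or (ev_by_arm == 0).any():
            return None
        treated = (sub["arm"] == "treated").to_numpy(dtype=float)
        cols = [treated[:, None]]
        usable = [c for c in adjustments if sub[c].std() > 0]
        if usable:
            cols.append(sub[usable].astype(float).to_numpy())
        if self.trial_indicator:
            for s in sorted(sub["source"].unique())[1:]:
                cols.append((sub["source"] == s).to_numpy(dtype=float)[:, None])
        X = np.hstack(cols)
        try:
            fit = cox_fit(X, sub["time"].to_numpy(dtype=float), sub["event"].to_numpy(dtype=float))
        except Exception:
            return None
        return EffectEstimate(
            loghr=float(fit.beta[0]),
            se=float(fit.se[0]),
            n=len(sub),
            events=int(sub["event"].sum()),
            method="combined",
        )


def subgroup_benefit_report(
    cohort: CohortTable,
    tree: SubgroupTree | None,
    plan: BootstrapPlan = BootstrapPlan(),
    adjustments: tuple[str, ...] = (),
    t_star: float = 3.6,
    **kwargs,
) -> BenefitResults:
    """One-call per-subgroup benefit table (HR, risks, ARR, NNT, tests)."""
    return BenefitModel(
        cohort, tree, t_star=t_star, adjustments=adjustments, plan=plan, **kwargs
    ).fit()
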