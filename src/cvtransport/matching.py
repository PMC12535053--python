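"""Propensity-score matched emulation of an active-comparator study.

New users of the exposure drug class are matched 1:1 to new users of a
comparator class on the logit of the propensity score (nearest neighbor,
by default with replacement and no caliper). Balance before and after
matching is judged by absolute standardized mean differences, with
SMD < 0.10 as the conventional pass mark. Effect estimation on the
matched sets uses a Cox model with frequency weights for reused
comparators and a robust sandwich variance; when a subgroup partition is
supplied, each subgroup's model is re-adjusted automatically for
covariates left imbalanced within that subgroup (SMD > 0.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortTable, ValidationError
from .effects import EffectEstimate, weighted_cox_hr
from .subgroups import SubgroupTree, assign_subgroups
from .transport import SeparationError, _separating_covariates


# ---------------------------------------------------------------------------
# propensity model
# ---------------------------------------------------------------------------


@dataclass
class PropensityModel:
    covariates: list[str]
    params: pd.Series
    scores: pd.Series  # e(X) in (0, 1), indexed like the cohort frame

    @property
    def logit_scores(self) -> pd.Series:
        return np.log(self.scores / (1 - self.scores))


def estimate_propensity(
    cohort: CohortTable, covariates: list[str]
) -> PropensityModel:
    """Maximum-likelihood logistic model of P(exposed | X).

    The exposed group is the ``treated`` arm; the comparator is
    ``control``. Constant covariates are rejected up front.
    """
    df = cohort.df
    y = (df["arm"] == "treated").to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both exposure groups must be non-empty")
    X = df[list(covariates)].astype(float)
    constant = [c for c in covariates if X[c].nunique() < 2]
    if constant:
        raise ValidationError(f"covariates without variation: {constant}")
    sep = _separating_covariates(X, y)
    if sep:
        raise SeparationError(sep)
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    ps = np.clip(np.asarray(res.predict(Xc)), 1e-12, 1 - 1e-12)
    return PropensityModel(
        covariates=list(covariates),
        params=res.params,
        scores=pd.Series(ps, index=df.index),
    )


# ---------------------------------------------------------------------------
# nearest-neighbor matching on logit distance
# ---------------------------------------------------------------------------


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # exposed_id, comparator_id, distance
    with_replacement: bool
    caliper: float | None
    dropped_exposed: list[str] = field(default_factory=list)

    @property
    def comparator_use_counts(self) -> pd.Series:
        return self.pairs["comparator_id"].value_counts()


def nn_match(
    model: PropensityModel,
    cohort: CohortTable,
    with_replacement: bool = True,
    caliper: float | None = None,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor match on |logit e_i - logit e_j|.

    Exposed subjects are processed in descending logit-propensity order
    (ties by subject id); distance ties also break on subject id, so the
    match is fully deterministic. `caliper` is in units of the standard
    deviation of the logit propensity; exposed subjects with no
    comparator inside it are dropped and listed.
    """
    df = cohort.df
    logit = model.logit_scores
    exposed = df["arm"] == "treated"
    exp_df = pd.DataFrame(
        {"id": df.loc[exposed, "subject_id"], "lp": logit[exposed]}
    ).sort_values(["lp", "id"], ascending=[False, True], kind="stable")
    cmp_df = pd.DataFrame(
        {"id": df.loc[~exposed, "subject_id"], "lp": logit[~exposed]}
    ).sort_values(["lp", "id"], kind="stable")
    if not with_replacement and len(cmp_df) < len(exp_df):
        raise ValueError(
            "matching without replacement needs at least as many "
            "comparators as exposed subjects"
        )
    max_dist = np.inf
    if caliper is not None:
        max_dist = caliper * float(logit.std(ddof=1))

    pairs = []
    dropped: list[str] = []
    lp_arr = cmp_df["lp"].to_numpy()
    id_arr = cmp_df["id"].to_numpy()
    if with_replacement:
        pos = np.searchsorted(lp_arr, exp_df["lp"].to_numpy())
        for eid, lp, k in zip(exp_df["id"].to_numpy(), exp_df["lp"].to_numpy(), pos):
            cands = [j for j in (k - 1, k) if 0 <= j < len(lp_arr)]
            d = min(abs(lp_arr[j] - lp) for j in cands)
            if d > max_dist:
                dropped.append(eid)
                continue
            # comparators at exactly this distance form one or two blocks
            # of equal logit values; smallest subject id wins
            best_id = None
            for j in cands:
                if abs(lp_arr[j] - lp) != d:
                    continue
                a = np.searchsorted(lp_arr, lp_arr[j], side="left")
                b = np.searchsorted(lp_arr, lp_arr[j], side="right")
                cand = id_arr[a:b].min()
                if best_id is None or cand < best_id:
                    best_id = cand
            pairs.append((eid, best_id, float(d)))
    else:
        avail = np.ones(len(cmp_df), dtype=bool)
        for eid, lp in exp_df[["id", "lp"]].to_numpy():
            idx = np.flatnonzero(avail)
            if len(idx) == 0:
                dropped.append(eid)
                continue
            d_all = np.abs(lp_arr[idx] - lp)
            dmin = d_all.min()
            tie = idx[d_all <= dmin + 1e-15]
            best = tie[np.argmin(id_arr[tie])]
            if dmin > max_dist:
                dropped.append(eid)
                continue
            avail[best] = False
            pairs.append((eid, id_arr[best], float(dmin)))
    return MatchResult(
        pairs=pd.DataFrame(pairs, columns=["exposed_id", "comparator_id", "distance"]),
        with_replacement=with_replacement,
        caliper=caliper,
        dropped_exposed=dropped,
    )


# ---------------------------------------------------------------------------
# balance
# ---------------------------------------------------------------------------


def standardized_mean_difference(
    x_a: np.ndarray, x_b: np.ndarray, kind: str = "continuous"
) -> float:
    """Absolute SMD with the pooled-variance denominator.

    Continuous: |m_a - m_b| / sqrt((v_a + v_b) / 2) with sample (ddof=1)
    variances; binary: |p_a - p_b| / sqrt((p_a(1-p_a) + p_b(1-p_b)) / 2).
    Zero pooled variance with unequal means gives +inf.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if len(x_a) == 0 or len(x_b) == 0:
        raise ValueError("both samples must be non-empty")
    if kind == "binary":
        pa, pb = x_a.mean(), x_b.mean()
        denom = np.sqrt((pa * (1 - pa) + pb * (1 - pb)) / 2)
        num = abs(pa - pb)
    else:
        va = x_a.var(ddof=1) if len(x_a) > 1 else 0.0
        vb = x_b.var(ddof=1) if len(x_b) > 1 else 0.0
        denom = np.sqrt((va + vb) / 2)
        num = abs(x_a.mean() - x_b.mean())
    if denom == 0:
        return 0.0 if num == 0 else float("inf")
    return float(num / denom)


def _weighted_smd(x_a, x_b, w_b, kind) -> float:
    """SMD where the comparator sample carries frequency weights."""
    x_b = np.repeat(np.asarray(x_b, dtype=float), np.asarray(w_b, dtype=int))
    return standardized_mean_difference(x_a, x_b, kind)


@dataclass
class BalanceReport:
    table: pd.DataFrame  # covariate, kind, smd_before, smd_after, balanced

    @property
    def passed(self) -> bool:
        return bool(self.table["balanced"].all())


def balance_report(
    cohort: CohortTable, match: MatchResult, covariates: list[str]
) -> BalanceReport:
    """Pre/post-matching SMD per covariate (comparators weighted by reuse)."""
    df = cohort.df.set_index("subject_id")
    exposed = df[df["arm"] == "treated"]
    comparator = df[df["arm"] == "control"]
    matched_exp = df.loc[match.pairs["exposed_id"]]
    use = match.pairs["comparator_id"].value_counts()
    matched_cmp = df.loc[use.index]
    rows = []
    for cov in covariates:
        kind = cohort.schema[cov].kind if cov in cohort.schema else "continuous"
        before = standardized_mean_difference(
            exposed[cov].to_numpy(dtype=float),
            comparator[cov].to_numpy(dtype=float),
            kind,
        )
        after = _weighted_smd(
            matched_exp[cov].to_numpy(dtype=float),
            matched_cmp[cov].to_numpy(dtype=float),
            use.to_numpy(),
            kind,
        )
        rows.append(
            {
                "covariate": cov,
                "kind": kind,
                "smd_before": before,
                "smd_after": after,
                "balanced": after < 0.10,
            }
        )
    table = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["covariate", "kind", "smd_before", "smd_after", "balanced"]
    )
    return BalanceReport(table=table)


# ---------------------------------------------------------------------------
# matched-cohort analysis
# ---------------------------------------------------------------------------


def matched_cohort(cohort: CohortTable, match: MatchResult) -> tuple[CohortTable, np.ndarray]:
    """Matched analysis set: exposed rows + used comparators with weights."""
    df = cohort.df.set_index("subject_id", drop=False)
    exp_rows = df.loc[match.pairs["exposed_id"]]
    use = match.pairs["comparator_id"].value_counts()
    cmp_rows = df.loc[use.index]
    out = pd.concat([exp_rows, cmp_rows], ignore_index=True)
    weights = np.concatenate([np.ones(len(exp_rows)), use.to_numpy(dtype=float)])
    return CohortTable(out, cohort.schema), weights


def comparator_cox(
    cohort: CohortTable,
    match: MatchResult,
    tree: SubgroupTree | None = None,
    adjustments: tuple[str, ...] = (),
    auto_adjust: bool = True,
) -> tuple[dict[str, EffectEstimate | None], dict[str, list[str]]]:
    """Exposure hazard ratios on the matched sets.

    Returns ``(estimates, adjustment_lists)`` where estimates hold the
    overall row (key ``"overall"``) and, when a tree is given, one row
    per subgroup; each subgroup model is automatically re-adjusted for
    covariates with within-subgroup SMD > 0.1 between matched arms.
    Robust (sandwich) variance throughout, since comparator reuse breaks
    independence. When the matched sets pool several sub-studies
    (multiple ``source`` labels, e.g. one per comparator class), an
    indicator for the sub-study enters every model.
    """
    from .benefit import imbalance_adjustments

    mc, w = matched_cohort(cohort, match)
    if tree is not None:
        mc = assign_subgroups(mc, tree)
    df = mc.df
    base: tuple[str, ...] = tuple(adjustments)
    if df["source"].nunique() > 1:
        base = ("@source", *base)

    out: dict[str, EffectEstimate | None] = {}
    adj_used: dict[str, list[str]] = {}
    out["overall"] = weighted_cox_hr(
        mc, weights=w, covariate_adjustments=base, method="matched"
    )
    adj_used["overall"] = list(base)
    if tree is not None:
        for g in sorted(df["subgroup"].unique()):
            mask = (df["subgroup"] == g).to_numpy()
            sub = mc.subset(mask)
            extra: list[str] = []
            if auto_adjust:
                extra = imbalance_adjustments(sub.df, cohort.schema.names, cohort.schema)
            adj = tuple(dict.fromkeys((*base, *extra)))
            adj = tuple(
                c for c in adj if c == "@source" or sub.df[c].std() > 0
            )
            ev = sub.df.groupby(sub.df["arm"] == "treated")["event"].sum()
            if len(ev) < 2 or (ev == 0).any():
                out[g] = None
                adj_used[g] = list(adj)
                continue
            out[g] = weighted_cox_hr(
                sub, weights=w[mask], covariate_adjustments=adj, method="matched"
            )
            adj_used[g] = list(adj)
    return out, adj_used


# ---------------------------------------------------------------------------
# model facade
# ---------------------------------------------------------------------------


@dataclass
class MatchingResults:
    propensity: PropensityModel
    match: MatchResult
    balance: BalanceReport
    effects: dict[str, EffectEstimate | None]
    adjustments: dict[str, list[str]]

    def summary(self) -> pd.DataFrame:
        rows = []
        for g, est in self.effects.items():
            if est is None:
                rows.append({"group": g, "HR": np.nan})
                continue
            lo, hi = est.ci
            rows.append(
                {
                    "group": g,
                    "HR": est.hr,
                    "CI_low": lo,
                    "CI_high": hi,
                    "n": est.n,
                    "events": est.events,
                    "adjusted_for": ",".join(self.adjustments.get(g, [])),
                }
            )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        bal = "balanced" if self.balance.passed else "NOT balanced"
        out = [
            f"Propensity-matched analysis ({len(self.match.pairs)} pairs, "
            f"{bal}: max after-SMD = {self.balance.table['smd_after'].max():.3f})",
            self.summary().to_string(index=False),
        ]
        return "\n".join(out)


class MatchingModel:
    """Propensity matching plus matched-cohort Cox analysis.

    `cohort` holds new users of the exposure (arm ``treated``) and of the
    comparator (arm ``control``) with the modified composite endpoint.
    """

    def __init__(
        self,
        cohort: CohortTable,
        covariates: list[str] | None = None,
        with_replacement: bool = True,
        caliper: float | None = None,
        tree: SubgroupTree | None = None,
        adjustments: tuple[str, ...] = (),
        auto_adjust: bool = True,
    ):
        self.cohort = cohort
        self.covariates = list(covariates) if covariates else cohort.schema.names
        self.with_replacement = with_replacement
        self.caliper = caliper
        self.tree = tree
        self.adjustments = tuple(adjustments)
        self.auto_adjust = auto_adjust

    def fit(self) -> MatchingResults:
        ps = estimate_propensity(self.cohort, self.covariates)
        match = nn_match(
            ps, self.cohort, with_replacement=self.with_replacement, caliper=self.caliper
        )
        balance = balance_report(self.cohort, match, self.covariates)
        effects, adj = comparator_cox(
            self.cohort,
            match,
            tree=self.tree,
            adjustments=self.adjustments,
            auto_adjust=self.auto_adjust,
        )
        return MatchingResults(
            propensity=ps, match=match, balance=balance, effects=effects, adjustments=adj
        )
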