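"""Data-driven discovery of subgroups with heterogeneous treatment benefit.

A concrete instantiation of the stratified-medicine (PRISM-style)
recipe for survival outcomes, in three steps on a 70/30 train/test split
stratified by trial:

1. a multivariable Cox risk model fitted under control conditions,
   providing a prognostic score;
2. an elastic-net-penalized Cox model with unpenalized main effects and
   penalized treatment-by-covariate interaction terms — the magnitude of
   the standardized interaction coefficients at the cross-validated
   penalty ranks candidate effect modifiers;
3. a greedy, depth-limited partition tree on the top-ranked modifiers,
   splitting where the contrast between leaf-wise Cox treatment
   coefficients is largest, which yields labeled subgroups (A, B, C...).

The tree is derived on the training set only; held-out evaluation
re-estimates each leaf's treatment hazard ratio on the test set with a
trial-indicator covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._cox import CoxConvergenceError, cox_fit, cox_loglik
from .cohort import CohortTable
from .effects import EffectEstimate, weighted_cox_hr


# ---------------------------------------------------------------------------
# train/test protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitProtocol:
    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train fraction must be in (0, 1)")


def split_train_test(
    cohorts: CohortTable | list[CohortTable], protocol: SplitProtocol = SplitProtocol()
) -> tuple[CohortTable, CohortTable]:
    """Stratified train/test split: the train fraction is taken per source."""
    if isinstance(cohorts, CohortTable):
        stacked = cohorts
    else:
        schema = cohorts[0].schema
        stacked = CohortTable(
            pd.concat([c.df for c in cohorts], ignore_index=True), schema
        )
    rng = np.random.default_rng(protocol.seed)
    train_mask = np.zeros(stacked.n, dtype=bool)
    for source in stacked.sources:
        idx = np.flatnonzero((stacked.df["source"] == source).to_numpy())
        if len(idx) < 10:
            raise ValueError(f"source {source!r} has fewer than 10 subjects")
        n_train = int(round(protocol.train_fraction * len(idx)))
        chosen = rng.choice(idx, size=n_train, replace=False)
        train_mask[chosen] = True
    return stacked.subset(train_mask), stacked.subset(~train_mask)


# ---------------------------------------------------------------------------
# step 1: control-condition risk model
# ---------------------------------------------------------------------------


@dataclass
class ControlRiskModel:
    covariates: list[str]
    coefs: pd.Series

    def score(self, df: pd.DataFrame) -> np.ndarray:
        """Linear-predictor prognostic score (higher = higher risk)."""
        return df[self.covariates].astype(float).to_numpy() @ self.coefs.to_numpy()


def fit_control_risk_model(
    train: CohortTable, covariates: list[str]
) -> tuple[ControlRiskModel, np.ndarray]:
    """Cox risk model fitted on control-arm subjects only.

    Returns the model and the prognostic score for every training subject
    (both arms).
    """
    ctrl = train.df[train.df["arm"] == "control"]
    if len(ctrl) == 0 or ctrl["event"].sum() == 0:
        raise ValueError("no control-arm events; cannot fit the risk model")
    X = ctrl[covariates].astype(float).to_numpy()
    sd = X.std(axis=0)
    keep = sd > 0
    used = [c for c, k in zip(covariates, keep) if k]
    fit = cox_fit(
        (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep],
        ctrl["time"].to_numpy(dtype=float),
        ctrl["event"].to_numpy(dtype=float),
    )
    coefs = pd.Series(fit.beta / sd[keep], index=used)  # back to raw scale
    model = ControlRiskModel(covariates=used, coefs=coefs)
    return model, model.score(train.df)


# ---------------------------------------------------------------------------
# step 2: elastic-net interaction filter
# ---------------------------------------------------------------------------


@dataclass
class ModifierRanking:
    """Ordered candidate effect modifiers with importance scores."""

    table: pd.DataFrame  # columns: covariate, importance (desc)
    alpha: float
    l1_ratio: float

    @property
    def covariates(self) -> list[str]:
        return self.table["covariate"].tolist()

    def top(self, k: int) -> list[str]:
        return self.covariates[:k]


def _fold_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow partial log-likelihood of a fixed linear predictor."""
    return cox_loglik(np.array([1.0]), lp[:, None], time, event)


def elastic_net_interaction_filter(
    train: CohortTable,
    covariates: list[str],
    l1_ratio: float = 0.5,
    n_alphas: int = 30,
    cv_folds: int = 5,
    seed: int = 0,
    use_risk_score: bool = True,
    one_se_rule: bool = True,
) -> ModifierRanking:
    """Rank treatment-effect modifiers by penalized interaction modelling.

    Fits an elastic-net Cox model whose main effects (treatment, the
    standardized covariates and, optionally, the control-condition
    prognostic score) are unpenalized while the treatment-by-covariate
    interaction terms are penalized. The penalty is chosen by k-fold
    cross-validated partial likelihood with the one-standard-error rule;
    importance is the absolute standardized interaction coefficient at
    that penalty. Ties (e.g. duplicated columns) are broken by covariate
    name, so the ranking is always total.
    """
    from sklearn.model_selection import KFold
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    df = train.df
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=bool)
    treated = (df["arm"] == "treated").to_numpy(dtype=float)
    if treated.std() == 0:
        raise ValueError("no treatment-arm variation in the training set")

    X = df[covariates].astype(float).to_numpy()
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    tc = treated - treated.mean()  # centered to decorrelate from main effects

    blocks = [Z, treated[:, None], tc[:, None] * Z]
    names = (
        [f"main::{c}" for c in covariates]
        + ["main::treated"]
        + [f"int::{c}" for c in covariates]
    )
    penalty = [0.0] * len(covariates) + [0.0] + [1.0] * len(covariates)
    if use_risk_score:
        risk_model, score = fit_control_risk_model(train, covariates)
        s = (score - score.mean()) / max(score.std(), 1e-12)
        blocks.append(s[:, None])
        names.append("main::risk_score")
        penalty.append(0.0)
    D = np.hstack(blocks)
    y = np.empty(len(df), dtype=[("event", bool), ("time", float)])
    y["event"], y["time"] = event, time

    base = CoxnetSurvivalAnalysis(
        l1_ratio=l1_ratio,
        n_alphas=n_alphas,
        alpha_min_ratio=0.01,
        penalty_factor=np.asarray(penalty),
        max_iter=200000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base.fit(D, y)
    alphas = np.asarray(base.alphas_)

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_ll = np.zeros((cv_folds, len(alphas)))
    for k, (tr_idx, va_idx) in enumerate(kf.split(D)):
        m = CoxnetSurvivalAnalysis(
            l1_ratio=l1_ratio,
            alphas=alphas,
            penalty_factor=np.asarray(penalty),
            max_iter=200000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(D[tr_idx], y[tr_idx])
        # index by the base path's alphas: the fold model may keep its own
        # (slightly different) alpha list, so predict at explicit alphas
        for j, a in enumerate(alphas):
            lp = m.predict(D[va_idx], alpha=a)
            cv_ll[k, j] = _fold_loglik(np.asarray(lp), time[va_idx], event[va_idx].astype(float))
    mean_ll = cv_ll.mean(axis=0)
    best = int(np.argmax(mean_ll))
    if one_se_rule:
        # fold-level likelihood levels vary far more than the alpha
        # contrast, so all comparisons are paired within folds. Two steps:
        # (1) a gate against the all-interactions-zero model — the best
        # alpha must beat the strongest penalty by 2 paired SEs (argmax
        # selection inflates the apparent gain, hence 2 rather than 1);
        # (2) among qualifying alphas, the usual one-SE rule vs the best.
        gain = cv_ll - cv_ll[:, [0]]
        mean_gain = gain.mean(axis=0)
        se_gain = gain.std(axis=0, ddof=1) / np.sqrt(cv_folds)
        if best == 0 or mean_gain[best] <= 2 * se_gain[best]:
            chosen = 0
        else:
            deficit = cv_ll[:, best][:, None] - cv_ll
            mean_def = deficit.mean(axis=0)
            se_def = deficit.std(axis=0, ddof=1) / np.sqrt(cv_folds)
            ok = np.flatnonzero(mean_def <= se_def + 1e-12)
            chosen = int(ok[0])  # alphas_ descend: first = strongest penalty
    else:
        chosen = best
    alpha = float(alphas[chosen])

    coefs = pd.Series(base.coef_[:, chosen], index=names)
    imp = coefs[[n for n in names if n.startswith("int::")]].abs()
    imp.index = [n.split("::", 1)[1] for n in imp.index]
    table = (
        imp.rename("importance")
        .reset_index()
        .rename(columns={"index": "covariate"})
        .sort_values(["importance", "covariate"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    return ModifierRanking(table=table, alpha=alpha, l1_ratio=l1_ratio)


# ---------------------------------------------------------------------------
# step 3: partition tree
# ---------------------------------------------------------------------------


@dataclass
class SplitRule:
    covariate: str
    operator: str  # ">" (continuous) or "==" (binary; value 1)
    threshold: float

    def apply(self, df: pd.DataFrame) -> np.ndarray:
        x = df[self.covariate].to_numpy(dtype=float)
        return x > self.threshold if self.operator == ">" else x == self.threshold

    def __str__(self) -> str:
        if self.operator == "==":
            return f"{self.covariate} == {int(self.threshold)}"
        return f"{self.covariate} > {self.threshold:g}"


@dataclass
class TreeNode:
    rule: SplitRule | None = None
    yes: "TreeNode | None" = None
    no: "TreeNode | None" = None
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.rule is None


@dataclass
class SubgroupTree:
    """Ordered splitting rules partitioning any cohort into labeled leaves."""

    root: TreeNode
    max_depth: int

    def assign(self, df: pd.DataFrame) -> np.ndarray:
        labels = np.empty(len(df), dtype=object)

        def walk(node: TreeNode, mask: np.ndarray) -> None:
            if node.is_leaf:
                labels[mask] = node.label
                return
            hit = np.zeros(len(df), dtype=bool)
            hit[mask] = node.rule.apply(df.loc[mask])
            walk(node.yes, hit)
            walk(node.no, mask & ~hit)

        walk(self.root, np.ones(len(df), dtype=bool))
        return labels

    @property
    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.yes)
                walk(node.no)

        walk(self.root)
        return out

    @property
    def split_covariates(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                out.append(node.rule.covariate)
                walk(node.yes)
                walk(node.no)

        walk(self.root)
        return out

    def to_text(self, node: TreeNode | None = None, indent: int = 0) -> str:
        node = node or self.root
        pad = "  " * indent
        if node.is_leaf:
            return f"{pad}leaf {node.label}\n"
        out = f"{pad}if {node.rule}:\n"
        out += self.to_text(node.yes, indent + 1)
        out += f"{pad}else:\n"
        out += self.to_text(node.no, indent + 1)
        return out


def _arm_event_ok(df: pd.DataFrame) -> bool:
    g = df.groupby(df["arm"] == "treated")["event"].sum()
    return len(g) == 2 and (g > 0).all()


def _treatment_coef(df: pd.DataFrame) -> tuple[float, float]:
    x = (df["arm"] == "treated").to_numpy(dtype=float)[:, None]
    fit = cox_fit(x, df["time"].to_numpy(dtype=float), df["event"].to_numpy(dtype=float))
    return float(fit.beta[0]), float(fit.se[0])


def derive_subgroup_tree(
    train: CohortTable,
    ranking: ModifierRanking,
    max_depth: int = 2,
    min_leaf: int = 200,
    n_modifiers: int = 2,
    z_threshold: float = 0.0,
    quantile_grid: tuple[int, int, int] = (10, 90, 5),
    lookahead: bool = True,
) -> SubgroupTree:
    """Greedy benefit-contrast partition on the top-ranked modifiers.

    At each node, every candidate modifier (binary: the 0/1 split;
    continuous: thresholds on the percentile grid of the node's data) is
    scored by the z-statistic of the difference between the two children's
    Cox treatment coefficients. With `lookahead` (default), a split one
    level above the maximum depth is scored by the best z achievable at
    either itself or its children — without this a partition whose first
    split carries no marginal contrast (e.g. a prior-event split whose
    benefit heterogeneity only appears one level down) is never found.
    Both children must satisfy `min_leaf` and have events in both arms;
    ties break on covariate name, then smaller threshold. Splitting stops
    when no candidate clears `z_threshold`; the substantive null gate is
    upstream — a modifier only becomes a candidate if its elastic-net
    importance is positive, so a null ranking yields a single-leaf tree.
    """
    if ranking.table.empty:
        raise ValueError("empty modifier ranking")
    imp = ranking.table.set_index("covariate")["importance"]
    candidates = [c for c in ranking.covariates[:n_modifiers] if imp[c] > 0]
    lo, hi, step = quantile_grid
    df = train.df

    def is_binary(cov: str) -> bool:
        return cov in train.schema and train.schema[cov].kind == "binary"

    def iter_candidates(node_df: pd.DataFrame):
        for cov in candidates:
            x = node_df[cov].to_numpy(dtype=float)
            if is_binary(cov):
                if len(np.unique(x)) > 1:
                    yield cov, "==", 1.0, (x == 1.0)
            else:
                qs = np.percentile(x, np.arange(lo, hi + 1, step))
                for thr in sorted(set(np.round(qs, 6))):
                    yield cov, ">", float(thr), (x > thr)

    def split_z(yes_df: pd.DataFrame, no_df: pd.DataFrame) -> float | None:
        if len(yes_df) < min_leaf or len(no_df) < min_leaf:
            return None
        if not (_arm_event_ok(yes_df) and _arm_event_ok(no_df)):
            return None
        try:
            b1, s1 = _treatment_coef(yes_df)
            b2, s2 = _treatment_coef(no_df)
        except CoxConvergenceError:
            return None
        return abs(b1 - b2) / np.sqrt(s1**2 + s2**2)

    def best_z(node_df: pd.DataFrame) -> float:
        out = -np.inf
        for _, _, _, mask in iter_candidates(node_df):
            z = split_z(node_df[mask], node_df[~mask])
            if z is not None and z > out:
                out = z
        return out

    def best_split(node_df: pd.DataFrame, depth: int) -> SplitRule | None:
        best: tuple[float, str, float] | None = None  # (score, covariate, threshold)
        for cov, op, thr, mask in iter_candidates(node_df):
            yes_df, no_df = node_df[mask], node_df[~mask]
            z = split_z(yes_df, no_df)
            if z is None:
                continue
            score = z
            if lookahead and depth + 2 <= max_depth:
                score = max(score, best_z(yes_df), best_z(no_df))
            better = best is None or score > best[0] + 1e-12 or (
                abs(score - best[0]) <= 1e-12 and (cov, thr) < (best[1], best[2])
            )
            if better:
                best = (score, cov, thr)
        if best is None or best[0] < z_threshold:
            return None
        _, cov, thr = best
        return SplitRule(cov, "==" if is_binary(cov) else ">", thr)

    def grow(node_df: pd.DataFrame, depth: int) -> TreeNode:
        if depth >= max_depth:
            return TreeNode()
        rule = best_split(node_df, depth)
        if rule is None:
            return TreeNode()
        mask = rule.apply(node_df)
        return TreeNode(
            rule=rule,
            yes=grow(node_df[mask], depth + 1),
            no=grow(node_df[~mask], depth + 1),
        )

    root = grow(df, 0)
    tree = SubgroupTree(root=root, max_depth=max_depth)
    _label_leaves(tree, df, train.schema)
    if root.is_leaf:
        warnings.warn("no admissible split; returning a single-leaf tree")
    return tree


def _label_leaves(tree: SubgroupTree, df: pd.DataFrame, schema) -> None:
    """Deterministic leaf labels: the prior-event branch (a binary root
    split) is labeled first, remaining leaves by descending control-arm
    event risk."""
    # temporarily label leaves by position to compute per-leaf risk
    leaves = tree.leaves
    for i, leaf in enumerate(leaves):
        leaf.label = f"__tmp{i}"
    if len(leaves) == 1:
        leaves[0].label = "A"
        return
    lab = tree.assign(df)
    risk: dict[str, float] = {}
    for i, leaf in enumerate(leaves):
        sub = df[(lab == leaf.label) & (df["arm"] == "control")]
        risk[leaf.label] = float(sub["event"].mean()) if len(sub) else 0.0
    ordered: list[TreeNode] = []
    root = tree.root
    if (
        root.rule is not None
        and root.rule.operator == "=="
        and root.yes.is_leaf
    ):
        ordered.append(root.yes)
    rest = [lf for lf in leaves if lf not in ordered]
    rest.sort(key=lambda lf: -risk[lf.label])
    ordered.extend(rest)
    for letter, leaf in zip("ABCDEFGH", ordered):
        leaf.label = letter


def assign_subgroups(cohort: CohortTable, tree: SubgroupTree) -> CohortTable:
    """Attach the tree's leaf label to every subject (column ``subgroup``)."""
    missing = [c for c in tree.split_covariates if c not in cohort.df.columns]
    if missing:
        raise ValueError(f"cohort lacks covariates used by the tree: {missing}")
    df = cohort.df.copy()
    df["subgroup"] = tree.assign(df)
    return CohortTable(df, cohort.schema)


def subgroup_proportions(cohort: CohortTable, tree: SubgroupTree) -> pd.Series:
    labeled = assign_subgroups(cohort, tree)
    return labeled.df["subgroup"].value_counts(normalize=True).sort_index()


def evaluate_subgroups(
    test: CohortTable,
    tree: SubgroupTree,
    trial_indicator: bool = True,
) -> dict[str, EffectEstimate | None]:
    """Per-leaf treatment HR on held-out data (trial indicator included).

    A leaf with no events in one of the arms is reported as ``None``
    rather than a numeric estimate.
    """
    labeled = assign_subgroups(test, tree)
    df = labeled.df
    sources = sorted(df["source"].unique())
    out: dict[str, EffectEstimate | None] = {}
    for label in sorted(df["subgroup"].unique()):
        sub = labeled.subset((df["subgroup"] == label).to_numpy())
        if not _arm_event_ok(sub.df):
            out[label] = None
            continue
        adjustments: tuple[str, ...] = ()
        frame = sub
        if trial_indicator and len(sources) > 1:
            tmp = sub.df.copy()
            ind_cols = []
            for s in sources[1:]:
                col = f"_src_{s}"
                tmp[col] = (tmp["source"] == s).astype(float)
                ind_cols.append(col)
            est = _cox_with_extra(tmp, ind_cols)
        else:
            est = weighted_cox_hr(frame)
        out[label] = est
    return out


def _cox_with_extra(df: pd.DataFrame, extra: list[str]) -> EffectEstimate:
    from lifelines import CoxPHFitter

    d = pd.DataFrame(
        {
            "time": df["time"].astype(float),
            "event": df["event"].astype(int),
            "treated": (df["arm"] == "treated").astype(int),
        }
    )
    for c in extra:
        d[c] = df[c].to_numpy(dtype=float)
        if d[c].std() == 0:
            d = d.drop(columns=[c])
    cph = CoxPHFitter().fit(d, duration_col="time", event_col="event", fit_options={"precision": 1e-9})
    return EffectEstimate(
        loghr=float(cph.params_["treated"]),
        se=float(cph.standard_errors_["treated"]),
        n=len(d),
        events=int(d["event"].sum()),
        method="unweighted",
    )


# ---------------------------------------------------------------------------
# model facade
# ---------------------------------------------------------------------------


@dataclass
class SubgroupDiscoveryResults:
    ranking: ModifierRanking
    tree: SubgroupTree
    train_estimates: dict[str, EffectEstimate | None]
    test_estimates: dict[str, EffectEstimate | None]
    proportions: pd.DataFrame  # per source x subgroup
    risk_model: ControlRiskModel

    def summary(self) -> pd.DataFrame:
        rows = []
        for setname, ests in (("train", self.train_estimates), ("test", self.test_estimates)):
            for label, est in sorted(ests.items()):
                if est is None:
                    rows.append({"set": setname, "subgroup": label, "HR": np.nan})
                    continue
                lo, hi = est.ci
                rows.append(
                    {
                        "set": setname,
                        "subgroup": label,
                        "HR": est.hr,
                        "CI_low": lo,
                        "CI_high": hi,
                        "n": est.n,
                        "events": est.events,
                    }
                )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        out = ["Subgroup discovery", self.tree.to_text().rstrip()]
        out.append(self.summary().to_string(index=False))
        return "\n".join(out)


class SubgroupDiscoveryModel:
    """End-to-end subgroup discovery on one or more trial cohorts.

    70/30 stratified split, control-risk model, elastic-net interaction
    filter, benefit-contrast tree, and held-out per-leaf effect
    estimates; optionally reports the subgroup mix of additional
    covariates-only cohorts (e.g. the real-world target population).
    """

    def __init__(
        self,
        trials: CohortTable | list[CohortTable],
        covariates: list[str] | None = None,
        protocol: SplitProtocol | None = None,
        max_depth: int = 2,
        min_leaf: int = 200,
        n_modifiers: int = 2,
        z_threshold: float = 1.96,
        enet_settings: dict | None = None,
        extra_cohorts: dict[str, CohortTable] | None = None,
    ):
        self.trials = trials
        first = trials[0] if isinstance(trials, list) else trials
        self.covariates = list(covariates) if covariates else first.schema.names
        self.protocol = protocol
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.n_modifiers = n_modifiers
        self.z_threshold = z_threshold
        self.enet_settings = dict(enet_settings or {})
        self.extra_cohorts = dict(extra_cohorts or {})

    def fit(self, seed: int = 0) -> SubgroupDiscoveryResults:
        protocol = self.protocol or SplitProtocol(seed=seed)
        train, test = split_train_test(self.trials, protocol)
        risk_model, _ = fit_control_risk_model(train, self.covariates)
        ranking = elastic_net_interaction_filter(
            train, self.covariates, seed=seed, **self.enet_settings
        )
        tree = derive_subgroup_tree(
            train,
            ranking,
            max_depth=self.max_depth,
            min_leaf=self.min_leaf,
            n_modifiers=self.n_modifiers,
            z_threshold=self.z_threshold,
        )
        train_ests = evaluate_subgroups(train, tree)
        test_ests = evaluate_subgroups(test, tree)
        prop_rows = {}
        full = CohortTable(
            pd.concat(
                [c.df for c in (self.trials if isinstance(self.trials, list) else [self.trials])],
                ignore_index=True,
            ),
            train.schema,
        )
        prop_rows["trials"] = subgroup_proportions(full, tree)
        for name, cohort in self.extra_cohorts.items():
            prop_rows[name] = subgroup_proportions(cohort, tree)
        proportions = pd.DataFrame(prop_rows).T.fillna(0.0)
        return SubgroupDiscoveryResults(
            ranking=ranking,
            tree=tree,
            train_estimates=train_ests,
            test_estimates=test_ests,
            proportions=proportions,
            risk_model=risk_model,
        )
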