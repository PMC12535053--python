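"""Train/test protocol, interaction filter, partition tree, evaluation."""

import numpy as np
import pandas as pd
import pytest

from cvtransport import (
    CohortTable,
    ModifierRanking,
    OutcomeSpec,
    ScenarioSpec,
    SourceSpec,
    SplitProtocol,
    assign_subgroups,
    assign_treatment,
    default_schema,
    derive_subgroup_tree,
    elastic_net_interaction_filter,
    evaluate_subgroups,
    fit_control_risk_model,
    generate_covariates,
    generate_scenario,
    simulate_survival,
    split_train_test,
)
from cvtransport.subgroups import SplitRule, SubgroupTree, TreeNode, _label_leaves


def _strong_modifier_spec(n=6000, seed=0, beta_prior=-1.2, beta_age=-0.08):
    """Clean generator: interactions only on prior_mi_stroke and age,
    sized to be clearly detectable (this validates the machinery, not the
    statistical power at any particular field-realistic effect size)."""
    return ScenarioSpec(
        sources={
            "trial_1": SourceSpec(
                n=n,
                continuous={
                    "age": (65.0, 9.0),
                    "bmi": (30.0, 4.0),
                    "hba1c": (8.0, 1.2),
                    "diabetes_duration": (11.0, 5.0),
                    "egfr": (80.0, 15.0),
                },
                binary={name: 0.4 for name in default_schema().binary},
                baseline_rate=0.06,
                horizon=4.0,
                dropout_rate=0.0,
            )
        },
        outcome=OutcomeSpec(
            treatment_loghr=-0.1,
            effect_modifiers=(
                ("prior_mi_stroke == 1", beta_prior),
                ("age > 65", beta_age * 10),
            ),
        ),
        seed=seed,
    )


def _simulate(spec, seed):
    c = generate_covariates(spec, "trial_1", seed=seed)
    c = assign_treatment(c, "randomized", seed=seed)
    return simulate_survival(c, spec, seed=seed)


def _canonical_tree(df, schema):
    root = TreeNode(
        rule=SplitRule("prior_mi_stroke", "==", 1.0),
        yes=TreeNode(),
        no=TreeNode(rule=SplitRule("age", ">", 71.0), yes=TreeNode(), no=TreeNode()),
    )
    tree = SubgroupTree(root=root, max_depth=2)
    _label_leaves(tree, df, schema)
    return tree


class TestSplit:
    def _two_sources(self, schema, n1=1000, n2=300):
        rows = []
        for src, n in (("trial_1", n1), ("trial_2", n2)):
            df = pd.DataFrame(
                {
                    "subject_id": [f"{src}-{i}" for i in range(n)],
                    "source": src,
                    "arm": (["treated", "control"] * n)[:n],
                    "time": np.linspace(0.5, 4, n),
                    "event": ([0, 1] * n)[:n],
                }
            )
            for cov in schema.names:
                spec = schema[cov]
                df[cov] = 0.0 if spec.kind == "binary" else min(max(50.0, spec.lo), spec.hi)
            rows.append(df)
        return CohortTable(pd.concat(rows, ignore_index=True), schema)

    def test_seventy_thirty_arithmetic(self, schema):
        stacked = self._two_sources(schema)
        train, test = split_train_test(stacked, SplitProtocol(seed=0))
        tr = train.df["source"].value_counts()
        te = test.df["source"].value_counts()
        assert abs(tr["trial_1"] - 700) <= 1 and abs(tr["trial_2"] - 210) <= 1
        assert abs(te["trial_1"] - 300) <= 1 and abs(te["trial_2"] - 90) <= 1

    def test_partition_property_and_determinism(self, schema):
        stacked = self._two_sources(schema)
        t1 = split_train_test(stacked, SplitProtocol(seed=5))
        t2 = split_train_test(stacked, SplitProtocol(seed=5))
        ids = lambda c: set(c.df["subject_id"])
        assert ids(t1[0]) == ids(t2[0])
        assert ids(t1[0]) | ids(t1[1]) == ids(stacked)
        assert ids(t1[0]) & ids(t1[1]) == set()

    def test_small_source_rejected(self, schema):
        stacked = self._two_sources(schema, n1=100, n2=5)
        with pytest.raises(ValueError, match="fewer than 10"):
            split_train_test(stacked, SplitProtocol(seed=0))


class TestControlRiskModel:
    def test_strong_risk_covariate_sign(self):
        spec = ScenarioSpec(
            sources=_strong_modifier_spec(n=8000).sources,
            outcome=OutcomeSpec(covariate_coefs={"heart_failure": 1.0}),
            seed=2,
        )
        cohort = _simulate(spec, 2)
        model, scores = fit_control_risk_model(cohort, ["heart_failure", "bmi"])
        assert model.coefs["heart_failure"] > 0.5
        assert len(scores) == cohort.n

    def test_score_ranking_invariant_to_covariate_shift(self):
        spec = _strong_modifier_spec(n=2000, seed=3)
        cohort = _simulate(spec, 3)
        model, scores = fit_control_risk_model(cohort, ["age", "bmi"])
        shifted = cohort.df.copy()
        shifted["age"] = shifted["age"] + 5.0
        s2 = model.score(shifted)
        assert (np.argsort(scores) == np.argsort(s2)).all()

    def test_no_control_events_raises(self, toy_survival_cohort):
        df = toy_survival_cohort.df.copy()
        df.loc[df["arm"] == "control", "event"] = 0
        with pytest.raises(ValueError, match="control"):
            fit_control_risk_model(CohortTable(df, toy_survival_cohort.schema), ["age"])


class TestElasticNetFilter:
    def test_recovers_strong_clean_modifiers(self):
        hits = 0
        for r in range(6):
            spec = _strong_modifier_spec(n=6000, seed=100 + r)
            cohort = _simulate(spec, 100 + r)
            rank = elastic_net_interaction_filter(
                cohort, cohort.schema.names, seed=r
            )
            if set(rank.top(2)) == {"prior_mi_stroke", "age"}:
                hits += 1
        assert hits >= 5

    def test_null_generator_shrinks_everything(self):
        all_zero = 0
        for r in range(5):
            spec = ScenarioSpec(
                sources=_strong_modifier_spec(n=5000).sources,
                outcome=OutcomeSpec(treatment_loghr=-0.1),
                seed=200 + r,
            )
            cohort = _simulate(spec, 200 + r)
            rank = elastic_net_interaction_filter(cohort, cohort.schema.names, seed=r)
            if (rank.table["importance"] == 0).all():
                all_zero += 1
        assert all_zero >= 3

    def test_ranking_is_total_with_ties(self):
        spec = _strong_modifier_spec(n=3000, seed=5)
        cohort = _simulate(spec, 5)
        rank = elastic_net_interaction_filter(cohort, cohort.schema.names, seed=5)
        assert len(rank.covariates) == len(set(rank.covariates))
        imp = rank.table["importance"].to_numpy()
        assert (np.diff(imp) <= 1e-15).all()  # sorted descending


class TestTree:
    def test_max_depth_zero_single_leaf(self):
        spec = _strong_modifier_spec(n=2000, seed=6)
        cohort = _simulate(spec, 6)
        rank = ModifierRanking(
            table=pd.DataFrame(
                {"covariate": ["prior_mi_stroke"], "importance": [1.0]}
            ),
            alpha=0.1,
            l1_ratio=0.5,
        )
        tree = derive_subgroup_tree(cohort, rank, max_depth=0)
        assert len(tree.leaves) == 1

    def test_zero_importance_candidates_yield_single_leaf(self):
        spec = _strong_modifier_spec(n=2000, seed=7)
        cohort = _simulate(spec, 7)
        rank = ModifierRanking(
            table=pd.DataFrame({"covariate": ["age"], "importance": [0.0]}),
            alpha=0.1,
            l1_ratio=0.5,
        )
        with pytest.warns(UserWarning, match="no admissible split"):
            tree = derive_subgroup_tree(cohort, rank)
        assert len(tree.leaves) == 1

    def test_recovers_strong_clean_structure(self):
        recovered = 0
        for r in range(4):
            spec = _strong_modifier_spec(n=8000, seed=300 + r, beta_prior=-1.2, beta_age=-0.08)
            cohort = _simulate(spec, 300 + r)
            rank = ModifierRanking(
                table=pd.DataFrame(
                    {"covariate": ["prior_mi_stroke", "age"], "importance": [1.0, 0.8]}
                ),
                alpha=0.1,
                l1_ratio=0.5,
            )
            tree = derive_subgroup_tree(cohort, rank)
            if set(tree.split_covariates) == {"prior_mi_stroke", "age"}:
                recovered += 1
        assert recovered >= 3


class TestAssignment:
    def test_rule_structure_mapping(self, schema):
        # prior event -> A; no prior event, age 75 -> B; age exactly 71 -> C
        df = pd.DataFrame(
            {
                "subject_id": ["x1", "x2", "x3"],
                "source": "target",
                "arm": "none",
            }
        )
        for cov in schema.names:
            spec = schema[cov]
            df[cov] = 0.0 if spec.kind == "binary" else min(max(50.0, spec.lo), spec.hi)
        df["age"] = [75.0, 40.0, 71.0]
        df["prior_mi_stroke"] = [0, 1, 0]
        cohort = CohortTable(df, schema)
        tree = _canonical_tree(_label_frame(schema), schema)
        labeled = assign_subgroups(cohort, tree)
        assert list(labeled.df["subgroup"]) == ["B", "A", "C"]

    def test_missing_covariate_errors(self, tiny_schema, covariate_cohort, schema):
        tree = _canonical_tree(_label_frame(schema), schema)
        bad = covariate_cohort.df.drop(columns=["age"])
        bad["age"] = np.nan  # column exists but tree needs real values
        with pytest.raises(Exception):
            assign_subgroups(
                CohortTable(bad.drop(columns=["age"]), covariate_cohort.schema), tree
            )


def _label_frame(schema):
    """Training-like frame giving the canonical risk ordering A > B > C."""
    n = 600
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "subject_id": [f"l{i}" for i in range(n)],
            "source": "trial_1",
            "arm": (["treated", "control"] * n)[:n],
        }
    )
    for cov in schema.names:
        spec = schema[cov]
        df[cov] = 0.0 if spec.kind == "binary" else min(max(50.0, spec.lo), spec.hi)
    df["prior_mi_stroke"] = (rng.random(n) < 0.5).astype(int)
    df["age"] = rng.uniform(50, 90, n)
    risk = np.where(df.prior_mi_stroke == 1, 0.5, np.where(df.age > 71, 0.3, 0.1))
    df["event"] = (rng.random(n) < risk).astype(int)
    df["time"] = rng.uniform(0.5, 4, n)
    return df


class TestEvaluation:
    def test_heterogeneous_effects_recovered_on_test_set(self):
        # single-replicate group-B estimates carry SE ~ 0.2-0.3 on the log
        # scale, so recovery is asserted on the replicate-averaged log HR
        logs = {"A": [], "B": [], "C": []}
        for seed in range(420, 428):
            b = generate_scenario(
                "shifted_subgroups", seed=seed, n_trial=13000, n_target=200, n_rw=200
            )
            train, test = split_train_test(b.trial, SplitProtocol(seed=seed))
            tree = _canonical_tree(train.df, b.spec.schema)
            ests = evaluate_subgroups(test, tree)
            assert set(ests) == {"A", "B", "C"}
            for g in logs:
                logs[g].append(ests[g].loghr)
        means = {g: np.exp(np.mean(v)) for g, v in logs.items()}
        assert means["B"] < means["A"] < means["C"]
        assert means["B"] == pytest.approx(0.55, abs=0.12)
        assert means["A"] == pytest.approx(0.85, abs=0.10)

    def test_leaf_without_treated_events_flagged(self, schema):
        df = _label_frame(schema)
        df.loc[(df.prior_mi_stroke == 1) & (df.arm == "treated"), "event"] = 0
        tree = _canonical_tree(df, schema)
        ests = evaluate_subgroups(CohortTable(df, schema), tree)
        assert ests["A"] is None
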