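"""Membership models, inverse odds weights, ESS, weighted Cox transport."""

import numpy as np
import pandas as pd
import pytest

from conftest import cox_mle_oracle, logistic_mle_oracle
from cvtransport import (
    CohortTable,
    SeparationError,
    TranspositionModel,
    effective_sample_size,
    fit_membership_bn,
    fit_membership_lr,
    generate_scenario,
    inverse_odds_weights,
    weight_treatment_interaction,
    weighted_cox_hr,
)
from cvtransport.bayesnet import learn_structure


def _cohort(tiny_schema, source, age, prior, arm=None, time=None, event=None):
    n = len(age)
    df = pd.DataFrame(
        {
            "subject_id": [f"{source}{i}" for i in range(n)],
            "source": source,
            "arm": arm if arm is not None else "none",
            "age": age,
            "prior_mi_stroke": prior,
        }
    )
    if time is not None:
        df["time"] = time
        df["event"] = event
    return CohortTable(df, tiny_schema)


class TestMembershipLR:
    def test_no_signal_gives_trial_fraction(self, tiny_schema):
        rng = np.random.default_rng(0)
        age_t = np.clip(65 + 5 * rng.standard_normal(3000), 18, 110)
        age_g = np.clip(65 + 5 * rng.standard_normal(6000), 18, 110)
        trial = _cohort(tiny_schema, "trial_1", age_t, rng.integers(0, 2, 3000))
        target = _cohort(tiny_schema, "target", age_g, rng.integers(0, 2, 6000))
        m = fit_membership_lr(trial, target, ["age", "prior_mi_stroke"])
        assert np.abs(m.params[["age", "prior_mi_stroke"]]).max() < 0.1
        assert m.trial_probabilities.mean() == pytest.approx(1 / 3, abs=0.02)

    def test_toy_matches_bruteforce_mle(self, tiny_schema):
        # 6-row stacked toy, single covariate, overlapping supports
        trial = _cohort(tiny_schema, "trial_1", [55.0, 60.0, 66.0], [0, 0, 0])
        target = _cohort(tiny_schema, "target", [58.0, 68.0, 75.0], [0, 0, 0])
        m = fit_membership_lr(trial, target, ["age"])
        X = np.array([[55.0], [60.0], [66.0], [58.0], [68.0], [75.0]])
        y = np.array([1, 1, 1, 0, 0, 0.0])
        const, coefs = logistic_mle_oracle(X, y)
        assert m.params["const"] == pytest.approx(const, abs=1e-5)
        assert m.params["age"] == pytest.approx(coefs[0], abs=1e-6)

    def test_shifted_target_age_sign(self, tiny_schema):
        rng = np.random.default_rng(1)
        age_t = np.clip(60 + 5 * rng.standard_normal(4000), 18, 100)
        trial = _cohort(tiny_schema, "trial_1", age_t, rng.integers(0, 2, 4000))
        target = _cohort(tiny_schema, "target", age_t + 10, rng.integers(0, 2, 4000))
        m = fit_membership_lr(trial, target, ["age"])
        assert m.params["age"] < 0  # trial is younger: membership falls with age

    def test_separation_names_covariate(self, tiny_schema):
        trial = _cohort(tiny_schema, "trial_1", [50.0, 55.0], [0, 0])
        target = _cohort(tiny_schema, "target", [70.0, 75.0], [0, 0])
        with pytest.raises(SeparationError, match="age"):
            fit_membership_lr(trial, target, ["age"])


class TestMembershipBN:
    def test_independence_gives_marginal_fraction(self, tiny_schema):
        rng = np.random.default_rng(2)
        mk = lambda src, n: _cohort(
            tiny_schema,
            src,
            np.clip(65 + 5 * rng.standard_normal(n), 18, 110),
            rng.integers(0, 2, n),
        )
        trial, target = mk("trial_1", 2000), mk("target", 4000)
        m = fit_membership_bn(trial, target, ["age", "prior_mi_stroke"], seed=0)
        assert np.abs(m.trial_probabilities - 1 / 3).max() < 0.06

    def test_recovers_exact_bayes_on_known_network(self, tiny_schema):
        # generator: S ~ Bern(0.5); X1 | S with P(X1=1|S=1)=0.8, P(X1=1|S=0)=0.3;
        # X2 | X1 with P(X2=1|X1=1)=0.7, P(X2=1|X1=0)=0.2  (X2 independent of S | X1)
        rng = np.random.default_rng(3)
        n = 20000
        s = rng.random(n) < 0.5
        x1 = rng.random(n) < np.where(s, 0.8, 0.3)
        x2 = rng.random(n) < np.where(x1, 0.7, 0.2)
        df = pd.DataFrame({"prior_mi_stroke": x1.astype(int), "age": np.where(x2, 80.0, 50.0)})
        trial = _cohort(tiny_schema, "trial_1", df["age"][s].to_numpy(), df["prior_mi_stroke"][s].to_numpy())
        target = _cohort(tiny_schema, "target", df["age"][~s].to_numpy(), df["prior_mi_stroke"][~s].to_numpy())
        m = fit_membership_bn(trial, target, ["prior_mi_stroke", "age"], seed=1)
        # exact posterior: P(S=1 | X1) = P(X1|S=1) / (P(X1|S=1)+P(X1|S=0))
        exact = {1: 0.8 / 1.1, 0: 0.2 / 0.9}
        x1_trial = trial.df["prior_mi_stroke"].to_numpy()
        for v in (0, 1):
            got = m.trial_probabilities[x1_trial == v].mean()
            assert got == pytest.approx(exact[v], abs=0.02)

    def test_structure_deterministic_given_seed(self, tiny_schema):
        rng = np.random.default_rng(4)
        mk = lambda src, n: _cohort(
            tiny_schema,
            src,
            np.clip(65 + 5 * rng.standard_normal(n), 18, 110),
            rng.integers(0, 2, n),
        )
        trial, target = mk("trial_1", 1500), mk("target", 1500)
        m1 = fit_membership_bn(trial, target, ["age", "prior_mi_stroke"], seed=7)
        m2 = fit_membership_bn(trial, target, ["age", "prior_mi_stroke"], seed=7)
        assert m1.edges == m2.edges
        np.testing.assert_array_equal(m1.trial_probabilities, m2.trial_probabilities)

    def test_single_level_node_rejected(self):
        coded = pd.DataFrame({"a": [0, 0, 0, 0], "b": [0, 1, 0, 1]})
        with pytest.raises(ValueError, match="single observed level"):
            learn_structure(coded)


class TestWeights:
    def test_inverse_odds_formula(self, tiny_schema, covariate_cohort):
        from cvtransport.transport import MembershipModel

        trial = _cohort(tiny_schema, "trial_1", [60.0, 61.0, 62.0], [0, 1, 0])
        m = MembershipModel(
            method="LR",
            covariates=["age"],
            trial_fraction=0.5,
            params=pd.Series({"const": 0.0, "age": 0.0}),
            trial_probabilities=np.array([0.5, 0.25, 0.8]),
        )
        ws = inverse_odds_weights(m, trial, clip=None)
        np.testing.assert_allclose(ws.weights, [1.0, 3.0, 0.25])

    def test_boundary_probability_hard_error_without_clip(self, tiny_schema):
        from cvtransport.transport import MembershipModel

        trial = _cohort(tiny_schema, "trial_1", [60.0, 61.0], [0, 1])
        m = MembershipModel(
            method="LR",
            covariates=["age"],
            trial_fraction=0.5,
            params=None,
            trial_probabilities=np.array([1.0, 0.5]),
        )
        with pytest.raises(ValueError, match="clipping"):
            inverse_odds_weights(m, trial, clip=None)
        ws = inverse_odds_weights(m, trial, clip=(0.005, 0.995))
        assert ws.n_clipped == 1

    @pytest.mark.parametrize(
        "w, expected",
        [([2.0] * 5, 5.0), ([1.0, 3.0], 1.6), ([1.0, 1.0, 2.0], 16 / 6)],
    )
    def test_kish_ess(self, w, expected):
        assert effective_sample_size(np.array(w)) == pytest.approx(expected)

    def test_ess_empty_raises(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.array([]))


class TestWeightedCox:
    def test_unit_weights_equal_unweighted(self, toy_survival_cohort):
        unw = weighted_cox_hr(toy_survival_cohort)
        w = weighted_cox_hr(toy_survival_cohort, weights=np.ones(8))
        assert w.loghr == pytest.approx(unw.loghr, abs=1e-8)

    def test_toy_matches_bruteforce_partial_likelihood(self, toy_survival_cohort):
        est = weighted_cox_hr(toy_survival_cohort)
        df = toy_survival_cohort.df
        x = (df["arm"] == "treated").to_numpy(float)
        oracle = cox_mle_oracle(x, df["time"].to_numpy(), df["event"].to_numpy())
        assert est.loghr == pytest.approx(oracle[0], abs=1e-6)

    def test_integer_weights_equal_replication(self, toy_survival_cohort):
        # weights > 1 only on censored rows: replicating an event row
        # creates ties that Efron's correction treats differently from a
        # case weight, so the exact identity is a tie-free property (the
        # general Breslow version is covered by the engine tests)
        w = np.array([1, 1, 3, 1, 1, 1, 2, 1], dtype=float)
        est_w = weighted_cox_hr(toy_survival_cohort, weights=w)
        df = toy_survival_cohort.df.loc[
            toy_survival_cohort.df.index.repeat(w.astype(int))
        ].copy()
        df["subject_id"] = [f"r{i}" for i in range(len(df))]
        rep = CohortTable(df, toy_survival_cohort.schema)
        est_r = weighted_cox_hr(rep)
        assert est_w.loghr == pytest.approx(est_r.loghr, abs=1e-6)

    def test_scale_invariance(self, toy_survival_cohort):
        w = np.array([0.5, 1.5, 1.0, 2.0, 0.7, 1.2, 0.9, 1.1])
        a = weighted_cox_hr(toy_survival_cohort, weights=w)
        b = weighted_cox_hr(toy_survival_cohort, weights=10 * w)
        assert a.loghr == pytest.approx(b.loghr, abs=1e-8)
        assert a.ess == pytest.approx(b.ess, rel=1e-12)

    def test_no_events_raises(self, toy_survival_cohort):
        df = toy_survival_cohort.df.copy()
        df["event"] = 0
        with pytest.raises(ValueError, match="events"):
            weighted_cox_hr(CohortTable(df, toy_survival_cohort.schema))


class TestDiagnosticsAndWorkflow:
    def test_constant_weights_degenerate_interaction(self, toy_survival_cohort):
        p, degenerate = weight_treatment_interaction(toy_survival_cohort, np.ones(8))
        assert degenerate and p == 1.0

    def test_no_shift_transposed_close_to_unweighted(self):
        b = generate_scenario("no_shift", seed=17, n_trial=6000, n_target=6000, n_rw=100)
        res = TranspositionModel(b.trial, b.target, method="LR").fit()
        gap = abs(np.log(res.transposed.hr) - np.log(res.unweighted.hr))
        assert gap < 0.05
        assert res.weights.ess > 0.9 * b.trial.n

    def test_results_summary_shape(self):
        b = generate_scenario("no_shift", seed=18, n_trial=2000, n_target=2000, n_rw=100)
        res = TranspositionModel(b.trial, b.target, method="LR").fit()
        table = res.summary()
        assert list(table["method"]) == ["unweighted", "LR-weighted"]
        assert (table["CI_low"] < table["HR"]).all() and (table["HR"] < table["CI_high"]).all()
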