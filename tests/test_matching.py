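"""Propensity estimation, nearest-neighbor matching, balance, matched Cox."""

import numpy as np
import pandas as pd
import pytest

from conftest import logistic_mle_oracle
from cvtransport import (
    CohortTable,
    MatchingModel,
    ValidationError,
    balance_report,
    comparator_cox,
    estimate_propensity,
    generate_scenario,
    nn_match,
    standardized_mean_difference,
    weighted_cox_hr,
)
from cvtransport.matching import PropensityModel, matched_cohort


def _rw(tiny_schema, age, prior, arm, time=None, event=None, ids=None):
    n = len(age)
    df = pd.DataFrame(
        {
            "subject_id": ids if ids is not None else [f"r{i}" for i in range(n)],
            "source": "rw",
            "arm": arm,
            "age": age,
            "prior_mi_stroke": prior,
            "time": time if time is not None else np.linspace(1, 3, n),
            "event": event if event is not None else [1] * n,
        }
    )
    return CohortTable(df, tiny_schema)


def _ps_model(cohort, scores):
    return PropensityModel(
        covariates=["age"],
        params=pd.Series({"const": 0.0, "age": 0.0}),
        scores=pd.Series(scores, index=cohort.df.index),
    )


class TestPropensity:
    def test_independent_covariates_constant_ps(self, tiny_schema):
        rng = np.random.default_rng(0)
        n = 4000
        arm = np.where(rng.random(n) < 0.25, "treated", "control")
        c = _rw(tiny_schema, np.clip(65 + 5 * rng.standard_normal(n), 18, 110),
                rng.integers(0, 2, n), arm)
        m = estimate_propensity(c, ["age", "prior_mi_stroke"])
        assert np.abs(m.scores - 0.25).max() < 0.05

    def test_toy_matches_bruteforce_mle(self, tiny_schema):
        age = [55.0, 60.0, 66.0, 58.0, 68.0, 75.0]
        arm = ["treated", "treated", "treated", "control", "control", "control"]
        c = _rw(tiny_schema, age, [0] * 6, arm)
        m = estimate_propensity(c, ["age"])
        const, coefs = logistic_mle_oracle(np.array(age)[:, None], np.array([1, 1, 1, 0, 0, 0.0]))
        assert m.params["const"] == pytest.approx(const, abs=1e-5)
        assert m.params["age"] == pytest.approx(coefs[0], abs=1e-6)

    def test_constant_covariate_rejected(self, tiny_schema):
        c = _rw(tiny_schema, [60.0] * 6, [0] * 6, ["treated"] * 3 + ["control"] * 3)
        with pytest.raises(ValidationError, match="variation"):
            estimate_propensity(c, ["age"])


class TestNNMatch:
    def test_duplicate_pool_zero_distances(self, tiny_schema):
        age = [55.0, 60.0, 65.0] + [55.0, 60.0, 65.0]
        arm = ["treated"] * 3 + ["control"] * 3
        c = _rw(tiny_schema, age, [0] * 6, arm)
        ps = 1 / (1 + np.exp(-(np.array(age) - 60) / 10))
        match = nn_match(_ps_model(c, ps), c)
        assert (match.pairs["distance"] == 0).all()
        assert len(match.pairs) == 3

    def test_hand_enumerated_greedy_optimum(self, tiny_schema):
        # exposed PS: .9 .7 .4 .2 ; comparators: .85 .65 .45 .1
        # greedy descending-logit order pairs each exposed with its
        # exhaustive-search nearest comparator (with replacement)
        ps = [0.9, 0.7, 0.4, 0.2, 0.85, 0.65, 0.45, 0.1]
        arm = ["treated"] * 4 + ["control"] * 4
        ids = ["e1", "e2", "e3", "e4", "c1", "c2", "c3", "c4"]
        c = _rw(tiny_schema, [60.0] * 8, [0] * 8, arm, ids=ids)
        match = nn_match(_ps_model(c, np.array(ps)), c, with_replacement=True)
        got = dict(zip(match.pairs["exposed_id"], match.pairs["comparator_id"]))
        logit = lambda p: np.log(p / (1 - p))
        for i, eid in enumerate(["e1", "e2", "e3", "e4"]):
            dists = {cid: abs(logit(ps[i]) - logit(ps[4 + j])) for j, cid in enumerate(["c1", "c2", "c3", "c4"])}
            assert got[eid] == min(dists, key=dists.get)

    def test_without_replacement_exhausts_pool(self, tiny_schema):
        ps = [0.9, 0.7, 0.4, 0.85, 0.65, 0.45]
        arm = ["treated"] * 3 + ["control"] * 3
        c = _rw(tiny_schema, [60.0] * 6, [0] * 6, arm)
        match = nn_match(_ps_model(c, np.array(ps)), c, with_replacement=False)
        assert len(set(match.pairs["comparator_id"])) == 3

    def test_without_replacement_small_pool_rejected(self, tiny_schema):
        ps = [0.9, 0.7, 0.4, 0.85]
        arm = ["treated"] * 3 + ["control"]
        c = _rw(tiny_schema, [60.0] * 4, [0] * 4, arm)
        with pytest.raises(ValueError, match="replacement"):
            nn_match(_ps_model(c, np.array(ps)), c, with_replacement=False)

    def test_caliper_drops_far_subjects(self, tiny_schema):
        ps = [0.95, 0.5, 0.52, 0.48]
        arm = ["treated", "treated", "control", "control"]
        c = _rw(tiny_schema, [60.0] * 4, [0] * 4, arm)
        match = nn_match(_ps_model(c, np.array(ps)), c, caliper=0.5)
        assert len(match.dropped_exposed) == 1
        assert len(match.pairs) == 1


class TestSMD:
    def test_identical_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert standardized_mean_difference(x, x) == 0.0

    def test_unit_shift_unit_variance(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(200000)
        b = a + 1.0
        assert standardized_mean_difference(a, b) == pytest.approx(1.0, abs=0.01)

    def test_binary_hand_value(self):
        # |0.5 - 0.3| / sqrt((0.25 + 0.21)/2) = 0.4170 to 4 d.p.
        a = np.array([1] * 50 + [0] * 50)
        b = np.array([1] * 30 + [0] * 70)
        smd = standardized_mean_difference(a, b, "binary")
        assert smd == pytest.approx(0.4170, abs=5e-5)

    def test_degenerate_unequal_means_infinite(self):
        smd = standardized_mean_difference(np.array([1.0, 1.0]), np.array([2.0, 2.0]))
        assert np.isinf(smd)


class TestBalance:
    def test_perfect_duplicates_pass(self, tiny_schema):
        age = [55.0, 60.0, 65.0] + [55.0, 60.0, 65.0]
        prior = [0, 1, 0] * 2
        arm = ["treated"] * 3 + ["control"] * 3
        c = _rw(tiny_schema, age, prior, arm)
        ps = np.array([0.3, 0.5, 0.7] * 2)
        match = nn_match(_ps_model(c, ps), c)
        report = balance_report(c, match, ["age", "prior_mi_stroke"])
        assert (report.table["smd_after"] == 0).all()
        assert report.passed

    def test_empty_covariate_list_vacuous_pass(self, tiny_schema):
        age = [55.0, 60.0] * 2
        arm = ["treated"] * 2 + ["control"] * 2
        c = _rw(tiny_schema, age, [0] * 4, arm)
        match = nn_match(_ps_model(c, np.array([0.4, 0.6] * 2)), c)
        report = balance_report(c, match, [])
        assert report.passed and report.table.empty

    def test_matching_improves_balance_under_confounding(self):
        improved = 0
        for seed in range(5):
            b = generate_scenario("confounded_rw", seed=600 + seed, n_rw=5000)
            m = MatchingModel(b.rw).fit()
            t = m.balance.table.set_index("covariate")
            if t.loc["age", "smd_after"] < t.loc["age", "smd_before"]:
                improved += 1
        assert improved >= 4


class TestComparatorCox:
    def test_clone_oracle_identity(self, tiny_schema):
        # comparator pool contains an exact clone of each exposed subject:
        # matched analysis must equal a Cox fit on exposed + their clones
        rng = np.random.default_rng(1)
        n = 60
        age = np.clip(rng.uniform(50, 80, n), 18, 110)
        t = rng.exponential(2, n).clip(0.05)
        e = (rng.random(n) < 0.6).astype(int)
        c = _rw(
            tiny_schema,
            np.concatenate([age, age]),
            [0] * (2 * n),
            ["treated"] * n + ["control"] * n,
            time=np.concatenate([t, rng.exponential(3, n).clip(0.05)]),
            event=np.concatenate([e, (rng.random(n) < 0.5).astype(int)]),
        )
        ps = np.concatenate([np.linspace(0.2, 0.8, n)] * 2)
        match = nn_match(_ps_model(c, ps), c)
        assert (match.pairs["distance"] == 0).all()
        effects, _ = comparator_cox(c, match, auto_adjust=False)
        mc, w = matched_cohort(c, match)
        direct = weighted_cox_hr(mc, weights=w, method="matched")
        assert effects["overall"].loghr == pytest.approx(direct.loghr, abs=1e-12)

    def test_single_group_single_row(self, tiny_schema):
        rng = np.random.default_rng(2)
        n = 80
        c = _rw(
            tiny_schema,
            np.clip(rng.uniform(50, 80, 2 * n), 18, 110),
            rng.integers(0, 2, 2 * n),
            ["treated"] * n + ["control"] * n,
            time=rng.exponential(2, 2 * n).clip(0.05),
            event=(rng.random(2 * n) < 0.6).astype(int),
        )
        m = estimate_propensity(c, ["age", "prior_mi_stroke"])
        match = nn_match(m, c)
        effects, adj = comparator_cox(c, match, tree=None, auto_adjust=False)
        assert list(effects) == ["overall"]

    def test_confounded_recovery_and_balance(self):
        # single matched estimates carry SE ~0.1; recovery is judged on
        # the replicate-averaged log HR
        logs = []
        for seed in range(10):
            b = generate_scenario("confounded_rw", seed=seed, n_rw=10000)
            res = MatchingModel(b.rw).fit()
            assert res.balance.passed
            logs.append(res.effects["overall"].loghr)
        assert np.exp(np.mean(logs)) == pytest.approx(0.70, abs=0.05)
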