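import math

import numpy as np
import pandas as pd
import pytest

from methylomix.dmeg import roc_auc
from methylomix.io import ClinicalTable
from methylomix.prognosis import (
    RiskModel,
    _coxnet_path,
    cox_partial_loglik,
    cox_univariate,
    cox_multivariate,
    dichotomize,
    fit_risk_model,
    km_curve,
    lasso_stability,
    logrank,
    risk_score,
    split_cohort,
    td_roc_auc,
)


def _simulate(rng, n, coef, base=0.01, censor_hi=150.0, x=None):
    x = rng.normal(0, 1, n) if x is None else x
    t = rng.exponential(1.0 / (base * np.exp(coef * x)))
    c = rng.uniform(0, censor_hi, n)
    time, event = np.minimum(t, c), (t <= c).astype(int)
    idx = [f"S{i}" for i in range(n)]
    clin = ClinicalTable(pd.DataFrame({"time": time, "event": event}, index=idx))
    return pd.Series(x, index=idx, name="x"), clin


class TestSplit:
    def test_near_equal_halves(self):
        train, val = split_cohort([f"s{i}" for i in range(177)], seed=3)
        assert sorted((len(train), len(val))) == [88, 89]
        assert set(train) | set(val) == {f"s{i}" for i in range(177)}
        assert not set(train) & set(val)

    def test_small_even_split(self):
        train, val = split_cohort(list("abcd"), seed=1)
        assert len(train) == 2 and len(val) == 2

    def test_seed_determinism(self):
        s = [f"s{i}" for i in range(31)]
        assert split_cohort(s, 9) == split_cohort(s, 9)


class TestCoxUnivariate:
    def test_score_equation_satisfied_at_optimum(self, rng):
        x, clin = _simulate(rng, 120, 0.5)
        row = cox_univariate(x, clin)
        _, grad = cox_partial_loglik(
            np.array([row.coef]),
            x.to_numpy()[:, None],
            clin.time.to_numpy(),
            clin.event.to_numpy(),
            gradient=True,
        )
        assert abs(grad[0]) <= 1e-6

    def test_agrees_with_lifelines_on_tie_free_data(self, rng):
        from lifelines import CoxPHFitter

        x, clin = _simulate(rng, 90, 0.6)
        row = cox_univariate(x, clin)
        df = pd.DataFrame({"T": clin.time, "E": clin.event, "x": x})
        cph = CoxPHFitter().fit(df, "T", "E")
        assert row.coef == pytest.approx(float(cph.params_["x"]), abs=1e-4)
        assert row.se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-4)

    def test_null_covariate_gives_hr_near_one(self, rng):
        hrs = []
        for _ in range(20):
            x, clin = _simulate(rng, 100, 0.0)
            hrs.append(cox_univariate(x, clin).hr)
        assert np.mean(np.log(hrs)) == pytest.approx(0.0, abs=0.1)

    def test_planted_coefficient_recovered(self, rng):
        coefs = []
        for _ in range(20):
            x, clin = _simulate(rng, 200, 0.5, censor_hi=400.0)
            assert clin.event.mean() >= 0.6  # censoring kept moderate
            coefs.append(cox_univariate(x, clin).coef)
        assert abs(np.mean(coefs) - 0.5) <= 0.15

    def test_perfect_separation_flagged(self):
        idx = list("abcdef")
        clin = ClinicalTable(
            pd.DataFrame({"time": [6.0, 5, 4, 3, 2, 1], "event": 1}, index=idx)
        )
        x = pd.Series(np.arange(6.0), index=idx)
        assert cox_univariate(x, clin).flag == "monotone_likelihood"

    def test_too_few_events_rejected(self):
        clin = ClinicalTable(
            pd.DataFrame({"time": [1.0, 2, 3], "event": [1, 0, 0]}, index=list("abc"))
        )
        with pytest.raises(ValueError, match="events"):
            cox_univariate(pd.Series([1.0, 2, 3], index=list("abc")), clin)

    def test_breslow_likelihood_hand_value(self):
        # two subjects, events at t=1 (x=1) then t=2 (x=0), beta=0:
        # ll = [0 - log(2)] + [0 - log(1)] = -log 2
        ll = cox_partial_loglik(
            np.array([0.0]), np.array([[1.0], [0.0]]), np.array([1.0, 2.0]), np.array([1, 1])
        )
        assert ll == pytest.approx(-math.log(2))


class TestPenalizedPath:
    def test_nonzero_count_monotone_in_lambda(self, rng):
        n, p = 80, 12
        X = rng.normal(size=(n, p))
        risk = 1.2 * X[:, 0] - 1.0 * X[:, 1]
        t = rng.exponential(1.0 / (0.01 * np.exp(risk)))
        c = rng.uniform(0, 200, n)
        alphas, coefs = _coxnet_path(X, np.minimum(t, c), (t <= c).astype(int))
        counts = (coefs != 0).sum(axis=0)  # alphas decrease along the path
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_single_rep_stability_is_total(self, rng):
        x, clin = _simulate(rng, 60, 0.8)
        expr = pd.DataFrame({s: [v] for s, v in x.items()}, index=["g1"])
        table = lasso_stability(expr, clin, n_reps=1, k_folds=5, seed=2, lambda_rule="min")
        assert table.combinations["freq_per_100"].sum() == pytest.approx(100.0)
        assert len(table.combinations) == 1

    def test_permuted_survival_yields_no_dominant_combination(self, rng):
        n = 80
        expr = pd.DataFrame(
            rng.normal(size=(6, n)), index=[f"g{i}" for i in range(6)],
            columns=[f"S{i}" for i in range(n)],
        )
        _, clin = _simulate(rng, n, 0.0)
        table = lasso_stability(expr, clin, n_reps=30, k_folds=5, seed=4, lambda_rule="min")
        nonempty = table.combinations.drop(index=[""], errors="ignore")
        if len(nonempty):
            assert nonempty["freq_per_100"].max() <= 60.0


class TestRiskModel:
    def test_unpenalized_limit_matches_univariate_newton(self, rng):
        x, clin = _simulate(rng, 150, 0.6)
        expr = pd.DataFrame([x.to_numpy()], index=["g1"], columns=x.index)
        model = fit_risk_model(["g1"], expr, clin, mode="penalized", alpha=1e-6)
        ref = cox_univariate(x, clin).coef
        assert model.coefficients[0] == pytest.approx(ref, abs=5e-3)

    def test_protective_gene_gets_negative_sign(self, rng):
        x, clin = _simulate(rng, 150, -0.8)
        expr = pd.DataFrame([x.to_numpy()], index=["g1"], columns=x.index)
        model = fit_risk_model(["g1"], expr, clin, mode="refit")
        assert model.coefficients[0] < 0

    def test_fit_deterministic_under_seed(self, rng):
        x, clin = _simulate(rng, 100, 0.5)
        expr = pd.DataFrame([x.to_numpy()], index=["g1"], columns=x.index)
        m1 = fit_risk_model(["g1"], expr, clin, seed=5)
        m2 = fit_risk_model(["g1"], expr, clin, seed=5)
        assert m1.coefficients == m2.coefficients

    def test_risk_score_linear_form(self):
        model = RiskModel(("A", "B"), (-0.5, 0.25))
        assert risk_score(model, pd.Series({"A": 0.0, "B": 0.0})) == 0.0
        assert risk_score(model, pd.Series({"A": 2.0, "B": 4.0})) == pytest.approx(0.0)
        with pytest.raises(KeyError, match="missing"):
            risk_score(model, pd.Series({"A": 1.0}))

    def test_json_round_trip(self, tmp_path):
        model = RiskModel(("A",), (0.3,), {"mean": 0.1, "sd": 1.0, "median": 0.0})
        model.to_json(tmp_path / "m.json")
        back = RiskModel.from_json(tmp_path / "m.json")
        assert back == model


class TestDichotomize:
    def test_median_rule_ties_high(self):
        groups = dichotomize(pd.Series([1.0, 2.0, 3.0, 4.0]), "median")
        assert list(groups) == ["low", "low", "high", "high"]
        # median of even series is 2.5; a score exactly at the median goes high
        groups2 = dichotomize(pd.Series([1.0, 2.0, 2.0, 4.0]), "median")
        assert list(groups2) == ["low", "high", "high", "high"]

    def test_zscore_rule(self):
        groups = dichotomize(pd.Series([-1.0, -1.0, 2.0]), "zscore")
        assert list(groups) == ["low", "low", "high"]

    def test_degenerate_scores_single_group(self, caplog):
        groups = dichotomize(pd.Series([3.0, 3.0, 3.0]), "median")
        assert len(set(groups)) == 1


class TestKmAndLogrank:
    def test_all_censored_constant_one(self):
        curve = km_curve([5.0, 7.0, 9.0], [0, 0, 0])
        assert (curve["survival"] == 1.0).all()

    def test_hand_product_limit(self):
        curve = km_curve([1.0, 2.0], [1, 1]).set_index("time")["survival"]
        assert curve.loc[1.0] == 0.5 and curve.loc[2.0] == 0.0

    def test_never_increases(self, rng):
        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        curve = km_curve(t, e)
        assert (np.diff(curve["survival"]) <= 1e-12).all()

    def test_identical_groups_null(self):
        chi2, p = logrank([1, 2, 3], [1, 1, 0], [1, 2, 3], [1, 1, 0])
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_hand_example(self):
        chi2, _ = logrank([1, 2], [1, 1], [3, 4], [1, 1])
        assert chi2 == pytest.approx(2.882, abs=1e-3)

    def test_label_swap_symmetry(self):
        a = ([1, 4, 6], [1, 0, 1])
        b = ([2, 3, 9], [1, 1, 0])
        assert logrank(*a, *b)[0] == pytest.approx(logrank(*b, *a)[0])


class TestTimeDependentAuc:
    def test_uncensored_equals_rank_auc(self, rng):
        n = 80
        x = rng.normal(0, 1, n)
        t = rng.exponential(1.0 / (0.02 * np.exp(0.8 * x)))
        idx = [f"S{i}" for i in range(n)]
        clin = ClinicalTable(pd.DataFrame({"time": t, "event": 1}, index=idx))
        scores = pd.Series(x, index=idx)
        h = float(np.median(t))
        expected = roc_auc(scores.to_numpy(), (t <= h).astype(int)).auc
        assert td_roc_auc(scores, clin, h) == pytest.approx(expected)

    def test_uninformative_score_near_half(self, rng):
        aucs = []
        for _ in range(20):
            x, clin = _simulate(rng, 100, 0.0)
            h = float(np.quantile(clin.time, 0.5))
            aucs.append(td_roc_auc(pd.Series(rng.normal(size=100), index=clin.samples), clin, h))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_perfect_ranking_reaches_one(self):
        idx = [f"S{i}" for i in range(6)]
        t = np.array([1.0, 2, 3, 4, 5, 6])
        clin = ClinicalTable(pd.DataFrame({"time": t, "event": 1}, index=idx))
        scores = pd.Series(-t, index=idx)
        assert td_roc_auc(scores, clin, 3.5) == pytest.approx(1.0)

    def test_late_dominant_risk_orders_horizon_aucs(self, rng):
        # early failures are score-independent accidents; the score only
        # drives late disease deaths, so discrimination grows with horizon
        n = 300
        x = rng.normal(0, 1, n)
        early = rng.exponential(2000.0, n)
        late = 900.0 + rng.exponential(1.0 / (0.005 * np.exp(1.5 * x)))
        t = np.minimum(early, late)
        idx = [f"S{i}" for i in range(n)]
        clin = ClinicalTable(pd.DataFrame({"time": t, "event": 1}, index=idx))
        scores = pd.Series(x, index=idx)
        auc_early = td_roc_auc(scores, clin, 365.0)
        auc_late = td_roc_auc(scores, clin, 1825.0)
        assert auc_late > auc_early

    def test_horizon_before_first_event_rejected(self):
        idx = ["a", "b", "c"]
        clin = ClinicalTable(pd.DataFrame({"time": [5.0, 6, 7], "event": [1, 1, 1]}, index=idx))
        with pytest.raises(ValueError, match="horizon"):
            td_roc_auc(pd.Series([1.0, 2, 3], index=idx), clin, 1.0)
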