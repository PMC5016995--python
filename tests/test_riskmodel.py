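"""Penalized Cox fitting, CVL tuning, stratification, KM and tests."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy.optimize import minimize

from prognosig import (ConvergenceError, DataError, ParameterError,
                       PenaltyConfig, SurvivalData, cox_hazard_ratios,
                       cox_partial_loglik, cross_validated_loglik,
                       fit_penalized_cox, km_estimate, lambda1_max,
                       likelihood_ratio_test, risk_scores, stratify_by_median,
                       tune_penalties_cvl)
from prognosig.riskmodel import CoxRiskModel, _make_folds, _newton_cox


class TestPartialLoglik:
    def test_brute_force_enumeration_oracle(self):
        time = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        event = np.array([1, 0, 1, 1, 0])
        x = np.array([0.5, -1.0, 1.0, 0.0, 2.0])
        d = SurvivalData(time, event, pd.DataFrame({"g": x}))
        beta = 0.5
        expected = 0.0
        for i in range(5):
            if event[i]:
                rs = [j for j in range(5) if time[j] >= time[i]]
                expected += x[i] * beta - np.log(
                    sum(np.exp(x[j] * beta) for j in rs))
        assert cox_partial_loglik(d, [beta]) == pytest.approx(expected)

    def test_null_beta_single_event_uniform_risk(self):
        d = SurvivalData([1.0, 2.0, 3.0], [1, 0, 0],
                         pd.DataFrame({"g": [1.0, 2.0, 3.0]}))
        assert cox_partial_loglik(d, [0.0]) == pytest.approx(-np.log(3))

    def test_invariant_to_covariate_shift(self, toy_survival):
        d = toy_survival
        shifted = SurvivalData(d.time, d.event, d.covariates + 10.0)
        assert cox_partial_loglik(d, [0.4, -0.2]) == pytest.approx(
            cox_partial_loglik(shifted, [0.4, -0.2]))

    def test_zero_events_rejected(self):
        d = SurvivalData([1.0, 2.0], [0, 0], pd.DataFrame({"g": [1.0, 2.0]}))
        with pytest.raises(DataError):
            cox_partial_loglik(d, [0.0])


class TestPenalizedFit:
    def test_unpenalized_matches_newton_and_lifelines(self, toy_survival):
        d = toy_survival
        m = fit_penalized_cox(d, 0.0, 0.0)
        bn, _, _ = _newton_cox(d)
        np.testing.assert_allclose(m.coefficients.to_numpy(), bn, atol=1e-5)
        df = d.covariates.copy()
        df["T"], df["E"] = d.time, d.event
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(m.coefficients.to_numpy(),
                                   cph.params_.to_numpy(), atol=1e-5)

    def test_ridge_matches_direct_optimization(self, toy_survival):
        d = toy_survival
        m = fit_penalized_cox(d, 0.0, 1.0)

        def neg_obj(b):
            return -(cox_partial_loglik(d, b) - 1.0 * np.sum(np.square(b)))

        opt = minimize(neg_obj, [0.0, 0.0], method="BFGS")
        np.testing.assert_allclose(m.coefficients.to_numpy(), opt.x, atol=1e-5)

    def test_large_l1_gives_exact_zeros(self, toy_survival):
        lam = lambda1_max(toy_survival)
        m = fit_penalized_cox(toy_survival, lam * 1.0001, 0.0)
        assert (m.coefficients.to_numpy() == 0.0).all()
        m2 = fit_penalized_cox(toy_survival, lam * 0.5, 0.0)
        assert np.abs(m2.coefficients.to_numpy()).max() > 0

    def test_objective_not_below_null_model(self, toy_survival):
        for l1, l2 in [(0.0, 0.0), (0.5, 0.2), (2.0, 1.0)]:
            m = fit_penalized_cox(toy_survival, l1, l2)
            pen = (m.loglik - l1 * m.coefficients.abs().sum()
                   - l2 * (m.coefficients**2).sum())
            null = cox_partial_loglik(toy_survival, [0.0, 0.0])
            assert pen >= null - 1e-9

    def test_l1_path_monotone_shrinkage(self, toy_survival):
        lams = np.linspace(0, lambda1_max(toy_survival), 8)
        prev = None
        for lam in lams:
            m = fit_penalized_cox(toy_survival, lam, 0.1)
            cur = m.coefficients.abs().to_numpy()
            if prev is not None:
                assert (cur <= prev + 1e-6).all()
            prev = cur

    def test_separation_raises_advising_penalty(self):
        # perfectly separating covariate: MLE diverges
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.ones(6, dtype=int)
        x = np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        d = SurvivalData(time, event, pd.DataFrame({"g": x}))
        with pytest.raises(ConvergenceError, match="penalt"):
            fit_penalized_cox(d, 0.0, 0.0)


class TestCVLTuning:
    @pytest.fixture(scope="class")
    def signal_data(self):
        rng = np.random.default_rng(5)
        n, p = 60, 6
        x = rng.standard_normal((n, p))
        beta = np.array([0.8, -0.8, 0.0, 0.0, 0.0, 0.0])
        t = rng.exponential(np.exp(-(x @ beta))) * 30
        e = (rng.random(n) < 0.85).astype(int)
        return SurvivalData(t, e, pd.DataFrame(
            x, columns=[f"g{i}" for i in range(p)]))

    def test_optimum_beats_null_cvl(self, signal_data):
        cfg = PenaltyConfig(folds=5, starts=3, grid_points=4, seed=2)
        m = tune_penalties_cvl(signal_data, cfg)
        folds = _make_folds(signal_data, 5, np.random.default_rng(2))
        null_cvl = 0.0
        p = signal_data.x.shape[1]
        for f in np.unique(folds):
            sub = signal_data.subset(np.flatnonzero(folds != f))
            null_cvl += (cox_partial_loglik(signal_data, np.zeros(p))
                         - cox_partial_loglik(sub, np.zeros(p)))
        assert m.cvl > null_cvl

    def test_deterministic_given_seed(self, signal_data):
        cfg = PenaltyConfig(folds=5, starts=2, grid_points=3, seed=7)
        a = tune_penalties_cvl(signal_data, cfg)
        b = tune_penalties_cvl(signal_data, cfg)
        assert (a.lambda1, a.lambda2) == (b.lambda1, b.lambda2)
        assert a.coefficients.equals(b.coefficients)

    def test_huge_l1_grid_returns_null_model(self, signal_data):
        folds = _make_folds(signal_data, 5, np.random.default_rng(0))
        big = 100 * lambda1_max(signal_data)
        cvl = cross_validated_loglik(signal_data, big, 0.0, folds)
        m = fit_penalized_cox(signal_data, big, 0.0)
        assert (m.coefficients == 0).all()
        p = signal_data.x.shape[1]
        null_cvl = 0.0
        for f in np.unique(folds):
            sub = signal_data.subset(np.flatnonzero(folds != f))
            null_cvl += (cox_partial_loglik(signal_data, np.zeros(p))
                         - cox_partial_loglik(sub, np.zeros(p)))
        assert cvl == pytest.approx(null_cvl)


class TestScoresAndStratification:
    def test_dot_product_scores(self):
        model = CoxRiskModel(
            coefficients=pd.Series([1.0, -1.0], index=["g1", "g2"]),
            lambda1=0, lambda2=0, loglik=0.0)
        z = pd.DataFrame([[2.0], [3.0]], index=["g1", "g2"], columns=["s1"])
        assert risk_scores(model, z)["s1"] == pytest.approx(-1.0)

    def test_null_model_all_zero_scores(self, toy_survival):
        model = CoxRiskModel(
            coefficients=pd.Series([0.0, 0.0], index=["a", "b"]),
            lambda1=0, lambda2=0, loglik=0.0)
        z = toy_survival.covariates.T
        assert (risk_scores(model, z) == 0).all()

    def test_median_cutoff_and_ge_rule(self):
        strat = stratify_by_median(pd.Series([1.0, 2.0, 3.0, 4.0],
                                             index=list("abcd")))
        assert strat.cutoff == 2.5
        assert set(strat.labels[strat.labels == "high"].index) == {"c", "d"}
        # exactly-at-cutoff goes high
        s2 = stratify_by_median(pd.Series([1.0, 2.0, 3.0]), cutoff=2.0)
        assert s2.labels.iloc[1] == "high"

    def test_odd_n_median_sample_is_high(self):
        strat = stratify_by_median(pd.Series([10.0, 20.0, 30.0, 40.0, 50.0]))
        assert (strat.labels == "high").sum() == 3
        assert strat.labels.iloc[2] == "high"

    def test_identical_scores_degenerate(self):
        with pytest.raises(DataError):
            stratify_by_median(pd.Series([1.0, 1.0, 1.0]))


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_estimate([5.0, 10.0, 15.0, 20.0], [0, 1, 1, 0])
        s = dict(zip(km["time"], km["survival"]))
        assert s[10.0] == pytest.approx(2 / 3)
        assert s[15.0] == pytest.approx(1 / 3)

    def test_no_events_flat_at_one(self):
        km = km_estimate([3.0, 4.0, 5.0], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_all_events_equals_empirical_survival(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        km = km_estimate(t, np.ones(4, dtype=int))
        emp = 1.0 - np.arange(1, 5) / 4
        np.testing.assert_allclose(km["survival"].to_numpy()[1:], emp)

    def test_curve_starts_at_one_and_nonincreasing(self, small_study):
        km = km_estimate(small_study.clinical.time, small_study.clinical.event)
        surv = km["survival"].to_numpy()
        assert surv[0] == 1.0
        assert (np.diff(surv) <= 1e-12).all()


class TestGroupTests:
    def test_identical_groups_null_statistic(self):
        t = np.array([1.0, 2, 3, 4, 5, 6] * 2)
        e = np.array([1, 0, 1, 1, 0, 1] * 2)
        labels = ["high"] * 6 + ["low"] * 6
        r = likelihood_ratio_test(t, e, labels)
        assert r.statistic == pytest.approx(0.0, abs=1e-8)
        assert r.p == pytest.approx(1.0)
        assert r.hazard_ratio == pytest.approx(1.0)

    def test_strong_separation_matches_newton_oracle(self):
        rng = np.random.default_rng(2)
        g = np.repeat([0.0, 1.0], 40)
        t = rng.exponential(np.exp(-1.2 * g))
        e = np.ones(80, dtype=int)
        r = likelihood_ratio_test(t, e, np.where(g == 1, "high", "low"))
        d = SurvivalData(t, e, pd.DataFrame({"g": g}))
        bn, ll1, _ = _newton_cox(d)
        ll0 = cox_partial_loglik(d, [0.0])
        assert r.statistic == pytest.approx(2 * (ll1 - ll0), abs=1e-5)
        assert np.log(r.hazard_ratio) == pytest.approx(bn[0], abs=1e-5)

    def test_lrt_type_one_error_calibrated(self):
        rng = np.random.default_rng(17)
        n, reps = 60, 400
        rejections = 0
        for _ in range(reps):
            t = rng.exponential(1.0, n)
            e = (rng.random(n) < 0.8).astype(int)
            lab = np.where(rng.random(n) < 0.5, "high", "low")
            if len(set(lab)) < 2:
                continue
            r = likelihood_ratio_test(t, e, lab)
            rejections += r.p < 0.05
        assert abs(rejections / reps - 0.05) < 0.025

    def test_no_events_in_one_group_warns_unbounded(self):
        t = np.array([1.0, 2, 3, 10, 11, 12])
        e = np.array([1, 1, 1, 0, 0, 0])
        lab = ["high"] * 3 + ["low"] * 3
        with pytest.warns(UserWarning, match="unbounded"):
            r = likelihood_ratio_test(t, e, lab)
        assert r.ci[1] == np.inf


class TestHazardRatioTables:
    def test_univariate_matches_brute_force(self, toy_survival):
        table = cox_hazard_ratios(toy_survival, "univariate")
        for c in ("a", "b"):
            sub = SurvivalData(toy_survival.time, toy_survival.event,
                               toy_survival.covariates[[c]])
            opt = minimize(lambda b: -cox_partial_loglik(sub, b), [0.0],
                           method="BFGS")
            assert np.log(table.loc[c, "hr"]) == pytest.approx(opt.x[0],
                                                               abs=1e-5)

    def test_multivariate_joint_fit(self, toy_survival):
        table = cox_hazard_ratios(toy_survival, "multivariate")
        bn, _, _ = _newton_cox(toy_survival)
        np.testing.assert_allclose(np.log(table["hr"].to_numpy()), bn,
                                   atol=1e-6)
        assert ((table["ci_low"] <= table["hr"])
                & (table["hr"] <= table["ci_high"])).all()

    def test_duplicated_covariate_collinearity_error(self, toy_survival):
        cov = toy_survival.covariates.copy()
        cov["a2"] = cov["a"]
        d = SurvivalData(toy_survival.time, toy_survival.event, cov)
        with pytest.raises(ConvergenceError, match="collinear"):
            cox_hazard_ratios(d, "multivariate")

    def test_null_covariate_ci_coverage(self):
        rng = np.random.default_rng(23)
        n, reps, cover = 80, 200, 0
        for _ in range(reps):
            x = rng.standard_normal(n)
            t = rng.exponential(1.0, n)
            e = (rng.random(n) < 0.8).astype(int)
            d = SurvivalData(t, e, pd.DataFrame({"x": x}))
            row = cox_hazard_ratios(d, "univariate").loc["x"]
            cover += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert abs(cover / reps - 0.95) < 0.05


def test_folds_avoid_all_censored_complements():
    time = np.linspace(1, 10, 20)
    event = np.zeros(20, dtype=int)
    event[:3] = 1
    d = SurvivalData(time, event, pd.DataFrame({"g": np.arange(20.0)}))
    folds = _make_folds(d, 3, np.random.default_rng(0))
    for f in np.unique(folds):
        assert d.event[folds != f].sum() >= 1
    with pytest.raises(ParameterError):
        _make_folds(d, 10, np.random.default_rng(0))  # folds > events
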