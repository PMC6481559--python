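import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize, minimize_scalar

from cohortmi.cox import (
    breslow_baseline,
    fit_cox_full,
    fit_cox_substudy,
    nelson_aalen,
)
from cohortmi.designs import SampledRiskSet
from cohortmi.simulate import SimScenario, simulate_cohort
from conftest import make_cohort


def enumerated_partial_loglik(times, events, x, beta):
    """Brute-force Breslow partial log-likelihood for a single covariate."""
    ll = 0.0
    for tau in np.unique(np.asarray(times)[np.asarray(events) == 1.0]):
        cases = [i for i in range(len(times)) if times[i] == tau and events[i] == 1]
        risk = [i for i in range(len(times)) if times[i] >= tau]
        denom = sum(np.exp(beta * x[i]) for i in risk)
        for i in cases:
            ll += beta * x[i] - np.log(denom)
    return ll


class TestFullPartialLikelihood:
    def test_constant_covariate_drops_out(self):
        data = make_cohort([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1], w=[1.0, 1.0, 1.0, 1.0])
        fit = fit_cox_full(data, ["w"])
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-12)

    def test_toy_fit_matches_brute_force_maximization(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        events = [1, 0, 1, 1, 0]
        x = [0.5, -1.0, 2.0, 0.0, 1.0]
        fit = fit_cox_full(make_cohort(times, events, x=x), ["x"])
        res = minimize_scalar(
            lambda b: -enumerated_partial_loglik(times, events, x, b),
            bounds=(-5, 5), method="bounded", options={"xatol": 1e-10},
        )
        assert fit.beta[0] == pytest.approx(res.x, abs=1e-6)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)

    def test_first_order_condition_and_curvature(self, small_cohort):
        # convergence requires max |score| < 1e-9 by construction; the
        # observed information at the optimum must be positive definite
        fit = fit_cox_full(small_cohort, ["x1", "x2", "z"])
        assert fit.converged
        assert np.all(np.linalg.eigvalsh(np.linalg.inv(fit.vcov)) > 0)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        cohort = simulate_cohort(SimScenario(n_cohort=800, seed=3, censor_time=0.4))
        fit = fit_cox_full(cohort, ["x1", "x2", "z"])
        cph = lifelines.CoxPHFitter()
        cph.fit(cohort[["time", "event", "x1", "x2", "z"]], "time", "event")
        np.testing.assert_allclose(fit.beta, cph.params_.values, atol=1e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values, atol=1e-5)

    def test_rank_invariance_under_monotone_time_transform(self, small_cohort):
        fit = fit_cox_full(small_cohort, ["x1", "x2", "z"])
        warped = small_cohort.copy()
        warped["time"] = np.expm1(warped["time"]) ** 1.5
        fit2 = fit_cox_full(warped, ["x1", "x2", "z"])
        np.testing.assert_allclose(fit.beta, fit2.beta, atol=1e-10)

    def test_breslow_tie_handling_matches_brute_force(self):
        times = [1.0, 1.0, 2.0, 3.0, 3.0, 4.0]
        events = [1, 1, 0, 1, 1, 0]
        x = [1.0, 0.0, -1.0, 2.0, 0.5, 0.0]
        fit = fit_cox_full(make_cohort(times, events, x=x), ["x"])
        res = minimize_scalar(
            lambda b: -enumerated_partial_loglik(times, events, x, b),
            bounds=(-5, 5), method="bounded", options={"xatol": 1e-10},
        )
        assert fit.beta[0] == pytest.approx(res.x, abs=1e-6)

    def test_no_events_is_an_error(self):
        data = make_cohort([1.0, 2.0], [0, 0], x=[0.0, 1.0])
        with pytest.raises(ValueError, match="no events"):
            fit_cox_full(data, ["x"])

    def test_missing_covariates_rejected(self):
        data = make_cohort([1.0, 2.0], [1, 0], x=[np.nan, 1.0])
        with pytest.raises(ValueError, match="missing"):
            fit_cox_full(data, ["x"])

    def test_separation_like_divergence_is_an_error(self):
        # covariate perfectly orders the events: the likelihood is monotone
        # in beta and the coefficient runs away
        data = make_cohort([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], x=[3.0, 2.0, 1.0, 0.0])
        with pytest.raises(RuntimeError, match="separation|degenerate"):
            fit_cox_full(data, ["x"])


def full_risk_sets(cohort):
    sets = []
    t = cohort["time"].to_numpy()
    ids = cohort["id"].to_numpy()
    for k, row in enumerate(np.flatnonzero(cohort["event"].to_numpy() == 1)):
        tau = t[row]
        comps = ids[(t >= tau) & (ids != ids[row])]
        sets.append(SampledRiskSet(k, float(tau), ids[row], tuple(comps), c=len(comps)))
    return sets


class TestSubstudyLikelihood:
    def test_full_risk_sets_reduce_to_full_likelihood(self, small_cohort):
        cohort = small_cohort.head(400).copy()
        fit_full = fit_cox_full(cohort, ["x1", "x2", "z"])
        fit_sub = fit_cox_substudy(cohort, full_risk_sets(cohort), "model",
                                   ["x1", "x2", "z"])
        np.testing.assert_allclose(fit_sub.beta, fit_full.beta, atol=1e-8)

    def test_ncc_pairs_equal_conditional_logistic(self):
        # 1 control per case: the modified partial likelihood is the
        # conditional-logistic likelihood sum log sigmoid(lp_case - lp_control)
        rng = np.random.default_rng(8)
        n = 12
        x = rng.normal(size=n)
        data = make_cohort(np.arange(1, n + 1.0), np.ones(n), x=x)
        sets = [
            SampledRiskSet(j, float(j + 1), j, (int(rng.integers(j + 1, n)),), c=1)
            for j in range(0, n - 1, 2)
        ]

        def clogit_negll(beta):
            ll = 0.0
            for rs in sets:
                d = beta * (x[rs.case_id] - x[rs.comparator_ids[0]])
                ll += -np.log1p(np.exp(-d))
            return -ll

        fit = fit_cox_substudy(data, sets, "model", ["x"])
        assert fit.loglik == pytest.approx(-clogit_negll(fit.beta[0]), abs=1e-10)
        res = minimize_scalar(clogit_negll, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        assert fit.beta[0] == pytest.approx(res.x, abs=1e-6)

    def test_cc_toy_matches_enumerated_pseudo_likelihood(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 0, 1, 0, 0]
        x = [1.0, -0.5, 0.3, 2.0, 0.0, -1.0]
        data = make_cohort(times, events, x=x)
        sets = [
            SampledRiskSet(0, 1.0, 0, (2, 4, 5)),
            SampledRiskSet(1, 2.0, 1, (2, 4)),
            SampledRiskSet(2, 4.0, 3, (4, 5)),
        ]

        def negll(beta):
            ll = 0.0
            for rs in sets:
                members = [rs.case_id, *rs.comparator_ids]
                denom = sum(np.exp(beta * x[m]) for m in members)
                ll += beta * x[rs.case_id] - np.log(denom)
            return -ll

        fit = fit_cox_substudy(data, sets, "sandwich", ["x"])
        res = minimize_scalar(negll, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        assert fit.beta[0] == pytest.approx(res.x, abs=1e-6)
        assert fit.vcov[0, 0] >= 0.0

    def test_empty_comparator_set_contributes_one(self):
        data = make_cohort([1.0, 2.0, 3.0, 4.0], [1, 0, 0, 1], x=[0.5, 1.0, 0.0, -1.0])
        sets = [
            SampledRiskSet(0, 1.0, 0, (1, 2)),
            SampledRiskSet(1, 4.0, 3, ()),  # no eligible comparators
        ]
        fit = fit_cox_substudy(data, sets, "model", ["x"])
        assert fit.n_events == 1  # only the informative set contributes

    def test_unknown_member_id_rejected(self):
        data = make_cohort([1.0, 2.0], [1, 0], x=[0.0, 1.0])
        with pytest.raises(ValueError, match="ids absent"):
            fit_cox_substudy(data, [SampledRiskSet(0, 1.0, 0, (99,))], "model", ["x"])

    def test_case_cannot_be_its_own_comparator(self):
        with pytest.raises(ValueError, match="comparator"):
            SampledRiskSet(0, 1.0, 3, (3,))


class TestHazardEstimators:
    def test_nelson_aalen_hand_example(self):
        # events at 1 and 2, censored at 3: H(2) = 1/3 + 1/2
        sf = nelson_aalen([1.0, 2.0, 3.0], [1, 1, 0])
        assert sf(2.0) == pytest.approx(1.0 / 3.0 + 1.0 / 2.0)
        assert sf(0.9) == pytest.approx(0.0)

    def test_nelson_aalen_no_events(self):
        sf = nelson_aalen([1.0, 2.0], [0, 0])
        assert sf(5.0) == 0.0

    def test_nelson_aalen_exponential_consistency(self):
        rng = np.random.default_rng(15)
        t = rng.exponential(size=1000)
        sf = nelson_aalen(t, np.ones(1000))
        # Var of NA at t is roughly sum d/n^2; 3 MC SEs around H(1) = 1
        var = np.sum(
            [1.0 / (1000 - k) ** 2 for k, tt in enumerate(np.sort(t)) if tt <= 1.0]
        )
        assert abs(sf(1.0) - 1.0) < 3 * np.sqrt(var)

    def test_breslow_reduces_to_nelson_aalen_at_zero_beta(self, small_cohort):
        na = nelson_aalen(small_cohort["time"], small_cohort["event"])
        br = breslow_baseline(small_cohort, [0.0, 0.0, 0.0])
        np.testing.assert_allclose(br.cumulative_values, na.cumulative_values, rtol=1e-12)

    def test_breslow_toy_hand_enumeration(self):
        data = make_cohort([1.0, 2.0, 3.0], [1, 1, 0], x=[1.0, 0.0, -1.0])
        b = 0.5
        sf = breslow_baseline(data, [b], ["x"])
        j1 = 1.0 / (np.exp(b) + 1.0 + np.exp(-b))
        j2 = 1.0 / (1.0 + np.exp(-b))
        np.testing.assert_allclose(sf.cumulative_values, [j1, j1 + j2], rtol=1e-12)

    def test_breslow_jump_scaling(self):
        data = make_cohort([1.0, 2.0, 3.0], [1, 1, 0], x=[1.0, 0.5, -0.5])
        base = breslow_baseline(data, [0.3], ["x"])
        shifted = data.copy()
        shifted["x"] = shifted["x"] + np.log(2.0) / 0.3  # exp(beta x) doubles
        half = breslow_baseline(shifted, [0.3], ["x"])
        np.testing.assert_allclose(half.jumps, base.jumps / 2.0, rtol=1e-12)
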