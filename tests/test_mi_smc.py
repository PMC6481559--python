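from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from cohortmi.cox import breslow_baseline
from cohortmi.designs import sample_case_cohort, sample_ncc
from cohortmi.hazards import cc_substudy_table
from cohortmi.mi_smc import (
    ProposalModel,
    ProposalSpec,
    SubstantiveSpec,
    Term,
    _rejection_sample_column,
    fit_covariate_model,
    full_cohort_fit_draw,
    mi_smc_run,
    smc_accept_prob,
)
from cohortmi.simulate import SimScenario, generate_event_times, simulate_cohort
from cohortmi.stepfun import StepFunction


class ZeroNoiseRng:
    """Stands in for a Generator so posterior draws collapse to the mean."""

    def standard_normal(self, size=None):
        return np.zeros(size) if size is not None else 0.0


class TestAcceptProbability:
    def test_zero_hazard_always_accepts_censored(self):
        H0 = StepFunction.zero()
        assert smc_accept_prob(1.0, 0.0, 5.0, H0) == pytest.approx(1.0)

    def test_event_at_unit_scaled_hazard_accepts_surely(self):
        # u = H0(T) e^lp = 1 is the mode of u exp(-u)
        H0 = StepFunction(np.array([0.5]), np.array([1.0]))
        assert smc_accept_prob(1.0, 1.0, 0.0, H0) == pytest.approx(1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        h=st.floats(0.0, 50.0),
        lp=st.floats(-20.0, 20.0),
        d=st.sampled_from([0.0, 1.0]),
    )
    def test_probability_always_in_unit_interval(self, h, lp, d):
        H0 = (
            StepFunction(np.array([0.5]), np.array([h]))
            if h > 0
            else StepFunction.zero()
        )
        p = smc_accept_prob(np.array([1.0]), np.array([d]), np.array([lp]), H0)
        assert 0.0 <= p[0] <= 1.0


class TestProposalSpec:
    def test_outcome_columns_forbidden(self):
        with pytest.raises(ValueError, match="outcome"):
            ProposalSpec("x2", "logistic", ("x1", "time"))
        with pytest.raises(ValueError, match="outcome"):
            ProposalSpec("x2", "logistic", ("x1", "event"))

    def test_log_transform_requires_linear_family(self):
        with pytest.raises(ValueError):
            ProposalSpec("x2", "logistic", ("z",), target_transform="log")


@pytest.fixture(scope="module")
def ncc_data():
    scen = SimScenario(n_cohort=1500, seed=31, censor_time=0.4)
    cohort = simulate_cohort(scen)
    _, info = sample_ncc(cohort, 1, np.random.default_rng(4))
    return cohort.loc[info.substudy_member.astype(bool)].reset_index(drop=True)


class TestCovariateModel:
    def test_full_data_equals_unweighted_fit(self, ncc_data):
        spec = ProposalSpec("x2", "logistic", ("x1", "z"))
        rng = ZeroNoiseRng()
        m1 = fit_covariate_model(ncc_data, spec, rng)
        import statsmodels.api as sm

        X = np.column_stack([np.ones(len(ncc_data)), ncc_data[["x1", "z"]].to_numpy()])
        ref = sm.GLM(ncc_data["x2"].to_numpy(), X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(m1.alpha, ref.params, atol=1e-8)

    def test_unit_ipw_weights_match_unweighted(self, ncc_data):
        rng = ZeroNoiseRng()
        full = fit_covariate_model(
            ncc_data, ProposalSpec("x2", "logistic", ("x1", "z")), rng
        )
        ipw = fit_covariate_model(
            ncc_data,
            ProposalSpec("x2", "logistic", ("x1", "z"), fit_method="ipw_samuelsen"),
            rng,
            weights=np.ones(len(ncc_data)),
        )
        np.testing.assert_allclose(ipw.alpha, full.alpha, atol=1e-8)

    def test_ipw_without_weights_rejected(self, ncc_data):
        with pytest.raises(ValueError, match="weights"):
            fit_covariate_model(
                ncc_data,
                ProposalSpec("x2", "logistic", ("x1", "z"), fit_method="ipw_samuelsen"),
                np.random.default_rng(0),
            )

    def test_subcohort_method_needs_membership_column(self, ncc_data):
        with pytest.raises(ValueError, match="subcohort"):
            fit_covariate_model(
                ncc_data,
                ProposalSpec("x2", "logistic", ("x1", "z"), fit_method="subcohort"),
                np.random.default_rng(0),
            )

    def test_controls_only_and_ipw_recover_generating_coefficients(self):
        # cohort built so x2 | x1, z is exactly logistic; both NCC covariate
        # model estimators should recover (a, b, c), controls-only with a
        # rare-disease bias bounded by the event fraction
        truth = np.array([-0.3, 0.8, 0.5])
        reps = 30
        rng = np.random.default_rng(77)
        est_controls, est_ipw = [], []
        scen = SimScenario(n_cohort=3000, seed=0, censor_time=0.35)
        from cohortmi.designs import samuelsen_prob

        for r in range(reps):
            n = scen.n_cohort
            x1 = rng.normal(size=n)
            z = (rng.random(n) < 0.5).astype(float)
            x2 = (rng.random(n) < expit(truth[0] + truth[1] * x1 + truth[2] * z)).astype(float)
            cov = pd.DataFrame({"x1": x1, "x2": x2, "z": z})
            surv = generate_event_times(cov, scen, rng)
            cohort = pd.concat([cov, surv], axis=1)
            cohort.insert(0, "id", np.arange(n))
            sets, info = sample_ncc(cohort, 4, rng)
            sub = cohort.loc[info.substudy_member.astype(bool)].reset_index(drop=True)
            zn = ZeroNoiseRng()
            est_controls.append(
                fit_covariate_model(
                    sub, ProposalSpec("x2", "logistic", ("x1", "z"),
                                      fit_method="controls_only"), zn
                ).alpha
            )
            probs = samuelsen_prob(cohort, 4)
            in_sub = info.substudy_member.astype(bool)
            d_sub = cohort.loc[in_sub, "event"].to_numpy()
            w = np.where(d_sub == 1.0, 1.0, 1.0 / probs[in_sub])
            est_ipw.append(
                fit_covariate_model(
                    sub, ProposalSpec("x2", "logistic", ("x1", "z"),
                                      fit_method="ipw_samuelsen"), zn, weights=w
                ).alpha
            )
        event_frac = 0.1
        for ests, slack in ((np.array(est_ipw), 0.0), (np.array(est_controls), event_frac)):
            mc_se = ests.std(axis=0, ddof=1) / np.sqrt(reps)
            assert np.all(np.abs(ests.mean(axis=0) - truth) < 3 * mc_se + slack)


def two_point_conditional(z, T, D, H0_T, beta_x, beta_z, p_x_given_z):
    """Exact p(x | T, D, z) on {0, 1} by normalizing p(T, D | x, z) p(x | z)."""
    probs = []
    for x in (0.0, 1.0):
        lp = beta_x * x + beta_z * z
        dens = np.exp(lp) ** D * np.exp(-H0_T * np.exp(lp))
        prior = p_x_given_z if x == 1.0 else 1.0 - p_x_given_z
        probs.append(dens * prior)
    probs = np.asarray(probs)
    return probs[1] / probs.sum()


class TestRejectionSampler:
    @pytest.mark.parametrize("D", [0.0, 1.0])
    def test_accepted_draws_match_exact_two_point_conditional(self, D):
        n = 20_000
        beta_x, beta_z = 0.8, 0.4
        z = 1.0
        T, H0_val = 0.3, 0.6
        gamma = np.array([-0.2, 0.3])  # proposal logit: g0 + g1 z
        p_prior = expit(gamma[0] + gamma[1] * z)
        work = pd.DataFrame(
            {
                "time": np.full(n, T),
                "event": np.full(n, D),
                "x": np.full(n, np.nan),
                "z": np.full(n, z),
            }
        )
        substantive = SubstantiveSpec((Term("x"), Term("z")), ("x",))
        spec = ProposalSpec("x", "logistic", ("z",))
        proposal = ProposalModel(spec=spec, alpha=gamma)
        H0 = StepFunction(np.array([0.1]), np.array([H0_val]))
        col, n_fb = _rejection_sample_column(
            work, substantive, np.array([beta_x, beta_z]), H0, proposal,
            work["x"].isna().to_numpy(), 1000, np.random.default_rng(13),
        )
        assert n_fb == 0
        p_exact = two_point_conditional(z, T, D, H0_val, beta_x, beta_z, p_prior)
        se = np.sqrt(p_exact * (1 - p_exact) / n)
        assert abs(col.mean() - p_exact) < 3 * se

    def test_no_missing_data_gives_bit_identical_copies(self):
        scen = SimScenario(n_cohort=400, seed=41, censor_time=0.4)
        cohort = simulate_cohort(scen)
        substantive = SubstantiveSpec.linear(("x1", "x2", "z"), ("x2",))
        out = mi_smc_run(
            cohort, substantive, [ProposalSpec("x2", "logistic", ("x1", "z"))],
            full_cohort_fit_draw(substantive), M=3, n_cycles=2,
            rng=np.random.default_rng(1),
        )
        for d in out.datasets:
            pd.testing.assert_frame_equal(d, cohort)

    def test_full_cohort_draw_baseline_matches_breslow_at_drawn_beta(self):
        scen = SimScenario(n_cohort=400, seed=42, censor_time=0.4)
        cohort = simulate_cohort(scen)
        substantive = SubstantiveSpec.linear(("x1", "x2", "z"), ("x2",))
        beta_m, H0 = full_cohort_fit_draw(substantive)(cohort, ZeroNoiseRng())
        ref = breslow_baseline(cohort, beta_m, ["x1", "x2", "z"])
        np.testing.assert_allclose(H0.cumulative_values, ref.cumulative_values, rtol=1e-12)

    def test_transformed_proposal_reduces_misspecification_bias(self):
        # log-normal x1 with a linear substantive term: a normal proposal for
        # log(x1) must beat a normal proposal for x1 itself on bias in the
        # x1 coefficient
        reps, n = 6, 3000
        bias = {"identity": [], "log": []}
        for r in range(reps):
            scen = SimScenario(
                n_cohort=n, seed=500 + r, variant="misspecified",
                beta_x1=0.7, beta_x2=0.7, beta_z=0.7, censor_time=0.7,
            )
            cohort = simulate_cohort(scen)
            masked = cohort.copy()
            # x1 missing by design: observed only in a 15% substudy-like
            # subset plus the cases, as in a case-cohort sample
            rng_d = np.random.default_rng(600 + r)
            observed = (rng_d.random(n) < 0.15) | (cohort["event"].to_numpy() == 1)
            masked.loc[~observed, "x1"] = np.nan
            for transform in ("identity", "log"):
                substantive = SubstantiveSpec.linear(("x1", "x2", "z"), ("x1",))
                prop = ProposalSpec("x1", "linear", ("x2", "z"),
                                    target_transform=transform)
                out = mi_smc_run(
                    masked, substantive, [prop], full_cohort_fit_draw(substantive),
                    M=3, n_cycles=4, rng=np.random.default_rng(700 + r),
                )
                from cohortmi.cox import fit_cox_full

                ests = [fit_cox_full(d, ["x1", "x2", "z"]).beta[0] for d in out.datasets]
                bias[transform].append(np.mean(ests) - 0.7)
        assert abs(np.mean(bias["log"])) < abs(np.mean(bias["identity"]))

    def test_missing_target_without_proposal_rejected(self):
        scen = SimScenario(n_cohort=200, seed=43, censor_time=0.4)
        cohort = simulate_cohort(scen)
        cohort.loc[cohort.index[:20], "x2"] = np.nan
        substantive = SubstantiveSpec.linear(("x1", "x2", "z"), ("x2",))
        with pytest.raises(ValueError, match="proposal"):
            mi_smc_run(cohort, substantive, [], full_cohort_fit_draw(substantive),
                       M=2, rng=np.random.default_rng(0))
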