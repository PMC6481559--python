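"""Synthetic prospective cohorts with substudy-style missingness.

The generator emulates a prospective cohort with three correlated explanatory
variables — continuous ``x1``, binary ``x2`` and binary ``z`` — and event
times from a Weibull proportional-hazards model

    h(t | x1, x2, z) = t * lam * exp(beta_x1*x1 + beta_x2*x2 + beta_z*z),

so the cumulative hazard is H(t) = (lam * t^2 / 2) * exp(lp) and latent event
times can be drawn by inverse transform, t = sqrt(-2*log(U) / (lam*exp(lp))).
Administrative censoring is applied at a fixed time.  Missingness by chance
in ``x2`` follows a missing-at-random logistic model in ``z``, the event
indicator ``d`` and their interaction, with the intercept calibrated by root
finding so the population-averaged missingness fraction hits its target.

A "misspecified" variant generates log-normal ``x1`` and an ``x2`` that
depends on ``x1 + x1^2``, which breaks normal/main-effects imputation models
downstream while the substantive Cox model keeps linear terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "SimScenario",
    "generate_covariates",
    "generate_misspecified",
    "generate_event_times",
    "generate_missingness",
    "simulate_cohort",
    "calibrate_censor_time",
    "calibrate_missingness_intercept",
    "scenario_from_yaml",
    "cohort_to_csv",
    "cohort_from_csv",
]

COHORT_COLUMNS = ["id", "time", "event", "x1", "x2", "z", "miss_x1_design", "miss_x2_chance"]


@dataclass(frozen=True)
class SimScenario:
    """Configuration of one simulated-cohort condition.

    Parameters
    ----------
    n_cohort
        Cohort size (default 15,000).
    lam
        Weibull rate parameter of the hazard ``h(t) = t*lam*exp(lp)``.
    beta_x1, beta_x2, beta_z
        Log hazard ratios of the generating Cox model.
    covariate_corr
        Exchangeable correlation of the latent trivariate Gaussian behind
        (x1, x2, z); must keep the latent covariance positive definite.
    p_x2, p_z
        Marginal Bernoulli probabilities of the binary covariates.
    missing_frac_x2
        Population-averaged fraction of x2 values missing by chance.
    gamma_z, gamma_d, gamma_zd
        Log-odds slopes of the missingness model for x2 on z, d and z*d.
    censor_time
        Fixed administrative censoring time; ``None`` disables censoring.
    variant
        ``"standard"`` or ``"misspecified"`` covariate generator.
    seed
        Mandatory integer seed; identical scenario+seed gives a bit-identical
        cohort.
    """

    n_cohort: int = 15_000
    lam: float = 1.0
    beta_x1: float = 0.2
    beta_x2: float = 0.2
    beta_z: float = 0.2
    covariate_corr: float = 0.5
    p_x2: float = 0.5
    p_z: float = 0.5
    missing_frac_x2: float = 0.5
    gamma_z: float = 0.5
    gamma_d: float = 0.5
    gamma_zd: float = 0.25
    censor_time: float | None = 0.5
    variant: str = "standard"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohort < 1:
            raise ValueError("n_cohort must be positive")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        for name in ("p_x2", "p_z", "missing_frac_x2"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.variant not in ("standard", "misspecified"):
            raise ValueError("variant must be 'standard' or 'misspecified'")
        if self.censor_time is not None and self.censor_time <= 0:
            raise ValueError("censor_time must be positive or None")
        rho = self.covariate_corr
        if not -1.0 < rho < 1.0 or np.linalg.eigvalsh(self._latent_corr()).min() <= 1e-12:
            raise ValueError(
                "covariate_corr does not give a positive-definite latent "
                "3x3 exchangeable correlation (need -0.5 < corr < 1)"
            )

    def _latent_corr(self) -> np.ndarray:
        rho = self.covariate_corr
        return np.full((3, 3), rho) + (1.0 - rho) * np.eye(3)

    @property
    def betas(self) -> np.ndarray:
        return np.array([self.beta_x1, self.beta_x2, self.beta_z])

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def generate_covariates(scenario: SimScenario, rng: np.random.Generator) -> pd.DataFrame:
    """Draw (x1, x2, z) from the latent-Gaussian copula of the standard variant.

    x1 is the first latent coordinate (marginally standard normal); x2 and z
    are obtained by thresholding the other two coordinates at the upper
    quantile matching their marginal probability, so a positive latent
    correlation yields positively associated binaries.
    """
    if scenario.variant != "standard":
        raise ValueError("generate_covariates requires variant='standard'")
    corr = scenario._latent_corr()
    chol = np.linalg.cholesky(corr)
    latent = rng.standard_normal((scenario.n_cohort, 3)) @ chol.T
    x1 = latent[:, 0]
    x2 = (latent[:, 1] > norm.ppf(1.0 - scenario.p_x2)).astype(float)
    z = (latent[:, 2] > norm.ppf(1.0 - scenario.p_z)).astype(float)
    return pd.DataFrame({"x1": x1, "x2": x2, "z": z})


def generate_misspecified(scenario: SimScenario, rng: np.random.Generator) -> pd.DataFrame:
    """Covariates of the misspecified variant.

    z ~ Bernoulli(p_z); log x1 ~ Normal(0.25*z, 0.65^2);
    x2 ~ Bernoulli(expit(0.5*z + 0.25*(x1 + x1^2))).
    """
    if scenario.variant != "misspecified":
        raise ValueError("generate_misspecified requires variant='misspecified'")
    n = scenario.n_cohort
    z = (rng.random(n) < scenario.p_z).astype(float)
    x1 = np.exp(0.25 * z + 0.65 * rng.standard_normal(n))
    p = expit(0.5 * z + 0.25 * (x1 + x1**2))
    x2 = (rng.random(n) < p).astype(float)
    return pd.DataFrame({"x1": x1, "x2": x2, "z": z})


def _jitter_event_ties(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Break tied event times by a jitter of a few machine epsilons."""
    time = time.copy()
    ev_idx = np.flatnonzero(event == 1)
    if ev_idx.size == 0:
        return time
    for _ in range(100):
        ev_times = time[ev_idx]
        order = np.argsort(ev_times, kind="stable")
        sorted_t = ev_times[order]
        dup = np.concatenate([[False], np.diff(sorted_t) == 0])
        if not dup.any():
            return time
        bump = sorted_t[dup] * np.finfo(float).eps * 8.0
        time[ev_idx[order[dup]]] = sorted_t[dup] + np.maximum(bump, np.finfo(float).tiny)
    raise RuntimeError("could not break event-time ties by jitter")


def generate_event_times(
    covariates: pd.DataFrame, scenario: SimScenario, rng: np.random.Generator
) -> pd.DataFrame:
    """Inverse-transform event times under the Weibull hazard, with censoring.

    The latent time solves H(t) = -log(U): t = sqrt(-2*log(U)/(lam*exp(lp))).
    ``event = 1`` iff the latent time does not exceed the censoring time;
    tied event times are separated by an infinitesimal jitter.
    """
    if covariates[["x1", "x2", "z"]].isna().any().any():
        raise ValueError("covariates must be complete to generate event times")
    lp = covariates[["x1", "x2", "z"]].to_numpy() @ scenario.betas
    u = rng.random(len(covariates))
    latent = np.sqrt(-2.0 * np.log(u) / (scenario.lam * np.exp(lp)))
    if scenario.censor_time is None:
        time, event = latent, np.ones(len(latent))
    else:
        event = (latent <= scenario.censor_time).astype(float)
        time = np.minimum(latent, scenario.censor_time)
    time = _jitter_event_ties(time, event)
    return pd.DataFrame({"time": time, "event": event})


def calibrate_missingness_intercept(
    z: np.ndarray, d: np.ndarray, scenario: SimScenario
) -> float:
    """Solve for the missingness-model intercept hitting the target fraction.

    One-dimensional root finding of
    mean_i expit(g0 + gamma_z*z_i + gamma_d*d_i + gamma_zd*z_i*d_i) = target.
    """
    shift = scenario.gamma_z * z + scenario.gamma_d * d + scenario.gamma_zd * z * d
    target = scenario.missing_frac_x2

    def f(g0: float) -> float:
        return float(np.mean(expit(g0 + shift))) - target

    lo, hi = -50.0, 50.0
    if not f(lo) < 0.0 < f(hi):
        raise ValueError(
            f"target fraction {target} unattainable; feasible range is "
            f"({np.mean(expit(lo + shift)):.3g}, {np.mean(expit(hi + shift)):.3g})"
        )
    return brentq(f, lo, hi, xtol=1e-12)


def generate_missingness(
    cohort: pd.DataFrame, scenario: SimScenario, rng: np.random.Generator
) -> pd.DataFrame:
    """Mask x2 missing-at-random given (z, event) per the logistic model."""
    if cohort["x2"].isna().any():
        raise ValueError("cohort must have complete x2 before masking")
    out = cohort.copy()
    z = out["z"].to_numpy(float)
    d = out["event"].to_numpy(float)
    g0 = calibrate_missingness_intercept(z, d, scenario)
    p_miss = expit(g0 + scenario.gamma_z * z + scenario.gamma_d * d + scenario.gamma_zd * z * d)
    miss = rng.random(len(out)) < p_miss
    out.loc[miss, "x2"] = np.nan
    out["miss_x2_chance"] = miss.astype(int)
    return out


def simulate_cohort(scenario: SimScenario, mask_x2: bool = False) -> pd.DataFrame:
    """Generate one complete cohort table; optionally apply x2 missingness.

    Returns a frame with columns id, time, event, x1, x2, z,
    miss_x1_design, miss_x2_chance.  Missingness by design in x1 is applied
    later, when a substudy is drawn from the cohort.
    """
    rng = scenario.rng()
    if scenario.variant == "standard":
        cov = generate_covariates(scenario, rng)
    else:
        cov = generate_misspecified(scenario, rng)
    surv = generate_event_times(cov, scenario, rng)
    cohort = pd.concat([cov, surv], axis=1)
    cohort.insert(0, "id", np.arange(scenario.n_cohort))
    cohort["miss_x1_design"] = 0
    cohort["miss_x2_chance"] = 0
    cohort = cohort[COHORT_COLUMNS]
    if mask_x2:
        cohort = generate_missingness(cohort, scenario, rng)
    return cohort


def calibrate_censor_time(
    scenario: SimScenario, target_event_frac: float, n_mc: int = 100_000, seed: int = 12345
) -> float:
    """Censoring time giving a target event fraction, by root finding.

    The event probability given covariates is 1 - exp(-lam*c^2/2 * exp(lp));
    its population average is approximated on a large Monte Carlo covariate
    draw with an internal fixed seed, then inverted for the censoring time c.
    """
    if not 0.0 < target_event_frac < 1.0:
        raise ValueError("target_event_frac must lie in (0, 1)")
    mc = replace(scenario, n_cohort=n_mc, seed=seed)
    rng = mc.rng()
    cov = generate_covariates(mc, rng) if mc.variant == "standard" else generate_misspecified(mc, rng)
    lp = cov[["x1", "x2", "z"]].to_numpy() @ scenario.betas
    elp = np.exp(lp)

    def frac(c: float) -> float:
        return float(np.mean(-np.expm1(-scenario.lam * c * c / 2.0 * elp))) - target_event_frac

    hi = 1.0
    while frac(hi) < 0:
        hi *= 2.0
        if hi > 1e8:
            raise RuntimeError("failed to bracket censoring time")
    return brentq(frac, 1e-12, hi, xtol=1e-10)


def scenario_from_yaml(path) -> SimScenario:
    """Load a scenario from a flat key-value YAML file; ``seed`` is mandatory."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError("scenario file must specify a seed")
    if raw.get("censor_time") in ("none", "None"):
        raw["censor_time"] = None
    return SimScenario(**raw)


def cohort_to_csv(cohort: pd.DataFrame, path) -> None:
    """Write the cohort table; missing payloads become empty fields."""
    cohort.to_csv(path, index=False)


def cohort_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    return df[COHORT_COLUMNS]
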