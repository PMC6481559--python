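"""Substantive-model-compatible imputation by rejection sampling.

A proposal value for a missing covariate X is drawn from a covariate-only
model p(X | other covariates; gamma) — never conditioning on the outcome —
and accepted as a draw from p(X | T, D, other covariates) with probability
proportional to the Cox-model density of the observed outcome at the
proposed value:

    censored (D = 0): exp(-H0(T) * e^lp)
    event    (D = 1): u * exp(1 - u),  u = H0(T) * e^lp,

the event case being self-normalized through max_u u*e^(-u) = e^(-1); both
expressions lie in [0, 1] for any nonnegative u.  The substantive-model
parameters (beta, H0) are redrawn each FCS cycle from the fit appropriate to
the analysis approach: full partial likelihood with the Breslow baseline on
the full cohort, or the modified partial likelihood with a design-adapted
baseline estimator on the substudy.

Because the acceptance probability is evaluated through the substantive
model's own linear predictor, imputed variables may enter that model through
transformations (log, square, interactions) while the proposal models them
on whatever scale fits; compatibility is preserved automatically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .cox import RiskSetIndex, breslow_baseline, fit_cox_full, fit_cox_substudy
from .hazards import h0_cc, h0_ncc
from .mi_common import ImputedDatasets, initial_fill, linear_posterior_draw, mvn_draw
from .stepfun import StepFunction

logger = logging.getLogger(__name__)

__all__ = [
    "Term",
    "SubstantiveSpec",
    "ProposalSpec",
    "ProposalModel",
    "fit_covariate_model",
    "smc_accept_prob",
    "full_cohort_fit_draw",
    "cc_substudy_fit_draw",
    "ncc_substudy_fit_draw",
    "mi_smc_run",
]

OUTCOME_COLUMNS = frozenset({"time", "event"})


@dataclass(frozen=True)
class Term:
    """One term of the Cox linear predictor: a transformed raw covariate.

    ``transform`` is one of identity/log/square; ``interact_with`` multiplies
    by a second raw covariate.
    """

    covariate: str
    transform: str = "identity"
    interact_with: str | None = None

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "log", "square"):
            raise ValueError("transform must be identity, log or square")

    @property
    def name(self) -> str:
        base = {"identity": "{0}", "log": "log({0})", "square": "{0}^2"}[self.transform]
        label = base.format(self.covariate)
        return f"{label}*{self.interact_with}" if self.interact_with else label

    def column(self, df: pd.DataFrame) -> np.ndarray:
        x = df[self.covariate].to_numpy(float)
        if self.transform == "log":
            x = np.log(x)
        elif self.transform == "square":
            x = x * x
        if self.interact_with:
            x = x * df[self.interact_with].to_numpy(float)
        return x


@dataclass(frozen=True)
class SubstantiveSpec:
    """The Cox substantive model: terms of the linear predictor and which
    raw covariates are imputation targets."""

    terms: tuple
    targets: tuple

    def __post_init__(self) -> None:
        raws = {t.covariate for t in self.terms} | {
            t.interact_with for t in self.terms if t.interact_with
        }
        for tgt in self.targets:
            if tgt not in raws:
                raise ValueError(f"target {tgt!r} appears in no substantive term")

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def design(self, df: pd.DataFrame) -> np.ndarray:
        return np.column_stack([t.column(df) for t in self.terms])

    def with_term_columns(self, df: pd.DataFrame) -> pd.DataFrame:
        """Copy of ``df`` with one column per substantive term."""
        out = df.copy()
        for t in self.terms:
            out[t.name] = t.column(df)
        return out

    @classmethod
    def linear(cls, covariates=("x1", "x2", "z"), targets=("x1", "x2")) -> "SubstantiveSpec":
        return cls(tuple(Term(c) for c in covariates), tuple(targets))


@dataclass(frozen=True)
class ProposalSpec:
    """Proposal distribution p(X | other covariates): family, predictors and
    (for linear) the scale the target is modelled on.

    Proposals must condition only on covariates, never on the outcome.
    ``target_transform='log'`` models log X as conditionally normal while the
    substantive model still receives X itself.
    """

    target: str
    family: str  # "linear" or "logistic"
    predictors: tuple
    target_transform: str = "identity"  # identity | log (linear family only)
    fit_method: str = "full_data"  # full_data | subcohort | controls_only | ipw_samuelsen

    def __post_init__(self) -> None:
        if self.family not in ("linear", "logistic"):
            raise ValueError("family must be 'linear' or 'logistic'")
        if self.target_transform not in ("identity", "log"):
            raise ValueError("target_transform must be 'identity' or 'log'")
        if self.target_transform == "log" and self.family != "linear":
            raise ValueError("log target transform applies to the linear family only")
        if self.fit_method not in ("full_data", "subcohort", "controls_only", "ipw_samuelsen"):
            raise ValueError(f"unknown covariate-model fit method {self.fit_method!r}")
        bad = (set(self.predictors) | {self.target}) & OUTCOME_COLUMNS
        if bad:
            raise ValueError(f"proposal must not involve outcome columns: {sorted(bad)}")
        if self.target in self.predictors:
            raise ValueError("target must not predict itself")


@dataclass
class ProposalModel:
    """A fitted proposal distribution with drawn parameters."""

    spec: ProposalSpec
    alpha: np.ndarray
    sigma: float | None = None  # linear family residual SD

    def draw(self, df: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
        X = np.column_stack([np.ones(len(df)), df[list(self.spec.predictors)].to_numpy(float)])
        eta = X @ self.alpha
        if self.spec.family == "logistic":
            return (rng.random(len(df)) < expit(eta)).astype(float)
        vals = eta + self.sigma * rng.standard_normal(len(df))
        if self.spec.target_transform == "log":
            vals = np.exp(vals)
        return vals


def fit_covariate_model(
    data: pd.DataFrame,
    spec: ProposalSpec,
    rng: np.random.Generator,
    observed_mask: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> ProposalModel:
    """Fit the proposal model and draw its parameters from the posterior.

    The fitting rows depend on ``spec.fit_method``:

    * ``full_data`` — every observed-target row (weights all one);
    * ``subcohort`` — observed-target rows with ``subcohort == 1`` (the
      subcohort is a random sample of the cohort, CC design);
    * ``controls_only`` — observed-target rows with ``event == 0``, the
      rare-disease approximation p(X|...) ~= p(X|..., D=0) (NCC design);
    * ``ipw_samuelsen`` — all observed-target rows, non-cases weighted by the
      reciprocal of their Samuelsen inclusion probability (``weights``),
      cases with weight 1.
    """
    if observed_mask is None:
        observed_mask = ~data[spec.target].isna().to_numpy()
    mask = np.asarray(observed_mask, dtype=bool).copy()
    w = np.ones(len(data))
    if spec.fit_method == "subcohort":
        if "subcohort" not in data.columns:
            raise ValueError("fit_method 'subcohort' needs a subcohort membership column")
        mask &= data["subcohort"].to_numpy(bool)
    elif spec.fit_method == "controls_only":
        mask &= data["event"].to_numpy(float) == 0.0
    elif spec.fit_method == "ipw_samuelsen":
        if weights is None:
            raise ValueError("fit_method 'ipw_samuelsen' requires inclusion-probability weights")
        w = np.asarray(weights, dtype=float)
    if not mask.any():
        raise ValueError(f"empty fitting subset for proposal of {spec.target!r}")
    rows = data.loc[mask]
    w = w[mask]
    y = rows[spec.target].to_numpy(float)
    if spec.target_transform == "log":
        y = np.log(y)
    X = np.column_stack([np.ones(len(rows)), rows[list(spec.predictors)].to_numpy(float)])
    if spec.family == "linear":
        res = sm.WLS(y, X, weights=w).fit()
        Xw = X * np.sqrt(w)[:, None]
        alpha, sigma2 = linear_posterior_draw(
            res.params, np.linalg.inv(Xw.T @ Xw), float(res.scale), int(res.df_resid), rng
        )
        return ProposalModel(spec=spec, alpha=alpha, sigma=float(np.sqrt(sigma2)))
    glm = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
    res = glm.fit()
    alpha = mvn_draw(res.params, np.asarray(res.cov_params()), rng)
    return ProposalModel(spec=spec, alpha=alpha)


def smc_accept_prob(T, D, linear_predictor, H0: StepFunction) -> np.ndarray:
    """Rejection-rule acceptance probability, elementwise in [0, 1]."""
    u = H0(np.asarray(T, dtype=float)) * np.exp(np.asarray(linear_predictor, dtype=float))
    D = np.asarray(D, dtype=float)
    with np.errstate(over="ignore"):
        p = np.where(D == 1.0, u * np.exp(1.0 - u), np.exp(-u))
    return np.clip(np.nan_to_num(p, nan=0.0), 0.0, 1.0)


def _beta_draw(fit, rng):
    return mvn_draw(fit.beta, fit.vcov, rng)


def full_cohort_fit_draw(substantive: SubstantiveSpec):
    """Substantive-parameter draw for the full-cohort approach.

    Refits the full partial likelihood on the working data, draws
    beta ~ Normal(beta_hat, V_hat), and recomputes the Breslow baseline at
    the drawn beta.
    """

    def fit_draw(work: pd.DataFrame, rng: np.random.Generator):
        tdf = substantive.with_term_columns(work)
        fit = fit_cox_full(tdf, substantive.term_names)
        beta_m = _beta_draw(fit, rng)
        return beta_m, breslow_baseline(tdf, beta_m, substantive.term_names)

    return fit_draw


def cc_substudy_fit_draw(substantive: SubstantiveSpec, risk_sets, design_info):
    """Substantive draw for the CC substudy approach: pseudo-partial
    likelihood with sandwich variance and the modified Breslow baseline
    scaled by the known subcohort sampling fraction."""

    cache: dict = {}

    def fit_draw(work: pd.DataFrame, rng: np.random.Generator):
        tdf = substantive.with_term_columns(work)
        if "index" not in cache:
            cache["index"] = RiskSetIndex(tdf["id"], risk_sets)
        fit = fit_cox_substudy(
            tdf, risk_sets, "sandwich", substantive.term_names,
            index=cache["index"], beta0=cache.get("beta"),
        )
        cache["beta"] = fit.beta
        beta_m = _beta_draw(fit, rng)
        return beta_m, h0_cc(tdf, beta_m, design_info, substantive.term_names)

    return fit_draw


def ncc_substudy_fit_draw(substantive: SubstantiveSpec, risk_sets, n_at_risk):
    """Substantive draw for the NCC substudy approach: maximum modified
    partial likelihood and the sampled-risk-set baseline estimator (needs
    full-cohort at-risk counts: the time-only information setting)."""

    cache: dict = {}

    def fit_draw(work: pd.DataFrame, rng: np.random.Generator):
        tdf = substantive.with_term_columns(work)
        if "index" not in cache:
            cache["index"] = RiskSetIndex(tdf["id"], risk_sets)
        fit = fit_cox_substudy(
            tdf, risk_sets, "model", substantive.term_names,
            index=cache["index"], beta0=cache.get("beta"),
        )
        cache["beta"] = fit.beta
        beta_m = _beta_draw(fit, rng)
        return beta_m, h0_ncc(tdf, risk_sets, beta_m, n_at_risk, substantive.term_names)

    return fit_draw


def _target_lp_parts(substantive, beta_m, sub: pd.DataFrame, target: str):
    """Split the linear predictor into a fixed part and target-dependent terms.

    Returns ``lp_fixed`` (contribution of terms not involving the target) and
    a list of ``(beta_j, transform, multiplier)`` for terms that do, so the
    rejection loop can update the linear predictor from a candidate vector
    without touching pandas.
    """
    lp_fixed = np.zeros(len(sub))
    dynamic = []
    for coef, term in zip(beta_m, substantive.terms):
        involves = term.covariate == target or term.interact_with == target
        if not involves:
            lp_fixed += coef * term.column(sub)
            continue
        if term.covariate == target:
            mult = sub[term.interact_with].to_numpy(float) if term.interact_with else 1.0
            dynamic.append((coef, term.transform, mult))
        else:  # fixed covariate interacting with the candidate target
            base = Term(term.covariate, term.transform).column(sub)
            dynamic.append((coef, "identity", base))
    return lp_fixed, dynamic


def _apply_dynamic(dynamic, cand: np.ndarray) -> np.ndarray:
    lp = np.zeros(cand.shape)
    for coef, transform, mult in dynamic:
        x = cand
        if transform == "log":
            x = np.log(x)
        elif transform == "square":
            x = x * x
        lp += coef * (x * mult if not np.isscalar(mult) else x * mult)
    return lp


def _rejection_sample_column(
    work, substantive, beta_m, H0_m, proposal, missing_mask, max_rejects, rng
):
    """Redraw the missing cells of one target by rejection sampling.

    All per-iteration work is plain numpy: the proposal linear predictor and
    the fixed part of the substantive linear predictor are precomputed for
    the missing rows, and only the candidate-dependent terms are re-evaluated.
    """
    rows = np.flatnonzero(missing_mask)
    if rows.size == 0:
        return work[proposal.spec.target].to_numpy(float), 0
    sub = work.iloc[rows]
    T = sub["time"].to_numpy(float)
    D = sub["event"].to_numpy(float)
    H0_T = np.asarray(H0_m(T), dtype=float)

    spec = proposal.spec
    Xp = np.column_stack([np.ones(rows.size), sub[list(spec.predictors)].to_numpy(float)])
    eta_prop = Xp @ proposal.alpha
    lp_fixed, dynamic = _target_lp_parts(substantive, beta_m, sub, spec.target)

    undecided = np.arange(rows.size)
    best_prob = np.full(rows.size, -1.0)
    best_val = np.empty(rows.size)
    accepted_val = np.empty(rows.size)
    n_fallback = 0
    attempts = 0
    batch = 64  # candidates drawn per cell per round; sequential-order equivalent
    while attempts < max_rejects and undecided.size:
        b = min(batch, max_rejects - attempts)
        m = undecided.size
        if spec.family == "logistic":
            cand = (rng.random((b, m)) < expit(eta_prop[undecided])).astype(float)
        else:
            cand = eta_prop[undecided] + proposal.sigma * rng.standard_normal((b, m))
            if spec.target_transform == "log":
                cand = np.exp(cand)
        lp = lp_fixed[undecided] + _apply_dynamic(
            [(c, tr, m_[undecided] if not np.isscalar(m_) else m_) for c, tr, m_ in dynamic],
            cand,
        )
        u = H0_T[undecided] * np.exp(lp)
        with np.errstate(over="ignore", invalid="ignore"):
            a = np.where(D[undecided] == 1.0, u * np.exp(1.0 - u), np.exp(-u))
        a = np.clip(np.nan_to_num(a, nan=0.0), 0.0, 1.0)  # (b, m)
        round_best = a.argmax(axis=0)
        rb_prob = a[round_best, np.arange(m)]
        better = rb_prob > best_prob[undecided]
        best_prob[undecided[better]] = rb_prob[better]
        best_val[undecided[better]] = cand[round_best, np.arange(m)][better]
        hit = rng.random((b, m)) < a
        any_hit = hit.any(axis=0)
        first = hit.argmax(axis=0)
        accepted_val[undecided[any_hit]] = cand[first, np.arange(m)][any_hit]
        undecided = undecided[~any_hit]
        attempts += b
    if undecided.size:
        n_fallback = int(undecided.size)
        logger.info(
            "%d cell(s) of %r hit max_rejects=%d; keeping the highest-acceptance draw",
            n_fallback, proposal.spec.target, max_rejects,
        )
        accepted_val[undecided] = best_val[undecided]
    out = work[proposal.spec.target].to_numpy(float).copy()
    out[rows] = accepted_val
    return out, n_fallback


def mi_smc_run(
    data: pd.DataFrame,
    substantive: SubstantiveSpec,
    proposals: list[ProposalSpec],
    fit_draw,
    M: int = 10,
    n_cycles: int = 10,
    max_rejects: int = 1000,
    rng: np.random.Generator | None = None,
    ipw_weights: np.ndarray | None = None,
) -> ImputedDatasets:
    """Run M independent SMC-FCS chains.

    ``fit_draw(work, rng) -> (beta_draw, H0)`` supplies the approach-specific
    substantive fit; substantive parameters are redrawn at the start of every
    cycle.  Cells that exhaust ``max_rejects`` keep their
    highest-acceptance-probability draw; if more than 5% of cells fall back
    in a run, a warning is surfaced in the run log.
    """
    if rng is None:
        rng = np.random.default_rng()
    spec_by_target = {p.target: p for p in proposals}
    for tgt in substantive.targets:
        if data[tgt].isna().any() and tgt not in spec_by_target:
            raise ValueError(f"missing values in {tgt!r} but no proposal spec")
    masks = {p.target: data[p.target].isna().to_numpy() for p in proposals}
    total_missing = sum(int(m.sum()) for m in masks.values())

    datasets = []
    n_fallback_total = 0
    for _ in range(M):
        work = data.copy()
        for p in proposals:
            if masks[p.target].any():
                initial_fill(work, p.target, masks[p.target], rng)
        for _ in range(n_cycles):
            beta_m, H0_m = fit_draw(work, rng)
            for p in proposals:
                model = fit_covariate_model(
                    work, p, rng, observed_mask=~masks[p.target], weights=ipw_weights
                )
                col, nfb = _rejection_sample_column(
                    work, substantive, beta_m, H0_m, model, masks[p.target], max_rejects, rng
                )
                work[p.target] = col
                n_fallback_total += nfb
        datasets.append(work)
    log = {"n_fallback": n_fallback_total, "n_missing_cells": total_missing * n_cycles * M}
    if total_missing and n_fallback_total > 0.05 * total_missing * n_cycles * M:
        log["warning"] = "max_rejects exhausted on more than 5% of imputed cells"
        logger.warning(log["warning"])
    return ImputedDatasets(M=M, datasets=datasets, log=log)
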