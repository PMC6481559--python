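"""Approximate imputation for Cox outcomes (White–Royston style).

The imputation model for a partially observed covariate X regresses X on the
other covariates, the event indicator D, and the cumulative-hazard value
H(T) evaluated at each individual's follow-up time:

    linear:   X = a0 + a1'Z + a2*D + a3*H(T) + eps
    logistic: logit P(X=1 | ...) = a0 + a1'Z + a2*D + a3*H(T)

H(T) may come from the full-cohort Nelson–Aalen estimator or, in the
substudy approach, from a design-adapted estimator.  When several covariates
need imputation the models are cycled as chained equations (FCS); with a
single target one pass is a complete draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mi_common import ImputedDatasets, initial_fill, linear_posterior_draw, mvn_draw
from .stepfun import StepFunction

__all__ = [
    "ImputationModelSpec",
    "fit_imputation_model",
    "draw_imputation_params",
    "impute_once",
    "mi_approx_run",
]

CUMHAZ_COL = "_cumhaz"


@dataclass(frozen=True)
class ImputationModelSpec:
    """One univariate imputation model.

    ``predictors`` are covariate column names; the event indicator and the
    cumulative-hazard value are appended automatically unless
    ``include_event``/``include_cumhaz`` are disabled.
    """

    target: str
    family: str  # "linear" or "logistic"
    predictors: tuple
    include_event: bool = True
    include_cumhaz: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("linear", "logistic"):
            raise ValueError("family must be 'linear' or 'logistic'")
        if self.target in self.predictors:
            raise ValueError("target must not appear among its own predictors")

    def design_columns(self) -> list[str]:
        cols = list(self.predictors)
        if self.include_event:
            cols.append("event")
        if self.include_cumhaz:
            cols.append(CUMHAZ_COL)
        return cols


def _design_matrix(data: pd.DataFrame, cols: list[str]) -> np.ndarray:
    X = data[cols].to_numpy(float)
    return np.column_stack([np.ones(len(X)), X])


def _check_full_rank(X: np.ndarray, cols: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"singular imputation design matrix; collinear predictors among "
            f"intercept + {cols}"
        )


def fit_imputation_model(
    data: pd.DataFrame, spec: ImputationModelSpec, observed_mask: np.ndarray | None = None
) -> dict:
    """Maximum-likelihood fit on the rows where the target is observed.

    ``observed_mask`` marks the originally observed rows; inside an FCS cycle
    the working table has no NaNs, so the mask must be supplied to avoid
    fitting on imputed cells.
    """
    if observed_mask is None:
        observed_mask = ~data[spec.target].isna().to_numpy()
    obs = data.loc[observed_mask]
    cols = spec.design_columns()
    if obs[cols].isna().any().any():
        raise ValueError("predictors contain missing payloads; FCS must fill them first")
    X = _design_matrix(obs, cols)
    y = obs[spec.target].to_numpy(float)
    _check_full_rank(X, cols)
    if spec.family == "linear":
        res = sm.OLS(y, X).fit()
        XtX_inv = np.linalg.inv(X.T @ X)
        return {
            "family": "linear",
            "alpha": res.params,
            "XtX_inv": XtX_inv,
            "sigma2": float(res.scale),
            "df": int(res.df_resid),
        }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100)
    return {"family": "logistic", "alpha": res.params, "vcov": np.asarray(res.cov_params())}


def draw_imputation_params(fit: dict, family: str, rng: np.random.Generator) -> dict:
    """Draw imputation-model parameters from their approximate posterior.

    Logistic: alpha ~ Normal(alpha_hat, V_hat).  Linear: sigma^2 drawn from
    its scaled inverse-chi-square posterior, then alpha ~ Normal(alpha_hat,
    sigma^2_m (X'X)^{-1}).
    """
    if family != fit["family"]:
        raise ValueError("family mismatch between fit and draw request")
    if family == "linear":
        alpha_m, sigma2_m = linear_posterior_draw(
            fit["alpha"], fit["XtX_inv"], fit["sigma2"], fit["df"], rng
        )
        return {"family": "linear", "alpha": alpha_m, "sigma": float(np.sqrt(sigma2_m))}
    return {"family": "logistic", "alpha": mvn_draw(fit["alpha"], fit["vcov"], rng)}


def impute_once(
    data: pd.DataFrame,
    spec: ImputationModelSpec,
    params: dict,
    rng: np.random.Generator,
    missing_mask: np.ndarray,
) -> np.ndarray:
    """Return the completed target column; observed cells untouched."""
    out = data[spec.target].to_numpy(float).copy()
    rows = data.loc[missing_mask]
    if len(rows) == 0:
        return out
    cols = spec.design_columns()
    if rows[cols].isna().any().any():
        raise ValueError("predictors missing for rows being imputed; FCS must fill first")
    eta = _design_matrix(rows, cols) @ params["alpha"]
    if params["family"] == "linear":
        out[missing_mask] = eta + params["sigma"] * rng.standard_normal(len(rows))
    else:
        from scipy.special import expit

        out[missing_mask] = (rng.random(len(rows)) < expit(eta)).astype(float)
    return out


def mi_approx_run(
    data: pd.DataFrame,
    specs: list[ImputationModelSpec],
    cumhaz: StepFunction,
    M: int = 10,
    n_cycles: int | None = None,
    rng: np.random.Generator | None = None,
) -> ImputedDatasets:
    """Produce M completed datasets by the approximate method.

    Each imputation initializes missing cells with draws from the observed
    marginal, then cycles the univariate models ``n_cycles`` times (default
    10 with two or more targets, 1 with a single target, where one pass is
    already a complete draw).
    """
    if rng is None:
        rng = np.random.default_rng()
    targets = [s.target for s in specs]
    for col in data.columns:
        if data[col].isna().any() and col not in targets and col != CUMHAZ_COL:
            raise ValueError(f"partially observed column {col!r} has no imputation spec")
    if n_cycles is None:
        n_cycles = 10 if len(specs) > 1 else 1
    masks = {s.target: data[s.target].isna().to_numpy() for s in specs}

    base = data.copy()
    base[CUMHAZ_COL] = cumhaz(base["time"].to_numpy(float))
    datasets = []
    for _ in range(M):
        work = base.copy()
        for s in specs:
            if masks[s.target].any():
                initial_fill(work, s.target, masks[s.target], rng)
        for _ in range(n_cycles):
            for s in specs:
                fit = fit_imputation_model(work, s, observed_mask=~masks[s.target])
                params = draw_imputation_params(fit, s.family, rng)
                work[s.target] = impute_once(work, s, params, rng, masks[s.target])
        datasets.append(work.drop(columns=[CUMHAZ_COL]))
    return ImputedDatasets(M=M, datasets=datasets, log={"n_cycles": n_cycles})
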