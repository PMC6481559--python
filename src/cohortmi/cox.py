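"""Cox model fitting by full and modified (substudy) partial likelihood.

The full-cohort analysis maximizes Cox's partial likelihood with risk sets
R_j = {k : T_k >= tau_j}.  Nested case-control and case-cohort substudies
are analysed with the modified partial likelihood in which R_j is replaced
by a sampled subset.  For the nested case-control design this is a true
partial likelihood and the model-based (inverse observed information)
variance applies; for the case-cohort design it is a pseudo-partial
likelihood and a robust sandwich variance built from per-individual score
residuals (Lin–Ying type) is used.

Both fits use Newton–Raphson with step-halving; ties are handled by the
Breslow approximation (the simulator produces none, but CSV inputs may).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stepfun import StepFunction

logger = logging.getLogger(__name__)

MAX_ABS_BETA = 20.0  # |log HR| beyond this indicates separation/monotone likelihood
SCORE_TOL = 1e-9
LOGLIK_RTOL = 1e-12
MAX_ITER = 50

__all__ = [
    "CoxFit",
    "RiskSetIndex",
    "fit_cox_full",
    "fit_cox_substudy",
    "nelson_aalen",
    "breslow_baseline",
]


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class CoxFit:
    """Result of a (pseudo-)partial-likelihood maximization.

    ``beta`` are log hazard ratios; ``vcov`` is model-based (inverse observed
    information) or sandwich, per ``variance_kind``.
    """

    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    converged: bool
    n_events: int
    variance_kind: str
    names: list[str]
    n_iter: int = 0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))


def _reverse_cumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def _invert_information(info: np.ndarray, context: str) -> np.ndarray:
    """Inverse observed information; pseudo-inverse for degenerate fits
    (e.g. a covariate constant within every risk set)."""
    try:
        return np.linalg.inv(info)
    except np.linalg.LinAlgError:
        warnings.warn(
            f"{context}: singular observed information; variance via pseudo-inverse",
            ConvergenceWarning,
        )
        return np.linalg.pinv(info)


def _full_quantities(t_s, d_s, X_s, beta):
    """Log-likelihood, score and information of the full partial likelihood.

    Rows must be sorted ascending in time.  Risk-set sums are suffix
    cumulative sums; tied event times share one Breslow denominator.
    """
    n, p = X_s.shape
    lp = X_s @ beta
    shift = lp.max() if n else 0.0
    w = np.exp(lp - shift)
    tau, d_counts = np.unique(t_s[d_s == 1], return_counts=True)
    start = np.searchsorted(t_s, tau, side="left")

    S0 = _reverse_cumsum(w)[start]
    S1 = _reverse_cumsum(X_s * w[:, None])[start]
    Xw = X_s * w[:, None]
    S2 = _reverse_cumsum(np.einsum("ni,nj->nij", X_s, Xw))[start]

    mu = S1 / S0[:, None]
    loglik = float(lp[d_s == 1].sum() - shift * d_counts.sum() - (d_counts * np.log(S0)).sum())
    score = X_s[d_s == 1].sum(axis=0) - (d_counts[:, None] * mu).sum(axis=0)
    info = np.einsum("j,jik->ik", d_counts, S2 / S0[:, None, None]) - np.einsum(
        "j,ji,jk->ik", d_counts.astype(float), mu, mu
    )
    return loglik, score, info


def _newton_raphson(quantities, p, context, beta0=None):
    """Maximize a concave objective via Newton–Raphson with step-halving."""
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    loglik, score, info = quantities(beta)
    n_iter = 0
    converged = False
    for n_iter in range(1, MAX_ITER + 1):
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(f"singular information matrix in {context}") from err
        new_beta = beta + step
        new_ll, new_score, new_info = quantities(new_beta)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < loglik) and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = quantities(new_beta)
            halvings += 1
        if np.max(np.abs(new_beta)) > MAX_ABS_BETA:
            raise RuntimeError(
                f"{context}: |beta| exceeded {MAX_ABS_BETA}; likely complete "
                "separation or a degenerate likelihood"
            )
        rel_change = abs(new_ll - loglik) / max(abs(loglik), 1.0)
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
        if np.max(np.abs(score)) < SCORE_TOL or rel_change < LOGLIK_RTOL:
            converged = np.max(np.abs(score)) < SCORE_TOL or rel_change < LOGLIK_RTOL
            break
    if not converged and np.max(np.abs(score)) >= SCORE_TOL:
        warnings.warn(f"{context}: Newton–Raphson did not converge", ConvergenceWarning)
    return beta, loglik, score, info, converged, n_iter


def fit_cox_full(data: pd.DataFrame, covariate_names: list[str]) -> CoxFit:
    """Maximum partial likelihood on a complete cohort table.

    Requires ``time`` and ``event`` columns and complete covariate payloads;
    at least one event.  Variance is the inverse observed information.
    """
    cov = data[list(covariate_names)]
    if cov.isna().any().any():
        raise ValueError("missing covariate payloads; impute before fitting")
    d = data["event"].to_numpy(float)
    if d.sum() < 1:
        raise ValueError("no events: partial likelihood is undefined")
    order = np.argsort(data["time"].to_numpy(), kind="stable")
    t_s = data["time"].to_numpy(float)[order]
    d_s = d[order]
    X_s = cov.to_numpy(float)[order]

    beta, loglik, _, info, converged, n_iter = _newton_raphson(
        lambda b: _full_quantities(t_s, d_s, X_s, b), X_s.shape[1], "full-cohort Cox fit"
    )
    return CoxFit(
        beta=beta,
        vcov=_invert_information(info, "full-cohort Cox fit"),
        loglik=loglik,
        converged=converged,
        n_events=int(d.sum()),
        variance_kind="model",
        names=list(covariate_names),
        n_iter=n_iter,
    )


class RiskSetIndex:
    """Precomputed flat member/set-index arrays for the modified partial
    likelihood, reusable across refits on tables with the same row ids
    (e.g. FCS cycles of an imputation run)."""

    def __init__(self, data_ids, risk_sets) -> None:
        id_index = pd.Index(data_ids)
        member_ids, set_idx, case_pos = [], [], []
        kept = 0
        for rs in risk_sets:
            members = [rs.case_id] + [m for m in rs.comparator_ids]
            if len(members) == 1:
                logger.info("risk set %s has no comparators; term contributes 1", rs.set_id)
                continue
            member_ids.extend(members)
            set_idx.extend([kept] * len(members))
            case_pos.append(len(member_ids) - len(members))
            kept += 1
        if kept == 0:
            raise ValueError("no informative risk sets (all lack comparators)")
        rows = id_index.get_indexer(member_ids)
        if (rows < 0).any():
            raise ValueError("risk set refers to ids absent from the data table")
        self.rows = rows
        self.set_idx = np.asarray(set_idx)
        self.case_pos = np.asarray(case_pos)
        self.n_sets = kept


def _flatten_risk_sets(data, risk_sets, covariate_names, index: RiskSetIndex | None = None):
    """Flat member arrays for the modified partial likelihood."""
    if index is None:
        index = RiskSetIndex(data["id"], risk_sets)
    Xm = data[list(covariate_names)].to_numpy(float)[index.rows]
    if np.isnan(Xm).any():
        raise ValueError("risk-set member with missing covariate payload")
    return index.rows, index.set_idx, index.case_pos, Xm, index.n_sets


def _substudy_quantities(Xm, F, starts, case_pos, J, beta):
    """Per-set sums via one segmented reduction over the flat member array.

    ``F`` holds [1, x_1..x_p, upper-triangle products] per member row;
    ``starts`` are the first member positions of each (contiguous) set.
    """
    p = Xm.shape[1]
    lp = Xm @ beta
    shift = lp.max() if lp.size else 0.0
    w = np.exp(lp - shift)
    S = np.add.reduceat(F * w[:, None], starts, axis=0)
    S0 = S[:, 0]
    mu = S[:, 1 : 1 + p] / S0[:, None]
    loglik = float((lp[case_pos] - shift).sum() - np.log(S0).sum())
    score = (Xm[case_pos] - mu).sum(axis=0)
    iu = np.triu_indices(p)
    s2 = (S[:, 1 + p :] / S0[:, None]).sum(axis=0)
    info = np.zeros((p, p))
    info[iu] = s2 - np.einsum("ji,jk->ik", mu, mu)[iu]
    info = info + info.T - np.diag(np.diag(info))
    return loglik, score, info, w, S0, mu


def fit_cox_substudy(
    data: pd.DataFrame,
    risk_sets,
    variance_kind: str = "model",
    covariate_names: list[str] = ("x1", "x2", "z"),
    index: RiskSetIndex | None = None,
    beta0=None,
) -> CoxFit:
    """Maximize the modified partial likelihood over sampled risk sets.

    ``variance_kind='model'`` (NCC: true partial likelihood) uses the inverse
    observed information; ``'sandwich'`` (CC: pseudo-partial likelihood) the
    robust variance from per-individual score residuals.
    """
    if variance_kind not in ("model", "sandwich"):
        raise ValueError("variance_kind must be 'model' or 'sandwich'")
    covariate_names = list(covariate_names)
    rows, set_idx, case_pos, Xm, J = _flatten_risk_sets(data, risk_sets, covariate_names, index)
    p = Xm.shape[1]
    starts = np.flatnonzero(np.concatenate([[True], np.diff(set_idx) != 0]))
    iu = np.triu_indices(p)
    F = np.column_stack([np.ones(len(Xm)), Xm, Xm[:, iu[0]] * Xm[:, iu[1]]])

    cache = {}

    def quantities(b):
        key = b.tobytes()
        if key not in cache:
            cache.clear()
            cache[key] = _substudy_quantities(Xm, F, starts, case_pos, J, b)
        ll, score, info, *_ = cache[key]
        return ll, score, info

    beta, loglik, _, info, converged, n_iter = _newton_raphson(
        quantities, p, "substudy Cox fit", beta0=beta0
    )
    info_inv = _invert_information(info, "substudy Cox fit")
    if variance_kind == "model":
        vcov = info_inv
    else:
        _, _, _, w, S0, mu = cache[beta.tobytes()]
        resid = Xm - mu[set_idx]
        contrib = -(w / S0[set_idx])[:, None] * resid
        contrib[case_pos] += resid[case_pos]
        n = len(data)
        U = np.zeros((n, p))
        np.add.at(U, rows, contrib)
        vcov = info_inv @ (U.T @ U) @ info_inv
    return CoxFit(
        beta=beta,
        vcov=vcov,
        loglik=loglik,
        converged=converged,
        n_events=J,
        variance_kind=variance_kind,
        names=covariate_names,
        n_iter=n_iter,
    )


def nelson_aalen(times, events) -> StepFunction:
    """Nelson–Aalen marginal cumulative hazard: jumps d(tau)/n(tau)."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float)
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if d.sum() == 0:
        return StepFunction.zero()
    order = np.argsort(t, kind="stable")
    t_s, d_s = t[order], d[order]
    tau, d_counts = np.unique(t_s[d_s == 1], return_counts=True)
    n_at_risk = len(t_s) - np.searchsorted(t_s, tau, side="left")
    return StepFunction(tau, np.cumsum(d_counts / n_at_risk))


def breslow_baseline(
    data: pd.DataFrame, beta, covariate_names: list[str] = ("x1", "x2", "z")
) -> StepFunction:
    """Breslow baseline cumulative hazard: jumps d(tau)/sum_{R} exp(beta'x)."""
    cov = data[list(covariate_names)]
    if cov.isna().any().any():
        raise ValueError("missing covariate payloads")
    t = data["time"].to_numpy(float)
    d = data["event"].to_numpy(float)
    if d.sum() == 0:
        return StepFunction.zero()
    order = np.argsort(t, kind="stable")
    t_s, d_s = t[order], d[order]
    w = np.exp(cov.to_numpy(float)[order] @ np.asarray(beta, dtype=float))
    tau, d_counts = np.unique(t_s[d_s == 1], return_counts=True)
    S0 = _reverse_cumsum(w)[np.searchsorted(t_s, tau, side="left")]
    return StepFunction(tau, np.cumsum(d_counts / S0))
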