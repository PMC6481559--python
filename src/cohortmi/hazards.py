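"""Design-adapted cumulative-hazard estimators for substudy imputation.

The substudy-approach imputers need estimates of the marginal cumulative
hazard H(t) (for the approximate imputation models) and of the baseline
cumulative hazard H_0(t) (for substantive-model-compatible imputation), but
only have access to substudy data plus limited cohort information.  Four
estimators cover the case-cohort (CC) and nested case-control (NCC)
designs:

* ``h_cc`` — weighted estimator using the subcohort sampling fraction:
  jumps (n_S(0)/n) * d(tau_k)/n_S(tau_k).
* ``h_cc_star`` — jumps d(tau_k)/n_cc(tau_k) with n_cc(tau_k) = n_S(tau_k)
  plus one if the case at tau_k lies outside the subcohort.  This is the
  Nelson–Aalen estimator applied to the case-cohort sample under the usual
  convention that a non-subcohort case contributes risk time only at its own
  event time.
* ``h0_cc`` — modified Breslow estimator over subcohort members at risk,
  scaled by the sampling fraction.
* ``h0_ncc`` — baseline estimator from sampled NCC risk sets, inversely
  weighting each set's risk-set total by n(tau_k)/(c(tau_k)+1); needs the
  full-cohort at-risk counts (time-only information setting).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .designs import DesignInfo, SampledRiskSet
from .stepfun import StepFunction

__all__ = [
    "cc_substudy_table",
    "h_cc",
    "h_cc_star",
    "h0_cc",
    "h0_ncc",
    "ncc_risk_counts",
]


def cc_substudy_table(cohort: pd.DataFrame, info: DesignInfo) -> pd.DataFrame:
    """Substudy rows of a CC design with a ``subcohort`` membership column."""
    if info.kind != "cc":
        raise ValueError("requires a case-cohort DesignInfo")
    out = cohort.loc[info.substudy_member.astype(bool)].copy()
    out["subcohort"] = info.subcohort_member[info.substudy_member.astype(bool)]
    return out.reset_index(drop=True)


def _cc_counts(substudy: pd.DataFrame):
    """Event times, subcohort-at-risk counts and outside-subcohort flags."""
    t = substudy["time"].to_numpy(float)
    d = substudy["event"].to_numpy(float)
    sub = substudy["subcohort"].to_numpy(bool)
    sub_t = np.sort(t[sub])
    case_rows = np.flatnonzero(d == 1)
    case_rows = case_rows[np.argsort(t[case_rows], kind="stable")]
    tau = t[case_rows]
    n_s = len(sub_t) - np.searchsorted(sub_t, tau, side="left")
    outside = ~sub[case_rows]
    return tau, n_s, outside, case_rows


def h_cc(substudy: pd.DataFrame, info: DesignInfo) -> StepFunction:
    """Weighted marginal cumulative-hazard estimator for the CC design."""
    tau, n_s, _, _ = _cc_counts(substudy)
    if np.any(n_s == 0):
        bad = tau[n_s == 0][0]
        raise ValueError(f"no subcohort member at risk at event time {bad:.6g}; H^CC undefined")
    frac = info.n_subcohort_0 / info.n_cohort
    return StepFunction(tau, np.cumsum(frac / n_s))


def h_cc_star(substudy: pd.DataFrame) -> StepFunction:
    """Nelson–Aalen on the CC sample: jumps 1/n_cc(tau_k).

    Proportional to ``h_cc`` without the sampling-fraction factor, so it
    estimates (n/n_S(0)) * H(t).  The scale is immaterial when the curve
    enters an imputation model as a regressor (the coefficient absorbs it),
    and this version needs no cohort-size information at all.
    """
    tau, n_s, outside, _ = _cc_counts(substudy)
    n_cc = n_s + outside.astype(int)
    return StepFunction(tau, np.cumsum(1.0 / n_cc))


def h0_cc(
    substudy: pd.DataFrame,
    beta,
    info: DesignInfo,
    covariate_names: list[str] = ("x1", "x2", "z"),
) -> StepFunction:
    """Modified Breslow baseline-hazard estimator for the CC design.

    Jump (n_S(0)/n) / sum_{l in S_k} exp(beta'x_l), with S_k the subcohort
    members at risk at tau_k; requires their covariates complete.
    """
    tau, n_s, _, _ = _cc_counts(substudy)
    if np.any(n_s == 0):
        bad = tau[n_s == 0][0]
        raise ValueError(f"no subcohort member at risk at event time {bad:.6g}; H^0CC undefined")
    sub = substudy.loc[substudy["subcohort"].astype(bool)]
    cov = sub[list(covariate_names)]
    if cov.isna().any().any():
        raise ValueError("subcohort members at risk must have complete covariates")
    sub_t = sub["time"].to_numpy(float)
    order = np.argsort(sub_t, kind="stable")
    w = np.exp(cov.to_numpy(float)[order] @ np.asarray(beta, dtype=float))
    suffix = np.cumsum(w[::-1])[::-1]
    denom = suffix[np.searchsorted(sub_t[order], tau, side="left")]
    frac = info.n_subcohort_0 / info.n_cohort
    return StepFunction(tau, np.cumsum(frac / denom))


def ncc_risk_counts(cohort_times, risk_sets: list[SampledRiskSet]) -> np.ndarray:
    """Full-cohort at-risk counts n(tau_k), aligned with ``risk_sets``."""
    t_sorted = np.sort(np.asarray(cohort_times, dtype=float))
    tau = np.array([rs.event_time for rs in risk_sets])
    return len(t_sorted) - np.searchsorted(t_sorted, tau, side="left")


def h0_ncc(
    data: pd.DataFrame,
    risk_sets: list[SampledRiskSet],
    beta,
    n_at_risk,
    covariate_names: list[str] = ("x1", "x2", "z"),
) -> StepFunction:
    """Baseline cumulative hazard from sampled NCC risk sets.

    Jump at tau_k is 1 / [ (n(tau_k)/(c(tau_k)+1)) * sum_{l in set} exp(beta'x_l) ].
    ``n_at_risk`` holds the full-cohort at-risk count per set (time-only
    information setting); ``data`` provides members' covariates by id.
    """
    n_at_risk = np.asarray(n_at_risk, dtype=float)
    if len(n_at_risk) != len(risk_sets) or np.any(~np.isfinite(n_at_risk)):
        raise ValueError(
            "full-cohort at-risk counts n(tau_k) are required for every sampled "
            "risk set; the information setting is insufficient without them"
        )
    id_index = pd.Index(data["id"])
    X = data[list(covariate_names)].to_numpy(float)
    beta = np.asarray(beta, dtype=float)
    member_ids = [m for rs in risk_sets for m in rs.member_ids]
    set_idx = np.repeat(np.arange(len(risk_sets)), [len(rs.member_ids) for rs in risk_sets])
    rows = id_index.get_indexer(member_ids)
    if (rows < 0).any():
        raise ValueError("risk-set member absent from the data table")
    Xi = X[rows]
    if np.isnan(Xi).any():
        raise ValueError("risk-set member with missing covariates")
    totals = np.bincount(set_idx, weights=np.exp(Xi @ beta), minlength=len(risk_sets))
    tau = np.array([rs.event_time for rs in risk_sets])
    c = np.array([len(rs.comparator_ids) for rs in risk_sets])
    jumps = 1.0 / (n_at_risk / (c + 1) * totals)
    return StepFunction.from_jumps(tau, jumps)
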