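"""Substudy designs: nested case-control and case-cohort sampling.

A nested case-control (NCC) study matches each case to ``c`` controls drawn
uniformly without replacement from the risk set at the case's event time
(time-matching only).  A case-cohort (CC) study draws a simple random
subcohort at baseline; the substudy is the subcohort plus every case.  The
module also computes the Samuelsen inclusion probability of ever being
sampled as an NCC control, used for inverse-probability-weighted covariate
models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SampledRiskSet",
    "DesignInfo",
    "sample_ncc",
    "sample_case_cohort",
    "cc_risk_sets",
    "samuelsen_prob",
    "risk_sets_to_csv",
    "risk_sets_from_csv",
    "substudy_ids",
]


@dataclass(frozen=True)
class SampledRiskSet:
    """One case's event time with the case and its sampled comparators."""

    set_id: int
    event_time: float
    case_id: int
    comparator_ids: tuple
    c: int = 0  # number of controls requested (NCC)

    def __post_init__(self) -> None:
        if self.case_id in self.comparator_ids:
            raise ValueError("case must not appear among its own comparators")

    @property
    def member_ids(self) -> tuple:
        return (self.case_id, *self.comparator_ids)


@dataclass(frozen=True)
class DesignInfo:
    """Which design was drawn and who belongs to the substudy."""

    kind: str  # "ncc" or "cc"
    n_cohort: int
    substudy_member: np.ndarray  # 0/1 per cohort row, aligned with the cohort table
    n_subcohort_0: int = 0  # subcohort size at baseline (CC)
    c_per_case: int = 0  # controls per case (NCC)
    subcohort_member: np.ndarray | None = None  # CC only

    def __post_init__(self) -> None:
        if self.kind not in ("ncc", "cc"):
            raise ValueError("kind must be 'ncc' or 'cc'")
        if self.n_subcohort_0 > self.n_cohort:
            raise ValueError("subcohort cannot exceed the cohort")


def sample_ncc(
    cohort: pd.DataFrame, c_per_case: int, rng: np.random.Generator
) -> tuple[list[SampledRiskSet], DesignInfo]:
    """Draw an NCC study: per case, ``c`` controls from the risk set.

    Sampling is independent across sets, so an individual can be a control
    for several cases and later a case.  When fewer than ``c`` eligible
    controls exist, all of them are taken (variable c(tau_j)), with a log
    message.
    """
    if c_per_case < 1:
        raise ValueError("c_per_case must be at least 1")
    t = cohort["time"].to_numpy(float)
    d = cohort["event"].to_numpy(float)
    ids = cohort["id"].to_numpy()
    order = np.argsort(t, kind="stable")
    t_s, ids_s = t[order], ids[order]

    case_rows = np.flatnonzero(d == 1)
    case_order = case_rows[np.argsort(t[case_rows], kind="stable")]
    sets: list[SampledRiskSet] = []
    in_substudy = np.zeros(len(cohort), dtype=int)

    for set_id, row in enumerate(case_order):
        tau = t[row]
        start = np.searchsorted(t_s, tau, side="left")
        at_risk = ids_s[start:]
        eligible = at_risk[at_risk != ids[row]]
        k = min(c_per_case, eligible.size)
        if k < c_per_case:
            logger.warning(
                "risk set at t=%.6g has only %d eligible controls (requested %d)",
                tau, eligible.size, c_per_case,
            )
        controls = rng.choice(eligible, size=k, replace=False) if k else np.empty(0, dtype=ids.dtype)
        sets.append(
            SampledRiskSet(
                set_id=set_id,
                event_time=float(tau),
                case_id=ids[row],
                comparator_ids=tuple(controls.tolist()),
                c=c_per_case,
            )
        )
        in_substudy[row] = 1
        in_substudy[order[start + np.flatnonzero(np.isin(ids_s[start:], controls))]] = 1

    info = DesignInfo(
        kind="ncc",
        n_cohort=len(cohort),
        substudy_member=in_substudy,
        c_per_case=c_per_case,
    )
    return sets, info


def sample_case_cohort(
    cohort: pd.DataFrame, n_subcohort: int, rng: np.random.Generator
) -> DesignInfo:
    """Draw a CC study: SRS subcohort at baseline; substudy adds all cases."""
    n = len(cohort)
    if n_subcohort > n:
        raise ValueError("n_subcohort cannot exceed the cohort size")
    sub_rows = rng.choice(n, size=n_subcohort, replace=False)
    subcohort = np.zeros(n, dtype=int)
    subcohort[sub_rows] = 1
    substudy = np.where((subcohort == 1) | (cohort["event"].to_numpy() == 1), 1, 0)
    return DesignInfo(
        kind="cc",
        n_cohort=n,
        substudy_member=substudy,
        n_subcohort_0=n_subcohort,
        subcohort_member=subcohort,
    )


def cc_risk_sets(cohort: pd.DataFrame, info: DesignInfo) -> list[SampledRiskSet]:
    """Sampled risk sets of the CC pseudo-partial likelihood.

    At each event time the set is the subcohort members at risk, plus the
    case if it lies outside the subcohort.
    """
    if info.kind != "cc":
        raise ValueError("cc_risk_sets requires a case-cohort DesignInfo")
    t = cohort["time"].to_numpy(float)
    d = cohort["event"].to_numpy(float)
    ids = cohort["id"].to_numpy()
    sub = info.subcohort_member.astype(bool)
    sub_t = t[sub]
    sub_ids = ids[sub]
    order = np.argsort(sub_t, kind="stable")
    sub_t_s, sub_ids_s = sub_t[order], sub_ids[order]

    case_rows = np.flatnonzero(d == 1)
    case_rows = case_rows[np.argsort(t[case_rows], kind="stable")]
    sets = []
    for set_id, row in enumerate(case_rows):
        tau = t[row]
        start = np.searchsorted(sub_t_s, tau, side="left")
        at_risk = sub_ids_s[start:]
        comparators = at_risk[at_risk != ids[row]]
        if comparators.size == 0:
            logger.info("event at t=%.6g after all subcohort exits; set is the case alone", tau)
        sets.append(
            SampledRiskSet(
                set_id=set_id,
                event_time=float(tau),
                case_id=ids[row],
                comparator_ids=tuple(comparators.tolist()),
            )
        )
    return sets


def samuelsen_prob(cohort: pd.DataFrame, c_per_case: int) -> np.ndarray:
    """Probability of ever being sampled as an NCC control, per individual.

    For individual i with follow-up time T_i this is
    1 - prod_{j : tau_j <= T_i} (1 - c(tau_j)/(n(tau_j) - 1)),
    with c(tau_j) truncated to the number of eligible controls.  Requires
    c(tau_j) <= n(tau_j) - 1 is handled by that truncation; a risk set with a
    lone case contributes nothing.  Cases enter downstream IPW fits with
    weight 1 regardless of this probability.
    """
    t = cohort["time"].to_numpy(float)
    d = cohort["event"].to_numpy(float)
    order = np.argsort(t, kind="stable")
    t_s, d_s = t[order], d[order]
    tau = t_s[d_s == 1]
    n_at_risk = len(t_s) - np.searchsorted(t_s, tau, side="left")
    c_eff = np.minimum(c_per_case, n_at_risk - 1)
    if np.any(n_at_risk - 1 < 0):
        raise ValueError("risk set smaller than its own case")
    with np.errstate(divide="ignore"):
        log_terms = np.log1p(-c_eff / np.maximum(n_at_risk - 1, 1))
    log_terms[n_at_risk - 1 == 0] = 0.0
    cum_log = np.concatenate([[0.0], np.cumsum(log_terms)])
    n_terms = np.searchsorted(tau, t, side="right")
    return -np.expm1(cum_log[n_terms])


def substudy_ids(cohort: pd.DataFrame, info: DesignInfo) -> np.ndarray:
    return cohort["id"].to_numpy()[info.substudy_member.astype(bool)]


def risk_sets_to_csv(risk_sets, path) -> None:
    """Long-format CSV: set_id,case_id,member_id,member_role."""
    rows = []
    for rs in risk_sets:
        rows.append((rs.set_id, rs.case_id, rs.case_id, "case", rs.event_time))
        role = "control" if rs.c else "subcohort"
        for m in rs.comparator_ids:
            rows.append((rs.set_id, rs.case_id, m, role, rs.event_time))
    pd.DataFrame(
        rows, columns=["set_id", "case_id", "member_id", "member_role", "event_time"]
    ).to_csv(path, index=False)


def risk_sets_from_csv(path) -> list[SampledRiskSet]:
    df = pd.read_csv(path)
    sets = []
    for set_id, grp in df.groupby("set_id", sort=True):
        case_id = grp["case_id"].iloc[0]
        comps = tuple(grp.loc[grp["member_role"] != "case", "member_id"].tolist())
        is_ncc = (grp["member_role"] == "control").any()
        sets.append(
            SampledRiskSet(
                set_id=int(set_id),
                event_time=float(grp["event_time"].iloc[0]),
                case_id=case_id,
                comparator_ids=comps,
                c=len(comps) if is_ncc else 0,
            )
        )
    return sets
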