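"""Study orchestration: which data are imputed, which are analysed, and how
the simulation study summarizes performance.

Three imputation approaches are supported for each substudy design:

* full-cohort — impute missing covariates on the whole cohort, fit the full
  partial likelihood to the completed cohort (maximum information setting);
* intermediate — impute on the whole cohort but fit the substudy
  (pseudo-)partial likelihood, so heavily-imputed cells outside the substudy
  never enter the analysis likelihood;
* substudy — impute and analyse only the substudy, with design-adapted
  cumulative-hazard inputs.

``run_study`` repeats simulate → sample designs → analyse over replicates
and reports bias, empirical SE, mean model SE, coverage of nominal
intervals, and efficiency relative to the complete-data substudy analysis
(ratio of empirical variances), each with its Monte Carlo standard error.
All methods within a replicate share the same simulated cohort and design
draw (paired comparisons), and the whole study is reproducible bit-for-bit
from its base seed.
"""

from __future__ import annotations

import logging
import traceback
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cox import CoxFit, RiskSetIndex, fit_cox_full, fit_cox_substudy, nelson_aalen
from .designs import (
    DesignInfo,
    SampledRiskSet,
    cc_risk_sets,
    sample_case_cohort,
    sample_ncc,
    samuelsen_prob,
)
from .hazards import cc_substudy_table, h_cc, h_cc_star, ncc_risk_counts
from .matched_set import mi_matched_set_run
from .mi_approx import ImputationModelSpec, mi_approx_run
from .mi_smc import (
    ProposalSpec,
    SubstantiveSpec,
    cc_substudy_fit_draw,
    full_cohort_fit_draw,
    mi_smc_run,
    ncc_substudy_fit_draw,
)
from .pooling import PooledResult, rubin_pool
from .simulate import SimScenario, calibrate_censor_time, generate_missingness, simulate_cohort

logger = logging.getLogger(__name__)

COVS = ["x1", "x2", "z"]

CC_METHODS = [
    "complete_data_substudy",
    "complete_data_full",
    "complete_case_substudy",
    "mi_approx_full",
    "mi_smc_full",
    "mi_approx_intermediate",
    "mi_smc_intermediate",
    "mi_approx_substudy",
    "mi_smc_substudy",
]
NCC_METHODS = CC_METHODS + ["mi_matched_set"]

__all__ = [
    "StudyConfig",
    "AnalysisResult",
    "StudyResult",
    "standard_scenario",
    "prepare_replicate",
    "run_approach",
    "run_study",
    "CC_METHODS",
    "NCC_METHODS",
]


@dataclass(frozen=True)
class StudyConfig:
    """Design and MI settings shared across a study."""

    design: str = "cc"  # "cc" or "ncc"
    n_subcohort: int = 750
    c_per_case: int = 1
    M: int = 10
    ci_level: float = 0.95
    mi_interval: str = "t"  # "t" (Rubin df) or "normal"
    cumhaz_source: str = "cc_star"  # substudy MI-approx, CC: cc_star | cc_weighted | full_na
    ncc_covmodel: str = "controls_only"  # or "ipw_samuelsen"
    fcs_cycles: int = 10
    smc_cycles: int = 10
    max_rejects: int = 1000
    proposal_x1_transform: str = "identity"  # "log" models log(x1) as conditionally normal
    include_case_indicator: bool = True  # matched-set imputation model

    def __post_init__(self) -> None:
        if self.design not in ("cc", "ncc"):
            raise ValueError("design must be 'cc' or 'ncc'")
        if self.mi_interval not in ("t", "normal"):
            raise ValueError("mi_interval must be 't' or 'normal'")
        if self.cumhaz_source not in ("cc_star", "cc_weighted", "full_na"):
            raise ValueError("cumhaz_source must be cc_star, cc_weighted or full_na")


@dataclass
class AnalysisResult:
    """One analysis of one replicate: estimates, SEs and Wald intervals."""

    method: str
    estimate: np.ndarray
    se: np.ndarray
    conf_int: np.ndarray  # (p, 2)
    names: list[str]
    pooled: PooledResult | None = None
    fit: CoxFit | None = None


@dataclass
class StudyResult:
    summary: pd.DataFrame
    estimates: pd.DataFrame  # long per-replicate table
    n_reps: int
    failures: list
    invalid: bool


def standard_scenario(
    effect: float = 0.2,
    missing_frac: float = 0.5,
    event_frac: float = 0.1,
    variant: str = "standard",
    n_cohort: int = 15_000,
    seed: int = 0,
) -> SimScenario:
    """Scenario with all three log hazard ratios equal and the censoring time
    calibrated so the expected event fraction hits ``event_frac``."""
    base = SimScenario(
        n_cohort=n_cohort,
        beta_x1=effect,
        beta_x2=effect,
        beta_z=effect,
        missing_frac_x2=missing_frac,
        variant=variant,
        seed=seed,
    )
    return replace(base, censor_time=calibrate_censor_time(base, event_frac))


# ---------------------------------------------------------------------------
# replicate preparation


@dataclass
class Replicate:
    """One simulated cohort with its masked version and design draw."""

    complete: pd.DataFrame
    masked: pd.DataFrame  # x2 MAR-masked; x1 masked outside the substudy
    info: DesignInfo
    risk_sets: list[SampledRiskSet]
    scenario: SimScenario


def prepare_replicate(scenario: SimScenario, config: StudyConfig, seed_seq) -> Replicate:
    """Simulate a cohort, mask x2 by chance, draw the substudy, mask x1 by design."""
    s_cohort, s_miss, s_design = seed_seq.spawn(3)
    scen = replace(scenario, seed=int(s_cohort.generate_state(1)[0] % 2**31))
    complete = simulate_cohort(scen)
    masked = generate_missingness(complete, scen, np.random.default_rng(s_miss))
    rng_design = np.random.default_rng(s_design)
    if config.design == "cc":
        info = sample_case_cohort(complete, config.n_subcohort, rng_design)
        sets = cc_risk_sets(complete, info)
    else:
        sets, info = sample_ncc(complete, config.c_per_case, rng_design)
    outside = ~info.substudy_member.astype(bool)
    masked = masked.copy()
    masked.loc[outside, "x1"] = np.nan
    masked["miss_x1_design"] = outside.astype(int)
    return Replicate(complete=complete, masked=masked, info=info, risk_sets=sets, scenario=scen)


def _substudy_frame(masked: pd.DataFrame, info: DesignInfo) -> pd.DataFrame:
    out = masked.loc[info.substudy_member.astype(bool)].copy()
    if info.kind == "cc":
        out["subcohort"] = info.subcohort_member[info.substudy_member.astype(bool)]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# single-fit analyses


def _fit_to_result(method: str, fit: CoxFit, ci_level: float) -> AnalysisResult:
    q = stats.norm.ppf(1.0 - (1.0 - ci_level) / 2.0)
    ci = np.column_stack([fit.beta - q * fit.se, fit.beta + q * fit.se])
    return AnalysisResult(
        method=method, estimate=fit.beta, se=fit.se, conf_int=ci, names=fit.names, fit=fit
    )


def _analyze_substudy(data, sets, design: str, index=None) -> CoxFit:
    kind = "sandwich" if design == "cc" else "model"
    return fit_cox_substudy(data, sets, kind, COVS, index=index)


def _complete_case(rep: Replicate, config: StudyConfig):
    """Drop substudy members with missing x2; rebuild the sampled risk sets."""
    sub = _substudy_frame(rep.masked, rep.info)
    keep = sub.dropna(subset=["x2"]).reset_index(drop=True)
    keep = keep.dropna(subset=["x1"]).reset_index(drop=True)
    if config.design == "cc":
        flags = keep["subcohort"].to_numpy(int)
        cc_info = DesignInfo(
            kind="cc",
            n_cohort=len(keep),
            substudy_member=np.ones(len(keep), dtype=int),
            n_subcohort_0=int(flags.sum()),
            subcohort_member=flags,
        )
        sets = cc_risk_sets(keep, cc_info)
        return keep, sets
    kept_ids = set(keep["id"].tolist())
    sets = []
    for rs in rep.risk_sets:
        if rs.case_id not in kept_ids:
            continue
        comps = tuple(m for m in rs.comparator_ids if m in kept_ids)
        sets.append(replace_set(rs, comps))
    return keep, sets


def replace_set(rs: SampledRiskSet, comparators) -> SampledRiskSet:
    return SampledRiskSet(
        set_id=rs.set_id,
        event_time=rs.event_time,
        case_id=rs.case_id,
        comparator_ids=tuple(comparators),
        c=rs.c,
    )


# ---------------------------------------------------------------------------
# MI building blocks


def _pool_fits(method, fits, config) -> AnalysisResult:
    pooled = rubin_pool(
        [f.beta for f in fits], [f.vcov for f in fits], ci_level=config.ci_level, names=COVS
    )
    if config.mi_interval == "t":
        ci = pooled.conf_int
    else:
        q = stats.norm.ppf(1.0 - (1.0 - config.ci_level) / 2.0)
        ci = np.column_stack([pooled.estimate - q * pooled.se, pooled.estimate + q * pooled.se])
    return AnalysisResult(
        method=method, estimate=pooled.estimate, se=pooled.se, conf_int=ci,
        names=COVS, pooled=pooled,
    )


def _approx_specs(data: pd.DataFrame) -> list[ImputationModelSpec]:
    """One White–Royston-style spec per covariate with any missing values."""
    specs = []
    if data["x1"].isna().any():
        specs.append(ImputationModelSpec("x1", "linear", ("x2", "z")))
    if data["x2"].isna().any():
        specs.append(ImputationModelSpec("x2", "logistic", ("x1", "z")))
    return specs


def _substudy_cumhaz(rep: Replicate, config: StudyConfig, substudy: pd.DataFrame):
    if config.design == "ncc" or config.cumhaz_source == "full_na":
        # time-only information setting: (T, D) known for the whole cohort
        return nelson_aalen(rep.masked["time"], rep.masked["event"])
    if config.cumhaz_source == "cc_star":
        return h_cc_star(substudy)
    return h_cc(substudy, rep.info)


def _smc_proposals(data: pd.DataFrame, config: StudyConfig, fit_method: str):
    proposals = []
    if data["x1"].isna().any():
        proposals.append(
            ProposalSpec(
                "x1", "linear", ("x2", "z"),
                target_transform=config.proposal_x1_transform,
                fit_method=fit_method,
            )
        )
    if data["x2"].isna().any():
        proposals.append(ProposalSpec("x2", "logistic", ("x1", "z"), fit_method=fit_method))
    return proposals


def _matched_set_tables(rep: Replicate):
    """Long member-level table of the sampled risk sets (case first)."""
    sub = rep.masked.set_index("id")
    rows = []
    for rs in rep.risk_sets:
        for role, member in [("case", rs.case_id)] + [("control", m) for m in rs.comparator_ids]:
            rec = sub.loc[member]
            rows.append((rs.set_id, role, rec["x1"], rec["x2"], rec["z"]))
    return pd.DataFrame(rows, columns=["set_id", "member_role", "x1", "x2", "z"])


def _conditional_logistic_fit(long: pd.DataFrame) -> CoxFit:
    """Modified partial likelihood over member rows (== conditional logistic)."""
    df = long.reset_index(drop=True).copy()
    df["id"] = np.arange(len(df))
    sets = []
    for set_id, grp in df.groupby("set_id", sort=True):
        case_rows = grp.index[grp["member_role"] == "case"]
        comp_rows = grp.index[grp["member_role"] != "case"]
        sets.append(
            SampledRiskSet(
                set_id=int(set_id), event_time=float(set_id) + 1.0,
                case_id=int(case_rows[0]), comparator_ids=tuple(int(i) for i in comp_rows),
                c=len(comp_rows),
            )
        )
    return fit_cox_substudy(df, sets, "model", COVS)


# ---------------------------------------------------------------------------
# the Table-of-analyses dispatcher


def run_approach(
    rep: Replicate,
    method: str,
    config: StudyConfig,
    rng: np.random.Generator,
) -> AnalysisResult:
    """Run one named analysis on one prepared replicate.

    ``method`` combines the imputation method and the approach, e.g.
    ``mi_smc_intermediate``; ``complete_data_*`` and ``complete_case_substudy``
    are the non-MI baselines.
    """
    valid = NCC_METHODS if config.design == "ncc" else CC_METHODS
    if method not in valid:
        raise ValueError(f"unknown method {method!r} for design {config.design!r}; valid: {valid}")

    if method == "complete_data_full":
        return _fit_to_result(method, fit_cox_full(rep.complete, COVS), config.ci_level)
    if method == "complete_data_substudy":
        fit = _analyze_substudy(rep.complete, rep.risk_sets, config.design)
        return _fit_to_result(method, fit, config.ci_level)
    if method == "complete_case_substudy":
        keep, sets = _complete_case(rep, config)
        return _fit_to_result(method, _analyze_substudy(keep, sets, config.design), config.ci_level)

    approach = method.rsplit("_", 1)[-1]  # full | intermediate | substudy | set
    if method == "mi_matched_set":
        long = _matched_set_tables(rep)
        imputed = mi_matched_set_run(
            long, M=config.M, n_cycles=config.fcs_cycles, rng=rng,
            include_case_indicator=config.include_case_indicator,
        )
        fits = [_conditional_logistic_fit(d) for d in imputed.datasets]
        return _pool_fits(method, fits, config)

    if approach in ("full", "intermediate"):
        data = rep.masked
        specs = _approx_specs(data)
        if method.startswith("mi_approx"):
            cumhaz = nelson_aalen(data["time"], data["event"])
            imputed = mi_approx_run(
                data, specs, cumhaz, M=config.M,
                n_cycles=config.fcs_cycles if len(specs) > 1 else 1, rng=rng,
            )
        else:
            targets = tuple(s.target for s in specs)
            substantive = SubstantiveSpec.linear(tuple(COVS), targets)
            proposals = _smc_proposals(data, config, "full_data")
            imputed = mi_smc_run(
                data, substantive, proposals, full_cohort_fit_draw(substantive),
                M=config.M, n_cycles=config.smc_cycles, max_rejects=config.max_rejects, rng=rng,
            )
        if approach == "full":
            fits = [fit_cox_full(d, COVS) for d in imputed.datasets]
        else:
            idx = RiskSetIndex(imputed.datasets[0]["id"], rep.risk_sets)
            fits = [
                _analyze_substudy(d, rep.risk_sets, config.design, index=idx)
                for d in imputed.datasets
            ]
        return _pool_fits(method, fits, config)

    # substudy approach: impute and analyse the substudy only
    substudy = _substudy_frame(rep.masked, rep.info)
    if method.startswith("mi_approx"):
        cumhaz = _substudy_cumhaz(rep, config, substudy)
        specs = [ImputationModelSpec("x2", "logistic", ("x1", "z"))]
        imputed = mi_approx_run(substudy, specs, cumhaz, M=config.M, n_cycles=1, rng=rng)
    else:
        substantive = SubstantiveSpec.linear(tuple(COVS), ("x2",))
        if config.design == "cc":
            proposals = _smc_proposals(substudy, config, "subcohort")
            fit_draw = cc_substudy_fit_draw(substantive, rep.risk_sets, rep.info)
            weights = None
        else:
            proposals = _smc_proposals(substudy, config, config.ncc_covmodel)
            n_at_risk = ncc_risk_counts(rep.masked["time"], rep.risk_sets)
            fit_draw = ncc_substudy_fit_draw(substantive, rep.risk_sets, n_at_risk)
            weights = None
            if config.ncc_covmodel == "ipw_samuelsen":
                probs = samuelsen_prob(rep.masked, config.c_per_case)
                in_sub = rep.info.substudy_member.astype(bool)
                p_sub = probs[in_sub]
                d_sub = rep.masked.loc[in_sub, "event"].to_numpy(float)
                weights = np.where(d_sub == 1.0, 1.0, 1.0 / np.clip(p_sub, 1e-12, None))
        imputed = mi_smc_run(
            substudy, substantive, proposals, fit_draw, M=config.M,
            n_cycles=config.smc_cycles, max_rejects=config.max_rejects, rng=rng,
            ipw_weights=weights,
        )
    idx = RiskSetIndex(imputed.datasets[0]["id"], rep.risk_sets)
    fits = [
        _analyze_substudy(d, rep.risk_sets, config.design, index=idx) for d in imputed.datasets
    ]
    return _pool_fits(method, fits, config)


# ---------------------------------------------------------------------------
# the simulation-study loop


def run_study(
    scenario: SimScenario,
    methods: list[str],
    n_reps: int,
    base_seed: int,
    config: StudyConfig | None = None,
) -> StudyResult:
    """Simulate ``n_reps`` cohorts and run every requested analysis on each.

    Replicates failing in any method are recorded and excluded from that
    method's summary; a study with more than 5% failures is marked invalid.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    config = config or StudyConfig()
    truth = dict(zip(COVS, scenario.betas))
    records = []
    failures = []
    root = np.random.SeedSequence(base_seed)
    for r, rep_seq in enumerate(root.spawn(n_reps)):
        children = rep_seq.spawn(1 + len(methods))
        rep = prepare_replicate(scenario, config, children[0])
        for i, method in enumerate(methods):
            rng = np.random.default_rng(children[1 + i])
            try:
                res = run_approach(rep, method, config, rng)
            except Exception as err:  # noqa: BLE001 - recorded, counted, reported
                failures.append({"rep": r, "method": method, "error": repr(err)})
                logger.warning("replicate %d, %s failed: %s", r, method, err)
                logger.debug("%s", traceback.format_exc())
                continue
            for j, name in enumerate(res.names):
                records.append(
                    {
                        "rep": r,
                        "method": method,
                        "coef": name,
                        "estimate": res.estimate[j],
                        "se": res.se[j],
                        "ci_lo": res.conf_int[j, 0],
                        "ci_hi": res.conf_int[j, 1],
                        "covers": float(res.conf_int[j, 0] <= truth[name] <= res.conf_int[j, 1]),
                    }
                )
    estimates = pd.DataFrame(records)
    summary = summarize_study(estimates, truth, reference="complete_data_substudy")
    n_cells = n_reps * len(methods)
    invalid = len(failures) > 0.05 * n_cells
    if invalid:
        logger.warning("study invalid: %d of %d method-replicates failed", len(failures), n_cells)
    return StudyResult(
        summary=summary, estimates=estimates, n_reps=n_reps, failures=failures, invalid=invalid
    )


def summarize_study(
    estimates: pd.DataFrame, truth: dict, reference: str = "complete_data_substudy"
) -> pd.DataFrame:
    """Per method x coefficient performance metrics with Monte Carlo SEs."""
    rows = []
    ref_var = {}
    if reference in set(estimates["method"]):
        for coef, grp in estimates[estimates["method"] == reference].groupby("coef"):
            ref_var[coef] = grp["estimate"].var(ddof=1)
    for (method, coef), grp in estimates.groupby(["method", "coef"], sort=False):
        est = grp["estimate"].to_numpy()
        R = len(est)
        emp_se = est.std(ddof=1)
        cover = grp["covers"].mean()
        rows.append(
            {
                "method": method,
                "coef": coef,
                "n_reps": R,
                "mean_est": est.mean(),
                "bias": est.mean() - truth[coef],
                "emp_se": emp_se,
                "mean_model_se": grp["se"].mean(),
                "coverage_pct": 100.0 * cover,
                "rel_eff": ref_var.get(coef, np.nan) / est.var(ddof=1) if R > 1 else np.nan,
                "mc_se_bias": emp_se / np.sqrt(R),
                "mc_se_coverage_pct": 100.0 * np.sqrt(cover * (1.0 - cover) / R),
            }
        )
    return pd.DataFrame(rows)
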