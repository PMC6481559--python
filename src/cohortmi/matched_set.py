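"""Within-risk-set imputation for nested case-control studies.

In the minimum information setting an NCC analyst has only the sampled risk
sets themselves.  Missing x2 values are then imputed from a logistic model
fitted across all set members whose predictors are the member's own
covariates plus the sums of each covariate over the *other* members of the
same set — so no cohort-level quantity (at-risk counts, cumulative hazards)
is ever required.  Because the co-member sums involve imputed values, the
model is cycled as chained equations; each of the M imputations is an
independent chain.

Sets are held in a long table with columns ``set_id``, ``member_role``
("case"/"control"), ``x1``, ``x2``, ``z``; each set has exactly one case and
a possibly variable number of controls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mi_common import ImputedDatasets, initial_fill, mvn_draw

__all__ = ["validate_matched_sets", "build_set_predictors", "mi_matched_set_run"]

PREDICTOR_COLS = ["x1", "z", "sum_x1_others", "sum_x2_others", "sum_z_others"]


def validate_matched_sets(sets: pd.DataFrame) -> None:
    required = {"set_id", "member_role", "x1", "x2", "z"}
    if not required <= set(sets.columns):
        raise ValueError(f"matched-set table needs columns {sorted(required)}")
    cases_per_set = sets.groupby("set_id")["member_role"].apply(lambda r: (r == "case").sum())
    if (cases_per_set != 1).any():
        bad = cases_per_set.index[cases_per_set != 1][0]
        raise ValueError(f"set {bad!r} does not have exactly one case")


def build_set_predictors(sets: pd.DataFrame) -> pd.DataFrame:
    """Member-level predictors: own (x1, z) and co-member sums of (x1, x2, z).

    Co-member sums are the set totals minus the member's own value, so they
    are invariant to the ordering of the other members.  A singleton set gets
    zero sums and ``lone_member = 1``.
    """
    out = sets.copy()
    grp = out.groupby("set_id")
    sizes = grp["x1"].transform("size")
    for col in ("x1", "x2", "z"):
        out[f"sum_{col}_others"] = grp[col].transform("sum") - out[col]
    out["lone_member"] = (sizes == 1).astype(int)
    out.loc[out["lone_member"] == 1, [f"sum_{c}_others" for c in ("x1", "x2", "z")]] = 0.0
    return out


def mi_matched_set_run(
    sets: pd.DataFrame,
    M: int = 10,
    n_cycles: int = 10,
    rng: np.random.Generator | None = None,
    include_case_indicator: bool = True,
) -> ImputedDatasets:
    """Impute missing x2 within matched sets; returns M completed set tables.

    The logistic imputation model for x2 is fitted across all members of all
    sets on the originally observed rows, with co-member sums recomputed from
    the current working fills each cycle.  ``include_case_indicator`` adds
    the member's own case/control status as a predictor (it is known within
    every set).
    """
    if rng is None:
        rng = np.random.default_rng()
    validate_matched_sets(sets)
    miss = sets["x2"].isna().to_numpy()
    if miss.all():
        raise ValueError("every x2 value is missing; nothing to fit the imputation model on")
    sets_with_all_missing = (
        sets.assign(_m=miss).groupby("set_id")["_m"].all().pipe(lambda s: int(s.sum()))
    )
    predictors = PREDICTOR_COLS + (["is_case"] if include_case_indicator else [])

    datasets = []
    for _ in range(M):
        work = sets.reset_index(drop=True).copy()
        work["is_case"] = (work["member_role"] == "case").astype(float)
        if miss.any():
            initial_fill(work, "x2", miss, rng)
        for _ in range(n_cycles if miss.any() else 0):
            feat = build_set_predictors(work)
            X = np.column_stack(
                [np.ones(len(feat)), feat[predictors].to_numpy(float)]
            )
            y = feat["x2"].to_numpy(float)
            res = sm.GLM(y[~miss], X[~miss], family=sm.families.Binomial()).fit()
            alpha = mvn_draw(res.params, np.asarray(res.cov_params()), rng)
            from scipy.special import expit

            p = expit(X[miss] @ alpha)
            work.loc[miss, "x2"] = (rng.random(int(miss.sum())) < p).astype(float)
        datasets.append(work.drop(columns=["is_case"]))
    return ImputedDatasets(
        M=M,
        datasets=datasets,
        log={"n_cycles": n_cycles, "sets_fully_missing": sets_with_all_missing},
    )
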