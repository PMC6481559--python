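"""Shared multiple-imputation machinery: containers and posterior draws."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ImputedDatasets", "mvn_draw", "linear_posterior_draw", "initial_fill"]


@dataclass
class ImputedDatasets:
    """M completed copies of a data table plus a draw log.

    Observed cells are identical across the M datasets; only cells flagged
    missing in the input differ.
    """

    M: int
    datasets: list[pd.DataFrame]
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.datasets) != self.M:
            raise ValueError("number of datasets must equal M")


def _safe_cholesky(V: np.ndarray) -> np.ndarray:
    V = np.atleast_2d(np.asarray(V, dtype=float))
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        # near-singular posterior covariance: fall back to an eigen square root
        vals, vecs = np.linalg.eigh((V + V.T) / 2.0)
        return vecs * np.sqrt(np.clip(vals, 0.0, None))


def mvn_draw(mean, V, rng: np.random.Generator) -> np.ndarray:
    """One draw from Normal(mean, V) via a (robust) Cholesky factor."""
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    return mean + _safe_cholesky(V) @ rng.standard_normal(mean.size)


def linear_posterior_draw(
    alpha_hat, XtX_inv, sigma2_hat: float, df: int, rng: np.random.Generator
):
    """Noninformative normal-inverse-chi-square posterior draw for a linear model.

    sigma^2_m = sigma2_hat * df / chi2_df, then
    alpha_m ~ Normal(alpha_hat, sigma^2_m * (X'X)^{-1}).
    """
    if df < 1:
        raise ValueError("residual degrees of freedom must be positive")
    sigma2_m = sigma2_hat * df / rng.chisquare(df)
    alpha_m = mvn_draw(alpha_hat, sigma2_m * XtX_inv, rng)
    return alpha_m, sigma2_m


def initial_fill(
    work: pd.DataFrame, target: str, missing_mask: np.ndarray, rng: np.random.Generator
) -> None:
    """Fill missing cells in place with draws from the observed marginal."""
    observed = work.loc[~missing_mask, target].to_numpy()
    if observed.size == 0:
        raise ValueError(f"no observed values of {target!r} to initialize from")
    work.loc[missing_mask, target] = rng.choice(observed, size=int(missing_mask.sum()))
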