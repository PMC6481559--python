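"""Rubin's rules: pooling per-imputation estimates into one inference.

Given M estimates and their variance matrices, the pooled estimate is their
mean, the within-imputation variance W the mean of the variances, the
between-imputation variance B the sample covariance of the estimates, and
the total variance T = W + (1 + 1/M) B.  Per-coefficient degrees of freedom
follow the classical formula df = (M - 1) * (1 + W/((1 + 1/M) B))^2, and
Wald intervals use the t distribution with that df (reverting to normal
quantiles when B = 0, where df is infinite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PooledResult", "rubin_pool"]


@dataclass
class PooledResult:
    estimate: np.ndarray
    within_var: np.ndarray  # matrix
    between_var: np.ndarray  # matrix
    total_var: np.ndarray  # matrix
    df: np.ndarray  # per coefficient
    ci_level: float
    M: int
    names: list[str] | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.total_var))

    @property
    def conf_int(self) -> np.ndarray:
        """(p, 2) array of Wald interval endpoints at ``ci_level``."""
        alpha = 1.0 - self.ci_level
        q = np.where(
            np.isfinite(self.df),
            stats.t.ppf(1.0 - alpha / 2.0, np.clip(self.df, 1e-3, None)),
            stats.norm.ppf(1.0 - alpha / 2.0),
        )
        half = q * self.se
        return np.column_stack([self.estimate - half, self.estimate + half])


def rubin_pool(estimates, variances, ci_level: float = 0.95, names=None) -> PooledResult:
    """Pool M (estimate, variance) pairs by Rubin's rules.

    ``estimates``: (M, p) array-like; ``variances``: M matrices (p, p).
    Requires M >= 2 (the between-imputation variance is undefined at M = 1).
    """
    Q = np.asarray([np.atleast_1d(e) for e in estimates], dtype=float)
    M, p = Q.shape
    if M < 2:
        raise ValueError("Rubin's rules need at least 2 imputations")
    U = np.asarray([np.atleast_2d(v) for v in variances], dtype=float)
    if U.shape != (M, p, p):
        raise ValueError("variance shapes do not match the estimates")

    qbar = Q.mean(axis=0)
    W = U.mean(axis=0)
    dev = Q - qbar
    B = dev.T @ dev / (M - 1)
    T = W + (1.0 + 1.0 / M) * B

    Bd = np.diag(B)
    Wd = np.diag(W)
    with np.errstate(divide="ignore"):
        r = np.where(Bd > 0, Wd / ((1.0 + 1.0 / M) * np.where(Bd > 0, Bd, 1.0)), np.inf)
    df = np.where(np.isinf(r), np.inf, (M - 1) * (1.0 + r) ** 2)
    return PooledResult(
        estimate=qbar,
        within_var=W,
        between_var=B,
        total_var=T,
        df=df,
        ci_level=ci_level,
        M=M,
        names=list(names) if names is not None else None,
    )
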