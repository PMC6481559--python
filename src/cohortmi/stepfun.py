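"""Right-continuous step functions on the time axis.

All cumulative-hazard estimators in this package return a
:class:`StepFunction`: a nondecreasing, right-continuous function that is 0
before its first jump.  Evaluation at ``t`` returns the value at the largest
jump time ``<= t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StepFunction:
    """A nondecreasing right-continuous step function starting at 0.

    Parameters
    ----------
    jump_times
        Strictly increasing positive jump locations.
    cumulative_values
        Function value at and after each jump; nondecreasing, nonnegative.
    """

    jump_times: np.ndarray
    cumulative_values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.jump_times, dtype=float)
        v = np.asarray(self.cumulative_values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise ValueError("jump_times and cumulative_values must be 1-d and equal length")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] <= 0):
            raise ValueError("jump_times must be strictly increasing and positive")
        if v.size and (np.any(np.diff(v) < 0) or v[0] < 0):
            raise ValueError("cumulative_values must be nondecreasing and nonnegative")
        object.__setattr__(self, "jump_times", t)
        object.__setattr__(self, "cumulative_values", v)

    def __call__(self, t) -> np.ndarray | float:
        """Evaluate at ``t`` (scalar or array); 0 before the first jump."""
        idx = np.searchsorted(self.jump_times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate([[0.0], self.cumulative_values])
        out = padded[idx]
        if np.isscalar(t):
            return float(out)
        return out

    @property
    def jumps(self) -> np.ndarray:
        """Jump sizes at each jump time."""
        if self.jump_times.size == 0:
            return np.empty(0)
        return np.diff(np.concatenate([[0.0], self.cumulative_values]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.jump_times, "cumhaz": self.cumulative_values})

    def to_csv(self, path) -> None:
        """Serialize as two-column CSV (time, cumhaz)."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StepFunction":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["cumhaz"].to_numpy())

    @classmethod
    def from_jumps(cls, times, jumps) -> "StepFunction":
        """Build from (possibly unsorted) jump locations and jump sizes."""
        times = np.asarray(times, dtype=float)
        jumps = np.asarray(jumps, dtype=float)
        order = np.argsort(times)
        return cls(times[order], np.cumsum(jumps[order]))

    @classmethod
    def zero(cls) -> "StepFunction":
        return cls(np.empty(0), np.empty(0))
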