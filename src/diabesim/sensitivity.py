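"""Latin Hypercube and one-at-a-time sensitivity analysis.

Parameter uncertainty is described by :class:`ParamRange` entries (linear or
log scale).  :func:`lhs_sample` draws a stratified Latin Hypercube sample —
for every dimension exactly one draw falls in each of the n equal-probability
strata — and :func:`sensitivity_run` maps each draw through the simulator,
summarising the outcome distribution and ranking parameter influence with
partial rank correlation coefficients (PRCC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc, rankdata

from .core import ModelParams, SimConfig, simulate
from .paramspace import set_param
from .trends import DriverBundle

__all__ = ["ParamRange", "lhs_sample", "sensitivity_run", "univariable_sweep"]


@dataclass
class ParamRange:
    """Uncertainty range for one parameter."""

    name: str
    lower: float
    upper: float
    scale: str = "linear"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower must be < upper")
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")
        if self.scale == "log" and self.lower <= 0:
            raise ValueError("log scale requires lower > 0")

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        if self.scale == "log":
            return np.exp(np.log(self.lower) + u * (np.log(self.upper) - np.log(self.lower)))
        return self.lower + u * (self.upper - self.lower)


def lhs_sample(ranges, n: int, seed: int = 0) -> np.ndarray:
    """n x d Latin Hypercube draw over the given ranges (seeded)."""
    ranges = list(ranges)
    if n < 1 or len(ranges) < 1:
        raise ValueError("need n >= 1 and at least one range")
    unit = qmc.LatinHypercube(d=len(ranges), seed=seed).random(n)
    cols = [r.from_unit(unit[:, j]) for j, r in enumerate(ranges)]
    return np.column_stack(cols)


def _prcc(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Partial rank correlation of each column of x with y."""
    n, d = x.shape
    rx = np.column_stack([rankdata(x[:, j]) for j in range(d)])
    ry = rankdata(y)
    out = np.full(d, np.nan)
    for j in range(d):
        others = np.column_stack([np.ones(n), np.delete(rx, j, axis=1)])
        res_x = rx[:, j] - others @ np.linalg.lstsq(others, rx[:, j], rcond=None)[0]
        res_y = ry - others @ np.linalg.lstsq(others, ry, rcond=None)[0]
        sx, sy = np.std(res_x), np.std(res_y)
        if sx > 0 and sy > 0:
            out[j] = float(np.corrcoef(res_x, res_y)[0, 1])
    return out


def _outcome_value(traj, outcome) -> float:
    column, year = outcome
    return traj.value(column, year)


def sensitivity_run(samples: np.ndarray, names, params: ModelParams, bundle: DriverBundle,
                    outcome=("dm_prev", 2050.0), config: SimConfig | None = None) -> dict:
    """Run the model at each sampled parameter vector and summarise.

    Returns a dict with the per-sample ``outcomes`` (NaN where a sample
    failed), the count of ``failures``, percentile ``summary`` and a
    ``prcc`` Series per parameter (computed on the successful samples).
    """
    samples = np.asarray(samples, dtype=float)
    names = list(names)
    if samples.ndim != 2 or samples.shape[1] != len(names):
        raise ValueError("samples must be (n, len(names))")
    config = config or SimConfig()
    outcomes = np.full(samples.shape[0], np.nan)
    for i, row in enumerate(samples):
        p = params.copy()
        try:
            for name, value in zip(names, row):
                set_param(p, name, value)
            outcomes[i] = _outcome_value(simulate(p, bundle, config), outcome)
        except Exception:
            continue
    ok = np.isfinite(outcomes)
    good = outcomes[ok]
    if good.size == 0:
        raise RuntimeError("all sensitivity samples failed")
    summary = {
        "n": int(samples.shape[0]),
        "failures": int((~ok).sum()),
        "median": float(np.median(good)),
        "p2.5": float(np.percentile(good, 2.5)),
        "p97.5": float(np.percentile(good, 97.5)),
    }
    if good.size > len(names) + 2 and np.std(good) > 0:
        prcc = pd.Series(_prcc(samples[ok], good), index=names, name="prcc")
    else:
        prcc = pd.Series(np.nan, index=names, name="prcc")
    return {"outcomes": outcomes, "failures": summary["failures"],
            "summary": summary, "prcc": prcc}


def univariable_sweep(name: str, lower: float, upper: float, params: ModelParams,
                      bundle: DriverBundle, outcome=("dm_prev", 2050.0),
                      n_points: int = 11, config: SimConfig | None = None) -> pd.DataFrame:
    """One-at-a-time sweep of a single parameter over an even grid."""
    grid = np.linspace(lower, upper, n_points)
    config = config or SimConfig()
    rows = []
    for v in grid:
        p = params.copy()
        set_param(p, name, v)
        rows.append({"value": float(v),
                     "outcome": _outcome_value(simulate(p, bundle, config), outcome)})
    return pd.DataFrame(rows)
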