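"""Calibration of free model parameters to survey prevalence anchors.

The fit is a bounded weighted least-squares problem: the objective is the
weighted sum of squared residuals between simulated metrics at the anchor
years and the anchor values (weights default to 1, or 1/se^2 when a standard
error is given).  Minimisation uses scipy's trust-region reflective least
squares with multi-start (perturbed initial points drawn within bounds from
a seeded generator), returning the best converged result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import ModelParams, SimConfig, simulate, Trajectory
from .energy import SEXES
from .paramspace import get_param, set_param
from .trends import DriverBundle

__all__ = ["CalibrationTarget", "FitResult", "objective", "residuals", "fit", "read_targets"]

_METRICS = ("dm_prev", "predm_prev", "ob_prev", "mean_bmi")


@dataclass
class CalibrationTarget:
    """A survey anchor the fit must hit."""

    year: float
    metric: str
    value: float
    sex: str | None = None
    weight: float = 1.0
    se: float | None = None

    def __post_init__(self) -> None:
        if self.metric not in _METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {_METRICS}")
        if self.metric != "mean_bmi" and not 0 <= self.value <= 1:
            raise ValueError(f"{self.metric} target must be a fraction in [0, 1]")
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.se is not None:
            if self.se <= 0:
                raise ValueError("se must be > 0")
            self.weight = 1.0 / self.se**2

    def column(self) -> str:
        col = "bmi" if self.metric == "mean_bmi" else self.metric
        if self.sex is not None:
            return f"{col}_{self.sex}"
        return "mean_bmi" if self.metric == "mean_bmi" else col


@dataclass
class FitResult:
    """Outcome of a calibration run."""

    params: ModelParams
    values: dict
    objective: float
    residual_table: pd.DataFrame
    converged: bool
    at_bounds: list = field(default_factory=list)
    n_starts: int = 1
    seed: int | None = None
    trace: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "values": self.values,
            "objective": self.objective,
            "converged": self.converged,
            "at_bounds": self.at_bounds,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "residuals": self.residual_table.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _simulated_value(traj: Trajectory, target: CalibrationTarget) -> float:
    return traj.value(target.column(), target.year)


def residuals(params: ModelParams, bundle: DriverBundle, targets, config: SimConfig | None = None,
              traj: Trajectory | None = None) -> np.ndarray:
    """Weighted residual vector sqrt(w_i) * (sim_i - target_i)."""
    if traj is None:
        traj = simulate(params, bundle, config)
    return np.array([
        np.sqrt(t.weight) * (_simulated_value(traj, t) - t.value) for t in targets
    ])


def objective(params: ModelParams, bundle: DriverBundle, targets,
              config: SimConfig | None = None) -> float:
    """Weighted sum of squared residuals (order-invariant, >= 0)."""
    try:
        r = residuals(params, bundle, targets, config)
    except Exception as exc:  # propagate with parameter context
        raise RuntimeError(f"simulation failed during calibration: {exc}") from exc
    return float(np.sum(r**2))


def fit(params0: ModelParams, bounds: dict, bundle: DriverBundle, targets,
        seed: int = 0, n_starts: int = 5, config: SimConfig | None = None,
        tol: float = 1e-8) -> FitResult:
    """Fit the parameters named in ``bounds`` ({name: (lo, hi)}).

    Deterministic given ``seed`` and ``params0``.  Runs ``n_starts`` local
    minimisations (the first from ``params0``, the rest from points drawn
    uniformly within bounds) and returns the best.
    """
    names = list(bounds)
    lo = np.array([bounds[n][0] for n in names], dtype=float)
    hi = np.array([bounds[n][1] for n in names], dtype=float)
    if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)) or np.any(lo >= hi):
        raise ValueError("bounds must be finite with lo < hi")
    x0 = np.array([get_param(params0, n) for n in names])
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("params0 outside bounds")
    targets = list(targets)

    def make_params(x: np.ndarray) -> ModelParams:
        p = params0.copy()
        for n, v in zip(names, x):
            set_param(p, n, v)
        return p

    def resid(x: np.ndarray) -> np.ndarray:
        return residuals(make_params(x), bundle, targets, config)

    rng = np.random.default_rng(seed)
    starts = [x0] + [rng.uniform(lo, hi) for _ in range(max(0, n_starts - 1))]
    best, trace = None, []
    for x_start in starts:
        try:
            res = least_squares(resid, x_start, bounds=(lo, hi), xtol=tol, ftol=tol, gtol=tol)
        except Exception:
            trace.append({"start": x_start.tolist(), "status": "failed"})
            continue
        cost = 2.0 * res.cost
        trace.append({"start": x_start.tolist(), "objective": cost, "success": bool(res.success)})
        if best is None or cost < best[0]:
            best = (cost, res)
    if best is None:
        return FitResult(params0.copy(), {n: get_param(params0, n) for n in names},
                         np.inf, pd.DataFrame(), converged=False,
                         n_starts=len(starts), seed=seed, trace=trace)
    cost, res = best
    fitted = make_params(res.x)
    traj = simulate(fitted, bundle, config)
    table = pd.DataFrame([
        {"year": t.year, "metric": t.metric, "sex": t.sex or "", "target": t.value,
         "simulated": _simulated_value(traj, t), "weight": t.weight}
        for t in targets
    ])
    atol = 1e-6 * np.maximum(1.0, np.abs(hi - lo))
    at_bounds = [n for n, x, l, h, a in zip(names, res.x, lo, hi, atol)
                 if x - l < a or h - x < a]
    return FitResult(
        params=fitted,
        values={n: float(v) for n, v in zip(names, res.x)},
        objective=float(cost),
        residual_table=table,
        converged=bool(res.success),
        at_bounds=at_bounds,
        n_starts=len(starts),
        seed=seed,
        trace=trace,
    )


def read_targets(path) -> list:
    """Read calibration targets from CSV (year,metric,sex,value[,se[,weight]])."""
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        sex = r.get("sex")
        sex = None if (pd.isna(sex) or sex == "") else str(sex)
        se = r.get("se")
        se = None if (se is None or pd.isna(se)) else float(se)
        kwargs = {}
        if "weight" in df.columns and not pd.isna(r.get("weight")):
            kwargs["weight"] = float(r["weight"])
        out.append(CalibrationTarget(year=float(r["year"]), metric=str(r["metric"]),
                                     value=float(r["value"]), sex=sex, se=se, **kwargs))
    return out
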