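"""State representation and the annual-time-step integrator.

The simulator advances a sex-stratified glycemic state (NG / preDM / DM
person counts plus mean weight and BMI per sex) from ``t_start`` to ``t_end``
with an explicit forward-Euler scheme at ``dt`` years (reference dt = 1).

Update order within a step: demography and drivers are evaluated at the
current year; the energy-balance sub-model advances mean weight, BMI and the
obesity prevalences; the glycemic flows are then computed *using the
just-updated obesity prevalence* (obesity drives onset within the same year);
finally the stocks are advanced and mortality applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import SEXES, EnergyParams, DietIntake, harris_benedict_rmr, total_intake, \
    activity_expenditure, annual_weight_update, obesity_prev_from_bmi, _pair
from .flows import FlowParams, InterventionCoverage, NO_COVERAGE, glycemic_flow_set
from .trends import DriverBundle

__all__ = [
    "GlycemicState",
    "SimConfig",
    "ModelParams",
    "InitialConditions",
    "Trajectory",
    "advance_state",
    "simulate",
    "prevalence_series",
]


@dataclass
class GlycemicState:
    """Sex-stratified person counts and anthropometrics at one time point.

    All per-sex arrays are in :data:`~diabesim.energy.SEXES` order
    (female, male).
    """

    year: float
    ng: np.ndarray
    predm: np.ndarray
    dm: np.ndarray
    weight: np.ndarray
    bmi: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ng", "predm", "dm", "weight", "bmi"):
            setattr(self, name, _pair(getattr(self, name), name))
        if min(self.ng.min(), self.predm.min(), self.dm.min()) < 0:
            raise ValueError("stocks must be >= 0")
        if self.total <= 0:
            raise ValueError("total population must be > 0")

    @property
    def total_by_sex(self) -> np.ndarray:
        return self.ng + self.predm + self.dm

    @property
    def total(self) -> float:
        return float(self.total_by_sex.sum())


@dataclass
class SimConfig:
    """Simulation window and step size (calendar years)."""

    t_start: float = 1990.0
    t_end: float = 2050.0
    dt: float = 1.0
    seed: int | None = None  # stochastic utilities only; the core run is deterministic

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        n = (self.t_end - self.t_start) / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("(t_end - t_start) / dt must be integral")

    @property
    def n_steps(self) -> int:
        return int(round((self.t_end - self.t_start) / self.dt))


@dataclass
class InitialConditions:
    """State at ``t_start``: per-sex totals, glycemic shares and mean weight."""

    pop: np.ndarray = field(default_factory=lambda: np.array([676_000.0, 651_000.0]))
    dm_share: np.ndarray = field(default_factory=lambda: np.array([0.07, 0.05]))
    predm_share: np.ndarray = field(default_factory=lambda: np.array([0.12, 0.12]))
    weight: np.ndarray = field(default_factory=lambda: np.array([68.0, 76.0]))

    def __post_init__(self) -> None:
        for name in ("pop", "dm_share", "predm_share", "weight"):
            setattr(self, name, _pair(getattr(self, name), name))

    def copy(self) -> "InitialConditions":
        return InitialConditions(self.pop.copy(), self.dm_share.copy(),
                                 self.predm_share.copy(), self.weight.copy())


@dataclass
class ModelParams:
    """Everything the simulator needs besides the driver bundle."""

    flows: FlowParams = field(default_factory=FlowParams)
    energy: EnergyParams = field(default_factory=EnergyParams)
    init: InitialConditions = field(default_factory=InitialConditions)

    def copy(self) -> "ModelParams":
        return ModelParams(self.flows.copy(), self.energy.copy(), self.init.copy())


class Trajectory:
    """Ordered sequence of states plus derived prevalence series.

    Backed by a tidy :class:`pandas.DataFrame` (one row per year) with
    per-sex stock columns, flow bookkeeping and derived prevalences.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.empty:
            raise ValueError("empty trajectory")
        years = frame["year"].to_numpy()
        steps = np.diff(years)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ValueError("trajectory years must be strictly increasing with uniform step")
        self.frame = frame.reset_index(drop=True)

    @property
    def years(self) -> np.ndarray:
        return self.frame["year"].to_numpy()

    def at(self, year: float) -> pd.Series:
        idx = np.argmin(np.abs(self.years - year))
        if abs(self.years[idx] - year) > 1e-6:
            raise KeyError(f"year {year} not on the trajectory grid")
        return self.frame.iloc[idx]

    def series(self, column: str) -> pd.Series:
        return pd.Series(self.frame[column].to_numpy(), index=self.years, name=column)

    def value(self, column: str, year: float) -> float:
        return float(self.at(year)[column])

    def to_tidy(self) -> pd.DataFrame:
        """Long format: year, sex, variable, value."""
        rows = []
        for _, r in self.frame.iterrows():
            for col in self.frame.columns:
                if col == "year":
                    continue
                sex = ""
                name = col
                for s in SEXES:
                    if col.endswith("_" + s):
                        sex, name = s, col[: -len(s) - 1]
                rows.append({"year": r["year"], "sex": sex, "variable": name, "value": r[col]})
        return pd.DataFrame(rows, columns=["year", "sex", "variable", "value"])

    def to_csv(self, path) -> None:
        self.to_tidy().to_csv(path, index=False)


def advance_state(state: GlycemicState, flows: dict, inflow, dt: float,
                  weight=None, bmi=None) -> GlycemicState:
    """One explicit forward-Euler update of the glycemic stocks.

    ``flows`` holds per-sex rates (persons/yr) under the keys produced by
    :func:`diabesim.flows.glycemic_flow_set`; ``inflow`` is the per-sex
    demographic inflow into NG (persons/yr).  Stocks that would be overdrawn
    are clipped at zero with a warning.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    inflow = _pair(inflow, "inflow")
    for name, f in flows.items():
        if not np.all(np.isfinite(f)):
            raise ValueError(f"non-finite flow: {name}")
    f = {k: _pair(v, k) for k, v in flows.items()}
    ng = state.ng + dt * (inflow + f["pre_to_ng"] - f["ng_to_pre"] - f["deaths_ng"])
    predm = state.predm + dt * (f["ng_to_pre"] - f["pre_to_ng"] - f["pre_to_dm"] - f["deaths_pre"])
    dm = state.dm + dt * (f["pre_to_dm"] - f["deaths_dm"])
    for name, stock in (("ng", ng), ("predm", predm), ("dm", dm)):
        if np.any(stock < 0):
            warnings.warn(f"stock {name!r} overdrawn at year {state.year + dt:g}; clipped to 0")
    ng, predm, dm = (np.clip(s, 0.0, None) for s in (ng, predm, dm))
    return GlycemicState(
        year=state.year + dt,
        ng=ng, predm=predm, dm=dm,
        weight=state.weight if weight is None else weight,
        bmi=state.bmi if bmi is None else bmi,
    )


def _initial_state(params: ModelParams) -> GlycemicState:
    init, en = params.init, params.energy
    ng = init.pop * (1.0 - init.dm_share - init.predm_share)
    bmi = init.weight / en.height_m**2
    return GlycemicState(year=0.0, ng=ng, predm=init.pop * init.predm_share,
                         dm=init.pop * init.dm_share, weight=init.weight.copy(), bmi=bmi)


def _drivers_at(bundle: DriverBundle, t: float) -> dict:
    per_sex = {}
    for var in ("mvpa", "ssb", "fv", "upf", "other_kcal", "inflow"):
        per_sex[var] = np.array([bundle.value(var, t, sex) for sex in SEXES])
    return per_sex, float(bundle.value("mean_age", t)), float(bundle.value("m_base", t))


def simulate(params: ModelParams, bundle: DriverBundle, config: SimConfig | None = None,
             coverage: InterventionCoverage = NO_COVERAGE,
             coverage_start: float | None = None) -> Trajectory:
    """Run the coupled energy-balance / glycemic model over the window.

    Deterministic given identical inputs.  ``coverage`` applies from
    ``coverage_start`` (default: active over the whole window).
    """
    config = config or SimConfig()
    bundle.validate()
    state = _initial_state(params)
    state.year = config.t_start
    en, fl = params.energy, params.flows
    no_cov = NO_COVERAGE

    records = []

    def record(state: GlycemicState, flows: dict | None) -> None:
        ob = obesity_prev_from_bmi(state.bmi, en.bmi_sd)
        tot = state.total_by_sex
        row = {"year": state.year}
        for i, sex in enumerate(SEXES):
            row.update({
                f"ng_{sex}": state.ng[i], f"predm_{sex}": state.predm[i],
                f"dm_{sex}": state.dm[i], f"weight_{sex}": state.weight[i],
                f"bmi_{sex}": state.bmi[i], f"ob_prev_{sex}": ob[i],
                f"dm_prev_{sex}": state.dm[i] / tot[i],
                f"predm_prev_{sex}": state.predm[i] / tot[i],
            })
        total = tot.sum()
        row["total"] = total
        row["dm_prev"] = state.dm.sum() / total
        row["predm_prev"] = state.predm.sum() / total
        row["ng_prev"] = state.ng.sum() / total
        row["ob_prev"] = float((ob * tot).sum() / total)
        if flows is None:
            row["dm_deaths"] = np.nan
            row["dm_mortality_rate"] = np.nan
            row["total_deaths"] = np.nan
        else:
            dm_deaths = float(np.sum(flows["deaths_dm"]))
            row["dm_deaths"] = dm_deaths
            row["dm_mortality_rate"] = dm_deaths / state.dm.sum() if state.dm.sum() > 0 else np.nan
            row["total_deaths"] = float(sum(np.sum(flows[k]) for k in
                                            ("deaths_ng", "deaths_pre", "deaths_dm")))
        records.append(row)

    record(state, None)
    for _ in range(config.n_steps):
        t = state.year
        per_sex, age_index, m_base = _drivers_at(bundle, t)
        # --- energy balance: weight, BMI, obesity for the coming year -----
        try:
            diet = DietIntake(ssb=per_sex["ssb"], fv=per_sex["fv"], upf=per_sex["upf"],
                              other_kcal=per_sex["other_kcal"])
            intake = total_intake(diet, en)
            rmr = harris_benedict_rmr(list(SEXES), state.weight, en.height_cm, age_index, en)
            act = activity_expenditure(per_sex["mvpa"], state.weight, en)
            weight_new = annual_weight_update(state.weight, intake, rmr, act, en, config.dt)
            bmi_new = weight_new / en.height_m**2
            ob_new = obesity_prev_from_bmi(bmi_new, en.bmi_sd)
        except ValueError as exc:
            raise ValueError(f"year {t:g}: {exc}") from exc
        # --- glycemic flows using current-year obesity --------------------
        cov = coverage if (coverage_start is None or t >= coverage_start - 1e-9) else no_cov
        flows = glycemic_flow_set(state.ng, state.predm, state.dm, ob_new, age_index,
                                  per_sex["ssb"], per_sex["fv"], per_sex["mvpa"],
                                  fl, cov, m_base)
        state = advance_state(state, flows, per_sex["inflow"], config.dt,
                              weight=weight_new, bmi=bmi_new)
        if not np.all(np.isfinite(state.ng + state.predm + state.dm + state.weight)):
            raise FloatingPointError(f"NaN/Inf state produced at year {state.year:g}")
        record(state, flows)

    return Trajectory(pd.DataFrame.from_records(records))


_METRIC_COLUMNS = {"dm": "dm_prev", "predm": "predm_prev", "obesity": "ob_prev"}


def prevalence_series(traj: Trajectory, metric: str, sex: str | None = None) -> pd.Series:
    """Year-indexed prevalence fraction for ``metric`` in {dm, predm, obesity}."""
    if metric not in _METRIC_COLUMNS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {sorted(_METRIC_COLUMNS)}")
    col = _METRIC_COLUMNS[metric]
    if sex is not None:
        if sex not in SEXES:
            raise ValueError(f"unknown sex {sex!r}")
        col = f"{col}_{sex}"
    return traj.series(col)
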