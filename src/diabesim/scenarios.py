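"""Declarative scenario engine: trend modifications, coverage interventions,
the built-in Caribbean scenario bundles, the WHO Global Action Plan (GAP)
magnitude-search grid, and dose-response curves.

A scenario modifies the driver bundle from its start year onward.  Scaling a
trend multiplies every value from the start year by a constant, which
preserves the relative trajectory (doubling MVPA doubles the whole of the
post-start trend line); additive modifications shift the line by a constant.
Multiple modifications of one variable compose: all scales first
(multiplicative, order-free), then all adds.  Coverage-based downstream
interventions (lifestyle modification for the preDM stock, diabetes
self-management education for the DM stock) act on hazards, not trends.

All results are reported as deltas against a baseline run with identical
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import ModelParams, SimConfig, simulate, Trajectory
from .flows import InterventionCoverage, NO_COVERAGE
from .trends import DriverBundle

__all__ = [
    "TrendMod",
    "InfoCampaign",
    "ScenarioSpec",
    "DeltaTable",
    "apply_scenario",
    "run_scenario",
    "builtin_scenarios",
    "gap_search",
    "dose_response",
    "REPORT_YEARS",
]

REPORT_YEARS = (2021.0, 2025.0, 2030.0, 2050.0)

#: grams of fruit/vegetables per serving used to convert campaign effects
GRAMS_PER_SERVING = 80.0


@dataclass
class TrendMod:
    """One modification of one driver series."""

    variable: str
    mode: str  # "scale" | "add"
    magnitude: float

    def __post_init__(self) -> None:
        if self.mode not in ("scale", "add"):
            raise ValueError("mode must be 'scale' or 'add'")
        if self.mode == "scale" and self.magnitude <= 0:
            raise ValueError("scale magnitude must be > 0")


@dataclass
class InfoCampaign:
    """Front-of-package labelling plus public information campaigns.

    FOPL: a 6.6% mean reduction in (discretionary) caloric intake, a 13%
    increase in fruit-and-vegetable intake and a 13% decrease in
    ultra-processed foods.  The campaign adds up to 4 g/day of fruit and
    vegetables (converted at 80 g/serving).  A campaign MVPA boost is
    configurable but off by default.
    """

    kcal_scale: float = 0.934
    fv_scale: float = 1.13
    upf_scale: float = 0.87
    fv_add_g_per_day: float = 4.0
    mvpa_scale: float = 1.0

    def as_mods(self) -> list:
        mods = [
            TrendMod("ssb", "scale", self.kcal_scale),
            TrendMod("upf", "scale", self.upf_scale),
            TrendMod("fv", "scale", self.fv_scale),
            TrendMod("fv", "add", self.fv_add_g_per_day / GRAMS_PER_SERVING),
        ]
        if self.mvpa_scale != 1.0:
            mods.append(TrendMod("mvpa", "scale", self.mvpa_scale))
        return mods


@dataclass
class ScenarioSpec:
    """Declarative scenario: trend modifications + coverage interventions."""

    name: str
    start_year: float = 2020.0
    trend_mods: list = field(default_factory=list)
    coverage: InterventionCoverage = field(default_factory=InterventionCoverage)
    info: InfoCampaign | None = None

    def all_mods(self) -> list:
        mods = list(self.trend_mods)
        if self.info is not None:
            mods += self.info.as_mods()
        return mods


@dataclass
class DeltaTable:
    """Scenario-vs-baseline deltas at the reporting years.

    ``frame`` has one row per (metric, year) with baseline and scenario
    prevalence (fractions), the absolute delta in percentage points and the
    relative delta in percent.  ``dm_deaths_rel_change_2050`` is the relative
    change in annual deaths among the DM stock in 2050.
    """

    scenario: str
    frame: pd.DataFrame
    dm_deaths_rel_change_2050: float
    dm_mortality_rate_rel_change_2050: float

    def delta_pp(self, metric: str, year: float) -> float:
        sel = self.frame[(self.frame.metric == metric) & (self.frame.year == year)]
        if sel.empty:
            raise KeyError(f"no delta for ({metric}, {year})")
        return float(sel["delta_pp"].iloc[0])

    def delta_rel_pct(self, metric: str, year: float) -> float:
        sel = self.frame[(self.frame.metric == metric) & (self.frame.year == year)]
        if sel.empty:
            raise KeyError(f"no delta for ({metric}, {year})")
        return float(sel["delta_rel_pct"].iloc[0])


def apply_scenario(bundle: DriverBundle, spec: ScenarioSpec,
                   grid=None) -> DriverBundle:
    """Return a modified copy of the bundle; the input is untouched.

    Modified series are resampled to an annual grid first so that the
    modification starts exactly at the scenario start year.
    """
    out = bundle.copy()
    mods = spec.all_mods()
    for mod in mods:
        if (mod.variable, None) not in bundle.series and not any(
            name == mod.variable for name, _ in bundle.series
        ):
            raise KeyError(f"unknown variable in scenario: {mod.variable!r}")
    by_var = {}
    for mod in mods:
        by_var.setdefault(mod.variable, []).append(mod)
    for (name, sex), series in list(out.series.items()):
        if name not in by_var:
            continue
        if grid is None:
            years = np.arange(min(series.years[0], spec.start_year - 1.0),
                              max(series.years[-1], 2051.0) + 1.0)
        else:
            years = np.asarray(grid, dtype=float)
        s = series.resampled(years)
        mask = s.years >= spec.start_year - 1e-9
        values = s.values.copy()
        for mod in by_var[name]:
            if mod.mode == "scale":
                values[mask] *= mod.magnitude
        for mod in by_var[name]:
            if mod.mode == "add":
                values[mask] += mod.magnitude
        if np.any(values[mask] < 0):
            values[mask] = np.clip(values[mask], 0.0, None)
        out.series[(name, sex)] = replace(s, values=values)
    return out


def run_scenario(spec: ScenarioSpec, params: ModelParams, bundle: DriverBundle,
                 config: SimConfig | None = None,
                 baseline_traj: Trajectory | None = None,
                 report_years=REPORT_YEARS) -> DeltaTable:
    """Run baseline and scenario with identical parameters; report deltas."""
    config = config or SimConfig()
    if baseline_traj is None:
        baseline_traj = simulate(params, bundle, config)
    scen_bundle = apply_scenario(bundle, spec)
    scen_traj = simulate(params, scen_bundle, config,
                         coverage=spec.coverage, coverage_start=spec.start_year)
    rows = []
    for metric, col in (("dm_prev", "dm_prev"), ("ob_prev", "ob_prev")):
        for year in report_years:
            base = baseline_traj.value(col, year)
            scen = scen_traj.value(col, year)
            delta_pp = 100.0 * (scen - base)
            rows.append({
                "metric": metric, "year": year, "baseline": base, "scenario": scen,
                "delta_pp": delta_pp,
                "delta_rel_pct": delta_pp / base if base > 0 else np.nan,
            })
    d_base = baseline_traj.value("dm_deaths", 2050.0)
    d_scen = scen_traj.value("dm_deaths", 2050.0)
    r_base = baseline_traj.value("dm_mortality_rate", 2050.0)
    r_scen = scen_traj.value("dm_mortality_rate", 2050.0)
    return DeltaTable(
        scenario=spec.name,
        frame=pd.DataFrame(rows),
        dm_deaths_rel_change_2050=(d_scen - d_base) / d_base,
        dm_mortality_rate_rel_change_2050=(r_scen - r_base) / r_base,
    )


def _downstream_coverage() -> InterventionCoverage:
    return InterventionCoverage(lifestyle_cov=0.25, dsme_cov=1.0 / 3.0)


def builtin_scenarios(start_year: float = 2020.0) -> dict:
    """The combined Caribbean scenario bundles plus each individual piece.

    Combined bundles: ``downstream`` (lifestyle modification to 25% of the
    preDM stock + DSME to one third of the DM stock), ``modest_upstream``
    (15% SSB/UPF reductions, +15% F&V, FOPL, +15 min/day MVPA),
    ``intensive_upstream`` (25% changes, +30 min/day MVPA) and
    ``combined_intensive`` (intensive upstream + downstream).
    """
    def spec(name, mods=(), cov=None, info=None):
        return ScenarioSpec(name=name, start_year=start_year, trend_mods=list(mods),
                            coverage=cov or InterventionCoverage(), info=info)

    modest_mods = [TrendMod("ssb", "scale", 0.85), TrendMod("upf", "scale", 0.85),
                   TrendMod("fv", "scale", 1.15), TrendMod("mvpa", "add", 15.0)]
    intensive_mods = [TrendMod("ssb", "scale", 0.75), TrendMod("upf", "scale", 0.75),
                      TrendMod("fv", "scale", 1.25), TrendMod("mvpa", "add", 30.0)]
    return {
        "downstream": spec("downstream", cov=_downstream_coverage()),
        "modest_upstream": spec("modest_upstream", modest_mods, info=InfoCampaign()),
        "intensive_upstream": spec("intensive_upstream", intensive_mods, info=InfoCampaign()),
        "combined_intensive": spec("combined_intensive", intensive_mods,
                                   cov=_downstream_coverage(), info=InfoCampaign()),
        # individual interventions
        "lifestyle_only": spec("lifestyle_only", cov=InterventionCoverage(lifestyle_cov=0.25)),
        "dsme_only": spec("dsme_only", cov=InterventionCoverage(dsme_cov=1.0 / 3.0)),
        "mvpa15": spec("mvpa15", [TrendMod("mvpa", "add", 15.0)]),
        "mvpa30": spec("mvpa30", [TrendMod("mvpa", "add", 30.0)]),
        "ssb15": spec("ssb15", [TrendMod("ssb", "scale", 0.85)]),
        "ssb25": spec("ssb25", [TrendMod("ssb", "scale", 0.75)]),
        "upf15": spec("upf15", [TrendMod("upf", "scale", 0.85)]),
        "upf25": spec("upf25", [TrendMod("upf", "scale", 0.75)]),
        "fv15": spec("fv15", [TrendMod("fv", "scale", 1.15)]),
        "fv25": spec("fv25", [TrendMod("fv", "scale", 1.25)]),
        "info_campaign": spec("info_campaign", info=InfoCampaign()),
    }


#: driver variables treated as modifiable caloric components in the GAP search
GAP_CALORIC_VARIABLES = ("ssb", "upf")


def gap_search(mvpa_multipliers, kcal_reductions, params: ModelParams,
               bundle: DriverBundle, config: SimConfig | None = None,
               start_year: float = 2010.0, target_year: float = 2025.0) -> pd.DataFrame:
    """WHO Global Action Plan magnitude search.

    For each (MVPA multiplier m, caloric reduction r): scale the whole MVPA
    trend by m and the modifiable caloric components by (1 - r) from
    ``start_year``, then report the 2010->2025 change in diabetes and obesity
    prevalence and whether the "no increase vs 2010" target is met for each.
    """
    mvpa_multipliers = list(mvpa_multipliers)
    kcal_reductions = list(kcal_reductions)
    if not mvpa_multipliers or not kcal_reductions:
        raise ValueError("grid must be non-empty")
    config = config or SimConfig()
    rows = []
    for m in mvpa_multipliers:
        for r in kcal_reductions:
            mods = [TrendMod("mvpa", "scale", float(m))]
            if r > 0:
                mods += [TrendMod(v, "scale", 1.0 - float(r)) for v in GAP_CALORIC_VARIABLES]
            spec = ScenarioSpec(name=f"gap_m{m}_r{r}", start_year=start_year, trend_mods=mods)
            traj = simulate(params, apply_scenario(bundle, spec), config)
            dm_d = traj.value("dm_prev", target_year) - traj.value("dm_prev", start_year)
            ob_d = traj.value("ob_prev", target_year) - traj.value("ob_prev", start_year)
            rows.append({
                "mvpa_multiplier": float(m), "kcal_reduction": float(r),
                "dm_delta": dm_d, "ob_delta": ob_d,
                "dm_met": dm_d <= 0, "ob_met": ob_d <= 0,
                "both_met": dm_d <= 0 and ob_d <= 0,
            })
    return pd.DataFrame(rows)


def dose_response(variable: str, levels, horizon_years, params: ModelParams,
                  bundle: DriverBundle, config: SimConfig | None = None,
                  mode: str = "scale_reduction", start_year: float = 2020.0) -> pd.DataFrame:
    """Dose-response curves for one driver.

    ``mode='scale_reduction'``: levels are fractional reductions (0.10 scales
    the post-start trend by 0.90).  ``mode='add'``: levels are additive
    shifts in the driver's units.  Deltas are scenario - baseline prevalence
    (percentage points) at each horizon.
    """
    if list(levels) != sorted(levels):
        raise ValueError("levels must be sorted ascending")
    config = config or SimConfig()
    base = simulate(params, bundle, config)
    rows = []
    for level in levels:
        if mode == "scale_reduction":
            mods = [TrendMod(variable, "scale", 1.0 - float(level))] if level else []
        elif mode == "add":
            mods = [TrendMod(variable, "add", float(level))] if level else []
        else:
            raise ValueError("mode must be 'scale_reduction' or 'add'")
        spec = ScenarioSpec(name=f"dose_{variable}_{level}", start_year=start_year,
                            trend_mods=mods)
        traj = simulate(params, apply_scenario(bundle, spec), config) if mods else base
        for year in horizon_years:
            for metric in ("dm_prev", "ob_prev"):
                rows.append({
                    "variable": variable, "level": float(level), "year": float(year),
                    "metric": metric,
                    "baseline": base.value(metric, year),
                    "value": traj.value(metric, year),
                    "delta_pp": 100.0 * (traj.value(metric, year) - base.value(metric, year)),
                })
    return pd.DataFrame(rows)
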