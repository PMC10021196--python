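"""Synthetic driver bundles with known ground truth, and noisy survey draws.

The generator emulates the structure of the real model inputs — smooth
monotone annual trends (declining MVPA, rising SSB/UPF/caloric intake, an
ageing population, declining background mortality) plus binomially noisy
cross-sectional survey observations of prevalence at a few survey years —
without reproducing any published series.  Because the true parameters are
known, bundles from this module drive the calibration parameter-recovery
experiments and end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibrate import CalibrationTarget
from .core import InitialConditions, ModelParams, Trajectory
from .energy import EnergyParams, bmi_from_obesity_prev
from .flows import FlowParams, ReferenceConditions
from .construct import add_other_kcal
from .trends import DriverBundle, TrendSeries, default_units

__all__ = ["SynthConfig", "make_bundle", "make_survey_observations"]


@dataclass
class SynthConfig:
    """Trend shapes and survey design for a synthetic study.

    Slopes are per-year changes of the linear driver trends over 1990-2050;
    obesity endpoints define the designed per-sex obesity prevalence in 1990
    and 2050 from which the BMI paths (and the residual caloric driver) are
    constructed.
    """

    seed: int = 0
    t_start: float = 1990.0
    t_end: float = 2050.0
    mvpa_start: float = 70.0
    mvpa_slope: float = -0.35       # min/day per yr (declining)
    ssb_start: float = 0.30
    ssb_slope: float = 0.006        # servings/day per yr (rising)
    upf_start: float = 25.0
    upf_slope: float = 1.20         # kcal/day per yr (rising)
    fv_start: float = 1.60
    fv_slope: float = -0.004
    mean_age_start: float = 36.0
    mean_age_slope: float = 0.06
    m_base_start: float = 0.0115
    m_base_slope: float = -4.5e-5
    inflow_start: float = 15_000.0
    inflow_slope: float = -60.0
    ob_endpoints: dict = field(default_factory=lambda: {
        "female": (0.20, 0.50), "male": (0.09, 0.30)})
    survey_years: tuple = (1999.0, 2008.0, 2017.0)
    n_per_survey: int = 2500

    def __post_init__(self) -> None:
        if self.n_per_survey < 100:
            raise ValueError("n_per_survey must be >= 100")
        for y in self.survey_years:
            if not self.t_start <= y <= self.t_end:
                raise ValueError("survey years must lie within the simulation span")


def _true_params(config: SynthConfig) -> ModelParams:
    mid = 0.5 * (config.t_start + config.t_end)  # reference year ~2020
    energy = EnergyParams()
    ob_mid = {}
    for sex, (a, b) in config.ob_endpoints.items():
        ob_mid[sex] = a + (b - a) * (mid - config.t_start) / (config.t_end - config.t_start)
    ref = ReferenceConditions(
        ssb=config.ssb_start + config.ssb_slope * (mid - config.t_start),
        fv=config.fv_start + config.fv_slope * (mid - config.t_start),
        mvpa=config.mvpa_start + config.mvpa_slope * (mid - config.t_start),
        ob_prev=np.array([ob_mid["female"], ob_mid["male"]]),
        age_index=config.mean_age_start + config.mean_age_slope * (mid - config.t_start),
    )
    flows = FlowParams(h_ng_pre=0.020, h_pre_ng=0.035, h_pre_dm=0.050,
                       beta_ob=1.5, beta_age=1.0, rr_mvpa30=0.88,
                       hr_pre=1.1, hr_dm=1.8, ref=ref)
    bmi0 = {sex: bmi_from_obesity_prev(config.ob_endpoints[sex][0], energy.bmi_sd[i])
            for i, sex in enumerate(("female", "male"))}
    init = InitialConditions(
        pop=np.array([660_000.0, 650_000.0]),
        dm_share=np.array([0.055, 0.045]),
        predm_share=np.array([0.11, 0.11]),
        weight=np.array([bmi0["female"] * energy.height_m[0] ** 2,
                         bmi0["male"] * energy.height_m[1] ** 2]),
    )
    return ModelParams(flows=flows, energy=energy, init=init)


def make_bundle(config: SynthConfig | None = None):
    """Build a synthetic driver bundle and its ground-truth parameters.

    Deterministic given the config (trend construction uses no randomness;
    the seed only feeds survey observation noise).  Returns
    ``(bundle, params)``.
    """
    config = config or SynthConfig()
    years = np.arange(config.t_start, config.t_end + 1.0)
    t = years - config.t_start
    # seed-dependent shape perturbation: scales each slope by up to +/-10%,
    # which changes the series but never their direction of change
    rng = np.random.default_rng(config.seed)

    def linear(name, start, slope, sex=None):
        slope = slope * (1.0 + 0.1 * rng.uniform(-1.0, 1.0))
        return TrendSeries(name, years=years, values=start + slope * t, sex=sex,
                           units=default_units(name))

    bundle = DriverBundle()
    bundle.add(linear("mvpa", config.mvpa_start, config.mvpa_slope))
    bundle.add(linear("ssb", config.ssb_start, config.ssb_slope))
    bundle.add(linear("upf", config.upf_start, config.upf_slope))
    bundle.add(linear("fv", config.fv_start, config.fv_slope))
    bundle.add(linear("mean_age", config.mean_age_start, config.mean_age_slope))
    bundle.add(linear("m_base", config.m_base_start, config.m_base_slope))
    for sex in ("female", "male"):
        bundle.add(linear("inflow", config.inflow_start, config.inflow_slope, sex=sex))

    params = _true_params(config)
    # designed smooth obesity rise -> BMI paths -> residual caloric driver
    frac = t / t[-1]
    bmi_paths = {}
    for i, sex in enumerate(("female", "male")):
        a, b = config.ob_endpoints[sex]
        ob_path = a + (b - a) * frac
        bmi_paths[sex] = bmi_from_obesity_prev(ob_path, params.energy.bmi_sd[i])
    add_other_kcal(bundle, years, bmi_paths, params.energy)
    bundle.validate()
    return bundle, params


def make_survey_observations(traj: Trajectory, years, n: int, seed: int = 0,
                             metrics=("dm_prev", "predm_prev", "ob_prev")) -> list:
    """Binomially noisy survey observations of prevalence.

    For each year and metric a count is drawn as Binomial(n, true prevalence);
    the target value is count/n with the usual binomial standard error
    sqrt(p_hat (1 - p_hat) / n) (weights in calibration are 1/se^2).
    """
    rng = np.random.default_rng(seed)
    targets = []
    for year in years:
        for metric in metrics:
            p = traj.value(metric, year)
            if not 0 <= p <= 1:
                raise ValueError(f"trajectory {metric} at {year} is not a probability")
            count = rng.binomial(n, p)
            p_hat = count / n
            se = float(np.sqrt(max(p_hat * (1 - p_hat), 1e-12) / n))
            targets.append(CalibrationTarget(year=float(year), metric=metric,
                                             value=float(p_hat), se=se))
    return targets
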