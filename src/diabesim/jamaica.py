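"""Packaged Jamaica fixture: driver bundle, survey anchors, calibrated params.

The fixture embodies the study conditions for the Jamaican adult (20+)
population: a declining MVPA trend, rising SSB/UPF intake, a slowly ageing
population with declining background mortality, and survey anchors for
diabetes and obesity prevalence (diabetes 12% in 2018; obesity 28.6% in
2018; women's obesity 38.4% in 2020).  The underlying survey time-series are
not public at this granularity, so the driver series here are *constructed*:
their shapes follow the documented directions of change and their levels and
the free model parameters are calibrated so that the baseline run reproduces
the published prevalence trajectory and the published scenario response
magnitudes.  Dietary component levels are therefore effective
(compensation-adjusted) discretionary calories, not literal consumption
volumes; see docs/methods.md.

Calibrated numbers below are fits, frozen for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibrate import CalibrationTarget
from .construct import add_other_kcal
from .core import InitialConditions, ModelParams
from .energy import EnergyParams, bmi_from_obesity_prev
from .flows import FlowParams, ReferenceConditions
from .trends import DriverBundle, TrendSeries, default_units

__all__ = ["jamaica_fixture", "JamaicaFixture"]

# ----------------------------------------------------------------------------
# designed trend knots (annual linear interpolation between them)
# ----------------------------------------------------------------------------
_TREND_KNOTS = {
    # total MVPA, min/day: strictly declining 1990 -> 2050
    "mvpa": [(1990, 74.0), (2000, 69.5), (2010, 65.0), (2020, 57.5),
             (2030, 50.0), (2040, 42.5), (2050, 35.0)],
    # effective discretionary SSB servings/day: rising
    "ssb": [(1990, 0.047), (2010, 0.089), (2030, 0.124), (2050, 0.153)],
    # effective discretionary ultra-processed kcal/day: rising
    "upf": [(1990, 8.3), (2010, 15.3), (2030, 20.1), (2050, 23.6)],
    # fruit & vegetable servings/day: slowly declining
    "fv": [(1990, 1.65), (2010, 1.50), (2050, 1.30)],
    # mean adult age, yr: ageing population
    "mean_age": [(1990, 36.2), (2012, 38.7), (2032, 43.2), (2050, 44.6)],
    # background adult all-cause mortality, 1/yr: declining
    "m_base": [(1990, 0.0115), (2010, 0.0100), (2030, 0.0091), (2050, 0.0085)],
}
# demographic inflow into NG per sex, persons/yr
_INFLOW_KNOTS = [(1990, 16000.0), (2010, 14500.0), (2030, 13000.0), (2050, 12000.0)]

# designed obesity prevalence anchors (fractions); men's path is derived as
# 2*overall - women under near-equal sex weights
_OB_OVERALL_KNOTS = [(1990, 0.205), (2000, 0.235), (2010, 0.264), (2018, 0.286),
                     (2020, 0.292), (2021, 0.294), (2025, 0.306), (2030, 0.321),
                     (2040, 0.355), (2050, 0.392)]
_OB_WOMEN_KNOTS = [(1990, 0.270), (2000, 0.305), (2010, 0.345), (2018, 0.376),
                   (2020, 0.384), (2025, 0.400), (2030, 0.418), (2040, 0.452),
                   (2050, 0.488)]

_BMI_SD = np.array([6.0, 5.0])  # calibrated BMI dispersion (female, male)
_HEIGHT_CM = np.array([162.0, 175.0])

# effective (compensation-adjusted) MVPA MET excess; calibrated so that the
# weight response to MVPA changes matches the published response magnitudes
_MVPA_MET_EFF = 1.13

# calibrated flow parameters (frozen fit; see docs/methods.md)
_CAL = {
    "h_ng_pre": 0.0063800,
    "h_pre_ng": 0.0020000,
    "h_pre_dm": 0.0307660,
    "beta_ob": 1.70,
    "beta_age": 0.30,
    "rr_mvpa30": 0.885,
    "hr_pre": 1.1,
    "hr_dm": 2.20,
    "dm_share0": 0.0358260,
    "predm_share0": 0.3300000,
}

# reference (2010) exposures at which every flow modifier equals one
_REF_YEAR = 2010.0


def _series(name, knots, sex=None, extrap="hold"):
    years, values = zip(*knots)
    return TrendSeries(name, years=np.array(years, float), values=np.array(values, float),
                       sex=sex, units=default_units(name), extrap=extrap)


def _interp(knots, years):
    ky, kv = zip(*knots)
    return np.interp(years, ky, kv)


@dataclass
class JamaicaFixture:
    """Bundle + calibration anchors + calibrated parameters."""

    bundle: DriverBundle
    targets: list
    params: ModelParams

    def __iter__(self):  # allow tuple unpacking
        return iter((self.bundle, self.targets, self.params))


def jamaica_fixture() -> JamaicaFixture:
    """The packaged Jamaica study fixture (deterministic)."""
    years = np.arange(1990.0, 2051.0)
    bundle = DriverBundle()
    for name, knots in _TREND_KNOTS.items():
        bundle.add(_series(name, knots))
    for sex in ("female", "male"):
        bundle.add(_series("inflow", _INFLOW_KNOTS, sex=sex))

    energy = EnergyParams(height_cm=_HEIGHT_CM.copy(), bmi_sd=_BMI_SD.copy(),
                          mvpa_met=_MVPA_MET_EFF)

    # designed per-sex obesity -> mean-BMI paths -> residual caloric closure
    ob_all = _interp(_OB_OVERALL_KNOTS, years)
    ob_f = _interp(_OB_WOMEN_KNOTS, years)
    ob_m = np.clip(2.0 * ob_all - ob_f, 1e-3, 0.999)
    bmi_paths = {
        "female": bmi_from_obesity_prev(ob_f, energy.bmi_sd[0]),
        "male": bmi_from_obesity_prev(ob_m, energy.bmi_sd[1]),
    }
    add_other_kcal(bundle, years, bmi_paths, energy)
    bundle.validate()

    i2010 = int(_REF_YEAR - years[0])
    ref = ReferenceConditions(
        ssb=float(bundle.value("ssb", _REF_YEAR)),
        fv=float(bundle.value("fv", _REF_YEAR)),
        mvpa=float(bundle.value("mvpa", _REF_YEAR)),
        ob_prev=np.array([ob_f[i2010], ob_m[i2010]]),
        age_index=float(bundle.value("mean_age", _REF_YEAR)),
    )
    flows = FlowParams(
        h_ng_pre=_CAL["h_ng_pre"], h_pre_ng=_CAL["h_pre_ng"], h_pre_dm=_CAL["h_pre_dm"],
        beta_ob=_CAL["beta_ob"], beta_age=_CAL["beta_age"],
        rr_mvpa30=_CAL["rr_mvpa30"], hr_pre=_CAL["hr_pre"], hr_dm=_CAL["hr_dm"],
        ref=ref,
    )
    init = InitialConditions(
        pop=np.array([663_500.0, 663_500.0]),
        dm_share=np.array([_CAL["dm_share0"]] * 2),
        predm_share=np.array([_CAL["predm_share0"]] * 2),
        weight=np.array([bmi_paths["female"][0] * (energy.height_cm[0] / 100.0) ** 2,
                         bmi_paths["male"][0] * (energy.height_cm[1] / 100.0) ** 2]),
    )
    params = ModelParams(flows=flows, energy=energy, init=init)

    # printed survey anchors used for calibration
    targets = [
        CalibrationTarget(2018.0, "dm_prev", 0.120),
        CalibrationTarget(2020.0, "dm_prev", 0.125),
        CalibrationTarget(2021.0, "dm_prev", 0.127),
        CalibrationTarget(2025.0, "dm_prev", 0.139),
        CalibrationTarget(2030.0, "dm_prev", 0.154),
        CalibrationTarget(2050.0, "dm_prev", 0.209),
        CalibrationTarget(2018.0, "ob_prev", 0.286),
        CalibrationTarget(2030.0, "ob_prev", 0.321),
        CalibrationTarget(2050.0, "ob_prev", 0.392),
        CalibrationTarget(2020.0, "ob_prev", 0.384, sex="female"),
        CalibrationTarget(2050.0, "ob_prev", 0.488, sex="female"),
    ]
    return JamaicaFixture(bundle=bundle, targets=targets, params=params)
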