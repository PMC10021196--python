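"""Energy-balance sub-model: caloric intake and expenditure, annual weight
change, mean BMI, and the BMI-to-obesity-prevalence mapping.

The model tracks one mean body weight per sex.  Resting metabolic rate (RMR)
follows the classical Harris-Benedict equations; moderate-to-vigorous physical
activity (MVPA) is converted to kcal/day with a net-of-rest MET formula; the
annual caloric imbalance is turned into a weight change through an
energy-density constant (kcal per kg of body mass, "Forbes constant").
Because RMR is re-evaluated at the current weight every step, weight gain is
self-limiting.

Obesity prevalence is derived from the mean BMI by assuming a normal BMI
distribution per sex with a constant, calibrated standard deviation:
P(obese) = P(BMI >= 30) = 1 - Phi((30 - mean BMI) / sd).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

__all__ = [
    "SEXES",
    "EnergyParams",
    "DietIntake",
    "harris_benedict_rmr",
    "total_intake",
    "activity_expenditure",
    "annual_weight_update",
    "obesity_prev_from_bmi",
]

#: canonical sex ordering used for all per-sex arrays in the package
SEXES = ("female", "male")

OBESITY_BMI_THRESHOLD = 30.0

# Harris-Benedict coefficients (kcal/day): intercept, weight (kg),
# height (cm), age (yr) terms, in SEXES order.
_HB_DEFAULT = np.array(
    [
        [655.1, 9.563, 1.850, -4.676],  # female
        [66.5, 13.75, 5.003, -6.755],  # male
    ]
)


def _pair(value, name: str) -> np.ndarray:
    """Coerce a scalar or length-2 sequence to a (2,) float array."""
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 2)
    if arr.shape != (2,):
        raise ValueError(f"{name} must be a scalar or a (female, male) pair")
    return arr


@dataclass
class EnergyParams:
    """Parameters of the energy-balance sub-model.

    Attributes
    ----------
    hb_coef : (2, 4) array
        Harris-Benedict coefficients per sex (intercept, weight, height, age).
    forbes_k : float
        Energy density of body-mass change, kcal per kg.
    ssb_kcal_per_serving : float
        Caloric content of one sugar-sweetened-beverage serving.
    fv_kcal_per_serving : float
        Net caloric content of one fruit/vegetable serving (0 by default:
        their modelled effect is on diabetes incidence, not calories).
    mvpa_met : float
        MET value of MVPA; expenditure uses the excess over rest (met - 1).
    paf : float
        Sedentary physical-activity factor applied to RMR to represent
        non-MVPA expenditure.
    height_cm : (2,) array
        Mean adult height per sex, cm.
    bmi_sd : (2,) array
        Standard deviation of the population BMI distribution per sex
        (calibrated).
    """

    hb_coef: np.ndarray = field(default_factory=lambda: _HB_DEFAULT.copy())
    forbes_k: float = 7700.0
    ssb_kcal_per_serving: float = 150.0
    fv_kcal_per_serving: float = 0.0
    mvpa_met: float = 4.0
    paf: float = 1.2
    height_cm: np.ndarray = field(default_factory=lambda: np.array([162.0, 175.0]))
    bmi_sd: np.ndarray = field(default_factory=lambda: np.array([6.0, 5.0]))

    def __post_init__(self) -> None:
        self.hb_coef = np.asarray(self.hb_coef, dtype=float)
        self.height_cm = _pair(self.height_cm, "height_cm")
        self.bmi_sd = _pair(self.bmi_sd, "bmi_sd")
        if self.forbes_k <= 0:
            raise ValueError("forbes_k must be > 0")
        if np.any(self.bmi_sd <= 0):
            raise ValueError("bmi_sd must be > 0")
        if np.any((self.height_cm < 140) | (self.height_cm > 200)):
            raise ValueError("height_cm outside plausible adult range [140, 200]")

    @property
    def height_m(self) -> np.ndarray:
        return self.height_cm / 100.0

    def copy(self) -> "EnergyParams":
        out = replace(self)
        out.hb_coef = self.hb_coef.copy()
        out.height_cm = self.height_cm.copy()
        out.bmi_sd = self.bmi_sd.copy()
        return out


@dataclass
class DietIntake:
    """Dietary drivers at one point in time (per sex or scalar).

    ssb and fv are servings/day; upf and other_kcal are kcal/day.
    """

    ssb: float
    fv: float
    upf: float
    other_kcal: float

    def __post_init__(self) -> None:
        for name in ("ssb", "fv", "upf", "other_kcal"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"diet component {name!r} must be >= 0")


def _sex_index(sex) -> np.ndarray | int:
    if isinstance(sex, str):
        if sex not in SEXES:
            raise ValueError(f"unknown sex {sex!r}; expected one of {SEXES}")
        return SEXES.index(sex)
    return np.asarray([SEXES.index(s) for s in sex])


def harris_benedict_rmr(sex, weight, height, age, params: EnergyParams | None = None):
    """Resting metabolic rate, kcal/day.

    male:   66.5  + 13.75 W + 5.003 H - 6.755 A
    female: 655.1 + 9.563 W + 1.850 H - 4.676 A
    with W in kg, H in cm, A in years.
    """
    params = params or EnergyParams()
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any((weight <= 30) | (weight >= 250)):
        raise ValueError("weight outside plausible adult range (30, 250) kg")
    if np.any((height <= 120) | (height >= 220)):
        raise ValueError("height outside plausible adult range (120, 220) cm")
    if np.any(age < 20):
        raise ValueError("age must be >= 20 (adult population)")
    c = params.hb_coef[_sex_index(sex)]
    return c[..., 0] + c[..., 1] * weight + c[..., 2] * height + c[..., 3] * age


def total_intake(diet: DietIntake, params: EnergyParams | None = None):
    """Total caloric intake, kcal/day."""
    params = params or EnergyParams()
    return (
        np.asarray(diet.other_kcal, dtype=float)
        + np.asarray(diet.upf, dtype=float)
        + np.asarray(diet.ssb, dtype=float) * params.ssb_kcal_per_serving
        + np.asarray(diet.fv, dtype=float) * params.fv_kcal_per_serving
    )


def activity_expenditure(mvpa, weight, params: EnergyParams | None = None):
    """Net caloric expenditure of MVPA, kcal/day.

    Uses the net-of-rest MET convention:
    mvpa [min/day] * (MET - 1) * 3.5 * weight [kg] / 200.
    """
    params = params or EnergyParams()
    mvpa = np.asarray(mvpa, dtype=float)
    if np.any(mvpa < 0):
        raise ValueError("mvpa must be >= 0")
    return mvpa * (params.mvpa_met - 1.0) * 3.5 * np.asarray(weight, dtype=float) / 200.0


def annual_weight_update(weight, intake, rmr, activity, params: EnergyParams | None = None, dt: float = 1.0):
    """Advance mean body weight by ``dt`` years from the caloric gap.

    weight' = weight + dt * 365.25 * (intake - paf*rmr - activity) / forbes_k
    """
    params = params or EnergyParams()
    if np.any(np.asarray(weight) <= 0):
        raise ValueError("weight must be > 0")
    gap = np.asarray(intake, dtype=float) - params.paf * np.asarray(rmr, dtype=float) - np.asarray(activity, dtype=float)
    new = np.asarray(weight, dtype=float) + dt * 365.25 * gap / params.forbes_k
    if np.any(new <= 0):
        raise ValueError("weight update produced a non-positive weight")
    return new


def obesity_prev_from_bmi(mean_bmi, bmi_sd):
    """Obesity prevalence P(BMI >= 30) under a normal BMI distribution."""
    mean_bmi = np.asarray(mean_bmi, dtype=float)
    bmi_sd = np.asarray(bmi_sd, dtype=float)
    if np.any((mean_bmi <= 15) | (mean_bmi >= 50)):
        raise ValueError("mean_bmi outside plausible range (15, 50)")
    if np.any(bmi_sd <= 0):
        raise ValueError("bmi_sd must be > 0")
    return norm.sf((OBESITY_BMI_THRESHOLD - mean_bmi) / bmi_sd)


def bmi_from_obesity_prev(prev, bmi_sd):
    """Inverse of :func:`obesity_prev_from_bmi` (closed form)."""
    prev = np.asarray(prev, dtype=float)
    if np.any((prev <= 0) | (prev >= 1)):
        raise ValueError("prevalence must be in (0, 1)")
    return OBESITY_BMI_THRESHOLD - norm.isf(prev) * np.asarray(bmi_sd, dtype=float)
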