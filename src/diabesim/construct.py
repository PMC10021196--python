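"""Construction helpers for packaged and synthetic driver bundles.

The residual caloric driver (``other_kcal``) is obtained by *inverting* the
energy-balance update along a designed mean-BMI path: given the BMI (hence
weight) trajectory a bundle should produce, the annual caloric gap the Euler
update needs is exact, so total intake — and therefore the residual after
the explicit dietary components — follows in closed form.  This makes the
baseline obesity trajectory of a constructed bundle an exact design choice
while scenarios still perturb weight through the full dynamic model.
"""

from __future__ import annotations

import numpy as np

from .energy import SEXES, EnergyParams, harris_benedict_rmr, activity_expenditure
from .trends import DriverBundle, TrendSeries, default_units

__all__ = ["other_kcal_closure", "add_other_kcal"]


def other_kcal_closure(years: np.ndarray, bmi_path: np.ndarray, sex: str,
                       bundle: DriverBundle, energy: EnergyParams) -> np.ndarray:
    """Residual caloric intake series reproducing ``bmi_path`` exactly.

    ``years`` must be an annual grid; ``bmi_path`` the designed mean BMI at
    those years for ``sex``.  Uses the other drivers already present in the
    bundle (mvpa, ssb, fv, upf, mean_age).
    """
    years = np.asarray(years, dtype=float)
    if not np.allclose(np.diff(years), 1.0):
        raise ValueError("closure requires an annual year grid")
    i = SEXES.index(sex)
    h2 = energy.height_m[i] ** 2
    w = np.asarray(bmi_path, dtype=float) * h2
    # required caloric gap for each Euler step; extend the final step's slope
    dw = np.diff(w)
    dw = np.append(dw, dw[-1])
    gap = dw * energy.forbes_k / 365.25
    age = np.asarray([bundle.value("mean_age", t) for t in years])
    mvpa = np.asarray([bundle.value("mvpa", t, sex) for t in years])
    ssb = np.asarray([bundle.value("ssb", t, sex) for t in years])
    fv = np.asarray([bundle.value("fv", t, sex) for t in years])
    upf = np.asarray([bundle.value("upf", t, sex) for t in years])
    rmr = harris_benedict_rmr([sex] * len(years), w, energy.height_cm[i], age, energy)
    act = activity_expenditure(mvpa, w, energy)
    intake = gap + energy.paf * rmr + act
    other = intake - upf - ssb * energy.ssb_kcal_per_serving - fv * energy.fv_kcal_per_serving
    if np.any(other < 0):
        raise ValueError("closure produced negative other_kcal; implausible design inputs")
    return other


def add_other_kcal(bundle: DriverBundle, years: np.ndarray,
                   bmi_paths: dict, energy: EnergyParams) -> None:
    """Attach per-sex ``other_kcal`` closure series to the bundle in place."""
    for sex, path in bmi_paths.items():
        other = other_kcal_closure(years, path, sex, bundle, energy)
        bundle.add(TrendSeries("other_kcal", years=years, values=other, sex=sex,
                               units=default_units("other_kcal")))
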