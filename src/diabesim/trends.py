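"""Annual driver time series: validation, interpolation, extrapolation, I/O.

Every model input that changes over calendar time (MVPA, dietary components,
demographic inflow, mean adult age, background mortality) is a
:class:`TrendSeries` — a sparse set of (year, value) knots with linear
interpolation between knots and a configurable rule beyond the knot range
(``hold`` the end value, or ``linear`` continuation of the end slope).

A complete driver set is a :class:`DriverBundle`.  Bundles round-trip through
a tidy CSV with columns ``year,variable,sex,value,units``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["TrendSeries", "DriverBundle", "read_trends", "write_trends", "REQUIRED_VARIABLES"]

#: variables a bundle must provide (sex-specific or shared)
REQUIRED_VARIABLES = ("mvpa", "ssb", "fv", "upf", "other_kcal", "inflow", "mean_age", "m_base")

_DEFAULT_UNITS = {
    "mvpa": "min/day",
    "ssb": "servings/day",
    "fv": "servings/day",
    "upf": "kcal/day",
    "other_kcal": "kcal/day",
    "inflow": "persons/yr",
    "mean_age": "yr",
    "m_base": "1/yr",
}


@dataclass
class TrendSeries:
    """A named annual driver with interpolation and extrapolation rules."""

    name: str
    years: np.ndarray
    values: np.ndarray
    sex: str | None = None
    units: str = ""
    interp: str = "linear"
    extrap: str = "hold"  # or "linear"

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.size < 2:
            raise ValueError(f"trend {self.name!r}: need at least 2 points")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError(f"trend {self.name!r}: years must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"trend {self.name!r}: values must be finite")
        if self.interp != "linear":
            raise ValueError("only linear interpolation is supported")
        if self.extrap not in ("hold", "linear"):
            raise ValueError("extrap must be 'hold' or 'linear'")

    def value_at(self, year) -> np.ndarray | float:
        """Linear interpolation; beyond the knot range, per ``extrap``."""
        year = np.asarray(year, dtype=float)
        out = np.interp(year, self.years, self.values)
        if self.extrap == "linear":
            y, v = self.years, self.values
            lo_slope = (v[1] - v[0]) / (y[1] - y[0])
            hi_slope = (v[-1] - v[-2]) / (y[-1] - y[-2])
            out = np.where(year < y[0], v[0] + lo_slope * (year - y[0]), out)
            out = np.where(year > y[-1], v[-1] + hi_slope * (year - y[-1]), out)
        return out.item() if out.ndim == 0 else out

    def resampled(self, years) -> "TrendSeries":
        """A copy with knots at exactly the given years."""
        years = np.asarray(years, dtype=float)
        return replace(self, years=years, values=np.asarray(self.value_at(years), dtype=float))

    def copy(self) -> "TrendSeries":
        return replace(self, years=self.years.copy(), values=self.values.copy())


def value_at(series: TrendSeries, year):
    """Functional alias for :meth:`TrendSeries.value_at`."""
    return series.value_at(year)


@dataclass
class DriverBundle:
    """The complete set of driver series, keyed by (variable, sex).

    ``sex`` is ``None`` for shared series.  :meth:`get` falls back to the
    shared series when no sex-specific one exists.
    """

    series: dict = field(default_factory=dict)

    def add(self, s: TrendSeries) -> None:
        key = (s.name, s.sex)
        if key in self.series:
            raise ValueError(f"duplicate series {key}")
        self.series[key] = s

    def get(self, variable: str, sex: str | None = None) -> TrendSeries:
        if (variable, sex) in self.series:
            return self.series[(variable, sex)]
        if (variable, None) in self.series:
            return self.series[(variable, None)]
        raise KeyError(f"missing driver: {variable}" + (f" (sex={sex})" if sex else ""))

    def value(self, variable: str, year, sex: str | None = None):
        return self.get(variable, sex).value_at(year)

    def variables(self) -> set:
        return {name for name, _ in self.series}

    def validate(self) -> None:
        missing = [v for v in REQUIRED_VARIABLES if v not in self.variables()]
        if missing:
            raise ValueError("missing driver: " + ", ".join(missing))

    def copy(self) -> "DriverBundle":
        return DriverBundle({k: s.copy() for k, s in self.series.items()})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (name, sex), s in sorted(self.series.items(), key=lambda kv: (kv[0][0], kv[0][1] or "")):
            for y, v in zip(s.years, s.values):
                rows.append({"year": y, "variable": name, "sex": sex or "", "value": v,
                             "units": s.units, "extrap": s.extrap})
        return pd.DataFrame(rows, columns=["year", "variable", "sex", "value", "units", "extrap"])


def read_trends(path, require_complete: bool = True) -> DriverBundle:
    """Read a driver bundle from a tidy CSV (year,variable,sex,value,units).

    Unknown variables are rejected; duplicate (variable, sex, year) rows are
    rejected with the offending key named.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    needed = {"year", "variable", "sex", "value"}
    if not needed.issubset(df.columns):
        raise ValueError(f"malformed trends file: need columns {sorted(needed)}")
    if "units" not in df.columns:
        df["units"] = ""
    if "extrap" not in df.columns:
        df["extrap"] = "hold"
    df["sex"] = df["sex"].fillna("").astype(str)
    unknown = set(df["variable"]) - set(REQUIRED_VARIABLES)
    if unknown:
        raise ValueError(f"unknown driver variable(s): {sorted(unknown)}")
    if df[["variable", "sex", "year"]].duplicated().any():
        dup = df[df[["variable", "sex", "year"]].duplicated()].iloc[0]
        raise ValueError(
            f"duplicate trend row: ({dup['variable']}, {dup['sex'] or None}, {dup['year']:g})"
        )
    bundle = DriverBundle()
    for (name, sex), grp in df.groupby(["variable", "sex"]):
        grp = grp.sort_values("year")
        extrap = str(grp["extrap"].iloc[0])
        units = str(grp["units"].iloc[0]) if grp["units"].iloc[0] == grp["units"].iloc[0] else ""
        bundle.add(TrendSeries(name=name, sex=sex or None, years=grp["year"].to_numpy(),
                               values=grp["value"].to_numpy(), units=units, extrap=extrap))
    if require_complete:
        bundle.validate()
    return bundle


def write_trends(bundle: DriverBundle, path) -> None:
    """Write a bundle to tidy CSV; inverse of :func:`read_trends`."""
    # %.17g preserves every float64 exactly, so read_trends round-trips
    bundle.to_frame().to_csv(path, index=False, float_format="%.17g")


def bundle_roundtrip_equal(a: DriverBundle, b: DriverBundle) -> bool:
    if set(a.series) != set(b.series):
        return False
    for key, s in a.series.items():
        t = b.series[key]
        if not (np.array_equal(s.years, t.years) and np.allclose(s.values, t.values, rtol=0, atol=0)):
            return False
    return True


def default_units(variable: str) -> str:
    return _DEFAULT_UNITS.get(variable, "")
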