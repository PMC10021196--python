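"""Flat, name-based access to the tunable entries of a ModelParams tree.

Calibration and sensitivity analysis both address parameters by short names
("h_pre_dm", "beta_ob", "bmi_sd_female", "predm_share", ...).  Joint names
(e.g. "bmi_sd", "predm_share") set the same value for both sexes.
"""

from __future__ import annotations

import numpy as np

from .energy import SEXES

__all__ = ["get_param", "set_param", "PARAM_NAMES"]

_FLOW_SCALARS = (
    "h_ng_pre", "h_pre_ng", "h_pre_dm", "beta_ob", "beta_age",
    "rr_ssb", "rr_fv", "rr_mvpa30", "m_base", "hr_pre", "hr_dm",
)
_ENERGY_SCALARS = ("forbes_k", "ssb_kcal_per_serving", "fv_kcal_per_serving", "mvpa_met", "paf")
_ENERGY_PAIRS = ("bmi_sd", "height_cm")
_INIT_PAIRS = ("pop", "dm_share", "predm_share", "weight")


def _pair_target(params, name: str):
    for attr in _ENERGY_PAIRS:
        if name.startswith(attr):
            return params.energy, attr, name[len(attr):]
    for attr in _INIT_PAIRS:
        if name.startswith(attr):
            return params.init, attr, name[len(attr):]
    return None


def get_param(params, name: str) -> float:
    if name in _FLOW_SCALARS:
        return float(getattr(params.flows, name))
    if name in _ENERGY_SCALARS:
        return float(getattr(params.energy, name))
    tgt = _pair_target(params, name)
    if tgt is not None:
        obj, attr, suffix = tgt
        arr = getattr(obj, attr)
        if suffix == "":
            if not np.isclose(arr[0], arr[1]):
                raise ValueError(f"{name!r} is joint but per-sex values differ; "
                                 f"use {name}_female / {name}_male")
            return float(arr[0])
        sex = suffix.lstrip("_")
        if sex in SEXES:
            return float(arr[SEXES.index(sex)])
    raise KeyError(f"unknown parameter name: {name!r}")


def set_param(params, name: str, value: float) -> None:
    """Set parameter ``name`` in-place, re-running the dataclass validation."""
    value = float(value)
    if name in _FLOW_SCALARS:
        setattr(params.flows, name, value)
        params.flows.__post_init__()
        return
    if name in _ENERGY_SCALARS:
        setattr(params.energy, name, value)
        params.energy.__post_init__()
        return
    tgt = _pair_target(params, name)
    if tgt is not None:
        obj, attr, suffix = tgt
        arr = getattr(obj, attr)
        if suffix == "":
            arr[:] = value
        else:
            sex = suffix.lstrip("_")
            if sex not in SEXES:
                raise KeyError(f"unknown parameter name: {name!r}")
            arr[SEXES.index(sex)] = value
        obj.__post_init__()
        return
    raise KeyError(f"unknown parameter name: {name!r}")


PARAM_NAMES = _FLOW_SCALARS + _ENERGY_SCALARS + tuple(
    f"{base}{suffix}" for base in _ENERGY_PAIRS + _INIT_PAIRS
    for suffix in ("", "_female", "_male")
)
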