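"""Glycemic transition hazards and their modifiers.

Three stocks per sex — normoglycemia (NG), prediabetes (preDM) and diabetes
(DM) — are connected by four structural flows plus mortality:

* NG -> preDM: baseline hazard ``h_ng_pre`` scaled by the obesity/ageing
  multiplier,
* preDM -> NG: constant remission hazard ``h_pre_ng``,
* preDM -> DM: baseline hazard ``h_pre_dm`` scaled by the obesity/ageing
  multiplier, the diet/physical-activity relative-risk multiplier and the
  lifestyle-intervention coverage factor,
* all-cause mortality out of each stock (hazard ratios for preDM and DM).

There is no population-level remission from diabetes: no DM-source flow
exists other than mortality.  Demographic inflow enters NG only.

Obesity and ageing enter as reference-normalised power laws,
``(ob/ob_ref)^beta_ob * (age/age_ref)^beta_age`` — equal to one at the
reference (2010) conditions, so the baseline hazards are interpretable as the
reference-year hazards.  Diet and activity enter the preDM->DM hazard through
relative risks on the hazard scale with exponents linear in the exposure
delta from reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .energy import _pair

__all__ = [
    "ReferenceConditions",
    "FlowParams",
    "InterventionCoverage",
    "obesity_age_multiplier",
    "lifestyle_risk_multiplier",
    "dm_onset_hazard",
    "mortality_hazards",
    "glycemic_flow_set",
]


@dataclass
class ReferenceConditions:
    """Exposure levels at which all flow modifiers equal one (2010 defaults)."""

    ssb: float = 0.40        # servings/day
    fv: float = 1.50         # servings/day
    mvpa: float = 60.0       # min/day
    ob_prev: np.ndarray = field(default_factory=lambda: np.array([0.34, 0.17]))
    age_index: float = 38.5  # mean adult age, yr

    def __post_init__(self) -> None:
        self.ob_prev = _pair(self.ob_prev, "ob_prev")
        if self.age_index <= 0 or np.any(self.ob_prev <= 0) or np.any(self.ob_prev >= 1):
            raise ValueError("reference conditions out of range")


@dataclass
class FlowParams:
    """Baseline hazards, effect sizes and mortality parameters.

    Hazards are per year.  ``rr_ssb`` (>1) and ``rr_fv`` (<1) are relative
    risks of diabetes onset per serving/day; ``rr_mvpa30`` (<1) per +30
    min/day of MVPA.  ``m_base`` is the background adult all-cause mortality
    used when no mortality trend series is supplied; ``hr_pre`` and ``hr_dm``
    are mortality hazard ratios for the preDM and DM stocks.
    """

    h_ng_pre: float = 0.020
    h_pre_ng: float = 0.035
    h_pre_dm: float = 0.050
    beta_ob: float = 1.5
    beta_age: float = 1.0
    rr_ssb: float = 1.26
    rr_fv: float = 0.96
    rr_mvpa30: float = 0.85
    m_base: float = 0.010
    hr_pre: float = 1.1
    hr_dm: float = 1.8
    ref: ReferenceConditions = field(default_factory=ReferenceConditions)

    def __post_init__(self) -> None:
        if min(self.h_ng_pre, self.h_pre_ng, self.h_pre_dm, self.m_base) < 0:
            raise ValueError("hazards must be >= 0")
        if self.rr_ssb <= 1:
            raise ValueError("rr_ssb must be > 1")
        if not 0 < self.rr_fv < 1:
            raise ValueError("rr_fv must be in (0, 1)")
        if not 0 < self.rr_mvpa30 < 1:
            raise ValueError("rr_mvpa30 must be in (0, 1)")
        if not self.hr_dm >= self.hr_pre >= 1:
            raise ValueError("mortality hazard ratios must satisfy hr_dm >= hr_pre >= 1")

    def copy(self) -> "FlowParams":
        out = replace(self, ref=replace(self.ref))
        out.ref.ob_prev = self.ref.ob_prev.copy()
        return out


@dataclass
class InterventionCoverage:
    """Coverage-based downstream interventions.

    ``lifestyle_cov`` of the preDM stock receives a lifestyle-modification
    intervention with incidence relative risk ``lifestyle_rr`` (pooled 19%
    incidence reduction by default); ``dsme_cov`` of the DM stock receives
    diabetes self-management education reducing all-cause mortality by
    ``dsme_mort_reduction`` in the covered (pooled 25% by default).
    """

    lifestyle_cov: float = 0.0
    lifestyle_rr: float = 0.81
    dsme_cov: float = 0.0
    dsme_mort_reduction: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.lifestyle_cov <= 1 or not 0 <= self.dsme_cov <= 1:
            raise ValueError("coverages must be in [0, 1]")
        if not 0 < self.lifestyle_rr <= 1:
            raise ValueError("lifestyle_rr must be in (0, 1]")
        if not 0 <= self.dsme_mort_reduction < 1:
            raise ValueError("dsme_mort_reduction must be in [0, 1)")

    @property
    def lifestyle_factor(self) -> float:
        """Multiplier on the preDM->DM hazard: 1 - cov * (1 - rr)."""
        return 1.0 - self.lifestyle_cov * (1.0 - self.lifestyle_rr)

    @property
    def dsme_factor(self) -> float:
        """Multiplier on DM mortality: 1 - cov * reduction."""
        return 1.0 - self.dsme_cov * self.dsme_mort_reduction


#: coverage object with every intervention switched off
NO_COVERAGE = InterventionCoverage()


def obesity_age_multiplier(ob_prev, age_index, params: FlowParams):
    """Reference-normalised power-law multiplier from obesity and ageing."""
    ob_prev = np.asarray(ob_prev, dtype=float)
    if np.any((ob_prev <= 0) | (ob_prev >= 1)) or np.any(np.asarray(age_index) <= 0):
        raise ValueError("ob_prev must be in (0,1) and age_index > 0")
    if params.ref is None:
        raise ValueError("reference conditions unset")
    return (ob_prev / params.ref.ob_prev) ** params.beta_ob * (
        np.asarray(age_index, dtype=float) / params.ref.age_index
    ) ** params.beta_age


def lifestyle_risk_multiplier(ssb, fv, mvpa, params: FlowParams):
    """Diet/physical-activity relative-risk multiplier for diabetes onset.

    rr_ssb^(ssb-ref) * rr_fv^(fv-ref) * rr_mvpa30^((mvpa-ref)/30);
    equals 1 at the reference exposures.  Applied to preDM->DM only.
    """
    if np.any(np.asarray(ssb) < 0) or np.any(np.asarray(fv) < 0) or np.any(np.asarray(mvpa) < 0):
        raise ValueError("exposures must be >= 0")
    r = params.ref
    return (
        params.rr_ssb ** (np.asarray(ssb, dtype=float) - r.ssb)
        * params.rr_fv ** (np.asarray(fv, dtype=float) - r.fv)
        * params.rr_mvpa30 ** ((np.asarray(mvpa, dtype=float) - r.mvpa) / 30.0)
    )


def dm_onset_hazard(ob_prev, age_index, ssb, fv, mvpa, params: FlowParams,
                    cov: InterventionCoverage = NO_COVERAGE):
    """Effective preDM -> DM hazard (1/yr)."""
    return (
        params.h_pre_dm
        * obesity_age_multiplier(ob_prev, age_index, params)
        * lifestyle_risk_multiplier(ssb, fv, mvpa, params)
        * cov.lifestyle_factor
    )


def mortality_hazards(params: FlowParams, cov: InterventionCoverage = NO_COVERAGE,
                      m_base: float | None = None) -> dict:
    """Per-stock all-cause mortality hazards (1/yr)."""
    m = params.m_base if m_base is None else float(m_base)
    return {
        "ng": m,
        "predm": m * params.hr_pre,
        "dm": m * params.hr_dm * cov.dsme_factor,
    }


def glycemic_flow_set(ng, predm, dm, ob_prev, age_index, ssb, fv, mvpa,
                      params: FlowParams, cov: InterventionCoverage = NO_COVERAGE,
                      m_base: float | None = None) -> dict:
    """All glycemic flows (persons/yr) for the given per-sex stocks.

    Returns a dict with keys ``ng_to_pre``, ``pre_to_ng``, ``pre_to_dm``,
    ``deaths_ng``, ``deaths_pre``, ``deaths_dm``.  Structurally, no flow has
    DM as a source except mortality, and demographic inflow (handled by the
    integrator) enters NG only.
    """
    ng = np.asarray(ng, dtype=float)
    predm = np.asarray(predm, dtype=float)
    dm = np.asarray(dm, dtype=float)
    mult = obesity_age_multiplier(ob_prev, age_index, params)
    mort = mortality_hazards(params, cov, m_base)
    return {
        "ng_to_pre": params.h_ng_pre * mult * ng,
        "pre_to_ng": params.h_pre_ng * predm,
        "pre_to_dm": dm_onset_hazard(ob_prev, age_index, ssb, fv, mvpa, params, cov) * predm,
        "deaths_ng": mort["ng"] * ng,
        "deaths_pre": mort["predm"] * predm,
        "deaths_dm": mort["dm"] * dm,
    }
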