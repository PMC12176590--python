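"""Cost accounting: drug acquisition, adverse events, hospitalization,
post-progression care, and the tiered patient-assistance schedule.

Costing conventions
-------------------
* Doses are per administration, either flat (mg) or scaled by body surface
  area (mg/m2); partial vials are billed as whole vials per administration
  day (no vial sharing).
* First-line drug cost accrues while progression-free, weighted by PFS
  occupancy, up to each component's ``max_cycles`` (treatment-duration cap
  from the trial protocol: chemotherapy backbone 6 cycles, the PD-L1
  antibody 24 months).
* Adverse-event management costs are one-off at model entry (incidence x
  unit cost), undiscounted.
* Hospitalization accrues in every alive cycle; second-line (post
  progression) cost accrues in every progressed cycle until death.
* Under the assistance program, the antibody is paid only in cycles the tier
  schedule marks as purchased; beyond the last tier the drug is free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import EconParams, OccupancyTrace, cycle_weights

__all__ = [
    "PatientProfile",
    "RegimenComponent",
    "RegimenSpec",
    "AdverseEvent",
    "CostInputs",
    "PAPSchedule",
    "vials_needed",
    "cycle_drug_cost",
    "ae_cost_oneoff",
    "pap_paid",
    "arm_discounted_cost",
]


@dataclass(frozen=True)
class PatientProfile:
    """Reference patient used for dose arithmetic."""

    weight_kg: float = 65.0
    bsa_m2: float = 1.72

    def __post_init__(self):
        if self.weight_kg <= 0 or self.bsa_m2 <= 0:
            raise ValueError("weight and body surface area must be positive")


@dataclass(frozen=True)
class RegimenComponent:
    """One drug in a regimen, with its dosing and billing structure."""

    name: str
    dose_mg: float                     # per administration, before basis scaling
    basis: str = "flat"                # "flat" or "per_m2"
    administrations_per_cycle: int = 1
    vial_mg: float = 1.0
    vial_price: float = 0.0            # USD per vial
    max_cycles: int | None = None      # treatment-duration cap, cycles
    pap_eligible: bool = False         # gated by the assistance schedule

    def __post_init__(self):
        if self.dose_mg < 0 or self.vial_mg <= 0 or self.vial_price < 0:
            raise ValueError(f"invalid dosing/pricing for {self.name}")
        if self.basis not in ("flat", "per_m2"):
            raise ValueError(f"unknown dose basis {self.basis!r}")

    def administered_dose(self, profile: PatientProfile) -> float:
        return self.dose_mg * (profile.bsa_m2 if self.basis == "per_m2" else 1.0)

    def cost_per_cycle(self, profile: PatientProfile, vial_price: float | None = None) -> float:
        price = self.vial_price if vial_price is None else vial_price
        dose = self.administered_dose(profile)
        return vials_needed(dose, self.vial_mg) * self.administrations_per_cycle * price


@dataclass(frozen=True)
class RegimenSpec:
    """A treatment arm's first-line regimen (applies while progression-free)."""

    components: tuple

    def cycle_cost(self, profile: PatientProfile) -> float:
        return sum(c.cost_per_cycle(profile) for c in self.components)


@dataclass(frozen=True)
class AdverseEvent:
    name: str
    incidence: float
    unit_cost: float

    def __post_init__(self):
        if not 0 <= self.incidence <= 1:
            raise ValueError(f"AE incidence for {self.name} must lie in [0, 1]")
        if self.unit_cost < 0:
            raise ValueError(f"AE cost for {self.name} must be >= 0")


@dataclass(frozen=True)
class CostInputs:
    """Non-drug cost structure for one arm."""

    post_progression_per_cycle: float = 753.49
    hospitalization_per_cycle: float = 142.10
    adverse_events: tuple = ()

    def __post_init__(self):
        if self.post_progression_per_cycle < 0 or self.hospitalization_per_cycle < 0:
            raise ValueError("costs must be nonnegative")


@dataclass(frozen=True)
class PAPSchedule:
    """Alternating purchased/free cycle tiers of a patient assistance program."""

    tiers: tuple = ((2, 2), (2, 25), (1, 3))

    def __post_init__(self):
        for paid, free in self.tiers:
            if paid < 0 or free < 0 or paid != int(paid) or free != int(free):
                raise ValueError("PAP tiers must be nonnegative integers")


def vials_needed(dose_mg: float, vial_mg: float) -> int:
    """Whole vials billed for one administration day; zero dose needs none."""
    if dose_mg < 0 or vial_mg <= 0:
        raise ValueError("dose must be >= 0 and vial size > 0")
    if dose_mg == 0:
        return 0
    return math.ceil(dose_mg / vial_mg - 1e-12)


def cycle_drug_cost(regimen: RegimenSpec, profile: PatientProfile) -> float:
    """Uncapped per-cycle acquisition cost of a regimen for the profile."""
    return regimen.cycle_cost(profile)


def ae_cost_oneoff(adverse_events) -> float:
    """Expected one-off adverse-event management cost at model entry."""
    return float(sum(ae.incidence * ae.unit_cost for ae in adverse_events))


def pap_paid(schedule: PAPSchedule, cycle: int) -> bool:
    """Whether the antibody is purchased in 1-based treatment ``cycle``.

    Walks the tiers in order (paid block, then free block); cycles beyond the
    final tier are free.
    """
    if cycle < 1:
        raise ValueError("cycle index is 1-based")
    c = cycle
    for paid, free in schedule.tiers:
        if c <= paid:
            return True
        c -= paid
        if c <= free:
            return False
        c -= free
    return False


def _paid_mask(schedule: PAPSchedule | None, n_cycles: int) -> np.ndarray:
    if schedule is None:
        return np.ones(n_cycles, dtype=bool)
    return np.array([pap_paid(schedule, i) for i in range(1, n_cycles + 1)])


def arm_discounted_cost(
    trace: OccupancyTrace,
    regimen: RegimenSpec,
    costs: CostInputs,
    econ: EconParams,
    profile: PatientProfile | None = None,
    pap: PAPSchedule | None = None,
    convention: str = "start",
    price_overrides: dict | None = None,
    return_ledger: bool = False,
):
    """Total discounted cost for one arm over the model horizon.

    Per cycle: occupancy-weighted drug cost (capped per component, gated by
    the assistance schedule where eligible), hospitalization for alive
    cycles, and post-progression cost for progressed cycles — all discounted
    under the chosen accumulation convention — plus the one-off AE cost at
    entry. ``price_overrides`` maps component name to replacement vial price
    (used by sensitivity and price-cap analyses). With ``return_ledger`` the
    per-cycle cost breakdown is returned as a second value.
    """
    profile = profile or PatientProfile()
    n = trace.n_cycles
    w_pfs, w_pd, disc = cycle_weights(trace, econ, convention)
    cyc = np.arange(1, n + 1)
    paid = _paid_mask(pap, n)

    drug = np.zeros(n)
    for comp in regimen.components:
        price = None if price_overrides is None else price_overrides.get(comp.name)
        per_cycle = comp.cost_per_cycle(profile, vial_price=price)
        active = np.ones(n, dtype=bool) if comp.max_cycles is None else (cyc <= comp.max_cycles)
        if comp.pap_eligible:
            active = active & paid
        drug += per_cycle * active

    drug_cost = drug * w_pfs * disc
    hosp_cost = costs.hospitalization_per_cycle * (w_pfs + w_pd) * disc
    pd_cost = costs.post_progression_per_cycle * w_pd * disc
    ae = ae_cost_oneoff(costs.adverse_events)
    total = float(drug_cost.sum() + hosp_cost.sum() + pd_cost.sum() + ae)
    if not return_ledger:
        return total
    ledger = pd.DataFrame(
        {"cycle": cyc, "drug": drug_cost, "hospitalization": hosp_cost,
         "post_progression": pd_cost, "discount": disc}
    )
    return total, ledger
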