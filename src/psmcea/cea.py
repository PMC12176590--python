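"""Two-arm cost-effectiveness comparisons, net monetary benefit, and the
price-threshold search.

The central object is :class:`PartitionedSurvivalCEA`, a model in the
statsmodels mold: construct it from a validated config and a scenario label
(``from_config``), call :meth:`~PartitionedSurvivalCEA.fit` for a
:class:`CEAResults` carrying per-arm costs/QALYs, increments, the ICER and a
``summary()`` table. Sensitivity analyses (`owsa`, `psa` in
:mod:`psmcea.sensitivity`) and the price-cap bisection hang off the model,
re-evaluating it under parameter overrides.

Override keys understood by ``fit(overrides=...)``:

``price.<component>``, ``cost.post_progression``, ``cost.hospitalization``,
``ae_cost.<event>``, ``ae_risk.<arm>.<event>``, ``utility.pfs``,
``utility.pd``, ``econ.discount_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .config import ModelConfig
from .costing import AdverseEvent, CostInputs, arm_discounted_cost
from .engine import (
    EconParams,
    UtilitySet,
    discounted_life_years,
    discounted_qalys,
    occupancy_trace,
)

__all__ = [
    "ArmResult",
    "CEAResult",
    "CEAResults",
    "PartitionedSurvivalCEA",
    "run_arm",
    "icer",
    "nmb",
    "price_threshold",
    "run_all",
]


@dataclass(frozen=True)
class ArmResult:
    """Discounted totals for one treatment arm."""

    arm: str
    cost: float
    qalys: float
    life_years: float
    clamp_count: int = 0


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of an experimental arm against control."""

    incremental_cost: float
    incremental_qalys: float
    icer: float | None
    label: str  # "icer", "dominant", "dominated", "equivalent"


def icer(exp: ArmResult, ctrl: ArmResult) -> CEAResult:
    """Incremental cost-effectiveness ratio with dominance labelling."""
    dc = exp.cost - ctrl.cost
    dq = exp.qalys - ctrl.qalys
    if dq == 0:
        return CEAResult(dc, dq, None, "equivalent" if dc == 0 else "no_qaly_gain")
    if dq > 0 and dc < 0:
        return CEAResult(dc, dq, dc / dq, "dominant")
    if dq < 0 and dc >= 0:
        return CEAResult(dc, dq, dc / dq, "dominated")
    return CEAResult(dc, dq, dc / dq, "icer")


def nmb(exp: ArmResult, ctrl: ArmResult, wtp: float) -> float:
    """Incremental net monetary benefit wtp*dQALY - dCost."""
    return wtp * (exp.qalys - ctrl.qalys) - (exp.cost - ctrl.cost)


class PartitionedSurvivalCEA:
    """Partitioned-survival cost-effectiveness model for one scenario.

    Parameters come in as a validated :class:`~psmcea.config.ModelConfig`
    plus a scenario label; occupancy traces are computed once per arm at
    construction (survival parameters are fixed inputs, not resampled), so
    repeated evaluation under overrides is cheap.
    """

    def __init__(self, config: ModelConfig, scenario: str, convention: str = "start"):
        if scenario not in config.scenarios:
            raise KeyError(f"unknown scenario {scenario!r}; have {list(config.scenarios)}")
        self.config = config
        self.scenario = scenario
        self.convention = convention
        self.econ = config.econ_params()
        self.arms = list(config.arms)
        self.control_arm = config.control_arm
        self.pap = config.pap_schedule() if config.scenarios[scenario].pap else None
        self._traces = {}
        for arm in self.arms:
            pfs = config.survival_model(scenario, arm, "pfs")
            osm = config.survival_model(scenario, arm, "os")
            self._traces[arm] = occupancy_trace(pfs, osm, self.econ)

    # alias constructor, statsmodels-style
    @classmethod
    def from_config(cls, config: ModelConfig, scenario: str = "whole", **kw):
        return cls(config, scenario, **kw)

    # ------------------------------------------------------------------
    def _resolved_inputs(self, overrides: dict | None):
        ov = overrides or {}
        econ = self.econ
        if "econ.discount_rate" in ov:
            econ = replace(econ, discount_rate=float(ov["econ.discount_rate"]))
        u = self.config.utility_set()
        u_pfs = float(ov.get("utility.pfs", u.u_pfs))
        u_pd = float(ov.get("utility.pd", u.u_pd))
        # sensitivity draws may momentarily invert the ordering; accumulate
        # with the raw values rather than rejecting the draw
        utilities = SimpleNamespace(u_pfs=u_pfs, u_pd=u_pd)
        price_overrides = {
            k.split(".", 1)[1]: float(v) for k, v in ov.items() if k.startswith("price.")
        }
        cost_inputs = {}
        for arm in self.arms:
            ci = self.config.cost_inputs(arm)
            pp = float(ov.get("cost.post_progression", ci.post_progression_per_cycle))
            hosp = float(ov.get("cost.hospitalization", ci.hospitalization_per_cycle))
            aes = []
            for ae in ci.adverse_events:
                cost = float(ov.get(f"ae_cost.{ae.name}", ae.unit_cost))
                inc = float(ov.get(f"ae_risk.{arm}.{ae.name}", ae.incidence))
                aes.append(AdverseEvent(ae.name, min(max(inc, 0.0), 1.0), cost))
            cost_inputs[arm] = CostInputs(pp, hosp, tuple(aes))
        return econ, utilities, price_overrides, cost_inputs

    def run_arm(self, arm: str, overrides: dict | None = None) -> ArmResult:
        """Evaluate one arm: occupancy -> discounted QALYs, LYs and cost."""
        econ, utilities, price_ov, cost_inputs = self._resolved_inputs(overrides)
        trace = self._traces[arm]
        q = discounted_qalys(trace, utilities, econ, self.convention)
        ly = discounted_life_years(trace, econ, self.convention)
        cost = arm_discounted_cost(
            trace,
            self.config.regimen(arm),
            cost_inputs[arm],
            econ,
            profile=self.config.patient_profile(),
            pap=self.pap,
            convention=self.convention,
            price_overrides=price_ov or None,
        )
        return ArmResult(arm, cost, q, ly, trace.clamp_count)

    def fit(self, overrides: dict | None = None) -> "CEAResults":
        """Deterministic base-case evaluation of every arm plus increments."""
        arm_results = {arm: self.run_arm(arm, overrides) for arm in self.arms}
        ctrl = arm_results[self.control_arm]
        incs = {
            arm: icer(res, ctrl)
            for arm, res in arm_results.items()
            if arm != self.control_arm
        }
        return CEAResults(self, arm_results, incs)

    # ------------------------------------------------------------------
    def price_threshold(
        self,
        component: str = "sugemalimab",
        wtp: float | None = None,
        bounds: tuple = (0.0, None),
        tol: float = 0.01,
        max_iter: int = 60,
    ) -> dict:
        """Bisect the component's vial price until the ICER meets the WTP.

        Returns a dict with the threshold price, the percent reduction from
        the configured base price, the re-plugged ICER, and a ``verdict``:
        ``"threshold"`` when bracketed, ``"already_cost_effective"`` /
        ``"never_cost_effective"`` at the boundaries.
        """
        wtp = self.econ.wtp if wtp is None else wtp
        base_price = None
        for arm in self.arms:
            for comp in self.config.regimen(arm).components:
                if comp.name == component:
                    base_price = comp.vial_price
        if base_price is None:
            raise KeyError(f"component {component!r} not found in any regimen")
        lo, hi = bounds[0], bounds[1] if bounds[1] is not None else base_price

        def icer_at(price: float) -> float:
            res = self.fit({f"price.{component}": price})
            inc = res.incremental
            return -np.inf if inc.icer is None else inc.icer

        if icer_at(hi) <= wtp:
            return {"price": hi, "reduction_pct": 100 * (1 - hi / base_price),
                    "icer": icer_at(hi), "wtp": wtp, "verdict": "already_cost_effective"}
        if icer_at(lo) > wtp:
            return {"price": lo, "reduction_pct": 100 * (1 - lo / base_price),
                    "icer": icer_at(lo), "wtp": wtp, "verdict": "never_cost_effective"}
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            if icer_at(mid) > wtp:
                hi = mid
            else:
                lo = mid
            if hi - lo < tol:
                break
        price = 0.5 * (lo + hi)
        return {
            "price": price,
            "reduction_pct": 100 * (1 - price / base_price),
            "icer": icer_at(price),
            "wtp": wtp,
            "verdict": "threshold",
        }


class CEAResults:
    """Results of a two-arm partitioned-survival evaluation."""

    def __init__(self, model: PartitionedSurvivalCEA, arm_results: dict, incrementals: dict):
        self.model = model
        self.arm_results = arm_results
        self.incrementals = incrementals

    @property
    def incremental(self) -> CEAResult:
        (res,) = self.incrementals.values()
        return res

    @property
    def icer(self) -> float | None:
        return self.incremental.icer

    def nmb(self, wtp: float | None = None) -> float:
        wtp = self.model.econ.wtp if wtp is None else wtp
        exp = next(a for a in self.model.arms if a != self.model.control_arm)
        return nmb(self.arm_results[exp], self.arm_results[self.model.control_arm], wtp)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm, res in self.arm_results.items():
            inc = self.incrementals.get(arm)
            rows.append(
                {
                    "scenario": self.model.scenario,
                    "arm": arm,
                    "cost": res.cost,
                    "qalys": res.qalys,
                    "life_years": res.life_years,
                    "incremental_cost": inc.incremental_cost if inc else np.nan,
                    "incremental_qalys": inc.incremental_qalys if inc else np.nan,
                    "icer": (inc.icer if inc and inc.icer is not None else np.nan),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            f"Partitioned-survival CEA — scenario '{self.model.scenario}' "
            f"(WTP ${self.model.econ.wtp:,.2f}/QALY)",
            f"{'arm':<22}{'cost ($)':>14}{'QALYs':>9}{'dCost ($)':>14}{'dQALYs':>9}{'ICER ($/QALY)':>16}",
        ]
        for _, r in df.iterrows():
            ic = f"{r['icer']:,.2f}" if np.isfinite(r["icer"]) else "—"
            dc = f"{r['incremental_cost']:,.2f}" if np.isfinite(r["incremental_cost"]) else "—"
            dq = f"{r['incremental_qalys']:.3f}" if np.isfinite(r["incremental_qalys"]) else "—"
            lines.append(
                f"{r['arm']:<22}{r['cost']:>14,.2f}{r['qalys']:>9.3f}{dc:>14}{dq:>9}{ic:>16}"
            )
        return "\n".join(lines)


def run_arm(config: ModelConfig, scenario: str, arm: str, **kw) -> ArmResult:
    """Convenience wrapper: evaluate a single arm of a scenario."""
    return PartitionedSurvivalCEA(config, scenario, **kw).run_arm(arm)


def price_threshold(config: ModelConfig, scenario: str, **kw) -> dict:
    return PartitionedSurvivalCEA(config, scenario).price_threshold(**kw)


def run_all(config: ModelConfig, scenarios=None, convention: str = "start") -> pd.DataFrame:
    """Evaluate every configured scenario; one comparison table to rule them all."""
    labels = list(config.scenarios) if scenarios is None else list(scenarios)
    frames = [
        PartitionedSurvivalCEA(config, label, convention=convention).fit().to_frame()
        for label in labels
    ]
    if not frames:
        return pd.DataFrame(
            columns=["scenario", "arm", "cost", "qalys", "life_years",
                     "incremental_cost", "incremental_qalys", "icer"]
        )
    return pd.concat(frames, ignore_index=True)
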