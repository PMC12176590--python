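"""Product-limit estimation and pseudo-IPD reconstruction from digitized curves.

Published Kaplan–Meier plots, together with their numbers-at-risk tables, can
be inverted back into an individual-patient dataset that reproduces the
printed curve (Guyot-type reconstruction). This module provides that
inversion plus the product-limit estimator used to verify it. Digitized
coordinates are treated as exact inputs; pixel extraction from images is out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = ["KMCurve", "RiskTable", "km_estimate", "reconstruct_ipd"]


@dataclass(frozen=True)
class KMCurve:
    """A step survival curve: times ascending from 0, surv starting at 1."""

    times: np.ndarray
    surv: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.surv, dtype=float)
        if t.size != s.size or t.size == 0:
            raise ValueError("times and surv must be nonempty and equal length")
        if t[0] != 0 or s[0] != 1:
            t = np.concatenate([[0.0], t])
            s = np.concatenate([[1.0], s])
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly ascending")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("surv must be nonincreasing")
        if s.min() < -1e-12 or s.max() > 1 + 1e-12:
            raise ValueError("surv must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "surv", np.clip(s, 0.0, 1.0))

    def at(self, t):
        """Step-function evaluation S(t) (right-continuous)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        return self.surv[np.clip(idx, 0, len(self.surv) - 1)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "surv": self.surv})


@dataclass(frozen=True)
class RiskTable:
    """Numbers at risk at ascending landmark times."""

    times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_at_risk, dtype=int)
        if t.size != n.size or t.size == 0:
            raise ValueError("times and n_at_risk must be nonempty and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("risk-table times must be strictly ascending")
        if np.any(n < 0) or np.any(np.diff(n) > 0):
            raise ValueError("n_at_risk must be nonnegative and nonincreasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_at_risk", n)


def km_estimate(ipd) -> KMCurve:
    """Product-limit (Kaplan–Meier) estimate from IPD records.

    ``ipd`` is a DataFrame with ``time`` and ``event`` columns (the IPD CSV
    dialect); censored times reduce the risk set only.
    """
    df = ipd if isinstance(ipd, pd.DataFrame) else pd.DataFrame(ipd)
    if len(df) == 0:
        raise ValueError("km_estimate requires at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"])
    sf = kmf.survival_function_
    return KMCurve(sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float))


def _as_curve(curve) -> KMCurve:
    if isinstance(curve, KMCurve):
        return curve
    if isinstance(curve, pd.DataFrame):
        return KMCurve(curve["time"].to_numpy(), curve["surv"].to_numpy())
    times, surv = curve
    return KMCurve(np.asarray(times), np.asarray(surv))


def reconstruct_ipd(
    curve,
    risk: RiskTable | None = None,
    total_events: int | None = None,
    arm: str = "arm",
    endpoint: str = "OS",
    subgroup: str = "whole",
) -> pd.DataFrame:
    """Reconstruct pseudo-IPD from a digitized KM curve and numbers at risk.

    Implements the interval-wise inversion: within each risk-table interval,
    integer censoring counts are chosen (spread uniformly over the interval,
    the standard assumption) so that the product-limit estimate of the output
    matches the input curve steps and the reported numbers at risk. Event
    counts at each curve step are rounded with cumulative-error carrying so
    rounding never drifts. Output has ``n_at_risk[0]`` records.

    Without a risk table, no within-follow-up censoring is assumed (aside
    from ``total_events`` balancing at the end of follow-up).
    """
    km = _as_curve(curve)
    if risk is None:
        n0 = total_events if total_events is not None else 1000
        # flat curve with no events: everyone administratively censored
        risk = RiskTable(np.array([0.0]), np.array([max(n0, 1)]))
        if total_events is None and km.surv[-1] < 1.0:
            raise ValueError("reconstruction without a risk table needs total_events")
    if risk.n_at_risk[0] <= 0:
        raise ValueError("initial number at risk must be positive")
    t_end = km.times[-1]
    bounds = np.concatenate([risk.times, [np.inf]])

    events: list[float] = []
    censors: list[float] = []
    n_hat = float(risk.n_at_risk[0])
    s_prev = 1.0
    carry = 0.0  # cumulative-error carrying for event rounding

    # Pre-split curve indices by risk interval (drop the t=0 anchor point).
    step_times = km.times[1:]
    step_surv = km.surv[1:]

    for i in range(len(risk.times)):
        lo, hi = bounds[i], bounds[i + 1]
        in_iv = (step_times >= lo) & (step_times < hi)
        tt, ss = step_times[in_iv], step_surv[in_iv]
        target_next = float(risk.n_at_risk[i + 1]) if i + 1 < len(risk.times) else None

        # choose integer censor count for this interval by matching the next
        # reported number at risk; search a small window around the first guess
        def run_interval(n_cen: int, commit: bool = False):
            nonlocal n_hat, s_prev, carry
            nh, sp, cy = n_hat, s_prev, carry
            ev_i, cen_i = [], []
            cen_times = (
                np.linspace(lo, hi if np.isfinite(hi) else t_end, n_cen + 2)[1:-1]
                if n_cen > 0
                else np.array([])
            )
            k_c = 0
            for t_k, s_k in zip(tt, ss):
                # censors strictly before this event time reduce the risk set
                c_here = 0
                while k_c < len(cen_times) and cen_times[k_c] < t_k:
                    cen_i.append((cen_times[k_c], 1))
                    c_here += 1
                    k_c += 1
                if c_here:
                    nh -= c_here
                if sp <= 0 or nh <= 0:
                    d = 0.0
                else:
                    d_exact = nh * (1.0 - s_k / sp) + cy
                    d = np.round(d_exact)
                    cy = d_exact - d
                d = float(np.clip(d, 0, nh))
                if d > 0:
                    sp = sp * (1.0 - d / nh) if nh > 0 else 0.0
                    nh -= d
                    ev_i.append((t_k, d))
                else:
                    sp = sp if nh > 0 else sp
            # censors after the last event in the interval
            while k_c < len(cen_times):
                cen_i.append((cen_times[k_c], 1))
                nh -= 1
                k_c += 1
            if commit:
                n_hat, s_prev, carry = nh, sp, cy
                return ev_i, cen_i
            return nh

        if target_next is None:
            n_cen_best = 0
        else:
            s_lo = s_prev
            s_hi = float(ss[-1]) if len(ss) else s_prev
            guess = int(round(n_hat - target_next - n_hat * (1 - s_hi / s_lo))) if s_lo > 0 else 0
            guess = max(guess, 0)
            best, n_cen_best = None, 0
            for n_cen in range(max(0, guess - 4), guess + 5):
                if n_cen > n_hat:
                    break
                nh_end = run_interval(n_cen)
                err = abs(nh_end - target_next)
                if best is None or err < best:
                    best, n_cen_best = err, n_cen
                if err == 0:
                    break
        ev_i, cen_i = run_interval(n_cen_best, commit=True)
        events.extend(ev_i)
        censors.extend(cen_i)

    # distribute remaining subjects
    n_events_so_far = int(round(sum(d for _, d in events)))
    remaining = int(risk.n_at_risk[0]) - n_events_so_far - int(sum(c for _, c in censors))
    if remaining < 0:
        raise ValueError(
            f"infeasible reconstruction: allocated {-remaining} more records than at risk"
        )
    if total_events is not None and n_events_so_far < total_events and remaining > 0:
        extra = min(total_events - n_events_so_far, remaining)
        events.append((t_end, float(extra)))
        remaining -= extra
    if remaining > 0:
        censors.append((t_end, remaining))

    rows = []
    for t, d in events:
        rows.extend([(t, 1)] * int(round(d)))
    for t, c in censors:
        rows.extend([(t, 0)] * int(round(c)))
    out = pd.DataFrame(rows, columns=["time", "event"]).sort_values(
        ["time", "event"], kind="stable", ignore_index=True
    )
    out["time"] = out["time"].clip(lower=1e-9)
    out["arm"] = arm
    out["endpoint"] = endpoint
    out["subgroup"] = subgroup
    return out
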