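"""Synthetic trial-like data: endpoint-level IPD, KM coordinates, risk tables.

Emulates the inputs of a two-arm randomized trial the way the economic model
consumes them: per arm and endpoint, event times are drawn by inverse-CDF
from a parametric truth model, then right-censored at the minimum of an
administrative cutoff and an independent uniform dropout time. PFS and OS
cohorts are drawn independently (endpoint-level simulation): the partitioned
survival model only uses marginal curves, so patient-level PFS<=OS coupling
is deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .km import KMCurve, RiskTable
from .survival import ParametricSurvival

__all__ = ["EndpointTruth", "TrialSimSpec", "simulate_ipd", "risk_table_at", "digitize_curve"]


@dataclass(frozen=True)
class EndpointTruth:
    """Truth model for one arm x endpoint cell of the trial."""

    arm: str
    endpoint: str
    model: ParametricSurvival
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n per arm must be >= 1")


@dataclass(frozen=True)
class TrialSimSpec:
    """Simulation design: truth models, sample sizes, censoring, seed.

    ``cutoff`` is the administrative censoring time in cycles;
    ``dropout_rate`` is the probability of random early dropout, with the
    dropout time uniform on (0, cutoff).
    """

    cells: tuple
    cutoff: float = 35.0
    dropout_rate: float = 0.05
    seed: int = 0
    subgroup: str = "whole"

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")


def simulate_ipd(spec: TrialSimSpec) -> pd.DataFrame:
    """Draw IPD for every cell of the spec; reproducible under the seed."""
    rng = np.random.default_rng(spec.seed)
    frames = []
    for cell in spec.cells:
        u = rng.uniform(size=cell.n)
        t_event = np.maximum(cell.model.ppf(u), 1e-9)
        cens = np.full(cell.n, spec.cutoff)
        if spec.dropout_rate > 0:
            drop = rng.uniform(size=cell.n) < spec.dropout_rate
            t_drop = rng.uniform(0, spec.cutoff, size=cell.n)
            cens = np.where(drop, np.minimum(t_drop, cens), cens)
        time = np.minimum(t_event, cens)
        event = (t_event <= cens).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "time": np.maximum(time, 1e-9),
                    "event": event,
                    "arm": cell.arm,
                    "endpoint": cell.endpoint,
                    "subgroup": spec.subgroup,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def risk_table_at(ipd: pd.DataFrame, times) -> RiskTable:
    """Numbers at risk at the given ascending landmark times."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return RiskTable(np.array([0.0]), np.array([len(ipd)]))
    t = ipd["time"].to_numpy()
    n = np.array([(t >= tt).sum() for tt in times], dtype=int)
    return RiskTable(times, n)


def digitize_curve(curve: KMCurve, n_points: int = 200, jitter: float = 0.0,
                   rng: np.random.Generator | None = None) -> KMCurve:
    """Resample a KM curve on a regular grid, optionally adding digitization noise.

    Mimics manual curve extraction from a published figure: the step function
    is read off at ``n_points`` evenly spaced abscissae; ``jitter`` adds
    truncated vertical noise (monotonicity restored by a cumulative minimum).
    """
    grid = np.linspace(0, curve.times[-1], n_points)
    surv = curve.at(grid).astype(float).copy()
    if jitter > 0:
        rng = rng or np.random.default_rng(0)
        surv = np.clip(surv + rng.normal(0, jitter, surv.shape), 0, 1)
        surv[0] = 1.0
        surv = np.minimum.accumulate(surv)
    # collapse duplicate abscissae introduced by the grid
    return KMCurve(grid, surv)
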