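"""One-way and probabilistic sensitivity analysis, CEAC, tornado tables.

Parameter uncertainty follows the usual decision-model conventions: each
parameter carries a (base, low, high) range read as a 95% interval, so
SE = (high - low)/3.92; gamma distributions (method-of-moments) for costs
and beta for utilities, probabilities and the discount rate. Draws are
mean-preserving by construction, so the PSA cloud centres on the base case.

Survival-curve parameters are fixed inputs and are not resampled — the
published ranges cover only cost/utility/incidence parameters. The PSA
therefore understates total decision uncertainty; see the methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import PartitionedSurvivalCEA
from .config import DistributionSchema, ModelConfig

__all__ = [
    "ParamDistribution",
    "TornadoRow",
    "PSAResult",
    "sample_param",
    "owsa",
    "run_psa",
    "ceac",
]


@dataclass(frozen=True)
class ParamDistribution:
    """Sampling spec for one parameter: range plus distribution family."""

    name: str
    base: float
    low: float
    high: float
    family: str  # "gamma" | "beta"
    role: str = "cost"

    def __post_init__(self):
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: require low <= base <= high")
        if self.family not in ("gamma", "beta"):
            raise ValueError(f"{self.name}: unknown family {self.family!r}")

    @property
    def se(self) -> float:
        return (self.high - self.low) / 3.92


def _dists_from_config(config: ModelConfig) -> list[ParamDistribution]:
    return [
        ParamDistribution(d.name, d.base, d.low, d.high, d.family, d.role)
        for d in config.distributions
    ]


def _as_dist(d) -> ParamDistribution:
    if isinstance(d, ParamDistribution):
        return d
    if isinstance(d, DistributionSchema):
        return ParamDistribution(d.name, d.base, d.low, d.high, d.family, d.role)
    return ParamDistribution(**d)


def sample_param(dist: ParamDistribution, rng: np.random.Generator, size=None):
    """Method-of-moments draw(s) from the parameter's distribution.

    Gamma: shape = base^2/SE^2, scale = SE^2/base. Beta: alpha/beta solved
    from mean = base and the same SE. A zero SE (degenerate range) returns
    the base value.
    """
    dist = _as_dist(dist)
    se = dist.se
    if se == 0 or dist.base == 0:
        shape = () if size is None else size
        return np.broadcast_to(np.float64(dist.base), shape).copy() if size else dist.base
    if dist.family == "gamma":
        shape = dist.base**2 / se**2
        scale = se**2 / dist.base
        return rng.gamma(shape, scale, size=size)
    m, v = dist.base, se**2
    if not 0 < m < 1:
        raise ValueError(f"{dist.name}: beta requires base in (0, 1), got {m}")
    if v >= m * (1 - m):
        raise ValueError(f"{dist.name}: beta moments infeasible (SE too large)")
    nu = m * (1 - m) / v - 1.0
    return rng.beta(m * nu, (1 - m) * nu, size=size)


@dataclass(frozen=True)
class TornadoRow:
    name: str
    icer_low: float
    icer_high: float
    base_icer: float

    @property
    def span(self) -> float:
        return abs(self.icer_high - self.icer_low)


def owsa(model: PartitionedSurvivalCEA, distributions=None) -> pd.DataFrame:
    """One-way sensitivity: ICER at each parameter's low and high bound.

    Every other parameter stays at base. Returns a tornado-ready table
    sorted by span, descending. Parameters without a configured range would
    default to +/-20% around base, but the shipped config ranges every
    parameter explicitly.
    """
    dists = _dists_from_config(model.config) if distributions is None else [
        _as_dist(d) for d in distributions
    ]
    base = model.fit().incremental.icer
    rows = []
    for d in dists:
        lo, hi = d.low, d.high
        if lo == hi == d.base:
            lo, hi = 0.8 * d.base, 1.2 * d.base
        r_lo = model.fit({d.name: lo}).incremental
        r_hi = model.fit({d.name: hi}).incremental
        rows.append(TornadoRow(d.name, r_lo.icer, r_hi.icer, base))
    df = pd.DataFrame(
        [
            {"name": r.name, "icer_low": r.icer_low, "icer_high": r.icer_high,
             "base_icer": r.base_icer, "span": r.span}
            for r in rows
        ]
    )
    if len(df):
        df = df.sort_values("span", ascending=False, ignore_index=True)
    return df


class PSAResult:
    """Monte-Carlo draws of (dCost, dQALY) with their parameter records."""

    def __init__(self, draws: pd.DataFrame, params: pd.DataFrame, seed: int, n_failed: int = 0):
        self.draws = draws
        self.params = params
        self.seed = seed
        self.n_failed = n_failed

    @property
    def n(self) -> int:
        return len(self.draws)

    def icers(self) -> np.ndarray:
        return (self.draws["dcost"] / self.draws["dqaly"]).to_numpy()

    def prob_cost_effective(self, wtp: float) -> float:
        inb = wtp * self.draws["dqaly"] - self.draws["dcost"]
        return float((inb > 0).mean())


def run_psa(
    model: PartitionedSurvivalCEA,
    distributions=None,
    n: int = 1000,
    seed: int = 0,
) -> PSAResult:
    """Joint Monte-Carlo resampling of all parameters, n model reruns.

    Per draw every parameter is sampled independently, both arms are
    re-evaluated, and (dCost, dQALY) recorded. A draw where the model raises
    is excluded with a warning count — it never aborts the analysis.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dists = _dists_from_config(model.config) if distributions is None else [
        _as_dist(d) for d in distributions
    ]
    rng = np.random.default_rng(seed)
    rows, precs, failed = [], [], 0
    for i in range(n):
        overrides = {d.name: float(np.asarray(sample_param(d, rng))) for d in dists}
        try:
            res = model.fit(overrides)
            inc = res.incremental
        except Exception:  # pragma: no cover - defensive
            failed += 1
            continue
        rows.append({"draw": i, "dcost": inc.incremental_cost, "dqaly": inc.incremental_qalys})
        precs.append(overrides)
    if failed:
        warnings.warn(f"{failed} of {n} PSA draws failed and were excluded")
    return PSAResult(pd.DataFrame(rows), pd.DataFrame(precs), seed, failed)


def ceac(psa: PSAResult, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability: P(NMB > 0) at each WTP grid point."""
    if psa.n == 0:
        raise ValueError("PSA result is empty")
    grid = np.asarray(wtp_grid, dtype=float)
    dq = psa.draws["dqaly"].to_numpy()
    dc = psa.draws["dcost"].to_numpy()
    prob = [(w * dq - dc > 0).mean() for w in grid]
    return pd.DataFrame({"wtp": grid, "prob_cost_effective": prob})
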