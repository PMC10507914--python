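"""Non-parametric bootstrap of the cost-utility analysis.

Patients are resampled with replacement *within each arm* (original arm sizes
preserved — the standard design-respecting scheme for a two-arm trial); each
replicate recomputes the paired mean differentials (Δcost, Δeffect).  From the
replicate cloud come the percentile CI of the ICER, the quadrant shares of the
cost-utility plane, and the cost-effectiveness acceptability curve (CEAC):
the probability that the evaluated strategy is acceptable as a function of the
willingness-to-pay threshold λ.

Two acceptance rules are offered.  The default is net monetary benefit
(λ·Δeffect − Δcost > 0), which orders all four quadrants correctly.  The
figure-literal ratio rule (ICER < λ among replicates with a defined ratio) is
kept as an option; it misorders replicates in the NW/SW quadrants, which is
why NMB is the default.  The two agree when every replicate is in the NE
quadrant.  Replicates with Δeffect exactly 0 count as not acceptable under
both rules.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .comparative import ARM_A, ARM_B, quadrant_of

DEFAULT_B = 10_000

#: default willingness-to-pay grid, €/QALY (includes the 25,000 € reference)
DEFAULT_WTP_GRID = tuple(range(0, 100_001, 1_000))


@dataclass
class BootstrapDistribution:
    """B paired (Δcost, Δeffect) replicates with their provenance."""

    delta_cost: np.ndarray
    delta_effect: np.ndarray
    seed: int
    stratified_by_arm: bool = True
    point_delta_cost: Optional[float] = None
    point_delta_effect: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.delta_cost) != len(self.delta_effect):
            raise ValueError("replicate arrays must be paired")

    @property
    def B(self) -> int:
        return len(self.delta_cost)


def _replicate_rng(seed: int, r: int) -> np.random.Generator:
    # counter-based substream: replicate r is reproducible independently of
    # execution order
    return np.random.Generator(np.random.Philox(key=int(seed)).jumped(r + 1))


def bootstrap_ce(
    outcomes: pd.DataFrame,
    B: int = DEFAULT_B,
    seed: int = 0,
    *,
    cost_col: str = "cost",
    effect_col: str = "effect",
    arm_col: str = "arm",
) -> BootstrapDistribution:
    """Arm-stratified non-parametric bootstrap of the mean differentials.

    ``outcomes`` holds one included complete case per row with arm, cost and
    effect columns.  Each replicate draws, within each arm, a resample of the
    original size and records (mean_A − mean_B) for cost and effect.
    """
    cost_a = outcomes.loc[outcomes[arm_col] == ARM_A, cost_col].to_numpy(dtype=float)
    cost_b = outcomes.loc[outcomes[arm_col] == ARM_B, cost_col].to_numpy(dtype=float)
    eff_a = outcomes.loc[outcomes[arm_col] == ARM_A, effect_col].to_numpy(dtype=float)
    eff_b = outcomes.loc[outcomes[arm_col] == ARM_B, effect_col].to_numpy(dtype=float)
    na, nb = len(cost_a), len(cost_b)
    if na == 0 or nb == 0:
        raise ValueError("both arms must be non-empty")
    dc = np.empty(B)
    de = np.empty(B)
    for r in range(B):
        rng = _replicate_rng(seed, r)
        ia = rng.integers(0, na, na)
        ib = rng.integers(0, nb, nb)
        dc[r] = cost_a[ia].mean() - cost_b[ib].mean()
        de[r] = eff_a[ia].mean() - eff_b[ib].mean()
    return BootstrapDistribution(
        delta_cost=dc,
        delta_effect=de,
        seed=int(seed),
        stratified_by_arm=True,
        point_delta_cost=float(cost_a.mean() - cost_b.mean()),
        point_delta_effect=float(eff_a.mean() - eff_b.mean()),
    )


@dataclass
class ICERInterval:
    mean_icer: float
    ci_low: float
    ci_high: float
    n_undefined: int
    level: float = 0.95


def icer_ci(dist: BootstrapDistribution, level: float = 0.95) -> ICERInterval:
    """Mean and percentile CI of the per-replicate ICERs.

    Replicates with Δeffect exactly 0 have no ratio and are dropped (their
    count is reported).  Negative ratios are retained and ordered numerically —
    a documented caveat of ratio-scale percentile intervals.
    """
    defined = dist.delta_effect != 0
    n_undef = int((~defined).sum())
    if not defined.any():
        raise ValueError("all replicates have zero effect differential")
    ratios = dist.delta_cost[defined] / dist.delta_effect[defined]
    alpha = (1 - level) / 2
    lo, hi = np.percentile(ratios, [100 * alpha, 100 * (1 - alpha)])
    return ICERInterval(
        mean_icer=float(ratios.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_undefined=n_undef,
        level=level,
    )


def percentile_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Plain percentile interval of a bootstrap marginal (e.g. Δcost)."""
    alpha = (1 - level) / 2
    lo, hi = np.percentile(np.asarray(values, dtype=float), [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def quadrant_proportions(dist: BootstrapDistribution) -> dict[str, float]:
    """Fraction of replicates in each CU-plane quadrant (sums to 1; boundary
    points counted toward the non-negative side)."""
    if dist.B == 0:
        raise ValueError("empty distribution")
    quads = [quadrant_of(e, c) for e, c in zip(dist.delta_effect, dist.delta_cost)]
    return {q: quads.count(q) / dist.B for q in ("NE", "NW", "SE", "SW")}


@dataclass
class CEACCurve:
    wtp_grid: np.ndarray
    probability: np.ndarray
    rule: str

    def at(self, wtp: float) -> float:
        idx = np.nonzero(np.isclose(self.wtp_grid, wtp))[0]
        if len(idx) == 0:
            raise KeyError(f"WTP {wtp} not on the grid")
        return float(self.probability[idx[0]])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "probability": self.probability})


def ceac(
    dist: BootstrapDistribution,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
    rule: str = "nmb",
) -> CEACCurve:
    """Acceptability curve over a willingness-to-pay grid.

    ``rule="nmb"`` (default): acceptable iff λ·Δeffect − Δcost > 0.
    ``rule="ratio"``: acceptable iff the replicate's ICER is defined and below
    λ (the literal reading of an acceptability-curve caption; see module note).
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("WTP grid must be non-empty and strictly ascending")
    de, dc = dist.delta_effect, dist.delta_cost
    defined = de != 0
    if rule == "nmb":
        # Δeffect == 0 replicates are never acceptable; average over all B
        nmb = grid[:, None] * de[None, :] - dc[None, :]
        prob = ((nmb > 0) & defined[None, :]).mean(axis=1)
    elif rule == "ratio":
        ratios = np.full_like(de, np.inf)
        ratios[defined] = dc[defined] / de[defined]
        prob = ((ratios[None, :] < grid[:, None]) & defined[None, :]).mean(axis=1)
    else:
        raise ValueError("rule must be 'nmb' or 'ratio'")
    return CEACCurve(wtp_grid=grid, probability=prob, rule=rule)


def cu_plane_frame(dist: BootstrapDistribution) -> pd.DataFrame:
    """Replicate cloud for external plotting of the cost-utility plane."""
    return pd.DataFrame({"delta_effect": dist.delta_effect, "delta_cost": dist.delta_cost})
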