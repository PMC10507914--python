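"""Complete-case comparative analyses: exclusion cascade, mean differentials,
mortality contrasts and the incremental cost-utility ratio (ICER).

Conventions: the evaluated strategy (VATS) is arm A and the comparator
(thoracotomy) arm B; differentials are A − B.  Cost differentials alone form a
cost-minimisation analysis when mortality does not differ; relating the cost
differential to the QALY differential gives the ICER in €/QALY.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ARM_A = "VATS"
ARM_B = "THORACOTOMY"

#: exclusion criteria, in cascade order, per horizon
D30_CRITERIA = ("died_before_d30", "d30_visit_out_of_window", "d30_visit_undated", "missing_eq5d")
M3_CRITERIA = (
    "excluded_at_d30",
    "died_d30_to_m3",
    "m3_visit_out_of_window",
    "m3_visit_undated",
    "missing_eq5d",
)


def apply_cua_exclusions(
    table: pd.DataFrame, horizon: str, *, visit_tolerance: int = 14
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Complete-case selection for the cost-utility analysis.

    ``table`` is one row per randomised patient with columns ``death_day``,
    ``d30_visit_day``, ``m3_visit_day``, ``qaly_d30_complete`` and (for the
    3-month horizon) ``qaly_m3_complete``.  Criteria are applied in a fixed
    order and each exclusion is attributed to the *first* failing criterion:
    death before the visit, visit much earlier/later than nominal (beyond
    ``visit_tolerance`` days), undated visit, then missing questionnaire data.
    The 3-month cascade starts from the 30-day included set.

    Returns the included rows and the per-criterion exclusion counts.
    """
    if horizon not in ("d30", "m3"):
        raise ValueError("horizon must be 'd30' or 'm3'")

    def _cascade(df: pd.DataFrame, visit_col: str, nominal: int, qaly_flag: str, death_lo: float):
        counts: dict[str, int] = {}
        death = df["death_day"]
        visit = df[visit_col]
        died = death.notna() & (death > death_lo) & (death <= visit.fillna(nominal))
        counts["died"] = int(died.sum())
        df = df[~died]
        visit = df[visit_col]
        off = visit.notna() & ((visit - nominal).abs() > visit_tolerance)
        counts["off_window"] = int(off.sum())
        df = df[~off]
        undated = df[visit_col].isna()
        counts["undated"] = int(undated.sum())
        df = df[~undated]
        missing = ~df[qaly_flag].astype(bool)
        counts["missing"] = int(missing.sum())
        return df[~missing], counts

    if horizon == "d30":
        inc, c = _cascade(table, "d30_visit_day", 30, "qaly_d30_complete", -np.inf)
        counts = dict(zip(D30_CRITERIA, (c["died"], c["off_window"], c["undated"], c["missing"])))
        return inc, counts

    d30_included, _ = apply_cua_exclusions(table, "d30", visit_tolerance=visit_tolerance)
    base = table.index.isin(d30_included.index)
    counts = {"excluded_at_d30": int((~base).sum())}
    df = table[base]
    death_lo = df["d30_visit_day"].fillna(30)
    inc, c = _cascade(df, "m3_visit_day", 91, "qaly_m3_complete", death_lo)
    counts.update(
        zip(M3_CRITERIA[1:], (c["died"], c["off_window"], c["undated"], c["missing"]))
    )
    return inc, counts


@dataclass
class DifferentialResult:
    """Two-sample mean comparison, A − B, with a t-based CI and p-value."""

    mean_a: float
    mean_b: float
    difference: float
    ci_low: float
    ci_high: float
    p_value: float
    n_a: int
    n_b: int


def mean_difference(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "pooled",
    *,
    alpha: float = 0.05,
) -> DifferentialResult:
    """Student's t comparison of two group means (pooled-variance by default,
    ``method="welch"`` for unequal variances)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two observations")
    diff = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if method == "pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    elif method == "welch":
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        ) if se > 0 else na + nb - 2
    else:
        raise ValueError("method must be 'pooled' or 'welch'")
    if se == 0.0:
        p = 1.0 if diff == 0.0 else 0.0
        half = 0.0
    else:
        t = diff / se
        p = float(2 * stats.t.sf(abs(t), df))
        half = float(stats.t.ppf(1 - alpha / 2, df) * se)
    return DifferentialResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        difference=diff,
        ci_low=diff - half,
        ci_high=diff + half,
        p_value=p,
        n_a=na,
        n_b=nb,
    )


@dataclass
class MortalityContrast:
    risk_a: float
    risk_b: float
    risk_difference: float
    rd_ci_low: float
    rd_ci_high: float
    odds_ratio: Optional[float]
    or_ci_low: Optional[float]
    or_ci_high: Optional[float]


def mortality_contrast(
    deaths_a: int, n_a: int, deaths_b: int, n_b: int, *, alpha: float = 0.05
) -> MortalityContrast:
    """Risk difference (Wald CI) and logistic-regression odds ratio (Wald CI)
    for deaths in two arms.  With zero events in both arms the odds ratio is
    undefined and returned as None."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("arm sizes must be positive")
    pa, pb = deaths_a / n_a, deaths_b / n_b
    rd = pa - pb
    se_rd = math.sqrt(pa * (1 - pa) / n_a + pb * (1 - pb) / n_b)
    z = stats.norm.ppf(1 - alpha / 2)
    or_, lo, hi = None, None, None
    cells = (deaths_a, n_a - deaths_a, deaths_b, n_b - deaths_b)
    if all(c > 0 for c in cells):
        import statsmodels.api as sm

        y = np.concatenate([np.ones(deaths_a), np.zeros(n_a - deaths_a),
                            np.ones(deaths_b), np.zeros(n_b - deaths_b)])
        x = sm.add_constant(np.concatenate([np.ones(n_a), np.zeros(n_b)]))
        fit = sm.Logit(y, x).fit(disp=False)
        beta, se_b = fit.params[1], fit.bse[1]
        or_ = float(math.exp(beta))
        lo = float(math.exp(beta - z * se_b))
        hi = float(math.exp(beta + z * se_b))
    return MortalityContrast(
        risk_a=pa,
        risk_b=pb,
        risk_difference=rd,
        rd_ci_low=rd - z * se_rd,
        rd_ci_high=rd + z * se_rd,
        odds_ratio=or_,
        or_ci_low=lo,
        or_ci_high=hi,
    )


@dataclass
class ICERResult:
    """Incremental cost-utility ratio and its cost-utility-plane quadrant.

    The quadrant follows the signs of (Δeffect, Δcost): NE = more effective
    and more costly.  A zero effect differential leaves the ratio undefined
    (quadrant "axis")."""

    delta_cost: float
    delta_effect: float
    icer: Optional[float]
    quadrant: str

    @property
    def icer_rounded(self) -> Optional[int]:
        """Ratio reported to the nearest euro."""
        if self.icer is None:
            return None
        return int(round(self.icer))


def quadrant_of(delta_effect: float, delta_cost: float) -> str:
    """CU-plane quadrant; boundary points count toward the non-negative side
    (east for Δeffect = 0 is never reached — that case is 'axis' for the point
    ICER, but bootstrap replicates use this deterministic tie-break)."""
    east = delta_effect >= 0
    north = delta_cost >= 0
    return {(True, True): "NE", (True, False): "SE", (False, True): "NW", (False, False): "SW"}[
        (east, north)
    ]


def icer(delta_cost: float, delta_effect: float) -> ICERResult:
    """Cost differential over effect differential, in €/QALY."""
    if delta_effect == 0:
        return ICERResult(delta_cost=delta_cost, delta_effect=delta_effect, icer=None, quadrant="axis")
    return ICERResult(
        delta_cost=float(delta_cost),
        delta_effect=float(delta_effect),
        icer=float(delta_cost) / float(delta_effect),
        quadrant=quadrant_of(delta_effect, delta_cost),
    )


def arm_summary(values: Sequence[float]) -> dict[str, float]:
    """n / mean / SD / median / quartiles block of the results tables."""
    v = np.asarray(values, dtype=float)
    return {
        "n": int(len(v)),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        "median": float(np.median(v)),
        "q1": float(np.percentile(v, 25)),
        "q3": float(np.percentile(v, 75)),
    }
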