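"""Multiple imputation by chained equations (MICE) for EQ-5D items and cost
components, with Rubin-style pooling and a pooled bootstrap.

The chained-equation engine is implemented here: continuous cost variables are
imputed by predictive mean matching (k = 5 donors), ordinal EQ-5D items by a
multinomial-logit draw on the {1,2,3} scale.  Each of the m imputations is an
independent chain: missing cells are initialised by resampling observed
values, then the variables are revisited for a fixed number of cycles in order
of increasing missingness.  Observed values are never altered, and imputed
item levels are *rescored* to utilities afterwards rather than imputing the
utility index directly.

Imputation excludes patients who died or left the study early; the pooled
point estimate of each differential is the arithmetic mean across imputations
(Rubin's rule), and the pooled ICER relates the pooled differentials.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .comparative import ARM_A, ARM_B
from .uncertainty import BootstrapDistribution, bootstrap_ce, icer_ci
from .utility import DIMENSIONS, TIMEPOINTS

ITEM_COLUMNS = tuple(f"{dim}_{tp}" for tp in TIMEPOINTS for dim in DIMENSIONS)
COST_COLUMNS = ("cost_initial", "cost_rehosp", "cost_rehab")
COVARIATE_COLUMNS = ("age", "sex", "performance_status", "smoking", "bmi")


@dataclass
class ImputationConfig:
    """Settings of the chained-equation run.

    ``m`` completed datasets, ``max_iterations`` chained cycles per dataset,
    ``pmm_donors`` nearest predicted-mean donors for continuous draws.
    """

    m: int = 10
    predictors: tuple[str, ...] = COVARIATE_COLUMNS + ITEM_COLUMNS + COST_COLUMNS
    max_iterations: int = 10
    pmm_donors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need at least two imputations")
        if self.max_iterations < 1:
            raise ValueError("need at least one cycle")


def _design_matrix(data: pd.DataFrame, predictors: Sequence[str], exclude: str) -> np.ndarray:
    """Numeric predictor matrix from the current working data (dummy-coded
    categoricals, intercept included)."""
    cols = [c for c in predictors if c != exclude and c in data.columns]
    X = pd.get_dummies(data[cols], drop_first=True, dtype=float)
    X = X.fillna(X.mean())  # only reachable transiently before initialisation
    mat = X.to_numpy(dtype=float)
    # z-score the columns: mixed scales (costs in €10^4, items in 1..3) stall
    # the logistic solver and distort nothing for PMM matching
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)
    sd[sd == 0] = 1.0
    mat = (mat - mu) / sd
    return np.column_stack([np.ones(len(mat)), mat])


def _pmm_impute(
    y: np.ndarray, X: np.ndarray, miss: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Predictive mean matching: regress observed y on X, match each missing
    prediction to its k nearest observed predictions, draw one donor's y."""
    obs = ~miss
    beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
    yhat_obs = X[obs] @ beta
    yhat_mis = X[miss] @ beta
    y_obs = y[obs]
    out = y.copy()
    k = min(k, len(y_obs))
    draws = np.empty(miss.sum())
    for i, pred in enumerate(yhat_mis):
        nearest = np.argpartition(np.abs(yhat_obs - pred), k - 1)[:k]
        draws[i] = y_obs[rng.choice(nearest)]
    out[miss] = draws
    return out


def _multinomial_impute(
    y: np.ndarray, X: np.ndarray, miss: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial-logit draw for an ordinal item on the {1,2,3} scale."""
    obs = ~miss
    classes = np.unique(y[obs])
    out = y.copy()
    if len(classes) == 1:
        out[miss] = classes[0]
        return out
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        # coarse tolerance: coefficients feed a stochastic draw, not inference
        model = LogisticRegression(max_iter=100, tol=1e-3)
        model.fit(X[obs], y[obs].astype(int))
    proba = model.predict_proba(X[miss])
    cum = np.cumsum(proba, axis=1)
    u = rng.random((miss.sum(), 1))
    idx = (u > cum).sum(axis=1)
    out[miss] = model.classes_[idx]
    return out


def mice_impute(
    data: pd.DataFrame, config: ImputationConfig
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Run MICE and return the m completed datasets plus a chain-mean trace.

    ``data`` is one row per eligible patient (dead / early-exit patients
    removed beforehand); EQ-5D item columns are ordinal {1,2,3} with NaN for
    missing, cost columns continuous.  Variables with no missing values are
    used as predictors only.  A 100%-missing variable is an error.
    """
    for col in config.predictors:
        if col not in data.columns:
            raise ValueError(f"predictor {col!r} not in data")
    item_cols = [c for c in ITEM_COLUMNS if c in data.columns]
    cost_cols = [c for c in COST_COLUMNS if c in data.columns]
    targets = [c for c in item_cols + cost_cols if data[c].isna().any()]
    for c in targets:
        if data[c].isna().all():
            raise ValueError(f"variable {c!r} is 100% missing and cannot be imputed")
    if not targets:
        trace = pd.DataFrame(columns=["imputation", "cycle", "variable", "chain_mean"])
        return [data.copy() for _ in range(config.m)], trace

    targets.sort(key=lambda c: data[c].isna().mean())
    miss_masks = {c: data[c].isna().to_numpy() for c in targets}
    datasets: list[pd.DataFrame] = []
    trace_rows: list[dict] = []
    root = np.random.SeedSequence((int(config.seed), 0xA11CE))
    for m_idx, child in enumerate(root.spawn(config.m)):
        rng = np.random.default_rng(child)
        work = data.copy()
        for c in targets:  # initialise by resampling observed values
            miss = miss_masks[c]
            obs_vals = work.loc[~miss, c].to_numpy()
            work.loc[miss, c] = rng.choice(obs_vals, size=miss.sum(), replace=True)
        for cycle in range(config.max_iterations):
            for c in targets:
                miss = miss_masks[c]
                X = _design_matrix(work, config.predictors, exclude=c)
                y = work[c].to_numpy(dtype=float)
                if c in cost_cols:
                    y = _pmm_impute(y, X, miss, config.pmm_donors, rng)
                else:
                    y = _multinomial_impute(y, X, miss, rng)
                work[c] = y
                trace_rows.append(
                    {
                        "imputation": m_idx,
                        "cycle": cycle,
                        "variable": c,
                        "chain_mean": float(y[miss].mean()),
                    }
                )
        for c in item_cols:
            work[c] = work[c].astype(int)
        # observed entries must be byte-identical to the input
        for c in targets:
            assert (work.loc[~miss_masks[c], c] == data.loc[~miss_masks[c], c]).all()
        datasets.append(work)
    return datasets, pd.DataFrame(trace_rows)


@dataclass
class PooledResult:
    """Rubin-pooled differentials across m imputed datasets."""

    pooled_delta_cost: float
    pooled_delta_effect: float
    pooled_icer: Optional[float]
    between_var_cost: float
    between_var_effect: float
    within_var_cost: Optional[float] = None
    within_var_effect: Optional[float] = None
    m: int = 0


def pool_estimates(per_imputation: Sequence[Mapping[str, float]]) -> PooledResult:
    """Pool per-imputation differentials: point estimates are arithmetic means
    across imputations; the ICER relates the pooled differentials.  Each entry
    needs ``delta_cost`` and ``delta_effect``; optional ``var_cost`` /
    ``var_effect`` feed the within-imputation variance components."""
    if not per_imputation:
        raise ValueError("no results to pool")
    keys = {frozenset(r.keys()) for r in per_imputation}
    if len(keys) != 1:
        raise ValueError("per-imputation results have mismatched structures")
    dc = np.array([r["delta_cost"] for r in per_imputation], dtype=float)
    de = np.array([r["delta_effect"] for r in per_imputation], dtype=float)
    m = len(dc)
    pooled_dc, pooled_de = float(dc.mean()), float(de.mean())
    within_c = within_e = None
    if "var_cost" in next(iter(keys)):
        within_c = float(np.mean([r["var_cost"] for r in per_imputation]))
    if "var_effect" in next(iter(keys)):
        within_e = float(np.mean([r["var_effect"] for r in per_imputation]))
    return PooledResult(
        pooled_delta_cost=pooled_dc,
        pooled_delta_effect=pooled_de,
        pooled_icer=pooled_dc / pooled_de if pooled_de != 0 else None,
        between_var_cost=float(dc.var(ddof=1)) if m > 1 else 0.0,
        between_var_effect=float(de.var(ddof=1)) if m > 1 else 0.0,
        within_var_cost=within_c,
        within_var_effect=within_e,
        m=m,
    )


@dataclass
class ImputedCUAResult:
    pooled: PooledResult
    bootstrap: BootstrapDistribution
    icer_mean: float
    icer_ci_low: float
    icer_ci_high: float


def imputed_cua(
    data: pd.DataFrame,
    imp_config: ImputationConfig,
    B: int = 10_000,
    seed: int = 0,
    *,
    analyse,
    nesting: str = "within",
    datasets: Optional[list[pd.DataFrame]] = None,
) -> ImputedCUAResult:
    """Impute, analyse each completed dataset, pool, and bootstrap.

    ``analyse`` maps a completed dataset to a per-patient outcome frame with
    columns ``arm``, ``cost``, ``effect`` (it owns the rescoring of imputed
    item levels into utilities and QALYs).  The default nesting bootstraps
    ceil(B/m) replicates *within* each completed dataset and pools the
    combined replicate cloud for the percentile CI; ``nesting="across"``
    re-imputes inside each bootstrap resample of the patient table (costlier;
    provided for sensitivity).
    """
    if nesting not in ("within", "across"):
        raise ValueError("nesting must be 'within' or 'across'")
    if nesting == "across":
        return _imputed_cua_across(data, imp_config, B, seed, analyse)
    if datasets is None:
        datasets, _ = mice_impute(data, imp_config)
    per_imp = []
    clouds_c, clouds_e = [], []
    b_each = -(-B // imp_config.m)  # ceil
    for j, ds in enumerate(datasets):
        outcomes = analyse(ds)
        a = outcomes.loc[outcomes["arm"] == ARM_A]
        b = outcomes.loc[outcomes["arm"] == ARM_B]
        per_imp.append(
            {
                "delta_cost": a["cost"].mean() - b["cost"].mean(),
                "delta_effect": a["effect"].mean() - b["effect"].mean(),
                "var_cost": a["cost"].var(ddof=1) / len(a) + b["cost"].var(ddof=1) / len(b),
                "var_effect": a["effect"].var(ddof=1) / len(a) + b["effect"].var(ddof=1) / len(b),
            }
        )
        dist = bootstrap_ce(outcomes, B=b_each, seed=int(seed) + 7919 * (j + 1))
        clouds_c.append(dist.delta_cost)
        clouds_e.append(dist.delta_effect)
    pooled = pool_estimates(per_imp)
    cloud = BootstrapDistribution(
        delta_cost=np.concatenate(clouds_c)[:B],
        delta_effect=np.concatenate(clouds_e)[:B],
        seed=int(seed),
        point_delta_cost=pooled.pooled_delta_cost,
        point_delta_effect=pooled.pooled_delta_effect,
    )
    ci = icer_ci(cloud)
    return ImputedCUAResult(
        pooled=pooled,
        bootstrap=cloud,
        icer_mean=ci.mean_icer,
        icer_ci_low=ci.ci_low,
        icer_ci_high=ci.ci_high,
    )


def _imputed_cua_across(data, imp_config, B, seed, analyse) -> ImputedCUAResult:
    """Alternative nesting: re-impute (m=2, short chains) inside each bootstrap
    resample of the eligible patient table."""
    small = ImputationConfig(
        m=2,
        predictors=imp_config.predictors,
        max_iterations=min(3, imp_config.max_iterations),
        pmm_donors=imp_config.pmm_donors,
        seed=imp_config.seed,
    )
    datasets, _ = mice_impute(data, imp_config)
    per_imp = []
    for ds in datasets:
        outcomes = analyse(ds)
        a = outcomes.loc[outcomes["arm"] == ARM_A]
        b = outcomes.loc[outcomes["arm"] == ARM_B]
        per_imp.append(
            {
                "delta_cost": a["cost"].mean() - b["cost"].mean(),
                "delta_effect": a["effect"].mean() - b["effect"].mean(),
            }
        )
    pooled = pool_estimates(per_imp)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xB001)))
    arms = data["arm"].to_numpy()
    idx_a = np.flatnonzero(arms == ARM_A)
    idx_b = np.flatnonzero(arms == ARM_B)
    dc = np.empty(B)
    de = np.empty(B)
    for r in range(B):
        take = np.concatenate(
            [rng.choice(idx_a, len(idx_a)), rng.choice(idx_b, len(idx_b))]
        )
        boot = data.iloc[take].reset_index(drop=True)
        boot_small = ImputationConfig(
            m=small.m,
            predictors=small.predictors,
            max_iterations=small.max_iterations,
            pmm_donors=small.pmm_donors,
            seed=int(seed) + r,
        )
        ds_list, _ = mice_impute(boot, boot_small)
        reps = []
        for ds in ds_list:
            outcomes = analyse(ds)
            a = outcomes.loc[outcomes["arm"] == ARM_A]
            b = outcomes.loc[outcomes["arm"] == ARM_B]
            reps.append(
                (a["cost"].mean() - b["cost"].mean(), a["effect"].mean() - b["effect"].mean())
            )
        dc[r] = np.mean([x[0] for x in reps])
        de[r] = np.mean([x[1] for x in reps])
    cloud = BootstrapDistribution(
        delta_cost=dc,
        delta_effect=de,
        seed=int(seed),
        point_delta_cost=pooled.pooled_delta_cost,
        point_delta_effect=pooled.pooled_delta_effect,
    )
    ci = icer_ci(cloud)
    return ImputedCUAResult(
        pooled=pooled,
        bootstrap=cloud,
        icer_mean=ci.mean_icer,
        icer_ci_low=ci.ci_low,
        icer_ci_high=ci.ci_high,
    )
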