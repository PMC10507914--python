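"""End-to-end orchestration: simulate (or load) a trial, cost the stays, score
utilities, run the complete-case and imputed cost-utility analyses, and emit
paper-style tables plus a machine-readable summary.

Every number in the rendered tables is taken from the summary dictionary, so
the JSON is the single source of truth, and the whole bundle is reproducible
from the root seed.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import comparative, costing, imputation, synthetic_trial, uncertainty, utility
from .comparative import ARM_A, ARM_B

log = logging.getLogger("thoracic_cea")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``trial`` (a simulation config) or the three data paths must be
    given.  ``seed`` drives every stochastic stage via fixed substreams.
    """

    seed: int = 0
    trial: Optional[synthetic_trial.TrialConfig] = None
    patients_path: Optional[str] = None
    eq5d_path: Optional[str] = None
    stays_path: Optional[str] = None
    drg_catalog_path: Optional[str] = None
    value_set_path: Optional[str] = None
    rehosp_rules_path: Optional[str] = None
    b_replicates: int = uncertainty.DEFAULT_B
    imputation: imputation.ImputationConfig = field(
        default_factory=lambda: imputation.ImputationConfig()
    )
    wtp_grid: Sequence[float] = uncertainty.DEFAULT_WTP_GRID
    visit_tolerance: int = 14
    prorate_rehosp: bool = False
    output_dir: str = "results"
    horizons: tuple[str, ...] = ("d30", "m3")

    def __post_init__(self) -> None:
        if self.trial is None and not (self.patients_path and self.eq5d_path and self.stays_path):
            raise ValueError(
                "config needs either a simulation config ('trial') or the three "
                "data paths (patients_path, eq5d_path, stays_path)"
            )


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(int(seed)).generate_state(4) & 0x7FFFFFFF
    return {
        "simulate": int(state[0]),
        "bootstrap_d30": int(state[1]),
        "bootstrap_m3": int(state[2]),
        "impute": int(state[3]),
    }


# ---------------------------------------------------------------------------
# stages


def stage_simulate(trial_config: synthetic_trial.TrialConfig, value_set=None):
    """Generate the cohort, its EQ-5D trajectories (with missingness applied)
    and its stay events."""
    patients = synthetic_trial.generate_trial(trial_config)
    observations = synthetic_trial.simulate_eq5d(patients, trial_config, value_set)
    observations = synthetic_trial.apply_missingness(observations, trial_config, patients)
    stays = synthetic_trial.simulate_resource_use(patients, trial_config)
    log.info(
        "simulated %d patients, %d EQ-5D records, %d stays (seed %d)",
        len(patients), len(observations), len(stays), trial_config.seed,
    )
    return patients, observations, stays


def stage_cost(stays, patients_df: pd.DataFrame, *, catalog=None, surgery=None,
               rules=None, prorate_rehosp: bool = False):
    """Assign DRGs and production costs to every stay (adjusted-DRG for the
    initial stays, gross costing for follow-up stays)."""
    catalog = catalog or costing.DRGCatalog.load_default()
    surgery = surgery or costing.SurgeryCostTable()
    arm_by_patient = dict(zip(patients_df["patient_id"], patients_df["arm"]))
    return costing.cost_stays(
        stays, catalog, surgery, arm_by_patient, rules, prorate_los=prorate_rehosp
    )


def stage_utilities(observations, value_set=None):
    """Score every complete EQ-5D record with the tariff (idempotent for
    records the simulator already scored)."""
    value_set = value_set or utility.load_value_set()
    for o in observations:
        o.utility = value_set.score(o.levels) if o.complete else None
    return observations


def build_analysis_table(
    patients_df: pd.DataFrame,
    observations,
    stays,
    *,
    horizon_days: Optional[dict] = None,
) -> pd.DataFrame:
    """One row per randomised patient: covariates, visit calendar, per-window
    cost components, cumulative costs and QALY outcomes at both horizons."""
    obs_by_patient: dict[str, list] = {}
    for o in observations:
        obs_by_patient.setdefault(o.patient_id, []).append(o)
    stays_by_patient: dict[str, list] = {}
    for s in stays:
        stays_by_patient.setdefault(s.patient_id, []).append(s)

    rows = []
    for rec in patients_df.itertuples(index=False):
        pid = rec.patient_id
        p_obs = obs_by_patient.get(pid, [])
        p_stays = stays_by_patient.get(pid, [])
        d30_day = None if pd.isna(rec.d30_visit_day) else int(rec.d30_visit_day)
        m3_day = None if pd.isna(rec.m3_visit_day) else int(rec.m3_visit_day)
        row = {
            "patient_id": pid,
            "arm": rec.arm,
            "centre_id": rec.centre_id,
            "age": rec.age,
            "sex": rec.sex,
            "bmi": rec.bmi,
            "performance_status": rec.performance_status,
            "smoking": rec.smoking,
            "d30_visit_day": d30_day,
            "m3_visit_day": m3_day,
            "death_day": None if pd.isna(rec.death_day) else int(rec.death_day),
        }
        for tp in utility.TIMEPOINTS:
            match = [o for o in p_obs if o.timepoint == tp]
            row[f"utility_{tp}"] = match[0].utility if match else None
            for i, dim in enumerate(utility.DIMENSIONS):
                row[f"{dim}_{tp}"] = match[0].levels[i] if match else None
        q30 = utility.qaly_auc(p_obs, "d30")
        q3m = utility.qaly_auc(p_obs, "m3")
        row["qaly_d30"] = q30.qaly
        row["qaly_d30_complete"] = q30.complete
        row["qaly_m3"] = q3m.qaly
        row["qaly_m3_complete"] = q3m.complete
        row["cost_d30"] = float(
            costing.cumulative_costs(pid, p_stays, "d30", d30_visit_day=d30_day, m3_visit_day=m3_day)
        )
        row["cost_m3"] = float(
            costing.cumulative_costs(pid, p_stays, "m3", d30_visit_day=d30_day, m3_visit_day=m3_day)
        )
        comp = {"initial": Decimal(0), "rehospitalisation": Decimal(0), "rehabilitation": Decimal(0)}
        for s in p_stays:
            if s.cost is not None:
                comp[s.stay_type] += s.cost
        row["cost_initial"] = float(comp["initial"])
        row["cost_rehosp"] = float(comp["rehospitalisation"])
        row["cost_rehab"] = float(comp["rehabilitation"])
        rows.append(row)
    return pd.DataFrame(rows)


def _differential_block(table: pd.DataFrame, col: str) -> dict:
    a = table.loc[table["arm"] == ARM_A, col].astype(float)
    b = table.loc[table["arm"] == ARM_B, col].astype(float)
    res = comparative.mean_difference(a, b)
    return {
        "arm_a": comparative.arm_summary(a),
        "arm_b": comparative.arm_summary(b),
        "difference": res.difference,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "p_value": res.p_value,
    }


def stage_analyze(table: pd.DataFrame, *, visit_tolerance: int = 14) -> dict:
    """Cost-minimisation (all randomised patients) and complete-case
    cost-utility point analyses with the exclusion cascade."""
    out: dict = {"cost_minimisation": {}, "cua": {}, "exclusions": {}, "mortality": {}}
    for horizon in ("d30", "m3"):
        out["cost_minimisation"][horizon] = _differential_block(table, f"cost_{horizon}")
        included, counts = comparative.apply_cua_exclusions(
            table, horizon, visit_tolerance=visit_tolerance
        )
        out["exclusions"][horizon] = counts
        cost_block = _differential_block(included, f"cost_{horizon}")
        qaly_block = _differential_block(included, f"qaly_{horizon}")
        point = comparative.icer(cost_block["difference"], qaly_block["difference"])
        out["cua"][horizon] = {
            "cost": cost_block,
            "qaly": qaly_block,
            "icer": point.icer_rounded,
            "quadrant": point.quadrant,
            "n_included": int(len(included)),
            "n_included_a": int((included["arm"] == ARM_A).sum()),
            "n_included_b": int((included["arm"] == ARM_B).sum()),
        }
        death = table["death_day"]
        cutoff = 30 if horizon == "d30" else 91
        deaths_a = int(((table["arm"] == ARM_A) & death.notna() & (death <= cutoff)).sum())
        deaths_b = int(((table["arm"] == ARM_B) & death.notna() & (death <= cutoff)).sum())
        n_a = int((table["arm"] == ARM_A).sum())
        n_b = int((table["arm"] == ARM_B).sum())
        mc = comparative.mortality_contrast(deaths_a, n_a, deaths_b, n_b)
        out["mortality"][horizon] = {
            "deaths_a": deaths_a,
            "deaths_b": deaths_b,
            "risk_difference": mc.risk_difference,
            "rd_ci_low": mc.rd_ci_low,
            "rd_ci_high": mc.rd_ci_high,
            "odds_ratio": mc.odds_ratio,
            "or_ci_low": mc.or_ci_low,
            "or_ci_high": mc.or_ci_high,
        }
    # the comparison is labelled a cost-minimisation analysis when mortality
    # does not differ at the 5% level (labelling only, never a gate)
    out["cost_minimisation"]["label_applies"] = all(
        not (m["rd_ci_low"] > 0 or m["rd_ci_high"] < 0) for m in out["mortality"].values()
    )
    return out


def stage_bootstrap(
    table: pd.DataFrame,
    horizon: str,
    B: int,
    seed: int,
    *,
    visit_tolerance: int = 14,
    wtp_grid: Sequence[float] = uncertainty.DEFAULT_WTP_GRID,
):
    """Bootstrap the complete-case CUA at one horizon; returns the
    distribution, ICER interval, quadrant shares and the NMB-rule CEAC."""
    included, _ = comparative.apply_cua_exclusions(table, horizon, visit_tolerance=visit_tolerance)
    outcomes = included.rename(columns={f"cost_{horizon}": "cost", f"qaly_{horizon}": "effect"})[
        ["arm", "cost", "effect"]
    ]
    dist = uncertainty.bootstrap_ce(outcomes, B=B, seed=seed)
    interval = uncertainty.icer_ci(dist)
    quads = uncertainty.quadrant_proportions(dist)
    curve = uncertainty.ceac(dist, wtp_grid, rule="nmb")
    return dist, interval, quads, curve


def _imputation_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Eligible rows (alive, not lost to follow-up) and the columns the
    chained equations use."""
    eligible = table[table["death_day"].isna()].reset_index(drop=True)
    cols = (
        ["patient_id", "arm", "d30_visit_day", "m3_visit_day"]
        + list(imputation.COVARIATE_COLUMNS)
        + list(imputation.ITEM_COLUMNS)
        + list(imputation.COST_COLUMNS)
        + ["cost_d30", "cost_m3"]
    )
    return eligible[cols].copy()


def _analyse_imputed(horizon: str, value_set) -> Callable[[pd.DataFrame], pd.DataFrame]:
    """Per-dataset analysis: rescore imputed item levels to utilities, rebuild
    the interval-weighted QALY (nominal days for undated visits) and pair it
    with the observed cumulative cost."""

    def analyse(ds: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for rec in ds.itertuples(index=False):
            obs = []
            for tp in utility.TIMEPOINTS:
                levels = tuple(
                    int(getattr(rec, f"{dim}_{tp}")) for dim in utility.DIMENSIONS
                )
                if tp == "preop":
                    day = 0
                elif tp == "d3":
                    day = 3
                elif tp == "d30":
                    day = rec.d30_visit_day if pd.notna(rec.d30_visit_day) else 30
                else:
                    day = rec.m3_visit_day if pd.notna(rec.m3_visit_day) else 91
                obs.append(
                    utility.EQ5DObservation(
                        patient_id=rec.patient_id,
                        timepoint=tp,
                        day=int(day),
                        levels=levels,
                        utility=value_set.score(levels),
                    )
                )
            q = utility.qaly_auc(obs, horizon)
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "arm": rec.arm,
                    "cost": getattr(rec, f"cost_{horizon}"),
                    "effect": q.qaly,
                }
            )
        return pd.DataFrame(rows)

    return analyse


def stage_impute(
    table: pd.DataFrame,
    imp_config: imputation.ImputationConfig,
    B: int,
    seed: int,
    value_set=None,
) -> dict:
    """Sensitivity analysis on multiply-imputed data at both horizons."""
    value_set = value_set or utility.load_value_set()
    frame = _imputation_frame(table)
    out = {"n_eligible": int(len(frame))}
    cfg = imputation.ImputationConfig(
        m=imp_config.m,
        predictors=imp_config.predictors,
        max_iterations=imp_config.max_iterations,
        pmm_donors=imp_config.pmm_donors,
        seed=int(seed),
    )
    # one imputation model serves both horizons
    datasets, _ = imputation.mice_impute(frame, cfg)
    for h_idx, horizon in enumerate(("d30", "m3")):
        res = imputation.imputed_cua(
            frame,
            cfg,
            B=B,
            seed=int(seed) + h_idx,
            analyse=_analyse_imputed(horizon, value_set),
            datasets=datasets,
        )
        out[horizon] = {
            "pooled_delta_cost": res.pooled.pooled_delta_cost,
            "pooled_delta_effect": res.pooled.pooled_delta_effect,
            "pooled_icer": (
                int(round(res.pooled.pooled_icer)) if res.pooled.pooled_icer is not None else None
            ),
            "between_var_cost": res.pooled.between_var_cost,
            "between_var_effect": res.pooled.between_var_effect,
            "bootstrap_mean_icer": res.icer_mean,
            "bootstrap_ci_low": res.icer_ci_low,
            "bootstrap_ci_high": res.icer_ci_high,
        }
    return out


# ---------------------------------------------------------------------------
# full run


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), ndigits)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``output_dir``.

    Artifacts: cost-minimisation and CUA tables (CSV), CU-plane replicate and
    CEAC CSVs per horizon, exclusion-cascade counts, and ``summary.json``
    carrying every headline number.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    value_set = (
        utility.ValueSet.from_csv(config.value_set_path)
        if config.value_set_path
        else utility.load_value_set()
    )
    catalog = (
        costing.DRGCatalog.from_csv(config.drg_catalog_path)
        if config.drg_catalog_path
        else costing.DRGCatalog.load_default()
    )
    rules = (
        costing.RehospRules.from_csv(config.rehosp_rules_path)
        if config.rehosp_rules_path
        else costing.RehospRules.load_default()
    )

    if config.trial is not None:
        patients, observations, stays = stage_simulate(config.trial, value_set)
        patients_df = synthetic_trial.patients_frame(patients)
    else:
        patients_df, observations, stays = load_trial_files(
            config.patients_path, config.eq5d_path, config.stays_path
        )
    stays = stage_cost(
        stays, patients_df, catalog=catalog, rules=rules, prorate_rehosp=config.prorate_rehosp
    )
    observations = stage_utilities(observations, value_set)
    table = build_analysis_table(patients_df, observations, stays)

    analysis = stage_analyze(table, visit_tolerance=config.visit_tolerance)
    summary: dict = {
        "seed": int(config.seed),
        "n_patients": int(len(table)),
        "n_per_arm": {
            "a": int((table["arm"] == ARM_A).sum()),
            "b": int((table["arm"] == ARM_B).sum()),
        },
        "arms": {"a": ARM_A, "b": ARM_B},
        "b_replicates": int(config.b_replicates),
        **analysis,
        "uncertainty": {},
    }
    for horizon in config.horizons:
        dist, interval, quads, curve = stage_bootstrap(
            table,
            horizon,
            config.b_replicates,
            seeds[f"bootstrap_{horizon}"],
            visit_tolerance=config.visit_tolerance,
            wtp_grid=config.wtp_grid,
        )
        summary["uncertainty"][horizon] = {
            "bootstrap_mean_icer": interval.mean_icer,
            "bootstrap_ci_low": interval.ci_low,
            "bootstrap_ci_high": interval.ci_high,
            "n_undefined": interval.n_undefined,
            "quadrants": quads,
            "ceac_at_25000": curve.at(25_000.0),
        }
        uncertainty.cu_plane_frame(dist).to_csv(outdir / f"cu_plane_{horizon}.csv", index=False)
        curve.frame().to_csv(outdir / f"ceac_{horizon}.csv", index=False)

    summary["imputed"] = stage_impute(
        table, config.imputation, config.b_replicates, seeds["impute"], value_set
    )

    summary = _round_floats(summary)
    write_tables(summary, outdir)
    table.to_csv(outdir / "analysis_table.csv", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline complete; bundle written to %s", outdir)
    return summary


def write_tables(summary: dict, outdir: Path) -> None:
    """Render the cost-minimisation and CUA tables from the summary dict."""
    rows = []
    for horizon in ("d30", "m3"):
        cm = summary["cost_minimisation"][horizon]
        rows.append(
            {
                "analysis": "cost_minimisation",
                "horizon": horizon,
                "outcome": "cumulative_cost",
                **{f"a_{k}": v for k, v in cm["arm_a"].items()},
                **{f"b_{k}": v for k, v in cm["arm_b"].items()},
                "difference": cm["difference"],
                "ci_low": cm["ci_low"],
                "ci_high": cm["ci_high"],
                "p_value": cm["p_value"],
                "icer": None,
            }
        )
        cua = summary["cua"][horizon]
        for outcome, block in (("cumulative_cost", cua["cost"]), ("final_qaly", cua["qaly"])):
            rows.append(
                {
                    "analysis": "cost_utility_complete_case",
                    "horizon": horizon,
                    "outcome": outcome,
                    **{f"a_{k}": v for k, v in block["arm_a"].items()},
                    **{f"b_{k}": v for k, v in block["arm_b"].items()},
                    "difference": block["difference"],
                    "ci_low": block["ci_low"],
                    "ci_high": block["ci_high"],
                    "p_value": block["p_value"],
                    "icer": cua["icer"] if outcome == "final_qaly" else None,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "comparison_tables.csv", index=False)
    pd.DataFrame(
        [
            {"horizon": h, "criterion": crit, "excluded": n}
            for h, counts in summary["exclusions"].items()
            for crit, n in counts.items()
        ]
    ).to_csv(outdir / "exclusion_cascade.csv", index=False)


def load_trial_files(patients_path, eq5d_path, stays_path):
    """Read the three patient-level CSVs into the in-memory objects the
    pipeline stages consume."""
    return load_patients(patients_path), load_observations(eq5d_path), load_stays(stays_path)


def load_patients(patients_path) -> pd.DataFrame:
    return pd.read_csv(patients_path)


def load_observations(eq5d_path):
    obs_df = pd.read_csv(eq5d_path)
    observations = []
    for rec in obs_df.itertuples(index=False):
        levels = tuple(
            None if pd.isna(getattr(rec, dim)) else int(getattr(rec, dim))
            for dim in utility.DIMENSIONS
        )
        observations.append(
            utility.EQ5DObservation(
                patient_id=rec.patient_id,
                timepoint=rec.timepoint,
                day=int(rec.day),
                levels=levels,
                utility=None,
            )
        )
    return observations


def load_stays(stays_path):
    stays_df = pd.read_csv(stays_path)
    stays = [
        costing.StayEvent(
            patient_id=rec.patient_id,
            stay_type=rec.stay_type,
            admission_day=int(rec.admission_day),
            discharge_day=int(rec.discharge_day),
            complication_level=(
                None if pd.isna(rec.complication_level) else int(rec.complication_level)
            ),
            reason=None if pd.isna(rec.reason) else rec.reason,
        )
        for rec in stays_df.itertuples(index=False)
    ]
    return stays


def write_trial_files(patients, observations, stays, outdir) -> None:
    """Persist a simulated trial as the three patient-level CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    synthetic_trial.patients_frame(patients).to_csv(outdir / "patients.csv", index=False)
    synthetic_trial.observations_frame(observations).to_csv(outdir / "eq5d.csv", index=False)
    synthetic_trial.stays_frame(stays).to_csv(outdir / "stays.csv", index=False)
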