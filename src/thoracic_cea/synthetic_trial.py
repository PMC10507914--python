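"""Patient-level simulation of a two-arm surgical trial (VATS vs thoracotomy).

The generator emulates the statistical structure the downstream economic
analysis assumes: centre-stratified 1:1 block randomisation (blocks of 12),
EQ-5D-3L trajectories at four timepoints (pre-operative, day 3, day 30,
3 months) with configurable per-arm mean utilities, gamma-distributed initial
length of stay, rare re-hospitalisations / rehabilitation admissions / deaths
per follow-up window, visit-date jitter, and MCAR or MAR questionnaire
missingness.

Utility trajectories are generated by sampling a latent utility from a normal
distribution truncated to the tariff's achievable range and snapping it to the
nearest EQ-5D-3L state (ties broken toward the lexicographically smallest
state).  The latent mean is calibrated by root-finding so that the expected
value of the *discretised, truncated* draw equals the configured target mean —
a plain truncated normal centred on the target would undershoot it by up to
~0.1 near the ceiling of the scale.

All randomness flows from a single integer seed; each operation draws from its
own named substream so datasets are reproducible end-to-end and independent of
call order.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .costing import StayEvent, severity_level
from .utility import DIMENSIONS, TIMEPOINTS, EQ5DObservation, ValueSet, load_value_set

ARMS = ("VATS", "THORACOTOMY")

#: nominal day offsets of the four questionnaire administrations
NOMINAL_DAYS = {"preop": 0, "d3": 3, "d30": 30, "m3": 91}

PerArm = Union[float, Mapping[str, float]]


def _per_arm(x: PerArm) -> dict[str, float]:
    if isinstance(x, Mapping):
        return {a: float(x[a]) for a in ARMS}
    return {a: float(x) for a in ARMS}


def _default_utility_means() -> dict[str, dict[str, float]]:
    # per-arm, per-timepoint mean utilities of the trial the generator emulates
    return {
        "VATS": {"preop": 0.83, "d3": 0.66, "d30": 0.80, "m3": 0.79},
        "THORACOTOMY": {"preop": 0.78, "d3": 0.58, "d30": 0.74, "m3": 0.76},
    }


@dataclass
class TrialConfig:
    """Study-condition parameters of the simulated trial.

    Event probabilities are per follow-up window (surgery→d30 visit, d30→3-month
    visit) and may be a scalar (both arms) or a per-arm mapping.
    """

    seed: int
    n_per_arm: int = 130
    n_centres: int = 10
    block_size: int = 12
    utility_means: dict[str, dict[str, float]] = field(default_factory=_default_utility_means)
    utility_sd: float = 0.25
    los_mean: float = 7.2
    los_sd: float = 3.3
    rehosp_prob_30d: PerArm = field(
        default_factory=lambda: {"VATS": 0.0458, "THORACOTOMY": 0.0313}
    )
    rehosp_prob_3m: PerArm = field(
        default_factory=lambda: {"VATS": 0.0839, "THORACOTOMY": 0.0234}
    )
    rehab_prob_30d: PerArm = field(
        default_factory=lambda: {"VATS": 0.0687, "THORACOTOMY": 0.0625}
    )
    rehab_prob_3m: PerArm = field(default_factory=lambda: {"VATS": 0.0382, "THORACOTOMY": 0.0})
    death_prob_30d: PerArm = field(
        default_factory=lambda: {"VATS": 0.0076, "THORACOTOMY": 0.0078}
    )
    death_prob_3m: PerArm = 0.023
    missing_rate: Union[float, Mapping[str, float]] = field(
        default_factory=lambda: {"preop": 0.10, "d3": 0.17, "d30": 0.15, "m3": 0.27}
    )
    missing_mechanism: str = "MCAR"
    #: MAR deletion is logistic in arm and (centred) pre-operative utility
    mar_arm_coef: float = 0.3
    mar_utility_coef: float = -2.0
    visit_jitter_sd: float = 4.0
    late_visit_prob: float = 0.02
    undated_visit_prob: float = 0.01

    def __post_init__(self) -> None:
        if self.n_per_arm <= 0:
            raise ValueError("n_per_arm must be positive")
        if self.n_centres < 1:
            raise ValueError("need at least one centre")
        if self.block_size % 2 != 0:
            raise ValueError("block size must be even for 1:1 allocation")
        if self.los_mean <= 0 or self.los_sd < 0:
            raise ValueError("LOS parameters must be non-negative (mean positive)")
        for name in (
            "rehosp_prob_30d",
            "rehosp_prob_3m",
            "rehab_prob_30d",
            "rehab_prob_3m",
            "death_prob_30d",
            "death_prob_3m",
        ):
            for arm, p in _per_arm(getattr(self, name)).items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{arm}] outside [0,1]")
        for tp, r in self.missing_rates().items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missing rate for {tp} outside [0,1]")
        if self.missing_mechanism not in ("MCAR", "MAR"):
            raise ValueError("missing_mechanism must be MCAR or MAR")

    def missing_rates(self) -> dict[str, float]:
        if isinstance(self.missing_rate, Mapping):
            return {tp: float(self.missing_rate[tp]) for tp in TIMEPOINTS}
        return {tp: float(self.missing_rate) for tp in TIMEPOINTS}


@dataclass
class PatientRecord:
    """One randomised participant.  Day offsets count from surgery (day 0)."""

    patient_id: str
    centre_id: int
    arm: str
    age: float
    sex: str
    bmi: float
    performance_status: int
    smoking: str
    d30_visit_day: Optional[int]
    m3_visit_day: Optional[int]
    death_day: Optional[int] = None


def _stream(config: TrialConfig, label: int) -> np.random.Generator:
    """Named substream of the trial's root seed."""
    return np.random.default_rng(np.random.SeedSequence((int(config.seed), label)))


_ALLOC, _COVAR, _EVENTS, _EQ5D, _RESOURCE, _MISSING = range(6)


def generate_trial(config: TrialConfig) -> list[PatientRecord]:
    """Generate the randomised cohort.

    Patients are spread across centres as evenly as possible; within each
    centre, arms are allocated in shuffled blocks (half per arm), so every
    completed block is exactly balanced and per-centre imbalance never exceeds
    half a block.
    """
    rng = _stream(config, _ALLOC)
    total = 2 * config.n_per_arm
    base, extra = divmod(total, config.n_centres)
    centre_sizes = [base + (1 if c < extra else 0) for c in range(config.n_centres)]
    half = config.block_size // 2
    allocation: list[tuple[int, str]] = []
    for centre, size in enumerate(centre_sizes, start=1):
        seq: list[str] = []
        while len(seq) < size:
            block = ["VATS"] * half + ["THORACOTOMY"] * half
            rng.shuffle(block)
            seq.extend(block)
        allocation.extend((centre, arm) for arm in seq[:size])

    cov = _stream(config, _COVAR)
    ev = _stream(config, _EVENTS)
    death_30 = _per_arm(config.death_prob_30d)
    death_3m = _per_arm(config.death_prob_3m)
    patients: list[PatientRecord] = []
    for i, (centre, arm) in enumerate(allocation, start=1):
        age = float(np.clip(cov.normal(64.5, 9.3), 18, 90))
        sex = "M" if cov.random() < 0.61 else "F"
        bmi = float(np.clip(cov.normal(26.6, 5.0), 15, 50))
        ps = int(cov.random() < 0.29)
        smoking = ["smoker", "ex-smoker", "non-smoker"][
            int(cov.choice(3, p=[0.30, 0.52, 0.18]))
        ]
        death_day: Optional[int] = None
        if ev.random() < death_30[arm]:
            death_day = int(ev.integers(1, 30))
        elif ev.random() < death_3m[arm]:
            death_day = int(ev.integers(31, 91))

        d30_day = _visit_day(ev, config, nominal=30)
        m3_day = _visit_day(ev, config, nominal=91)
        if d30_day is not None and m3_day is not None and m3_day <= d30_day + 14:
            m3_day = d30_day + 15  # keep the visit calendar strictly ordered
        if death_day is not None:
            if d30_day is None or death_day <= d30_day:
                d30_day = None
            if m3_day is None or death_day <= m3_day:
                m3_day = None
        patients.append(
            PatientRecord(
                patient_id=f"P{i:04d}",
                centre_id=centre,
                arm=arm,
                age=round(age, 1),
                sex=sex,
                bmi=round(bmi, 1),
                performance_status=ps,
                smoking=smoking,
                d30_visit_day=d30_day,
                m3_visit_day=m3_day,
                death_day=death_day,
            )
        )
    return patients


def _visit_day(rng: np.random.Generator, config: TrialConfig, nominal: int) -> Optional[int]:
    if rng.random() < config.undated_visit_prob:
        return None
    if rng.random() < config.late_visit_prob:
        offset = int(rng.integers(15, 41)) * (1 if rng.random() < 0.5 else -1)
    else:
        offset = int(round(rng.normal(0.0, config.visit_jitter_sd)))
    return max(1, nominal + offset)


# ---------------------------------------------------------------------------
# EQ-5D trajectory simulation


def _calibrate_latent_mean(
    target: float, sd: float, values: np.ndarray
) -> float:
    """Latent normal mean whose truncated-then-discretised expectation equals
    ``target``.

    ``values`` are the distinct achievable tariff utilities (ascending).  The
    latent draw is truncated to [floor, 1] and snapped to the nearest value, so
    the expectation is a smooth, strictly increasing function of the latent
    mean; solve it by bisection.
    """
    floor, ceil = float(values[0]), float(values[-1])
    if sd == 0.0:
        if not floor <= target <= ceil:
            raise ValueError(f"target mean {target} outside tariff range [{floor}, {ceil}]")
        return float(target)
    if not floor < target < ceil:
        raise ValueError(f"target mean {target} outside achievable open range ({floor}, {ceil})")
    mids = (values[:-1] + values[1:]) / 2.0
    edges = np.concatenate(([floor], mids, [ceil]))

    def expected(mu: float) -> float:
        cdf = stats.norm.cdf((edges - mu) / sd)
        z = cdf[-1] - cdf[0]
        if z <= 0:
            return ceil if mu > target else floor
        return float(np.dot(np.diff(cdf), values) / z)

    lo, hi = floor - 8 * sd, ceil + 8 * sd
    return float(optimize.brentq(lambda m: expected(m) - target, lo, hi, xtol=1e-10))


def _snap_to_states(
    latent: np.ndarray, values: np.ndarray, states: Sequence[tuple[int, ...]]
) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    mids = (values[:-1] + values[1:]) / 2.0
    idx = np.searchsorted(mids, latent)
    return values[idx], [states[i] for i in idx]


def simulate_eq5d(
    patients: Sequence[PatientRecord],
    config: TrialConfig,
    value_set: Optional[ValueSet] = None,
) -> list[EQ5DObservation]:
    """EQ-5D-3L item responses at the four timepoints for every patient alive
    (and not yet censored by death) at that timepoint."""
    value_set = value_set or load_value_set()
    values, states = value_set.state_table()
    floor, ceil = float(values[0]), float(values[-1])
    sd = float(config.utility_sd)
    latent_means = {
        (arm, tp): _calibrate_latent_mean(config.utility_means[arm][tp], sd, values)
        for arm in ARMS
        for tp in TIMEPOINTS
    }
    rng = _stream(config, _EQ5D)
    observations: list[EQ5DObservation] = []
    for p in patients:
        for tp in TIMEPOINTS:
            day = _observation_day(p, tp)
            if day is None:
                continue
            mu = latent_means[(p.arm, tp)]
            if sd == 0.0:
                latent = np.array([mu])
            else:
                a, b = (floor - mu) / sd, (ceil - mu) / sd
                latent = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=1, random_state=rng)
            util, state = _snap_to_states(latent, values, states)
            observations.append(
                EQ5DObservation(
                    patient_id=p.patient_id,
                    timepoint=tp,
                    day=day,
                    levels=tuple(state[0]),
                    utility=float(util[0]),
                )
            )
    return observations


def _observation_day(p: PatientRecord, tp: str) -> Optional[int]:
    """Day the questionnaire is administered, or None if censored/undated."""
    if tp == "preop":
        day = 0
    elif tp == "d3":
        day = 3
    elif tp == "d30":
        if p.d30_visit_day is None:
            return None
        day = p.d30_visit_day
    else:
        if p.m3_visit_day is None:
            return None
        day = p.m3_visit_day
    if p.death_day is not None and day >= p.death_day:
        return None
    return day


# ---------------------------------------------------------------------------
# Resource use


_REHOSP_REASONS = (
    "respiratory_complication",
    "pleural_effusion",
    "reintervention",
    "cardiac",
    "other",
    "unclassifiable",  # no DRG rule: exercises the uncostable-stay path
)
_REHOSP_REASON_P = (0.35, 0.20, 0.15, 0.10, 0.15, 0.05)


def simulate_resource_use(
    patients: Sequence[PatientRecord], config: TrialConfig
) -> list[StayEvent]:
    """Hospital episodes: one initial stay per patient plus window-wise
    re-hospitalisation and rehabilitation events, censored at death."""
    rng = _stream(config, _RESOURCE)
    rehosp = {"30d": _per_arm(config.rehosp_prob_30d), "3m": _per_arm(config.rehosp_prob_3m)}
    rehab = {"30d": _per_arm(config.rehab_prob_30d), "3m": _per_arm(config.rehab_prob_3m)}
    stays: list[StayEvent] = []
    for p in patients:
        los = _draw_los(rng, config.los_mean, config.los_sd)
        major = rng.random() < 0.12
        reint = rng.random() < 0.04
        prolonged = los > config.los_mean + 2 * config.los_sd
        level = severity_level(major, reint, prolonged)
        discharge = los - 1  # admitted the day before surgery
        if p.death_day is not None:
            discharge = min(discharge, p.death_day)
        stays.append(
            StayEvent(
                patient_id=p.patient_id,
                stay_type="initial",
                admission_day=-1,
                discharge_day=discharge,
                complication_level=level,
            )
        )
        d30 = p.d30_visit_day if p.d30_visit_day is not None else 30
        m3 = p.m3_visit_day if p.m3_visit_day is not None else 91
        for window, (lo, hi) in (("30d", (discharge, d30)), ("3m", (d30, m3))):
            limit = hi if p.death_day is None else min(hi, p.death_day - 1)
            if limit <= lo:
                continue
            if rng.random() < rehosp[window][p.arm]:
                adm = int(rng.integers(lo + 1, limit + 1))
                ev_los = _draw_los(rng, 5.0, 3.0)
                reason = _REHOSP_REASONS[int(rng.choice(len(_REHOSP_REASONS), p=_REHOSP_REASON_P))]
                stays.append(
                    StayEvent(
                        patient_id=p.patient_id,
                        stay_type="rehospitalisation",
                        admission_day=adm,
                        discharge_day=adm + ev_los,
                        reason=reason,
                    )
                )
            if rng.random() < rehab[window][p.arm]:
                adm = int(rng.integers(lo + 1, limit + 1))
                stays.append(
                    StayEvent(
                        patient_id=p.patient_id,
                        stay_type="rehabilitation",
                        admission_day=adm,
                        discharge_day=adm + _draw_los(rng, 20.0, 8.0),
                    )
                )
    return stays


def _draw_los(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Whole-day LOS: gamma with the given mean/sd, rounded up, minimum 1."""
    if sd == 0.0:
        return max(1, math.ceil(mean))
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return max(1, math.ceil(rng.gamma(shape, scale)))


# ---------------------------------------------------------------------------
# Missingness


def apply_missingness(
    observations: Sequence[EQ5DObservation],
    config: TrialConfig,
    patients: Optional[Sequence[PatientRecord]] = None,
) -> list[EQ5DObservation]:
    """Delete whole questionnaire records with the configured per-timepoint
    probability.

    MCAR deletes each record independently.  MAR makes the deletion
    probability of *post-operative* records logistic in arm and the patient's
    centred pre-operative utility (requires ``patients``); pre-operative
    records stay MCAR.
    """
    rng = _stream(config, _MISSING)
    rates = config.missing_rates()
    preop_u = {o.patient_id: o.utility for o in observations if o.timepoint == "preop"}
    arm_of = {p.patient_id: p.arm for p in patients} if patients is not None else {}
    if config.missing_mechanism == "MAR" and patients is None:
        raise ValueError("MAR missingness needs the patient records")
    out: list[EQ5DObservation] = []
    for o in observations:
        rate = rates[o.timepoint]
        if config.missing_mechanism == "MAR" and o.timepoint != "preop":
            logit = math.log(rate / (1 - rate)) if 0 < rate < 1 else (-30 if rate == 0 else 30)
            logit += config.mar_arm_coef * (arm_of.get(o.patient_id) == "VATS")
            u0 = preop_u.get(o.patient_id)
            if u0 is not None:
                logit += config.mar_utility_coef * (u0 - 0.8)
            rate = 1.0 / (1.0 + math.exp(-logit))
        if rng.random() < rate:
            out.append(replace(o, levels=(None,) * len(DIMENSIONS), utility=None))
        else:
            out.append(replace(o))
    return out


# ---------------------------------------------------------------------------
# Tabular export


def patients_frame(patients: Iterable[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": p.patient_id,
            "centre_id": p.centre_id,
            "arm": p.arm,
            "age": p.age,
            "sex": p.sex,
            "bmi": p.bmi,
            "performance_status": p.performance_status,
            "smoking": p.smoking,
            "d30_visit_day": p.d30_visit_day,
            "m3_visit_day": p.m3_visit_day,
            "death_day": p.death_day,
        }
        for p in patients
    )


def observations_frame(observations: Iterable[EQ5DObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": o.patient_id,
            "timepoint": o.timepoint,
            "day": o.day,
            **{dim: o.levels[i] for i, dim in enumerate(DIMENSIONS)},
            "utility": o.utility,
        }
        for o in observations
    )


def stays_frame(stays: Iterable[StayEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": s.patient_id,
            "stay_type": s.stay_type,
            "admission_day": s.admission_day,
            "discharge_day": s.discharge_day,
            "los": s.los,
            "complication_level": s.complication_level,
            "reason": s.reason,
            "drg_code": s.drg_code,
            "cost": float(s.cost) if s.cost is not None else None,
        }
        for s in stays
    )
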