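"""EQ-5D-3L utility scoring and interval-weighted QALY outcomes.

The EQ-5D-3L describes a health state as five ordinal items (mobility,
self-care, usual activities, pain/discomfort, anxiety/depression), each at
level 1 (no problems), 2 (some problems) or 3 (extreme problems).  A national
*value set* (tariff) maps each of the 243 states to a utility index anchored
at 1 for full health (state 11111) and allowed to go below 0 for states worse
than death.  Additive TTO tariffs of the kind bundled here score a state as

    u = 1 - c - sum(decrement[dim, level]) - n3 * [any item at level 3]

where the constant ``c`` applies to any departure from full health.

QALYs over a horizon are the trapezoidal area under the utility-versus-time
curve, divided by the horizon length, i.e. a time-weighted average utility.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from itertools import product
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

TIMEPOINTS = ("preop", "d3", "d30", "m3")

#: nominal horizon day for each analysis horizon
HORIZON_DAYS = {"d30": 30, "m3": 91}

#: timepoints whose utilities must be observed for each horizon
HORIZON_TIMEPOINTS = {"d30": ("preop", "d3", "d30"), "m3": ("preop", "d3", "d30", "m3")}


class IncompleteObservationError(ValueError):
    """Raised when a state is scored with one or more items missing."""


@dataclass(frozen=True)
class ValueSet:
    """An additive EQ-5D-3L tariff.

    Parameters
    ----------
    name
        Identifier of the value set (e.g. ``"uk_tto"``).
    constant
        Decrement applied once for any departure from full health.
    decrements
        Mapping ``(dimension, level) -> decrement`` for levels 2 and 3.
    any_level3
        Additional decrement applied once if any item is at level 3.
    """

    name: str
    constant: float
    decrements: Mapping[tuple[str, int], float]
    any_level3: float = 0.0

    def __post_init__(self) -> None:
        for (dim, level), dec in self.decrements.items():
            if dim not in DIMENSIONS:
                raise ValueError(f"unknown dimension {dim!r}")
            if level not in (2, 3):
                raise ValueError(f"decrements are keyed on levels 2/3, got {level}")
            if dec < 0:
                raise ValueError("decrements must be non-negative")

    @property
    def floor(self) -> float:
        """Utility of the worst state 33333 (minimum achievable value)."""
        return self.score((3, 3, 3, 3, 3))

    def score(self, levels: Sequence[Optional[int]]) -> float:
        """Score one 5-tuple of item levels; full health scores exactly 1."""
        return score_eq5d(levels, self)

    def all_states(self) -> list[tuple[int, ...]]:
        """All 243 states in lexicographic order."""
        return list(product((1, 2, 3), repeat=5))

    def state_table(self) -> tuple[np.ndarray, list[tuple[int, ...]]]:
        """Distinct achievable utilities, ascending, with for each value the
        lexicographically smallest state attaining it (the nearest-state
        mapping tie-break used by the trial simulator)."""
        best: dict[float, tuple[int, ...]] = {}
        for state in self.all_states():
            v = round(self.score(state), 10)
            if v not in best:  # lexicographic order of iteration -> first wins
                best[v] = state
        values = np.array(sorted(best), dtype=float)
        return values, [best[v] for v in values]

    @classmethod
    def from_csv(cls, path, name: Optional[str] = None) -> "ValueSet":
        """Load a tariff from a ``term,value`` CSV.

        Recognised terms: ``constant``, ``any_level3`` and ``<dimension>_<level>``
        for each dimension at levels 2 and 3.
        """
        constant = 0.0
        any3 = 0.0
        decs: dict[tuple[str, int], float] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                term, value = row["term"].strip(), float(row["value"])
                if term == "constant":
                    constant = value
                elif term == "any_level3":
                    any3 = value
                else:
                    dim, _, level = term.rpartition("_")
                    decs[(dim, int(level))] = value
        return cls(name=name or str(path), constant=constant, decrements=decs, any_level3=any3)


def load_value_set(name: str = "uk_tto") -> ValueSet:
    """Load a bundled tariff.  ``uk_tto`` is the UK MVH time-trade-off set."""
    ref = resources.files("thoracic_cea.data") / f"eq5d3l_{name}.csv"
    with resources.as_file(ref) as path:
        return ValueSet.from_csv(path, name=name)


def score_eq5d(levels: Sequence[Optional[int]], value_set: ValueSet) -> float:
    """Score a 5-tuple of EQ-5D-3L item levels with ``value_set``.

    Raises
    ------
    IncompleteObservationError
        If any item is missing (the observation cannot be scored).
    ValueError
        If a level is outside {1, 2, 3}.
    """
    if len(levels) != len(DIMENSIONS):
        raise ValueError(f"expected {len(DIMENSIONS)} levels, got {len(levels)}")
    clean: list[int] = []
    for dim, level in zip(DIMENSIONS, levels):
        if level is None or (isinstance(level, float) and np.isnan(level)):
            raise IncompleteObservationError(f"missing level for {dim}")
        level = int(level)
        if level not in (1, 2, 3):
            raise ValueError(f"{dim} level must be in {{1,2,3}}, got {level}")
        clean.append(level)
    if all(l == 1 for l in clean):
        return 1.0
    u = 1.0 - value_set.constant
    for dim, level in zip(DIMENSIONS, clean):
        if level >= 2:
            u -= value_set.decrements.get((dim, level), 0.0)
    if any(l == 3 for l in clean):
        u -= value_set.any_level3
    return u


@dataclass
class EQ5DObservation:
    """One questionnaire administration for one patient.

    ``levels`` may contain ``None`` entries (item-level missingness); ``utility``
    is present iff all five levels are.  ``day`` is the day offset from surgery.
    """

    patient_id: str
    timepoint: str
    day: int
    levels: tuple[Optional[int], ...]
    utility: Optional[float] = None

    @property
    def complete(self) -> bool:
        return all(l is not None for l in self.levels)


@dataclass
class QALYOutcome:
    patient_id: str
    horizon: str
    qaly: Optional[float]
    complete: bool


def _trapezoid_to_horizon(days: np.ndarray, utils: np.ndarray, horizon_day: float) -> float:
    """Trapezoidal AUC from day 0 to ``horizon_day`` divided by the horizon.

    The curve is linear between observations; beyond the last observation it is
    extended flat, and an observation past the horizon is truncated by linear
    interpolation at the horizon.
    """
    if days[-1] < horizon_day:
        days = np.append(days, horizon_day)
        utils = np.append(utils, utils[-1])
    grid = np.append(days[days < horizon_day], horizon_day)
    vals = np.interp(grid, days, utils)
    return float(np.trapezoid(vals, grid) / horizon_day)


def qaly_auc(
    observations: Iterable[EQ5DObservation],
    horizon: str,
    *,
    horizon_day: Optional[int] = None,
    year_scale: bool = False,
) -> QALYOutcome:
    """Interval-weighted QALY for one patient at a horizon (``"d30"``/``"m3"``).

    The pre-operative observation is anchored at day 0 (surgery); subsequent
    observations sit at their actual day offsets.  The result is the trapezoidal
    area under utility-versus-day from day 0 to the nominal horizon day divided
    by the horizon length — a time-weighted average utility on the QALY scale
    the source tables use.  With ``year_scale`` the area is instead expressed in
    year-denominated QALYs (multiplied by horizon/365.25).

    If any required timepoint utility is absent the outcome is marked
    incomplete and carries no value.
    """
    if horizon not in HORIZON_DAYS:
        raise ValueError(f"horizon must be one of {sorted(HORIZON_DAYS)}")
    h_day = HORIZON_DAYS[horizon] if horizon_day is None else horizon_day
    obs = {o.timepoint: o for o in observations}
    pid = next(iter(obs.values())).patient_id if obs else ""
    required = HORIZON_TIMEPOINTS[horizon]
    if any(tp not in obs or obs[tp].utility is None for tp in required):
        return QALYOutcome(patient_id=pid, horizon=horizon, qaly=None, complete=False)
    points = sorted(
        ((0 if tp == "preop" else obs[tp].day, obs[tp].utility) for tp in required),
        key=lambda p: p[0],
    )
    days = np.array([p[0] for p in points], dtype=float)
    utils = np.array([p[1] for p in points], dtype=float)
    # collapse duplicate days (e.g. a d3 visit recorded on day 0): keep the mean
    if len(np.unique(days)) != len(days):
        uniq = np.unique(days)
        utils = np.array([utils[days == d].mean() for d in uniq])
        days = uniq
    q = _trapezoid_to_horizon(days, utils, float(h_day))
    if year_scale:
        q *= h_day / 365.25
    return QALYOutcome(patient_id=pid, horizon=horizon, qaly=q, complete=True)
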