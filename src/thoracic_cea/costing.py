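"""Hospital costing of trial stays in 2018 euros.

Costs take the hospital production-cost perspective.  Every stay is assigned a
diagnosis-related group (DRG) and valued against a national cost-per-DRG
catalog (production cost, operating-room component, national mean LOS).

The *adjusted-DRG* method applies to initial (surgical) stays: the catalog's
operating-room component is replaced with the micro-costed theatre cost of the
actual procedure (VATS or thoracotomy), and the remainder of the stay is
reconstituted as a per-diem — (total − operating room) / national mean LOS —
multiplied by the patient's own length of stay.  Follow-up stays are
gross-costed: re-hospitalisations at the catalog total (optionally
LOS-prorated), rehabilitation admissions at the flat cost of their single DRG.

All monetary arithmetic is carried out in exact decimal cents; rounding to
whole euros happens only at reporting.
"""
from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from typing import Iterable, Mapping, Optional, Union

CENT = Decimal("0.01")

#: DRG root shared by all initial stays; severity digit 1-4 is appended
INITIAL_STAY_DRG_ROOT = "04C02"
#: single DRG used for every rehabilitation admission
REHABILITATION_DRG = "0403B1"

Number = Union[int, float, str, Decimal]


def _dec(x: Number) -> Decimal:
    if isinstance(x, Decimal):
        return x
    return Decimal(str(x))


class MissingCatalogEntryError(KeyError):
    pass


class UncostableStayError(ValueError):
    """A stay whose DRG cannot be determined or valued (excluded with warning)."""


@dataclass(frozen=True)
class DRGCatalogEntry:
    drg_code: str
    label: str
    total_cost: Decimal
    operating_room_cost: Decimal
    national_mean_los: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "total_cost", _dec(self.total_cost))
        object.__setattr__(self, "operating_room_cost", _dec(self.operating_room_cost))
        if not self.total_cost >= self.operating_room_cost >= 0:
            raise ValueError(f"{self.drg_code}: need total >= operating room >= 0")
        if self.national_mean_los <= 0:
            raise ValueError(f"{self.drg_code}: national mean LOS must be > 0")

    @property
    def daily_cost(self) -> Decimal:
        """Per-diem of the stay remainder: (total − OR) / national mean LOS."""
        return (self.total_cost - self.operating_room_cost) / _dec(self.national_mean_los)


class DRGCatalog:
    """Cost-per-DRG lookup table."""

    def __init__(self, entries: Iterable[DRGCatalogEntry]):
        self._entries = {e.drg_code: e for e in entries}

    def __getitem__(self, code: str) -> DRGCatalogEntry:
        try:
            return self._entries[code]
        except KeyError:
            raise MissingCatalogEntryError(code) from None

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    @classmethod
    def from_csv(cls, path) -> "DRGCatalog":
        with open(path, newline="") as fh:
            return cls(
                DRGCatalogEntry(
                    drg_code=row["drg_code"],
                    label=row["label"],
                    total_cost=_dec(row["total_cost"]),
                    operating_room_cost=_dec(row["operating_room_cost"]),
                    national_mean_los=float(row["national_mean_los"]),
                )
                for row in csv.DictReader(fh)
            )

    @classmethod
    def load_default(cls) -> "DRGCatalog":
        """Bundled catalog.  The rehabilitation DRG total (6222.20 €) is the
        published flat cost; the surgical and re-hospitalisation entries are
        synthetic stand-ins calibrated to realistic magnitudes."""
        ref = resources.files("thoracic_cea.data") / "drg_catalog_synthetic.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


@dataclass(frozen=True)
class SurgeryCostTable:
    """Micro-costed theatre costs (€2018) substituted into initial stays."""

    vats_cost: Decimal = Decimal("3870.49")
    thoracotomy_cost: Decimal = Decimal("2455.58")

    def __post_init__(self) -> None:
        object.__setattr__(self, "vats_cost", _dec(self.vats_cost))
        object.__setattr__(self, "thoracotomy_cost", _dec(self.thoracotomy_cost))
        if self.vats_cost <= 0 or self.thoracotomy_cost <= 0:
            raise ValueError("surgery costs must be positive")

    def cost_for(self, arm: str) -> Decimal:
        arm = arm.upper()
        if arm == "VATS":
            return self.vats_cost
        if arm == "THORACOTOMY":
            return self.thoracotomy_cost
        raise ValueError(f"unknown arm {arm!r}")


class CPIIndex:
    """Harmonised consumer price index series (base 100), hospital services."""

    def __init__(self, values: Mapping[int, Number]):
        self._values = {int(y): _dec(v) for y, v in values.items()}
        if any(v <= 0 for v in self._values.values()):
            raise ValueError("CPI index values must be positive")

    def __getitem__(self, year: int) -> Decimal:
        try:
            return self._values[int(year)]
        except KeyError:
            raise KeyError(f"year {year} not in CPI index") from None

    @classmethod
    def from_csv(cls, path) -> "CPIIndex":
        with open(path, newline="") as fh:
            return cls({int(r["year"]): r["index"] for r in csv.DictReader(fh)})

    @classmethod
    def load_default(cls) -> "CPIIndex":
        """Bundled synthetic stand-in series, base 100 in 2015."""
        ref = resources.files("thoracic_cea.data") / "cpi_hospital_services_synthetic.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


@dataclass
class StayEvent:
    """One hospital episode.  Day offsets count from surgery (day 0)."""

    patient_id: str
    stay_type: str  # initial | rehospitalisation | rehabilitation
    admission_day: int
    discharge_day: int
    complication_level: Optional[int] = None
    reason: Optional[str] = None
    drg_code: Optional[str] = None
    cost: Optional[Decimal] = None

    def __post_init__(self) -> None:
        if self.discharge_day < self.admission_day:
            raise ValueError("discharge before admission")
        if self.stay_type == "initial" and not (self.admission_day <= 0 <= self.discharge_day):
            raise ValueError("initial stay must span surgery (day 0)")

    @property
    def los(self) -> int:
        return self.discharge_day - self.admission_day


def severity_level(
    major_complication: bool, reintervention: bool, prolonged_stay: bool
) -> int:
    """DRG severity digit for an initial stay: 1 plus one per adverse feature,
    capped at 4."""
    return min(4, 1 + int(major_complication) + int(reintervention) + int(prolonged_stay))


class RehospRules:
    """Admission-reason → DRG rule table for re-hospitalisations."""

    def __init__(self, mapping: Mapping[str, str]):
        self._map = dict(mapping)

    def __getitem__(self, reason: str) -> str:
        try:
            return self._map[reason]
        except KeyError:
            raise UncostableStayError(
                f"no DRG rule for re-hospitalisation reason {reason!r}"
            ) from None

    def __contains__(self, reason: str) -> bool:
        return reason in self._map

    @classmethod
    def from_csv(cls, path) -> "RehospRules":
        with open(path, newline="") as fh:
            return cls({r["reason"]: r["drg_code"] for r in csv.DictReader(fh)})

    @classmethod
    def load_default(cls) -> "RehospRules":
        ref = resources.files("thoracic_cea.data") / "rehosp_drg_rules.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


def inflate_cost(amount: Number, year_from: int, year_to: int, cpi: CPIIndex) -> Decimal:
    """Update ``amount`` from ``year_from`` euros to ``year_to`` euros with the
    CPI ratio, to the cent."""
    result = _dec(amount) * cpi[year_to] / cpi[year_from]
    return result.quantize(CENT, rounding=ROUND_HALF_UP)


def assign_drg(stay: StayEvent, rules: Optional[RehospRules] = None) -> str:
    """DRG code for a stay.

    Initial stays share one surgical DRG root with a severity digit from the
    complication level; rehabilitation stays all map to one DRG; a
    re-hospitalisation maps through the reason rule table, and a reason with no
    rule signals an uncostable stay.
    """
    if stay.stay_type == "initial":
        if stay.complication_level not in (1, 2, 3, 4):
            raise ValueError("initial stay needs a complication level in 1..4")
        return f"{INITIAL_STAY_DRG_ROOT}{stay.complication_level}"
    if stay.stay_type == "rehabilitation":
        return REHABILITATION_DRG
    if stay.stay_type == "rehospitalisation":
        rules = RehospRules.load_default() if rules is None else rules
        if stay.reason is None:
            raise UncostableStayError("re-hospitalisation without admission reason")
        return rules[stay.reason]
    raise ValueError(f"unknown stay type {stay.stay_type!r}")


def adjusted_drg_cost(
    stay: StayEvent,
    entry: DRGCatalogEntry,
    surgery: SurgeryCostTable,
    arm: str,
) -> Decimal:
    """Adjusted-DRG cost of an initial stay: micro-costed theatre cost of the
    arm's procedure plus the catalog per-diem times the patient's LOS."""
    if stay.stay_type != "initial":
        raise ValueError("adjusted-DRG costing applies to initial stays only")
    cost = surgery.cost_for(arm) + entry.daily_cost * _dec(stay.los)
    return cost.quantize(CENT, rounding=ROUND_HALF_UP)


def standard_drg_cost(
    stay: StayEvent, entry: DRGCatalogEntry, *, prorate_los: bool = False
) -> Decimal:
    """Gross cost of a follow-up stay.

    Rehabilitation stays carry the flat cost of their single DRG.
    Re-hospitalisations default to the catalog total; with ``prorate_los`` the
    catalog per-diem is applied to the patient's own LOS instead.
    """
    if stay.stay_type == "rehabilitation":
        return entry.total_cost.quantize(CENT, rounding=ROUND_HALF_UP)
    if stay.stay_type == "rehospitalisation":
        if prorate_los:
            cost = entry.daily_cost * _dec(stay.los)
        else:
            cost = entry.total_cost
        return cost.quantize(CENT, rounding=ROUND_HALF_UP)
    raise ValueError("standard costing applies to follow-up stays only")


def cost_stays(
    stays: Iterable[StayEvent],
    catalog: DRGCatalog,
    surgery: SurgeryCostTable,
    arm_by_patient: Mapping[str, str],
    rules: Optional[RehospRules] = None,
    *,
    prorate_los: bool = False,
) -> list[StayEvent]:
    """Assign DRGs and costs in place for a collection of stays.

    Uncostable stays (no DRG rule match) keep ``cost=None`` and raise a
    warning; downstream cumulative sums exclude them.
    """
    rules = RehospRules.load_default() if rules is None else rules
    out = list(stays)
    for stay in out:
        try:
            stay.drg_code = assign_drg(stay, rules)
        except UncostableStayError as exc:
            warnings.warn(
                f"stay for patient {stay.patient_id} could not be costed: {exc}",
                stacklevel=2,
            )
            stay.drg_code = None
            stay.cost = None
            continue
        entry = catalog[stay.drg_code]
        if stay.stay_type == "initial":
            stay.cost = adjusted_drg_cost(stay, entry, surgery, arm_by_patient[stay.patient_id])
        else:
            stay.cost = standard_drg_cost(stay, entry, prorate_los=prorate_los)
    return out


def cumulative_costs(
    patient_id: str,
    stays: Iterable[StayEvent],
    horizon: str,
    *,
    d30_visit_day: Optional[int] = None,
    m3_visit_day: Optional[int] = None,
) -> Decimal:
    """Cumulative hospital cost for one patient at a horizon.

    The 30-day figure sums the initial stay plus every follow-up stay admitted
    in the half-open window (initial discharge, d30 visit]; the 3-month figure
    adds follow-up stays admitted in (d30 visit, m3 visit].  Visit days default
    to the nominal 30/91 when undated.  Uncosted stays inside a window are
    excluded with a warning.
    """
    if horizon not in ("d30", "m3"):
        raise ValueError("horizon must be 'd30' or 'm3'")
    d30 = 30 if d30_visit_day is None else d30_visit_day
    m3 = 91 if m3_visit_day is None else m3_visit_day
    own = [s for s in stays if s.patient_id == patient_id]
    initial = [s for s in own if s.stay_type == "initial"]
    if len(initial) != 1:
        raise ValueError(f"patient {patient_id}: expected exactly one initial stay")
    if initial[0].cost is None:
        raise ValueError(f"patient {patient_id}: initial stay is uncosted")
    total = initial[0].cost
    cutoff = d30 if horizon == "d30" else m3
    lower = initial[0].discharge_day
    for s in own:
        if s.stay_type == "initial":
            continue
        if lower < s.admission_day <= cutoff:
            if s.cost is None:
                warnings.warn(
                    f"uncosted stay for patient {patient_id} inside {horizon} window; excluded",
                    stacklevel=2,
                )
                continue
            total += s.cost
    return total.quantize(CENT, rounding=ROUND_HALF_UP)


def to_euros(amount: Decimal) -> int:
    """Report a decimal amount as whole euros (half-up)."""
    return int(amount.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
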