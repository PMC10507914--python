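"""DRG costing: inflation, assignment, adjusted-DRG method, cumulative sums."""
from decimal import Decimal

import pytest

from thoracic_cea.costing import (
    CPIIndex,
    DRGCatalog,
    DRGCatalogEntry,
    MissingCatalogEntryError,
    StayEvent,
    SurgeryCostTable,
    UncostableStayError,
    adjusted_drg_cost,
    assign_drg,
    cost_stays,
    cumulative_costs,
    inflate_cost,
    severity_level,
    standard_drg_cost,
    to_euros,
)


def _initial(pid="p1", adm=-1, dis=6, level=1):
    return StayEvent(pid, "initial", adm, dis, complication_level=level)


class TestInflation:
    def test_identity_year(self):
        cpi = CPIIndex({2015: 100, 2018: 101.4})
        assert inflate_cost(100, 2015, 2015, cpi) == Decimal("100.00")

    def test_base_100_ratio(self):
        cpi = CPIIndex({2015: 100, 2017: 102})
        assert inflate_cost(100, 2015, 2017, cpi) == Decimal("102.00")

    def test_hand_ratio_product(self):
        # oracle: 2455.58 * (101.40/100.30) computed by hand arithmetic
        cpi = CPIIndex({2016: "100.30", 2018: "101.40"})
        expected = (Decimal("2455.58") * Decimal("101.40") / Decimal("100.30")).quantize(
            Decimal("0.01")
        )
        assert inflate_cost("2455.58", 2016, 2018, cpi) == expected

    def test_missing_year_raises(self):
        cpi = CPIIndex({2015: 100})
        with pytest.raises(KeyError):
            inflate_cost(100, 2015, 2019, cpi)


class TestAssignment:
    def test_initial_stay_severity_digit(self):
        for level in (1, 2, 3, 4):
            assert assign_drg(_initial(level=level)) == f"04C02{level}"

    def test_rehabilitation_single_drg(self):
        stay = StayEvent("p", "rehabilitation", 10, 30)
        assert assign_drg(stay) == "0403B1"

    def test_rehosp_rule_table(self, rules):
        stay = StayEvent("p", "rehospitalisation", 12, 18, reason="pleural_effusion")
        assert assign_drg(stay, rules) == "04M132"

    def test_unmatched_reason_is_uncostable(self, rules):
        stay = StayEvent("p", "rehospitalisation", 12, 18, reason="unclassifiable")
        with pytest.raises(UncostableStayError):
            assign_drg(stay, rules)

    def test_severity_level_rule(self):
        assert severity_level(False, False, False) == 1
        assert severity_level(True, False, True) == 3
        assert severity_level(True, True, True) == 4


class TestAdjustedDRG:
    entry = DRGCatalogEntry("04C021", "lvl1", Decimal("9000"), Decimal("2000"), 7.0)
    surgery = SurgeryCostTable()

    def test_hand_arithmetic(self):
        # 2455.58 + (9000-2000)/7 * 7 = 9455.58
        stay = _initial(adm=-1, dis=6)  # los 7
        cost = adjusted_drg_cost(stay, self.entry, self.surgery, "THORACOTOMY")
        assert cost == Decimal("9455.58")

    def test_zero_los_is_surgery_only(self):
        stay = StayEvent("p", "initial", 0, 0, complication_level=1)
        assert adjusted_drg_cost(stay, self.entry, self.surgery, "VATS") == Decimal("3870.49")

    def test_arm_difference_is_theatre_difference(self):
        stay = _initial()
        v = adjusted_drg_cost(stay, self.entry, self.surgery, "VATS")
        t = adjusted_drg_cost(stay, self.entry, self.surgery, "THORACOTOMY")
        assert v - t == Decimal("3870.49") - Decimal("2455.58")

    def test_degenerate_limit_reduces_to_daily_cost(self):
        # zero theatre substitution and zero OR component: pure per-diem costing
        entry = DRGCatalogEntry("04C021", "lvl1", Decimal("7000"), Decimal("0"), 7.0)
        surgery = SurgeryCostTable(vats_cost="0.01", thoracotomy_cost="0.01")
        stay = _initial(adm=-1, dis=4)  # los 5
        cost = adjusted_drg_cost(stay, entry, surgery, "VATS")
        assert cost == Decimal("0.01") + Decimal("1000") * 5


class TestStandardDRG:
    def test_rehabilitation_flat_cost(self, catalog):
        stay = StayEvent("p", "rehabilitation", 10, 30)
        entry = catalog[assign_drg(stay)]
        assert standard_drg_cost(stay, entry) == Decimal("6222.20")

    def test_rehosp_catalog_passthrough(self):
        entry = DRGCatalogEntry("x", "x", Decimal("4205"), Decimal("0"), 7.0)
        stay = StayEvent("p", "rehospitalisation", 10, 13, reason="other")
        assert standard_drg_cost(stay, entry) == Decimal("4205.00")

    def test_rehosp_los_prorating(self):
        entry = DRGCatalogEntry("x", "x", Decimal("4200"), Decimal("0"), 7.0)
        stay = StayEvent("p", "rehospitalisation", 10, 13, reason="other")  # los 3
        assert standard_drg_cost(stay, entry, prorate_los=True) == Decimal("1800.00")


class TestCumulative:
    def test_initial_only(self):
        stay = _initial()
        stay.cost = Decimal("9213")
        for horizon in ("d30", "m3"):
            assert cumulative_costs("p1", [stay], horizon) == Decimal("9213.00")

    def test_rehab_before_d30_adds_flat_cost(self):
        initial = _initial()
        initial.cost = Decimal("9213")
        rehab = StayEvent("p1", "rehabilitation", 15, 35)
        rehab.cost = Decimal("6222.20")
        assert cumulative_costs("p1", [initial, rehab], "d30") == Decimal("15435.20")

    def test_event_after_m3_visit_excluded_everywhere(self):
        initial = _initial()
        initial.cost = Decimal("9000")
        late = StayEvent("p1", "rehospitalisation", 95, 99, reason="other")
        late.cost = Decimal("4205")
        assert cumulative_costs("p1", [initial, late], "d30") == Decimal("9000.00")
        assert cumulative_costs("p1", [initial, late], "m3") == Decimal("9000.00")

    def test_uncosted_stay_warns_and_is_excluded(self):
        initial = _initial()
        initial.cost = Decimal("9000")
        bad = StayEvent("p1", "rehospitalisation", 10, 12, reason="unclassifiable")
        with pytest.warns(UserWarning, match="uncosted"):
            total = cumulative_costs("p1", [initial, bad], "d30")
        assert total == Decimal("9000.00")

    def test_window_uses_actual_visit_days(self):
        initial = _initial()
        initial.cost = Decimal("9000")
        ev = StayEvent("p1", "rehospitalisation", 33, 36, reason="other")
        ev.cost = Decimal("1000")
        # admitted day 33: after a day-30 visit on day 32 it belongs to the m3 window
        assert cumulative_costs("p1", [initial, ev], "d30", d30_visit_day=32) == Decimal("9000.00")
        assert cumulative_costs("p1", [initial, ev], "d30", d30_visit_day=34) == Decimal("10000.00")


class TestCostStaysProperties:
    def _cohort(self, catalog, rules, n=1000, seed=7):
        from thoracic_cea import synthetic_trial as st

        cfg = st.TrialConfig(seed=seed, n_per_arm=n // 2)
        patients = st.generate_trial(cfg)
        stays = st.simulate_resource_use(patients, cfg)
        arm = {p.patient_id: p.arm for p in patients}
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            cost_stays(stays, catalog, SurgeryCostTable(), arm, rules)
        return patients, stays

    def test_monotone_and_additive(self, catalog, rules):
        """m3 cumulative >= d30 cumulative, and each cumulative equals an
        independent summation over the stays in its window."""
        import warnings

        patients, stays = self._cohort(catalog, rules)
        by_pid = {}
        for s in stays:
            by_pid.setdefault(s.patient_id, []).append(s)
        for p in patients:
            own = by_pid[p.patient_id]
            d30v = p.d30_visit_day if p.d30_visit_day is not None else 30
            m3v = p.m3_visit_day if p.m3_visit_day is not None else 91
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                c30 = cumulative_costs(p.patient_id, own, "d30", d30_visit_day=d30v, m3_visit_day=m3v)
                c3m = cumulative_costs(p.patient_id, own, "m3", d30_visit_day=d30v, m3_visit_day=m3v)
            assert c3m >= c30
            initial = next(s for s in own if s.stay_type == "initial")
            oracle = initial.cost + sum(
                (s.cost for s in own
                 if s.stay_type != "initial" and s.cost is not None
                 and initial.discharge_day < s.admission_day <= m3v),
                Decimal(0),
            )
            assert c3m == oracle.quantize(Decimal("0.01"))

    def test_scale_equivariance(self, rules):
        """Multiplying every catalog and surgery cost by k multiplies every
        cumulative cost by k."""
        k = 3
        base = DRGCatalog.load_default()
        scaled = DRGCatalog(
            DRGCatalogEntry(e.drg_code, e.label, e.total_cost * k, e.operating_room_cost * k,
                            e.national_mean_los)
            for e in base
        )
        stay = _initial()
        entry1, entryk = base["04C021"], scaled["04C021"]
        s1 = SurgeryCostTable()
        sk = SurgeryCostTable(vats_cost=s1.vats_cost * k, thoracotomy_cost=s1.thoracotomy_cost * k)
        c1 = adjusted_drg_cost(stay, entry1, s1, "VATS")
        ck = adjusted_drg_cost(stay, entryk, sk, "VATS")
        assert ck == (c1 * k).quantize(Decimal("0.01"))

    def test_missing_catalog_entry(self, catalog):
        with pytest.raises(MissingCatalogEntryError):
            catalog["99Z999"]


def test_reporting_rounds_to_whole_euros():
    assert to_euros(Decimal("1560.50")) == 1561
    assert to_euros(Decimal("1560.49")) == 1560
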