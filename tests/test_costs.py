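"""Inflation factors, event costing rules and the per-person accounting identity."""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, timedelta

import pytest

from eolcare.costs import (
    CostConfigurationError,
    cost_dispensing,
    cost_ed_visit,
    cost_hospital_episode,
    cost_service,
    medicines_inflation_factor,
    normalize_ed_weights,
    service_inflation_factor,
    total_person_cost,
)
from eolcare.windows import ObservationWindow

# ---------------------------------------------------------------------------
# independent brute-force oracle for inflation factors

MED_ANNUAL = {2004: 0.1519, 2005: 0.2123, 2006: 0.2220, 2007: 0.4832,
              2008: 0.1603, 2009: 0.0200}
MED_MONTHLY = {2004: 0.0126, 2005: 0.0177, 2006: 0.0185, 2007: 0.0402,
               2008: 0.0133, 2009: 0.0017}
SECTOR_ANNUAL = {
    "mbs": {2005: 7.0593, 2006: 4.7857, 2007: 2.7389, 2008: 2.3338, 2009: 1.8166},
    "dental": {2005: 5.6317, 2006: 4.5525, 2007: 4.5682, 2008: 3.8390, 2009: 4.1654},
    "other": {2005: 3.5392, 2006: 3.8714, 2007: 1.1189, 2008: 1.3020, 2009: 5.6757},
}


def oracle_medicines_factor(d: date) -> float:
    """Term-by-term product: one monthly factor per month strictly after the
    supply month through June of the supply financial year, then annual
    factors for each later financial year."""
    fy = d.year if d.month >= 7 else d.year - 1
    factor = 1.0
    month, year = d.month, d.year
    while not (year == fy + 1 and month == 6):  # walk month-by-month to June
        month += 1
        if month == 13:
            month, year = 1, year + 1
        factor *= 1 + MED_MONTHLY[fy] / 100
    for later in range(fy + 1, 2010):
        factor *= 1 + MED_ANNUAL[later] / 100
    return factor


def oracle_service_factor(d: date, sector: str) -> float:
    sy = d.year if d.month >= 11 else d.year - 1
    factor = 1.0
    for year, rate in SECTOR_ANNUAL[sector].items():
        if year > sy:
            factor *= 1 + rate / 100
    return factor


def month_grid():
    d = date(2004, 7, 1)
    while d <= date(2010, 6, 1):
        yield d
        d = date(d.year + (d.month == 12), d.month % 12 + 1, 1)


class TestInflationFactors:
    def test_medicines_worked_example_march_2005(self, schedule):
        assert round(medicines_inflation_factor(date(2005, 3, 15), schedule), 4) == 1.0114

    def test_dental_worked_example_march_2005(self, schedule):
        assert round(service_inflation_factor(date(2005, 3, 15), "dental", schedule), 4) == 1.2491

    def test_june_2010_factors_are_exactly_one(self, schedule):
        assert medicines_inflation_factor(date(2010, 6, 30), schedule) == 1.0
        for sector in ("mbs", "dental", "other"):
            assert service_inflation_factor(date(2010, 6, 30), sector, schedule) == 1.0

    def test_mbs_december_2008_single_remaining_year(self, schedule):
        assert service_inflation_factor(date(2008, 12, 25), "mbs", schedule) == pytest.approx(
            1.018166, abs=1e-12
        )

    def test_july_2004_full_chain(self, schedule):
        expected = (1 + 0.0126 / 100) ** 11
        for y in (2005, 2006, 2007, 2008, 2009):
            expected *= 1 + MED_ANNUAL[y] / 100
        assert medicines_inflation_factor(date(2004, 7, 10), schedule) == pytest.approx(
            expected, rel=1e-12
        )

    def test_medicines_factor_matches_oracle_over_full_grid(self, schedule):
        for d in month_grid():
            got = medicines_inflation_factor(d, schedule)
            want = oracle_medicines_factor(d)
            assert got == pytest.approx(want, rel=1e-12), d

    def test_service_factor_matches_oracle_over_full_grid(self, schedule):
        for sector in ("mbs", "dental", "other"):
            for d in month_grid():
                if d < date(2004, 11, 1):
                    continue  # before service schedule coverage
                got = service_inflation_factor(d, sector, schedule)
                assert got == pytest.approx(oracle_service_factor(d, sector), rel=1e-12)

    def test_factors_non_increasing_in_spend_date(self, schedule):
        meds = [medicines_inflation_factor(d, schedule) for d in month_grid()]
        assert all(a >= b - 1e-15 for a, b in zip(meds, meds[1:]))

    def test_out_of_coverage_dates_rejected(self, schedule):
        with pytest.raises(CostConfigurationError):
            medicines_inflation_factor(date(2004, 6, 30), schedule)
        with pytest.raises(CostConfigurationError):
            medicines_inflation_factor(date(2010, 7, 1), schedule)
        with pytest.raises(CostConfigurationError):
            service_inflation_factor(date(2004, 10, 1), "mbs", schedule)

    def test_unknown_sector_rejected(self, schedule):
        with pytest.raises(CostConfigurationError, match="sector"):
            service_inflation_factor(date(2008, 1, 1), "optical", schedule)

    def test_monthly_rates_compound_to_annual(self, schedule):
        schedule.validate()


# ---------------------------------------------------------------------------
# event costing

@dataclass
class D:  # minimal dispensing record
    person_id: str = "X"
    supply_date: date = date(2005, 3, 15)
    atc_code: str = "N02AA01"
    form: str = "standard"
    quantity: float = 1.0
    benefit_paid: float = 100.0
    copay_applicable: bool = False
    private_hospital_flag: bool = False


@dataclass
class S:  # minimal service claim
    person_id: str = "X"
    service_date: date = date(2005, 3, 15)
    item_id: str = "GP01"
    benefit_paid: float = 100.0
    sector: str = "dental"
    in_hospital_flag: bool = False


@dataclass
class E:  # minimal hospital episode
    episode_id: str = "E1"
    person_id: str = "X"
    admission_date: date = date(2007, 6, 1)
    separation_date: date = date(2007, 6, 10)
    drg_code: str = "B02B"
    care_type: str = "acute"
    diagnoses: str = "I50"
    procedures: str | None = None
    source_of_referral: str = "other"
    separation_mode: str = "discharge"
    facility_type: str = "public"


@dataclass
class V:  # minimal ED visit
    person_id: str = "X"
    visit_date: date = date(2007, 6, 20)
    outcome: str = "discharged"


DEATH = date(2007, 6, 30)
WINDOW = ObservationWindow(DEATH, 6)


class TestDispensingCost:
    def test_benefit_inflated_by_monthly_factor(self, params, schedule):
        item = cost_dispensing(D(benefit_paid=100.0), params, schedule)
        assert round(item.final_cost, 2) == 101.14

    def test_copay_added_at_nominal_value(self, params, schedule):
        item = cost_dispensing(D(benefit_paid=0.0, copay_applicable=True), params, schedule)
        assert item.final_cost == pytest.approx(6.00)
        assert item.components["copay"] == pytest.approx(6.00)

    def test_target_year_unit_factor(self, params, schedule):
        item = cost_dispensing(D(supply_date=date(2010, 6, 1), benefit_paid=50.0),
                               params, schedule)
        assert item.final_cost == pytest.approx(50.0)


class TestServiceCost:
    def test_dental_worked_example(self, params, schedule):
        item = cost_service(S(), schedule)
        assert round(item.final_cost, 2) == 124.91

    def test_no_copay_ever_added(self, params, schedule):
        item = cost_service(S(benefit_paid=0.0), schedule)
        assert item.final_cost == 0.0

    def test_in_hospital_flagged_for_exclusion(self, params, schedule):
        item = cost_service(S(in_hospital_flag=True), schedule)
        assert "in_hospital_service" in item.flags


class TestHospitalCost:
    def test_snap_ten_days_fully_observed(self, params, schedule):
        e = E(admission_date=DEATH - timedelta(days=15),
              separation_date=DEATH - timedelta(days=5),
              drg_code="SNAP1", care_type="snap")
        item = cost_hospital_episode(e, WINDOW, params)
        assert round(item.final_cost, 2) == round(10 * 0.0424 * 11582, 2) == 4910.77

    def test_snap_cost_linear_in_observed_days(self, params):
        costs = []
        for days in (1, 5, 20, 60):
            e = E(admission_date=DEATH - timedelta(days=days),
                  separation_date=DEATH, drg_code="SNAP1", care_type="snap")
            costs.append(cost_hospital_episode(e, WINDOW, params).final_cost)
        per_day = params.snap_inlier_weight * params.snap_average_cost
        assert costs == [pytest.approx(d * per_day) for d in (1, 5, 20, 60)]

    def test_acute_inlier_only(self, params):
        e = E(admission_date=DEATH - timedelta(days=10),
              separation_date=DEATH - timedelta(days=5))  # LOS 5 <= trim 20
        item = cost_hospital_episode(e, WINDOW, params)
        assert item.final_cost == pytest.approx(4092.00)  # weight 1.0 x base

    def test_acute_outlier_and_flat_rate_piecewise_sum(self, params):
        # B02B: weight 1.0, trim 20, per-diem 500; LOS 130 fully observed:
        # 4092 + 100 x 500 + 10 x 200 = 56,092
        e = E(admission_date=DEATH - timedelta(days=130), separation_date=DEATH)
        item = cost_hospital_episode(e, WINDOW, params)
        assert item.final_cost == pytest.approx(56092.00)
        assert item.components["inlier"] == pytest.approx(4092.00)
        assert item.components["outlier_per_diem"] == pytest.approx(50000.00)
        assert item.components["long_stay_flat"] == pytest.approx(2000.00)

    def test_partial_observation_prorates_inlier_and_counts_observed_outliers(self, params):
        # LOS 30, first 25 days before the window: inlier days (1-20) all
        # unobserved -> 0; outlier days 21-30, of which days 26-30 observed
        w = ObservationWindow(DEATH, 6)
        adm = w.start_date - timedelta(days=25)
        e = E(admission_date=adm, separation_date=adm + timedelta(days=30))
        item = cost_hospital_episode(e, w, params)
        assert item.components["inlier"] == pytest.approx(0.0)
        assert item.components["outlier_per_diem"] == pytest.approx(5 * 500.0)
        assert "partially_observed" in item.flags

    def test_acute_cost_non_decreasing_in_los(self, params):
        prev = -1.0
        for los in range(1, 200, 7):
            e = E(admission_date=DEATH - timedelta(days=los), separation_date=DEATH)
            cost = cost_hospital_episode(e, ObservationWindow(DEATH, 12), params).final_cost
            assert cost >= prev
            prev = cost

    def test_same_day_stay_counts_one_day(self, params):
        e = E(admission_date=DEATH, separation_date=DEATH,
              drg_code="SNAP1", care_type="snap")
        item = cost_hospital_episode(e, WINDOW, params)
        assert item.final_cost == pytest.approx(params.snap_inlier_weight * params.snap_average_cost)

    def test_unknown_acute_drg_is_configuration_error(self, params):
        e = E(drg_code="ZZ99")
        with pytest.raises(CostConfigurationError, match="ZZ99"):
            cost_hospital_episode(e, WINDOW, params)


class TestEDCost:
    def test_unit_weights_give_average_cost(self, params):
        assert cost_ed_visit(V(), params).final_cost == pytest.approx(396.00)

    def test_weighted_outcome(self, params):
        p = replace_weights(params, {"admitted": 1.5, "died": 1.0, "discharged": 1.0})
        assert cost_ed_visit(V(outcome="admitted"), p).final_cost == pytest.approx(594.00)

    def test_mix_normalization_restores_average(self, params):
        mix = {"admitted": 0.3, "discharged": 0.7}
        raw = {"admitted": 1.5, "discharged": 1.0}
        norm = normalize_ed_weights(raw, mix)
        mean_cost = sum(
            mix[o] * params.ed_average_cost * norm[o] for o in mix
        )
        assert mean_cost == pytest.approx(396.00)
        assert norm["admitted"] / norm["discharged"] == pytest.approx(1.5)


def replace_weights(params, weights):
    return replace(params, ed_mode_weights=weights)


# ---------------------------------------------------------------------------
# per-person totals and the accounting identity

class TestTotalPersonCost:
    def test_in_hospital_service_contributes_zero_to_total(
        self, small_bundle, params, schedule
    ):
        pid = "PLANT-private_hospital_pharmacy"
        w = ObservationWindow(small_bundle.death_date_of(pid), 6)
        breakdown, ledger = total_person_cost(pid, small_bundle, w, params, schedule)
        assert breakdown["total"] == pytest.approx(
            breakdown["medicines"] + breakdown["services_out_of_hospital"]
            + breakdown["hospital"] + breakdown["ed"]
        )

    def test_private_episode_pharmacy_deduction(self, small_bundle, params, schedule):
        # planted scenario: private episode with a 100 AUD private-flagged
        # in-episode dispensing; hospital component reduced by exactly 100
        pid = "PLANT-private_hospital_pharmacy"
        w = ObservationWindow(small_bundle.death_date_of(pid), 6)
        breakdown, ledger = total_person_cost(pid, small_bundle, w, params, schedule)
        hospital_items = [i for i in ledger if i.source == "hospital"]
        assert len(hospital_items) == 1
        assert breakdown["private_pharmacy_deduction"] == pytest.approx(100.0)
        assert hospital_items[0].components["pharmacy_deduction"] == pytest.approx(-100.0)

    def test_accounting_identity_over_whole_bundle(
        self, small_bundle, small_cohorts, params, schedule
    ):
        """Per-person totals equal the ledger sum of included items."""
        in_cohort = small_cohorts.loc[
            small_cohorts["cohort"].isin(["cancer", "non_cancer"]), "person_id"
        ]
        for pid in in_cohort:
            w = ObservationWindow(small_bundle.death_date_of(pid), 6)
            breakdown, ledger = total_person_cost(pid, small_bundle, w, params, schedule)
            recomputed = sum(
                item.final_cost for item in ledger
                if not (item.source == "service" and "in_hospital_service" in item.flags)
            )
            assert breakdown["total"] == pytest.approx(recomputed, abs=1e-9), pid
            assert all(item.final_cost >= 0 for item in ledger)
            assert all(
                sum(item.components.values()) == pytest.approx(item.final_cost, abs=1e-9)
                for item in ledger
            )
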