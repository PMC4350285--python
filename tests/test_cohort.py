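"""Base eligibility, cancer ascertainment and the screening hierarchy."""

from __future__ import annotations

from datetime import date, timedelta

import pandas as pd
import pytest

from eolcare.bundle import DatasetBundle, format_periods
from eolcare.cohort import (
    CohortConfig,
    LClassPolicy,
    assign_cancer,
    build_cohorts,
    check_base_eligibility,
    screen_non_cancer,
)
from eolcare.generate import PLANTED_EXPECTATIONS, plant_case

DEATH = date(2007, 6, 30)


def make_person(
    bundle: DatasetBundle | None = None,
    pid: str = "X1",
    death: date = DEATH,
    age_years: int = 80,
    residence_days: int = 7000,
    entitlement_days: int = 7000,
) -> DatasetBundle:
    bundle = bundle if bundle is not None else DatasetBundle.empty()
    client = pd.DataFrame([{
        "person_id": pid, "sex": "female",
        "birth_date": death - timedelta(days=int(age_years * 365.25) + 40),
        "death_date": death,
        "entitlements": format_periods([(death - timedelta(days=entitlement_days), death, "gold")]),
        "residences": format_periods([(death - timedelta(days=residence_days), death, "NSW")]),
        "remoteness": "major_cities", "seifa_decile": 5,
    }])
    client["seifa_decile"] = client["seifa_decile"].astype("Int64")
    bundle.clients = pd.concat([bundle.clients, client], ignore_index=True)
    bundle.clients["seifa_decile"] = bundle.clients["seifa_decile"].astype("Int64")
    bundle.deaths = pd.concat([bundle.deaths, pd.DataFrame([{
        "person_id": pid, "death_date": death, "underlying_cause": None,
    }])], ignore_index=True)
    return bundle


def add_dispensing(bundle, pid, atc="N02BE01", form="standard", days_before=30):
    row = pd.DataFrame([{
        "person_id": pid, "supply_date": DEATH - timedelta(days=days_before),
        "atc_code": atc, "form": form, "quantity": 1.0, "benefit_paid": 10.0,
        "copay_applicable": True, "private_hospital_flag": False,
    }])
    bundle.dispensings = pd.concat([bundle.dispensings, row], ignore_index=True)
    return bundle


class TestBaseEligibility:
    def test_all_criteria_met(self):
        b = add_dispensing(make_person(), "X1")
        res = check_base_eligibility(b.clients.iloc[0], b)
        assert res.eligible and res.failed_criteria == []

    def test_age_64_fails_age_criterion(self):
        b = add_dispensing(make_person(age_years=64), "X1")
        res = check_base_eligibility(b.clients.iloc[0], b)
        assert res.failed_criteria == ["age_65"]

    def test_death_outside_window(self):
        b = make_person(death=date(2010, 1, 15))
        b = add_dispensing(b, "X1")  # dispensing dated relative to DEATH; still a claim? no
        res = check_base_eligibility(b.clients.iloc[0], b)
        assert "death_window" in res.failed_criteria

    def test_no_claims_in_final_year(self):
        b = make_person()
        res = check_base_eligibility(b.clients.iloc[0], b)
        assert "min_one_claim" in res.failed_criteria

    def test_entitlement_gap_fails_with_zero_grace(self):
        b = add_dispensing(make_person(entitlement_days=100), "X1")
        res = check_base_eligibility(b.clients.iloc[0], b)
        assert "entitlement_12m" in res.failed_criteria

    def test_short_residence_fails_18_month_criterion(self):
        b = add_dispensing(make_person(residence_days=400), "X1")
        res = check_base_eligibility(b.clients.iloc[0], b)
        assert res.failed_criteria == ["residence_18m"]

    def test_failures_recorded_in_fixed_order(self):
        b = make_person(age_years=60, residence_days=100, entitlement_days=100)
        res = check_base_eligibility(b.clients.iloc[0], b)
        assert res.failed_criteria == [
            "entitlement_12m", "residence_18m", "age_65", "min_one_claim",
        ]


class TestCancerAssignment:
    def test_registry_record_assigns_cancer(self):
        b = add_dispensing(make_person(), "X1")
        b.cancer_registry = pd.DataFrame([{
            "person_id": "X1", "cancer_code": "C61",
            "diagnosis_date": date(2005, 1, 1), "spread": "unknown",
            "registry_cod": "non_cancer",
        }])
        has, reason, evidence = assign_cancer("X1", b)
        assert (has, reason, evidence) == (True, "registry_cancer", "C61")

    def test_cod_only_assigns_cancer(self):
        b = add_dispensing(make_person(), "X1")
        b.deaths.loc[0, "underlying_cause"] = "C34"
        has, reason, _ = assign_cancer("X1", b)
        assert (has, reason) == (True, "cod_cancer")

    def test_non_cancer_cod_is_not_cancer(self):
        b = add_dispensing(make_person(), "X1")
        b.deaths.loc[0, "underlying_cause"] = "I50"
        assert assign_cancer("X1", b)[0] is False

    def test_registry_record_outside_window_ignored(self):
        b = add_dispensing(make_person(), "X1")
        b.cancer_registry = pd.DataFrame([{
            "person_id": "X1", "cancer_code": "C61",
            "diagnosis_date": date(1990, 1, 1), "spread": "unknown",
            "registry_cod": "non_cancer",
        }])
        assert assign_cancer("X1", b)[0] is False

    def test_adding_registry_record_flips_to_cancer_monotonically(self, small_bundle, small_cohorts):
        non_cancer = small_cohorts.loc[small_cohorts["cohort"] == "non_cancer", "person_id"]
        pid = non_cancer.iloc[0]
        b = small_bundle.copy()
        b.cancer_registry = pd.concat([b.cancer_registry, pd.DataFrame([{
            "person_id": pid, "cancer_code": "C61",
            "diagnosis_date": date(2005, 1, 1), "spread": "unknown",
            "registry_cod": "cancer",
        }])], ignore_index=True)
        after = build_cohorts(b)
        assert after.loc[after["person_id"] == pid, "cohort"].iloc[0] == "cancer"
        # nobody previously cancer moved out
        before_cancer = set(small_cohorts.loc[small_cohorts["cohort"] == "cancer", "person_id"])
        after_cancer = set(after.loc[after["cohort"] == "cancer", "person_id"])
        assert before_cancer <= after_cancer


class TestScreeningHierarchy:
    def _eligible_person(self):
        return add_dispensing(make_person(), "X1")

    def test_hospital_cancer_procedure_excludes(self):
        b = self._eligible_person()
        b.hospital_episodes = pd.DataFrame([{
            "episode_id": "X1-E1", "person_id": "X1",
            "admission_date": date(2006, 1, 1), "separation_date": date(2006, 1, 5),
            "drg_code": "B02B", "care_type": "acute",
            "diagnoses": "I50", "procedures": "C18",
            "source_of_referral": "other", "separation_mode": "discharge",
            "facility_type": "public",
        }])
        a = screen_non_cancer("X1", b)
        assert (a.cohort, a.reason, a.evidence) == ("excluded_screened", "hospital_procedure", "C18")

    def test_excepted_lclass_drug_retained(self):
        b = add_dispensing(self._eligible_person(), "X1", atc="L04AB02")
        a = screen_non_cancer("X1", b)
        assert (a.cohort, a.reason) == ("non_cancer", "clean")

    def test_nonexcepted_lclass_drug_excludes(self):
        b = add_dispensing(self._eligible_person(), "X1", atc="L01XA01")
        a = screen_non_cancer("X1", b)
        assert (a.cohort, a.reason) == ("excluded_screened", "lclass_drug")

    def test_iv_fluorouracil_excludes_with_its_own_reason(self):
        b = add_dispensing(self._eligible_person(), "X1", atc="L01BC02", form="intravenous")
        a = screen_non_cancer("X1", b)
        assert a.reason == "iv_fluorouracil"

    def test_cream_fluorouracil_retained(self):
        b = add_dispensing(self._eligible_person(), "X1", atc="L01BC02", form="cream")
        assert screen_non_cancer("X1", b).cohort == "non_cancer"

    def test_cancer_indicative_service_excludes(self):
        b = self._eligible_person()
        b.service_claims = pd.DataFrame([{
            "person_id": "X1", "service_date": date(2006, 5, 1), "item_id": "CHEMO01",
            "benefit_paid": 150.0, "sector": "mbs", "in_hospital_flag": False,
        }])
        a = screen_non_cancer("X1", b)
        assert (a.cohort, a.reason) == ("excluded_screened", "cancer_service")

    def test_non_notifiable_cancer_cod_excludes(self):
        b = self._eligible_person()
        b.deaths.loc[0, "underlying_cause"] = "D46.5"
        a = screen_non_cancer("X1", b)
        assert (a.cohort, a.reason) == ("excluded_screened", "non_notifiable_cod")

    def test_drug_rule_precedes_service_rule(self):
        """A person triggering both step 2 and step 3 records the drug reason."""
        b = add_dispensing(self._eligible_person(), "X1", atc="L01XA01")
        b.service_claims = pd.DataFrame([{
            "person_id": "X1", "service_date": date(2006, 5, 1), "item_id": "CHEMO01",
            "benefit_paid": 150.0, "sector": "mbs", "in_hospital_flag": False,
        }])
        assert screen_non_cancer("X1", b).reason == "lclass_drug"

    def test_drug_outside_screen_window_ignored(self):
        b = self._eligible_person()
        row = b.dispensings.iloc[[0]].copy()
        row["atc_code"], row["supply_date"] = "L01XA01", date(2004, 1, 1)
        b.dispensings = pd.concat([b.dispensings, row], ignore_index=True)
        assert screen_non_cancer("X1", b).cohort == "non_cancer"


class TestLClassPolicy:
    def test_rules(self):
        p = LClassPolicy()
        assert p.classify("N02AA01", "standard") is None
        assert p.classify("L04AB02", "standard") is None
        assert p.classify("L01XA01", "standard") == "lclass_drug"
        assert p.classify("L01BC02", "intravenous") == "iv_fluorouracil"
        assert p.classify("L01BC02", "cream") is None
        assert p.classify("L01BC02", "standard") == "lclass_drug"


class TestBuildCohorts:
    def test_partition_property(self, small_bundle, small_cohorts):
        assert len(small_cohorts) == len(small_bundle.clients)
        assert set(small_cohorts["person_id"]) == set(small_bundle.clients["person_id"])
        assert set(small_cohorts["cohort"]) <= {
            "cancer", "non_cancer", "excluded_ineligible", "excluded_screened",
        }

    def test_planted_cases_land_in_declared_buckets(self, small_cohorts):
        for scenario, (cohort, reason) in PLANTED_EXPECTATIONS.items():
            row = small_cohorts.loc[small_cohorts["person_id"] == f"PLANT-{scenario}"]
            assert len(row) == 1, scenario
            assert row.iloc[0]["cohort"] == cohort, scenario
            assert row.iloc[0]["reason"] == reason, scenario

    def test_ineligible_person_never_reaches_screening(self):
        b = add_dispensing(make_person(age_years=50), "X1", atc="L01XA01")
        out = build_cohorts(b)
        assert out.iloc[0]["reason"] == "base_ineligibility:age_65"

    def test_empty_bundle_gives_empty_assignments(self):
        out = build_cohorts(DatasetBundle.empty())
        assert len(out) == 0
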