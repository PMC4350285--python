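"""Seeded generator for linked synthetic administrative claims.

Emulates the eight linked source tables (client file, cancer registry,
death registry, dispensing claims, medical service claims, hospital
episodes, ED visits, residential aged care) for a decedent study
population, keyed by a shared person identifier.  Claim volumes are
person-level Poisson rates per constructed 30-day month with a
configurable intensification in the final months of life, so that
months-before-death trajectories are non-trivial.  Fixed (seed, config)
pairs give byte-identical output.

A catalogue of deterministic "planted" scenarios inserts one fully
specified person each, exercising every cohort rule and costing branch;
:data:`PLANTED_EXPECTATIONS` records the cohort/exclusion bucket each
scenario must land in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .bundle import DatasetBundle, TABLE_SCHEMAS, format_periods

__all__ = [
    "GeneratorConfigError",
    "GeneratorConfig",
    "generate_linked_data",
    "plant_case",
    "PLANTED_SCENARIOS",
    "PLANTED_EXPECTATIONS",
]


class GeneratorConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


# non-cancer ICD-10 codes safe for the non-cancer template: none is a
# notifiable cancer or a non-notifiable cancer COD.
_NONCANCER_CODES = [
    "I50", "I50.0", "I63", "I63.9", "I21", "I21.9", "I20", "J44", "J44.9",
    "F03", "G30", "G30.9", "A41.9", "N18.9", "E11.9", "K57.3", "M81.0",
    "I48", "J18.9", "N39.0",
]
_CANCER_CODES = [
    "C61", "C18.9", "C34.9", "C50.9", "C25.9", "C64", "C67.9", "C82.9",
    "C16.9", "C43.9", "D45", "C80",
]
_CANCER_CODE_W = [0.18, 0.11, 0.12, 0.08, 0.05, 0.04, 0.05, 0.07, 0.06, 0.08, 0.04, 0.12]
_GENERAL_ATC = [
    "N02AA01", "N02BE01", "A04AA01", "A06AB02", "N05BA01", "J01CA04",
    "N03AX09", "A10BA02", "C01AA05", "C03CA01", "C07AB02", "C09AA02",
    "B01AC06", "R03AC02", "C10AA05", "A11CC05", "A02BC01", "M04AA01",
    "N06AB04", "H03AA01", "S01EE01",
]
_GENERAL_ATC_W = np.array([
    0.10, 0.10, 0.04, 0.06, 0.05, 0.07, 0.03, 0.05, 0.05, 0.06, 0.05,
    0.05, 0.06, 0.05, 0.06, 0.03, 0.05, 0.02, 0.04, 0.02, 0.01,
])
_GENERAL_ATC_W = _GENERAL_ATC_W / _GENERAL_ATC_W.sum()
_CANCER_ATC = ["L01XA01", "L01BA01", "L02AE03", "L01CD01"]
_GENERAL_ITEMS = [
    "PATH01", "PATH02", "IMG01", "GP01", "GP02", "SPEC01", "PALL01",
    "ALLIED01", "NURSE01", "CAREPLAN01", "PROC01", "SURG01", "DENT01",
    "DENT02", "BULK01", "BULK02",
]
_GENERAL_ITEM_W = [
    0.12, 0.08, 0.07, 0.20, 0.10, 0.08, 0.03, 0.04, 0.04, 0.02, 0.04,
    0.02, 0.03, 0.02, 0.08, 0.03,
]
_CANCER_ITEMS = ["CHEMO01", "RADONC01", "SURG02", "MDC01"]
_ACUTE_DRGS = ["A01A", "B02B", "C03C", "D04D", "E05E"]
_ACUTE_DRG_W = [0.08, 0.30, 0.22, 0.25, 0.15]
_SNAP_DRGS = ["SNAP1", "SNAP2"]
_REMOTENESS = ["major_cities", "inner_regional", "outer_regional", "remote", "very_remote"]
_REMOTENESS_W = [0.619, 0.283, 0.090, 0.005, 0.003]


@dataclass
class GeneratorConfig:
    """Study conditions for the simulated jurisdiction.

    Claim intensities are events per person per constructed 30-day
    month, calibrated to per-person last-6-month claim volumes of an
    elderly decedent cohort (~17 medical services, ~7 dispensings,
    ~0.49 hospital episodes and ~0.21 ED presentations per
    person-month).
    """

    n_decedents: int = 200
    cancer_fraction: float = 0.4
    death_window: tuple[date, date] = (date(2005, 6, 30), date(2009, 12, 31))
    history_months: int = 24
    dispensing_rate: float = 7.0
    service_rate: float = 17.0
    hospital_rate: float = 0.49
    ed_rate: float = 0.21
    final_month_multiplier: float = 1.5
    intensified_months: int = 1
    cod_available_until: date = date(2007, 12, 31)
    non_gold_rate: float = 0.03
    short_residence_rate: float = 0.02
    missing_seifa_rate: float = 0.04
    missing_remoteness_rate: float = 0.003
    aged_care_rate: float = 0.30
    planted_cases: tuple[str, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_decedents <= 0:
            raise GeneratorConfigError("n_decedents must be positive")
        if not 0.0 <= self.cancer_fraction <= 1.0:
            raise GeneratorConfigError("cancer_fraction must lie in [0, 1]")
        if self.death_window[0] > self.death_window[1]:
            raise GeneratorConfigError("death_window is inverted")
        for name in ("dispensing_rate", "service_rate", "hospital_rate", "ed_rate"):
            if getattr(self, name) < 0:
                raise GeneratorConfigError(f"{name} must be non-negative")
        if self.final_month_multiplier <= 0:
            raise GeneratorConfigError("final_month_multiplier must be positive")
        if self.history_months < 1:
            raise GeneratorConfigError("history_months must be at least 1")
        unknown = set(self.planted_cases) - set(PLANTED_SCENARIOS)
        if unknown:
            raise GeneratorConfigError(
                f"planted_cases contains unknown scenario(s) {sorted(unknown)}; "
                f"catalogue: {sorted(PLANTED_SCENARIOS)}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["death_window"] = [x.isoformat() for x in self.death_window]
        d["cod_available_until"] = self.cod_available_until.isoformat()
        d["planted_cases"] = list(self.planted_cases)
        return d


class _Tables:
    """Row accumulators, turned into schema-conformant DataFrames."""

    def __init__(self) -> None:
        self.rows = {name: [] for name in TABLE_SCHEMAS}

    def add(self, table: str, **row) -> None:
        self.rows[table].append(row)

    def finish(self, provenance: dict, validate: bool = True) -> DatasetBundle:
        frames = {}
        for name, schema in TABLE_SCHEMAS.items():
            cols = list(schema)
            df = pd.DataFrame(self.rows[name], columns=cols)
            if schema.get("seifa_decile") == "int_opt" and "seifa_decile" in df:
                df["seifa_decile"] = df["seifa_decile"].astype("Int64")
            for col, kind in schema.items():
                if kind == "bool":
                    df[col] = df[col].astype(bool) if len(df) else df[col].astype(bool)
                elif kind == "float":
                    df[col] = df[col].astype("float64")
            frames[name] = df
        bundle = DatasetBundle(**frames, provenance=provenance)
        if validate:
            bundle.validate()
        return bundle


def _month_dates(rng: np.random.Generator, death: date, month: int, n: int) -> list[date]:
    """n dates uniform over constructed month *month* before death."""
    offsets = rng.integers(30 * (month - 1), 30 * month, size=n)
    return [death - timedelta(days=int(o)) for o in offsets]


def generate_linked_data(config: GeneratorConfig) -> DatasetBundle:
    """Generate the eight linked tables for one simulated jurisdiction."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = _Tables()
    lo, hi = config.death_window
    window_days = (hi - lo).days
    n_cancer = round(config.n_decedents * config.cancer_fraction)
    templates: dict[str, str] = {}

    for i in range(config.n_decedents):
        pid = f"P{i:05d}"
        is_cancer = i < n_cancer
        templates[pid] = "cancer" if is_cancer else "non_cancer"
        death = lo + timedelta(days=int(rng.integers(0, window_days + 1)))
        age_years = float(np.clip(rng.normal(86.0, 7.0), 65.2, 105.0))
        birth = death - timedelta(days=int(age_years * 365.25))
        male_p = 0.684 if is_cancer else 0.514
        sex = "male" if rng.random() < male_p else "female"

        ent_start = death - timedelta(days=int(rng.integers(3650, 7300)))
        if rng.random() < config.non_gold_rate:
            # entitlement downgraded mid-final-year: fails the 12-month test
            cut = death - timedelta(days=180)
            entitlements = [(ent_start, cut, "gold"), (cut + timedelta(days=1), death, "white")]
        else:
            entitlements = [(ent_start, death, "gold")]
        res_start = death - timedelta(days=int(rng.integers(3650, 7300)))
        if rng.random() < config.short_residence_rate:
            cut = death - timedelta(days=300)
            residences = [(res_start, cut, "VIC"), (cut + timedelta(days=1), death, "NSW")]
        else:
            residences = [(res_start, death, "NSW")]

        remoteness = (
            "missing" if rng.random() < config.missing_remoteness_rate
            else _REMOTENESS[int(rng.choice(len(_REMOTENESS), p=np.asarray(_REMOTENESS_W) / sum(_REMOTENESS_W)))]
        )
        seifa = None if rng.random() < config.missing_seifa_rate else int(rng.integers(1, 11))
        t.add(
            "clients", person_id=pid, sex=sex, birth_date=birth, death_date=death,
            entitlements=format_periods(entitlements),
            residences=format_periods(residences),
            remoteness=remoteness, seifa_decile=seifa,
        )

        # cancer registry / cause of death evidence
        cancer_code = None
        cod_possible = death <= config.cod_available_until
        if is_cancer:
            cancer_code = str(rng.choice(_CANCER_CODES, p=_CANCER_CODE_W))
            cod_only = cod_possible and rng.random() < 0.15
            if not cod_only:
                dx_lag = int(rng.exponential(700.0))
                dx = max(date(1994, 1, 1), death - timedelta(days=dx_lag))
                dx = min(dx, death, date(2008, 12, 31))
                spread = str(rng.choice(
                    ["insitu_localized", "regionalized", "metastatic", "unknown"],
                    p=[0.33, 0.13, 0.16, 0.38],
                ))
                t.add(
                    "cancer_registry", person_id=pid, cancer_code=cancer_code,
                    diagnosis_date=dx, spread=spread,
                    registry_cod="cancer" if rng.random() < 0.6 else "non_cancer",
                )
        if cod_possible:
            if is_cancer:
                cause = cancer_code if (cod_only or rng.random() < 0.6) else str(rng.choice(_NONCANCER_CODES))
            else:
                cause = str(rng.choice(_NONCANCER_CODES))
        else:
            cause = None
        t.add("deaths", person_id=pid, death_date=death, underlying_cause=cause)

        # hospital episodes (generated first so pharmacy/service flags can
        # reference private-episode spans)
        episode_spans: list[tuple[date, date, str]] = []
        ep_counter = 0
        death_mode_used = False
        admissions: list[date] = []
        for m in range(1, config.history_months + 1):
            mult = config.final_month_multiplier if m <= config.intensified_months else 1.0
            k = int(rng.poisson(config.hospital_rate * mult))
            admissions.extend(_month_dates(rng, death, m, k))
        for adm in sorted(admissions, reverse=True):
            los = 1 + int(rng.geometric(0.15))
            sep = min(adm + timedelta(days=los), death)
            if any(adm <= s and a <= sep for a, s, _ in episode_spans):
                continue  # one admission at a time per person
            ep_counter += 1
            snap = rng.random() < 0.15
            drg = str(rng.choice(_SNAP_DRGS)) if snap else str(
                rng.choice(_ACUTE_DRGS, p=_ACUTE_DRG_W))
            dx_pool = _NONCANCER_CODES if not is_cancer else _NONCANCER_CODES + [cancer_code]
            n_dx = int(rng.integers(1, 5))
            diagnoses = ";".join(str(rng.choice(dx_pool)) for _ in range(n_dx))
            procedures = ";".join(
                str(rng.choice(_NONCANCER_CODES)) for _ in range(int(rng.integers(0, 2)))
            )
            if sep == death and not death_mode_used:
                mode = "death"
                death_mode_used = True
            else:
                mode = "transfer" if rng.random() < 0.10 else "discharge"
            facility = "private" if rng.random() < 0.20 else "public"
            t.add(
                "hospital_episodes", episode_id=f"{pid}-E{ep_counter}", person_id=pid,
                admission_date=adm, separation_date=sep, drg_code=drg,
                care_type="snap" if snap else "acute",
                diagnoses=diagnoses, procedures=procedures or None,
                source_of_referral="ed" if rng.random() < 0.30 else "other",
                separation_mode=mode, facility_type=facility,
            )
            episode_spans.append((adm, sep, facility))

        # dispensings
        for m in range(1, config.history_months + 1):
            mult = config.final_month_multiplier if m <= config.intensified_months else 1.0
            n = int(rng.poisson(config.dispensing_rate * mult))
            for supply in _month_dates(rng, death, m, n):
                if is_cancer and rng.random() < 0.05:
                    atc = str(rng.choice(_CANCER_ATC))
                else:
                    atc = str(rng.choice(_GENERAL_ATC, p=_GENERAL_ATC_W))
                private = any(
                    a <= supply <= s and f == "private" for a, s, f in episode_spans
                ) and rng.random() < 0.5
                t.add(
                    "dispensings", person_id=pid, supply_date=supply, atc_code=atc,
                    form="standard", quantity=float(rng.integers(1, 4) * 28),
                    benefit_paid=round(float(rng.lognormal(3.3, 0.8)), 2),
                    copay_applicable=bool(rng.random() < 0.9),
                    private_hospital_flag=bool(private),
                )

        # service claims
        for m in range(1, config.history_months + 1):
            mult = config.final_month_multiplier if m <= config.intensified_months else 1.0
            n = int(rng.poisson(config.service_rate * mult))
            for svc in _month_dates(rng, death, m, n):
                if is_cancer and rng.random() < 0.03:
                    item = str(rng.choice(_CANCER_ITEMS))
                else:
                    item = str(rng.choice(_GENERAL_ITEMS, p=_GENERAL_ITEM_W))
                in_episode = any(a <= svc <= s for a, s, _ in episode_spans)
                t.add(
                    "service_claims", person_id=pid, service_date=svc, item_id=item,
                    benefit_paid=round(float(rng.lognormal(3.9, 0.7)), 2),
                    sector=str(rng.choice(["mbs", "dental", "other"], p=[0.90, 0.05, 0.05])),
                    in_hospital_flag=bool(in_episode and rng.random() < 0.7),
                )

        # ED visits; admitted visits get a matching ED-referred episode
        for m in range(1, config.history_months + 1):
            mult = config.final_month_multiplier if m <= config.intensified_months else 1.0
            n = int(rng.poisson(config.ed_rate * mult))
            for visit in _month_dates(rng, death, m, n):
                outcome = str(rng.choice(
                    ["admitted", "discharged", "died"], p=[0.30, 0.68, 0.02]
                ))
                if outcome == "died" and visit != death:
                    outcome = "discharged"
                los = 1 + int(rng.geometric(0.25))
                sep = min(visit + timedelta(days=los), death)
                if outcome == "admitted" and any(
                    visit <= s and a <= sep for a, s, _ in episode_spans
                ):
                    outcome = "discharged"  # already an inpatient
                t.add("ed_visits", person_id=pid, visit_date=visit, outcome=outcome)
                if outcome == "admitted":
                    ep_counter += 1
                    if sep == death and not death_mode_used:
                        mode, death_mode_used = "death", True
                    else:
                        mode = "discharge"
                    t.add(
                        "hospital_episodes", episode_id=f"{pid}-E{ep_counter}",
                        person_id=pid, admission_date=visit, separation_date=sep,
                        drg_code=str(rng.choice(_ACUTE_DRGS, p=_ACUTE_DRG_W)),
                        care_type="acute",
                        diagnoses=str(rng.choice(_NONCANCER_CODES)), procedures=None,
                        source_of_referral="ed", separation_mode=mode,
                        facility_type="public",
                    )
                    episode_spans.append((visit, sep, "public"))

        if rng.random() < config.aged_care_rate:
            entry = death - timedelta(days=int(rng.integers(100, 1000)))
            open_ended = rng.random() < 0.1
            t.add(
                "aged_care_stays", person_id=pid, entry_date=entry,
                exit_date=None if open_ended else death, care_type="permanent",
            )

    bundle = t.finish({
        "seed": config.seed,
        "config": config.to_dict(),
        "templates": templates,
        "planted_person_ids": [],
    })
    for scenario in config.planted_cases:
        bundle, _ = plant_case(bundle, scenario)
    return bundle


# ---------------------------------------------------------------------------
# planted scenarios

#: scenario -> (expected cohort, expected reason) once pushed through
#: the cohort builder with default configuration.
PLANTED_EXPECTATIONS: dict[str, tuple[str, str]] = {
    "underage": ("excluded_ineligible", "base_ineligibility:age_65"),
    "short_residence": ("excluded_ineligible", "base_ineligibility:residence_18m"),
    "no_claims": ("excluded_ineligible", "base_ineligibility:min_one_claim"),
    "registry_cancer": ("cancer", "registry_cancer"),
    "cod_only_cancer": ("cancer", "cod_cancer"),
    "hospital_cancer_procedure": ("excluded_screened", "hospital_procedure"),
    "lclass_excluded_drug": ("excluded_screened", "lclass_drug"),
    "lclass_excepted_drug": ("non_cancer", "clean"),
    "iv_fluorouracil": ("excluded_screened", "iv_fluorouracil"),
    "cancer_indicative_service": ("excluded_screened", "cancer_service"),
    "non_notifiable_cod": ("excluded_screened", "non_notifiable_cod"),
    "snap_long_stay": ("non_cancer", "clean"),
    "acute_outlier_stay": ("non_cancer", "clean"),
    "private_hospital_pharmacy": ("non_cancer", "clean"),
}

PLANTED_SCENARIOS = tuple(PLANTED_EXPECTATIONS)

_PLANT_DEATH = date(2007, 6, 30)  # inside death window and the COD-coded period


def _base_client(t: _Tables, pid: str, age_years: int = 80,
                 death: date = _PLANT_DEATH,
                 residence_days: int = 7000, with_claim: bool = True,
                 cause: str | None = "I50") -> None:
    birth = death - timedelta(days=int(age_years * 365.25) + 40)
    t.add(
        "clients", person_id=pid, sex="male", birth_date=birth, death_date=death,
        entitlements=format_periods([(death - timedelta(days=7000), death, "gold")]),
        residences=format_periods([(death - timedelta(days=residence_days), death, "NSW")]),
        remoteness="major_cities", seifa_decile=5,
    )
    t.add("deaths", person_id=pid, death_date=death, underlying_cause=cause)
    if with_claim:
        t.add(
            "dispensings", person_id=pid, supply_date=death - timedelta(days=30),
            atc_code="N02BE01", form="standard", quantity=28.0, benefit_paid=12.50,
            copay_applicable=True, private_hospital_flag=False,
        )


def _plant_dispensing(t, pid, atc, form, days_before=60, benefit=250.0, private=False):
    t.add(
        "dispensings", person_id=pid, supply_date=_PLANT_DEATH - timedelta(days=days_before),
        atc_code=atc, form=form, quantity=1.0, benefit_paid=benefit,
        copay_applicable=True, private_hospital_flag=private,
    )


def _plant_episode(t, pid, *, admission_days_before, los_days, drg, care_type,
                   procedures=None, diagnoses="I50", facility="public",
                   referral="other"):
    adm = _PLANT_DEATH - timedelta(days=admission_days_before)
    sep = min(adm + timedelta(days=los_days), _PLANT_DEATH)
    t.add(
        "hospital_episodes", episode_id=f"{pid}-E1", person_id=pid,
        admission_date=adm, separation_date=sep, drg_code=drg, care_type=care_type,
        diagnoses=diagnoses, procedures=procedures,
        source_of_referral=referral,
        separation_mode="death" if sep == _PLANT_DEATH else "discharge",
        facility_type=facility,
    )


def plant_case(bundle: DatasetBundle, scenario: str) -> tuple[DatasetBundle, str]:
    """Insert one deterministic scenario person; returns (bundle, person_id)."""
    if scenario not in PLANTED_EXPECTATIONS:
        raise GeneratorConfigError(
            f"unknown planted scenario {scenario!r}; catalogue: {sorted(PLANTED_SCENARIOS)}"
        )
    pid = f"PLANT-{scenario}"
    if pid in set(bundle.clients["person_id"]):
        raise GeneratorConfigError(f"scenario {scenario!r} already planted")
    t = _Tables()

    if scenario == "underage":
        _base_client(t, pid, age_years=64)
    elif scenario == "short_residence":
        _base_client(t, pid, residence_days=300)
    elif scenario == "no_claims":
        _base_client(t, pid, with_claim=False)
    elif scenario == "registry_cancer":
        _base_client(t, pid)
        t.add(
            "cancer_registry", person_id=pid, cancer_code="C61",
            diagnosis_date=date(2005, 3, 1), spread="insitu_localized",
            registry_cod="cancer",
        )
    elif scenario == "cod_only_cancer":
        _base_client(t, pid, cause="C34.9")
    elif scenario == "hospital_cancer_procedure":
        _base_client(t, pid)
        _plant_episode(t, pid, admission_days_before=400, los_days=5,
                       drg="B02B", care_type="acute", procedures="C18.9")
    elif scenario == "lclass_excluded_drug":
        _base_client(t, pid)
        _plant_dispensing(t, pid, "L01XA01", "standard")
    elif scenario == "lclass_excepted_drug":
        _base_client(t, pid)
        _plant_dispensing(t, pid, "L04AB02", "standard")
    elif scenario == "iv_fluorouracil":
        _base_client(t, pid)
        _plant_dispensing(t, pid, "L01BC02", "intravenous")
    elif scenario == "cancer_indicative_service":
        _base_client(t, pid)
        t.add(
            "service_claims", person_id=pid,
            service_date=_PLANT_DEATH - timedelta(days=90), item_id="CHEMO01",
            benefit_paid=180.0, sector="mbs", in_hospital_flag=False,
        )
    elif scenario == "non_notifiable_cod":
        _base_client(t, pid, cause="D46.5")
    elif scenario == "snap_long_stay":
        # SNAP episode starting well before the 6-month window: exercises
        # observed-day-only SNAP costing
        _base_client(t, pid)
        _plant_episode(t, pid, admission_days_before=200, los_days=200,
                       drg="SNAP1", care_type="snap")
    elif scenario == "acute_outlier_stay":
        # acute stay beyond trim point and the 120-day flat-rate threshold
        _base_client(t, pid)
        _plant_episode(t, pid, admission_days_before=130, los_days=130,
                       drg="B02B", care_type="acute")
    elif scenario == "private_hospital_pharmacy":
        # private episode with in-episode private pharmacy: exercises the
        # total-cost pharmacy deduction
        _base_client(t, pid)
        _plant_episode(t, pid, admission_days_before=20, los_days=10,
                       drg="B02B", care_type="acute", facility="private")
        _plant_dispensing(t, pid, "N02AA01", "standard", days_before=15,
                          benefit=100.0, private=True)

    merged = bundle.copy()
    for name, rows in t.rows.items():
        if not rows:
            continue
        addition = _Tables()
        addition.rows[name] = rows
        extra = addition.finish({}, validate=False).tables()[name]
        base = merged.tables()[name]
        combined = pd.concat([base, extra], ignore_index=True) if len(base) else extra
        if "seifa_decile" in combined:
            combined["seifa_decile"] = combined["seifa_decile"].astype("Int64")
        setattr(merged, name, combined)
    merged.provenance.setdefault("planted_person_ids", [])
    merged.provenance["planted_person_ids"] = list(
        merged.provenance["planted_person_ids"]) + [pid]
    merged.validate()
    return merged, pid
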