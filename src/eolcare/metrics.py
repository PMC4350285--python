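"""Window-based resource-use summaries, hospital-stay linkage, the
ED-admission cross-check, and the quality-of-care indicator engine.

A hospital *stay* chains consecutive episodes of care: an episode
separated by transfer followed by a (re)admission on the same day (gap
configurable) belongs to the same stay, so total length of stay can be
reported alongside per-episode lengths.  Quality indicators are
count-of-events thresholds inside a days-before-death window (day 0 is
the day of death); proportion denominators are reported with every
numerator.  Thresholds can be derived empirically from the cohort's own
utilization with a nearest-rank percentile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import timedelta
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bundle import DatasetBundle
from .classify import EolMedicineMap, ServiceCategoryMap, group_cause_of_death
from .windows import DAYS_PER_MONTH, ObservationWindow, month_index

__all__ = [
    "HospitalStay",
    "IndicatorDefinition",
    "link_stays",
    "ed_admission_crosscheck",
    "summarize_resource_use",
    "person_years",
    "compute_indicators",
    "derive_threshold",
    "load_indicator_definitions",
]


@dataclass
class HospitalStay:
    person_id: str
    episode_ids: list[str]
    stay_admission: object
    stay_separation: object
    per_episode_los: list[int]
    ended_in_death: bool
    ed_origin: bool

    @property
    def total_los_days(self) -> int:
        return sum(self.per_episode_los)


def _los(adm, sep) -> int:
    return max((sep - adm).days, 1)


def link_stays(episodes: pd.DataFrame, transfer_gap_days: int = 0) -> list[HospitalStay]:
    """Chain one person's date-sorted episodes into stays.

    A new episode joins the current stay when the previous episode
    separated by transfer and the admission follows within
    *transfer_gap_days* days of that separation.  Overlapping
    non-transfer episodes provoke a warning and are kept separate.
    """
    stays: list[HospitalStay] = []
    current: list = []
    for e in episodes.sort_values(["admission_date", "separation_date"]).itertuples(index=False):
        if current:
            prev = current[-1]
            joins = (
                prev.separation_mode == "transfer"
                and e.admission_date <= prev.separation_date + timedelta(days=transfer_gap_days)
            )
            if not joins:
                if e.admission_date < prev.separation_date:
                    warnings.warn(
                        f"overlapping non-transfer episodes for {e.person_id}: "
                        f"{prev.episode_id} and {e.episode_id}; kept separate",
                        stacklevel=2,
                    )
                stays.append(_finish_stay(current))
                current = []
        current.append(e)
    if current:
        stays.append(_finish_stay(current))
    return stays


def _finish_stay(episodes: list) -> HospitalStay:
    return HospitalStay(
        person_id=episodes[0].person_id,
        episode_ids=[e.episode_id for e in episodes],
        stay_admission=episodes[0].admission_date,
        stay_separation=episodes[-1].separation_date,
        per_episode_los=[_los(e.admission_date, e.separation_date) for e in episodes],
        ended_in_death=episodes[-1].separation_mode == "death",
        ed_origin=episodes[0].source_of_referral == "ed",
    )


def ed_admission_crosscheck(
    bundle: DatasetBundle, n_months: int = 6, cohorts: pd.DataFrame | None = None
) -> dict[str, dict[str, int]]:
    """ED presentations ending in admission, measured two ways.

    Counts ED-visit records with outcome ``admitted`` (the ED
    collection's own view) and hospital episodes with source of referral
    ``ed`` (the admitted-patient collection's view), both restricted to
    each decedent's observation window.  The ED collection covers only a
    subset of departments, so the episode-based count can exceed the
    visit-based count.
    """
    death_by_person = dict(zip(bundle.clients["person_id"], bundle.clients["death_date"]))
    cohort_by_person = (
        dict(zip(cohorts["person_id"], cohorts["cohort"])) if cohorts is not None else None
    )
    out: dict[str, dict[str, int]] = {}

    def bucket(pid: str) -> str:
        return cohort_by_person.get(pid, "all") if cohort_by_person else "all"

    for v in bundle.ed_visits.itertuples(index=False):
        w = ObservationWindow(death_by_person[v.person_id], n_months)
        if v.outcome == "admitted" and v.visit_date in w:
            b = out.setdefault(bucket(v.person_id), {"rate_from_eddc": 0, "rate_from_apdc": 0})
            b["rate_from_eddc"] += 1
    for e in bundle.hospital_episodes.itertuples(index=False):
        w = ObservationWindow(death_by_person[e.person_id], n_months)
        if e.source_of_referral == "ed" and e.admission_date in w:
            b = out.setdefault(bucket(e.person_id), {"rate_from_eddc": 0, "rate_from_apdc": 0})
            b["rate_from_apdc"] += 1
    return out


def person_years(n_persons: int, n_months: int = 6) -> float:
    """Observation person-years for fully observed decedents
    (days of observation / 365.25)."""
    return n_persons * DAYS_PER_MONTH * n_months / 365.25


_STRATIFIERS = ("age_band", "sex", "cod_group", "seifa_band", "remoteness")


def _age_band(age: int) -> str:
    for lo, hi in ((65, 74), (75, 84), (85, 94), (95, 104)):
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    return ">=105"


def _seifa_band(decile) -> str:
    if pd.isna(decile):
        return "missing"
    d = int(decile)
    return {1: "1-2", 2: "1-2", 3: "3-4", 4: "3-4", 5: "5-6", 6: "5-6",
            7: "7-8", 8: "7-8"}.get(d, "9-10")


def summarize_resource_use(
    bundle: DatasetBundle,
    cohorts: pd.DataFrame,
    n_months: int = 6,
    stratifier: str = "sex",
    medicine_map: EolMedicineMap | None = None,
    service_map: ServiceCategoryMap | None = None,
) -> pd.DataFrame:
    """Per (cohort, stratum) resource-use summary over the end-of-life window.

    Reports record counts per source (admin/billing service items
    excluded), counts per person, per-month event counts, medicine and
    service category shares, and person-years of observation.
    """
    if stratifier not in _STRATIFIERS:
        raise ValueError(
            f"unknown stratifier {stratifier!r}; valid: {_STRATIFIERS}"
        )
    medicine_map = medicine_map or EolMedicineMap.default()
    service_map = service_map or ServiceCategoryMap.default()

    clients = bundle.clients.merge(cohorts, on="person_id")
    clients = clients.loc[clients["cohort"].isin(["cancer", "non_cancer"])]
    cod_by_person = dict(zip(bundle.deaths["person_id"], bundle.deaths["underlying_cause"]))

    def stratum_of(row) -> str:
        if stratifier == "sex":
            return row.sex
        if stratifier == "age_band":
            age = (row.death_date - row.birth_date).days // 365
            return _age_band(int(age))
        if stratifier == "seifa_band":
            return _seifa_band(row.seifa_decile)
        if stratifier == "remoteness":
            return row.remoteness
        group = group_cause_of_death(cod_by_person.get(row.person_id))
        return group if group is not None else "missing"

    rows = []
    by_key: dict[tuple[str, str], dict] = {}
    for c in clients.itertuples(index=False):
        key = (c.cohort, stratum_of(c))
        entry = by_key.setdefault(key, {
            "n_persons": 0,
            "medicines": 0, "services": 0, "hospital_episodes": 0, "ed_visits": 0,
            "monthly": np.zeros(n_months, dtype=int),
            "med_categories": {}, "svc_categories": {},
        })
        entry["n_persons"] += 1
        w = ObservationWindow(c.death_date, n_months)
        for d in bundle.for_person("dispensings", c.person_id).itertuples(index=False):
            if d.supply_date in w:
                entry["medicines"] += 1
                entry["monthly"][w.month_of(d.supply_date) - 1] += 1
                cat = medicine_map.category(d.atc_code)
                entry["med_categories"][cat] = entry["med_categories"].get(cat, 0) + 1
        for s in bundle.for_person("service_claims", c.person_id).itertuples(index=False):
            if s.service_date in w:
                cat = service_map.category(s.item_id)
                if cat == "admin_billing":
                    continue  # costed elsewhere, never counted as resource use
                entry["services"] += 1
                entry["monthly"][w.month_of(s.service_date) - 1] += 1
                entry["svc_categories"][cat] = entry["svc_categories"].get(cat, 0) + 1
        for e in bundle.for_person("hospital_episodes", c.person_id).itertuples(index=False):
            if e.admission_date in w:
                entry["hospital_episodes"] += 1
                entry["monthly"][w.month_of(e.admission_date) - 1] += 1
        for v in bundle.for_person("ed_visits", c.person_id).itertuples(index=False):
            if v.visit_date in w:
                entry["ed_visits"] += 1
                entry["monthly"][w.month_of(v.visit_date) - 1] += 1

    for (cohort, stratum), e in sorted(by_key.items()):
        n = e["n_persons"]
        total_records = e["medicines"] + e["services"] + e["hospital_episodes"] + e["ed_visits"]
        med_total = sum(e["med_categories"].values()) or 1
        svc_total = sum(e["svc_categories"].values()) or 1
        row = {
            "cohort": cohort, "stratum": stratum, "n_persons": n,
            "medicines": e["medicines"], "services": e["services"],
            "hospital_episodes": e["hospital_episodes"], "ed_visits": e["ed_visits"],
            "records_per_person": total_records / n,
            "person_years": person_years(n, n_months),
        }
        for m in range(n_months):
            row[f"events_month_{m + 1}"] = int(e["monthly"][m])
        for cat, count in sorted(e["med_categories"].items()):
            row[f"med_share_{cat}"] = count / med_total
        for cat, count in sorted(e["svc_categories"].items()):
            row[f"svc_share_{cat}"] = count / svc_total
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class IndicatorDefinition:
    """Count-of-events >= threshold inside the last *window_days* of life."""

    name: str
    source: str  # ed_visits | hospital_admissions | hospital_days | service_claims | dispensings
    window_days: int
    threshold: int = 1
    direction: str = "aggressive"  # or palliative
    category: str | None = None
    items: tuple[str, ...] = ()
    atc_prefixes: tuple[str, ...] = ()

    VALID_SOURCES = (
        "ed_visits", "hospital_admissions", "hospital_days",
        "service_claims", "dispensings",
    )

    def __post_init__(self) -> None:
        if self.source not in self.VALID_SOURCES:
            raise ValueError(
                f"indicator {self.name!r}: unknown source {self.source!r}; "
                f"valid: {self.VALID_SOURCES}"
            )
        if self.window_days < 1 or self.threshold < 1:
            raise ValueError(f"indicator {self.name!r}: window and threshold must be >= 1")
        self.items = tuple(self.items)
        self.atc_prefixes = tuple(self.atc_prefixes)


def load_indicator_definitions(path: str | Path | None = None) -> list[IndicatorDefinition]:
    if path is None:
        raw = yaml.safe_load(
            resources.files("eolcare.data").joinpath("indicators.yaml").read_text()
        )
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return [IndicatorDefinition(**item) for item in raw]


def _event_count(defn: IndicatorDefinition, bundle: DatasetBundle, pid: str, death) -> int:
    horizon = timedelta(days=defn.window_days - 1)
    lo = death - horizon

    def in_win(d) -> bool:
        return lo <= d <= death

    if defn.source == "ed_visits":
        return sum(in_win(v.visit_date) for v in
                   bundle.for_person("ed_visits", pid).itertuples(index=False))
    if defn.source == "hospital_admissions":
        return sum(in_win(e.admission_date) for e in
                   bundle.for_person("hospital_episodes", pid).itertuples(index=False))
    if defn.source == "hospital_days":
        total = 0
        for e in bundle.for_person("hospital_episodes", pid).itertuples(index=False):
            los = _los(e.admission_date, e.separation_date)
            for i in range(los):
                if in_win(e.admission_date + timedelta(days=i)):
                    total += 1
        return total
    if defn.source == "service_claims":
        count = 0
        for s in bundle.for_person("service_claims", pid).itertuples(index=False):
            if in_win(s.service_date) and (not defn.items or s.item_id in defn.items):
                count += 1
        return count
    count = 0
    for d in bundle.for_person("dispensings", pid).itertuples(index=False):
        if in_win(d.supply_date) and (
            not defn.atc_prefixes
            or any(d.atc_code.upper().startswith(p.upper()) for p in defn.atc_prefixes)
        ):
            count += 1
    return count


def compute_indicators(
    bundle: DatasetBundle,
    cohorts: pd.DataFrame,
    definitions: list[IndicatorDefinition] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate indicators per person; return (person table, cohort proportions)."""
    definitions = definitions if definitions is not None else load_indicator_definitions()
    clients = bundle.clients.merge(cohorts, on="person_id")
    clients = clients.loc[clients["cohort"].isin(["cancer", "non_cancer"])]
    person_rows = []
    for c in clients.itertuples(index=False):
        row = {"person_id": c.person_id, "cohort": c.cohort}
        for defn in definitions:
            row[defn.name] = _event_count(defn, bundle, c.person_id, c.death_date) >= defn.threshold
        person_rows.append(row)
    person_table = pd.DataFrame(person_rows)

    cohort_rows = []
    for cohort, group in person_table.groupby("cohort"):
        for defn in definitions:
            numerator = int(group[defn.name].sum())
            denominator = int(len(group))
            cohort_rows.append({
                "cohort": cohort, "indicator": defn.name,
                "direction": defn.direction,
                "numerator": numerator, "denominator": denominator,
                "proportion": numerator / denominator if denominator else float("nan"),
            })
    return person_table, pd.DataFrame(cohort_rows)


def derive_threshold(values, percentile: float):
    """Nearest-rank percentile of *values*, for empirical indicator cut-offs.

    The nearest-rank definition returns the smallest element with at
    least ``p`` percent of the sample at or below it.
    """
    vals = sorted(values)
    if not vals:
        raise ValueError("cannot derive a threshold from an empty sequence")
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must lie in (0, 100), got {percentile}")
    rank = int(np.ceil(percentile / 100 * len(vals)))
    return vals[rank - 1]
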