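"""Clinical classification: cause-of-death groups, end-of-life medicine
categories, service categories, and the two comorbidity measures.

Cause-of-death grouping follows six literal ICD-10 code sets (cancer =
the notifiable set, heart failure, cerebrovascular disease, coronary
heart disease, COPD, dementia); everything else is ``other`` and a
missing cause stays missing.

The Charlson index uses hospital episodes admitted in constructed
months 18 to 7 before death (days 180-539) — the 12 months preceding
the final 6 months of life — with each condition counted once; with no
admissions in that window the score cannot be calculated.  The
medication-based (RxRisk-style) score counts distinct comorbidity
categories among dispensings in months 12 to 7 (days 180-359).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .bundle import DatasetBundle
from .icd import CodeSet, NOTIFIABLE_CANCER, normalize_icd10

__all__ = [
    "MappingError",
    "COD_GROUPS",
    "group_cause_of_death",
    "EolMedicineMap",
    "ServiceCategoryMap",
    "charlson",
    "rxrisk",
    "ComorbidityResult",
    "survival_fields",
    "load_charlson_mapping",
    "load_rxrisk_mapping",
]


class MappingError(ValueError):
    """Invalid classification mapping file (conflicts, duplicates)."""


COD_GROUPS: dict[str, CodeSet] = {
    "cancer": NOTIFIABLE_CANCER,
    "heart_failure": CodeSet("heart_failure", (
        "I21", "I22", "I25.2", "I50", "I70-I74", "I79.0", "R02", "Z95.8", "Z95.9",
    )),
    "cerebrovascular": CodeSet("cerebrovascular", ("I60-I69",)),
    "coronary_heart_disease": CodeSet("coronary_heart_disease", (
        "I20", "I23", "I24", "I25.0", "I25.1", "I25.3-I25.9",
    )),
    "copd": CodeSet("copd", ("J40-J44",)),
    "dementia": CodeSet("dementia", ("F00-F03", "F05.1", "G30", "G31")),
}


def group_cause_of_death(code: str | None) -> str | None:
    """Map an underlying cause of death to its group, or ``other``.

    Missing input stays missing; malformed codes raise.
    """
    if code is None or (isinstance(code, float) and pd.isna(code)):
        return None
    normalize_icd10(code)  # validate early, even if no group matches
    for group, codeset in COD_GROUPS.items():
        if code in codeset:
            return group
    return "other"


def _strip_dot(code: str) -> str:
    return code.replace(".", "").upper()


@dataclass
class EolMedicineMap:
    """Longest-prefix ATC mapping to end-of-life medicine categories."""

    prefix_to_category: dict[str, str]

    CATEGORIES = ("symptom_management", "active_treatment", "essential", "non_essential")

    @classmethod
    def from_dict(cls, raw: dict) -> "EolMedicineMap":
        table: dict[str, str] = {}
        for category, prefixes in raw.items():
            if category not in cls.CATEGORIES:
                raise MappingError(f"unknown medicine category {category!r}")
            for prefix in prefixes:
                prefix = prefix.upper()
                if prefix in table and table[prefix] != category:
                    raise MappingError(
                        f"ATC prefix {prefix!r} mapped to both {table[prefix]!r} "
                        f"and {category!r}"
                    )
                table[prefix] = category
        return cls(table)

    @classmethod
    def from_file(cls, path: str | Path) -> "EolMedicineMap":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "EolMedicineMap":
        raw = yaml.safe_load(
            resources.files("eolcare.data").joinpath("atc_eol_categories.yaml").read_text()
        )
        return cls.from_dict(raw)

    def category(self, atc: str) -> str:
        """Category of *atc* under longest-prefix match, or ``unmapped``."""
        atc = atc.upper()
        for n in range(len(atc), 0, -1):
            hit = self.prefix_to_category.get(atc[:n])
            if hit:
                return hit
        return "unmapped"


@dataclass
class ServiceCategoryMap:
    """Exact item-id mapping to service categories."""

    item_to_category: dict[str, str]

    CATEGORIES = (
        "diagnostics_imaging_pathology", "practitioner_visit",
        "allied_health_nursing_careplan", "therapeutic_procedure",
        "surgery", "dental", "admin_billing",
    )

    @classmethod
    def from_file(cls, path: str | Path) -> "ServiceCategoryMap":
        return cls._parse(Path(path).read_text())

    @classmethod
    def default(cls) -> "ServiceCategoryMap":
        return cls._parse(
            resources.files("eolcare.data").joinpath("service_categories.csv").read_text()
        )

    @classmethod
    def _parse(cls, text: str) -> "ServiceCategoryMap":
        import csv
        rows = [r for r in text.splitlines() if r.strip() and not r.startswith("#")]
        table: dict[str, str] = {}
        for lineno, row in enumerate(csv.DictReader(rows), start=2):
            item, category = row["item_id"], row["category"]
            if category not in cls.CATEGORIES:
                raise MappingError(f"line {lineno}: unknown service category {category!r}")
            if item in table:
                raise MappingError(f"line {lineno}: duplicate item {item!r}")
            table[item] = category
        return cls(table)

    def category(self, item_id: str) -> str:
        return self.item_to_category.get(item_id, "unmapped")

    def count_excluded(self, item_id: str) -> bool:
        """Admin/billing items are kept for costing but not counted as use."""
        return self.category(item_id) == "admin_billing"


@dataclass
class ComorbidityResult:
    person_id: str
    measure: str  # charlson | rxrisk
    raw_score: int | None  # None = not calculable
    bucket: str


CHARLSON_WINDOW = (180, 539)  # days before death, inclusive (months 7-18)
RXRISK_WINDOW = (180, 359)    # days before death, inclusive (months 7-12)


def load_charlson_mapping(path: str | Path | None = None) -> dict[str, tuple[str, int]]:
    """ICD-10 prefix (dot removed) -> (condition, weight)."""
    if path is None:
        raw = yaml.safe_load(
            resources.files("eolcare.data").joinpath("charlson_icd10.yaml").read_text()
        )
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    table: dict[str, tuple[str, int]] = {}
    for condition, spec in raw.items():
        for prefix in spec["prefixes"]:
            prefix = str(prefix).upper()
            if prefix in table:
                raise MappingError(f"Charlson prefix {prefix!r} appears twice")
            table[prefix] = (condition, int(spec["weight"]))
    return table


def load_rxrisk_mapping(path: str | Path | None = None) -> dict[str, str]:
    """ATC prefix -> comorbidity category."""
    if path is None:
        raw = yaml.safe_load(
            resources.files("eolcare.data").joinpath("rxrisk_atc.yaml").read_text()
        )
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    table: dict[str, str] = {}
    for category, prefixes in raw.items():
        for prefix in prefixes:
            prefix = prefix.upper()
            if prefix in table and table[prefix] != category:
                raise MappingError(f"RxRisk prefix {prefix!r} mapped twice")
            table[prefix] = category
    return table


def _charlson_bucket(score: int | None) -> str:
    if score is None:
        return "not_calculable"
    if score == 0:
        return "0"
    if score <= 2:
        return "1-2"
    return ">=3"


def _rxrisk_bucket(score: int) -> str:
    if score == 0:
        return "0"
    if score <= 2:
        return "1-2"
    if score <= 5:
        return "3-5"
    return ">=6"


def charlson(
    person_id: str,
    episodes: pd.DataFrame,
    death_date: date,
    mapping: dict[str, tuple[str, int]] | None = None,
    use_all_diagnosis_fields: bool = True,
) -> ComorbidityResult:
    """Charlson score from hospital diagnoses in months 18-7 before death."""
    mapping = mapping if mapping is not None else load_charlson_mapping()
    lo = death_date - timedelta(days=CHARLSON_WINDOW[1])
    hi = death_date - timedelta(days=CHARLSON_WINDOW[0])
    in_window = episodes.loc[
        episodes["admission_date"].map(lambda d: lo <= d <= hi)
    ] if len(episodes) else episodes
    if len(in_window) == 0:
        return ComorbidityResult(person_id, "charlson", None, "not_calculable")
    conditions: dict[str, int] = {}
    for e in in_window.itertuples(index=False):
        codes = (e.diagnoses or "").split(";") if e.diagnoses else []
        if not use_all_diagnosis_fields:
            codes = codes[:1]
        for code in codes:
            stripped = _strip_dot(code)
            for n in range(len(stripped), 0, -1):
                hit = mapping.get(stripped[:n])
                if hit:
                    conditions[hit[0]] = hit[1]
                    break
    score = sum(conditions.values())
    return ComorbidityResult(person_id, "charlson", score, _charlson_bucket(score))


def rxrisk(
    person_id: str,
    dispensings: pd.DataFrame,
    death_date: date,
    mapping: dict[str, str] | None = None,
) -> ComorbidityResult:
    """Distinct medication-comorbidity categories in months 12-7 before death."""
    mapping = mapping if mapping is not None else load_rxrisk_mapping()
    lo = death_date - timedelta(days=RXRISK_WINDOW[1])
    hi = death_date - timedelta(days=RXRISK_WINDOW[0])
    categories: set[str] = set()
    for d in dispensings.itertuples(index=False):
        if not (lo <= d.supply_date <= hi):
            continue
        atc = d.atc_code.upper()
        for n in range(len(atc), 0, -1):
            hit = mapping.get(atc[:n])
            if hit:
                categories.add(hit)
                break
    score = len(categories)
    return ComorbidityResult(person_id, "rxrisk", score, _rxrisk_bucket(score))


def survival_fields(
    registry_records: pd.DataFrame, birth_date: date, death_date: date
) -> dict:
    """Age at diagnosis, time from diagnosis to death (years, 1 d.p.) and
    spread, from the earliest registry record; flags multiple distinct
    cancer categories."""
    if registry_records.empty:
        raise ValueError("no registry records for survival fields")
    recs = registry_records.sort_values("diagnosis_date")
    first = recs.iloc[0]
    dx = first["diagnosis_date"]
    if dx > death_date:
        raise ValueError(
            f"diagnosis {dx.isoformat()} after death {death_date.isoformat()}"
        )
    categories = {normalize_icd10(c)[:3] for c in recs["cancer_code"]}
    return {
        "cancer_code": first["cancer_code"],
        "spread": first["spread"],
        "age_at_diagnosis": round((dx - birth_date).days / 365.25, 1),
        "time_to_death": round((death_date - dx).days / 365.25, 1),
        "multiple_cancers": len(categories) > 1,
    }


def classify_bundle(
    bundle: DatasetBundle,
    medicine_map: EolMedicineMap | None = None,
    service_map: ServiceCategoryMap | None = None,
    charlson_mapping=None,
    rxrisk_mapping=None,
) -> pd.DataFrame:
    """Per-person classification table: COD group and comorbidity buckets."""
    medicine_map = medicine_map or EolMedicineMap.default()
    service_map = service_map or ServiceCategoryMap.default()
    charlson_mapping = charlson_mapping if charlson_mapping is not None else load_charlson_mapping()
    rxrisk_mapping = rxrisk_mapping if rxrisk_mapping is not None else load_rxrisk_mapping()
    cod_by_person = {
        r.person_id: r.underlying_cause
        for r in bundle.deaths.itertuples(index=False)
    }
    rows = []
    for client in bundle.clients.itertuples(index=False):
        pid = client.person_id
        ch = charlson(
            pid, bundle.for_person("hospital_episodes", pid),
            client.death_date, charlson_mapping,
        )
        rx = rxrisk(
            pid, bundle.for_person("dispensings", pid),
            client.death_date, rxrisk_mapping,
        )
        rows.append({
            "person_id": pid,
            "cod_group": group_cause_of_death(cod_by_person.get(pid)),
            "charlson_score": ch.raw_score,
            "charlson_bucket": ch.bucket,
            "rxrisk_score": rx.raw_score,
            "rxrisk_bucket": rx.bucket,
        })
    return pd.DataFrame(rows)
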