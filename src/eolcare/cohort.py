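"""Decedent cohort construction: base eligibility plus the cancer /
non-cancer assignment hierarchy.

Every decedent is first tested against five base criteria (full Gold
entitlement over the last 12 constructed months, state residence over
the last 18, age >= 65 at death, death inside the study window, at
least one claim in the last 12 months).  Base-eligible decedents with a
notifiable cancer in the registry or as any coded cause of death form
the cancer cohort.  The remainder are screened, in fixed order, for
indirect evidence of cancer — hospital cancer procedures/diagnoses,
antineoplastic (ATC class L) dispensings outside an exception list,
intravenous fluorouracil, cancer-indicative service items, and
non-notifiable cancer causes of death — and only decedents clearing all
steps enter the non-cancer cohort.  The first triggering rule is
recorded, so the output is an attrition table as much as a cohort list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .bundle import DatasetBundle, parse_periods
from .icd import NOTIFIABLE_CANCER, NON_NOTIFIABLE_CANCER_COD, is_notifiable
from .windows import DAYS_PER_MONTH

__all__ = [
    "LClassPolicy",
    "CohortConfig",
    "EligibilityResult",
    "CohortAssignment",
    "check_base_eligibility",
    "assign_cancer",
    "screen_non_cancer",
    "build_cohorts",
    "is_notifiable",
]

BASE_CRITERIA = ("entitlement_12m", "residence_18m", "age_65", "death_window", "min_one_claim")


@dataclass(frozen=True)
class LClassPolicy:
    """Which ATC class-L dispensings do *not* exclude from the non-cancer cohort.

    ``excepted_atc`` codes are retained; fluorouracil (L01BC02) is
    retained in cream form only and excluded outright in intravenous
    form; every other class-L code excludes.
    """

    excepted_atc: frozenset[str] = frozenset({
        "L01AA01", "L01AA02", "L01BA01", "L01BB02", "L01XC02",
        "L02AB02", "L02AE03", "L03AA02", "L03AX03", "L04AA06",
        "L04AA13", "L04AB01", "L04AB02", "L04AB04", "L04AD01",
        "L04AX01", "L04AX03",
    })
    fluorouracil_code: str = "L01BC02"
    fluorouracil_retained_forms: frozenset[str] = frozenset({"cream"})

    def classify(self, atc: str, form: str) -> str | None:
        """None if retained, else the exclusion reason."""
        if not atc.upper().startswith("L"):
            return None
        atc = atc.upper()
        if atc == self.fluorouracil_code:
            if form == "intravenous":
                return "iv_fluorouracil"
            if form in self.fluorouracil_retained_forms:
                return None
            return "lclass_drug"
        if atc in self.excepted_atc:
            return None
        return "lclass_drug"


@dataclass
class CohortConfig:
    """Windows and code sets governing eligibility and screening."""

    death_window: tuple[date, date] = (date(2005, 6, 30), date(2009, 12, 31))
    registry_window: tuple[date, date] = (date(1994, 1, 1), date(2008, 12, 31))
    cod_window: tuple[date, date] = (date(1994, 1, 1), date(2007, 12, 31))
    hospital_screen_window: tuple[date, date] = (date(2000, 7, 1), date(2009, 12, 31))
    drug_screen_window: tuple[date, date] = (date(2004, 7, 1), date(2009, 12, 31))
    service_screen_window: tuple[date, date] = (date(2004, 7, 1), date(2009, 12, 31))
    entitlement_months: int = 12
    residence_months: int = 18
    min_age_years: int = 65
    entitlement_grace_days: int = 0
    required_state: str = "NSW"
    required_entitlement: str = "gold"
    policy: LClassPolicy = field(default_factory=LClassPolicy)
    cancer_service_items: frozenset[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cancer_service_items is None:
            raw = yaml.safe_load(
                resources.files("eolcare.data").joinpath("cancer_services.yaml").read_text()
            )
            self.cancer_service_items = frozenset(raw["cancer_indicative_items"])

    @classmethod
    def with_cancer_services(cls, path: str | Path, **kwargs) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(cancer_service_items=frozenset(raw["cancer_indicative_items"]), **kwargs)


@dataclass
class EligibilityResult:
    person_id: str
    failed_criteria: list[str]

    @property
    def eligible(self) -> bool:
        return not self.failed_criteria


@dataclass
class CohortAssignment:
    person_id: str
    cohort: str  # cancer | non_cancer | excluded_ineligible | excluded_screened
    reason: str
    evidence: str | None = None


def _covers(periods, tag_ok, start: date, end: date, grace_days: int = 0) -> bool:
    """True if qualifying periods cover [start, end] with at most
    *grace_days* uncovered days."""
    spans = sorted(
        (max(s, start), min(e, end))
        for s, e, t in periods
        if tag_ok(t) and s <= end and e >= start
    )
    uncovered = 0
    cursor = start
    for s, e in spans:
        if s > cursor:
            uncovered += (s - cursor).days
        cursor = max(cursor, e + timedelta(days=1))
        if cursor > end:
            break
    if cursor <= end:
        uncovered += (end - cursor).days + 1
    return uncovered <= grace_days


def _age_at(birth: date, on: date) -> int:
    return on.year - birth.year - ((on.month, on.day) < (birth.month, birth.day))


def check_base_eligibility(
    client, bundle: DatasetBundle, config: CohortConfig | None = None
) -> EligibilityResult:
    """Evaluate the five base criteria in fixed order, recording every failure."""
    config = config or CohortConfig()
    death = client.death_date
    failed: list[str] = []

    ent_start = death - timedelta(days=DAYS_PER_MONTH * config.entitlement_months - 1)
    if not _covers(
        parse_periods(client.entitlements),
        lambda t: t == config.required_entitlement,
        ent_start, death, config.entitlement_grace_days,
    ):
        failed.append("entitlement_12m")

    res_start = death - timedelta(days=DAYS_PER_MONTH * config.residence_months - 1)
    if not _covers(
        parse_periods(client.residences),
        lambda t: t == config.required_state,
        res_start, death, config.entitlement_grace_days,
    ):
        failed.append("residence_18m")

    if _age_at(client.birth_date, death) < config.min_age_years:
        failed.append("age_65")

    if not (config.death_window[0] <= death <= config.death_window[1]):
        failed.append("death_window")

    claim_start = death - timedelta(days=DAYS_PER_MONTH * config.entitlement_months - 1)
    pid = client.person_id
    has_claim = False
    for table, col in (
        ("dispensings", "supply_date"),
        ("service_claims", "service_date"),
        ("hospital_episodes", "admission_date"),
    ):
        dates = bundle.for_person(table, pid)[col]
        if any(claim_start <= d <= death for d in dates):
            has_claim = True
            break
    if not has_claim:
        failed.append("min_one_claim")

    return EligibilityResult(person_id=pid, failed_criteria=failed)


def assign_cancer(
    person_id: str, bundle: DatasetBundle, config: CohortConfig | None = None
) -> tuple[bool, str | None, str | None]:
    """(has_cancer, reason, evidence) from registry and cause of death."""
    config = config or CohortConfig()
    lo, hi = config.registry_window
    for rec in bundle.for_person("cancer_registry", person_id).itertuples(index=False):
        if lo <= rec.diagnosis_date <= hi and is_notifiable(rec.cancer_code):
            return True, "registry_cancer", rec.cancer_code
    clo, chi = config.cod_window
    for rec in bundle.for_person("deaths", person_id).itertuples(index=False):
        cause = rec.underlying_cause
        if cause and clo <= rec.death_date <= chi and is_notifiable(cause):
            return True, "cod_cancer", cause
    return False, None, None


def screen_non_cancer(
    person_id: str, bundle: DatasetBundle, config: CohortConfig | None = None
) -> CohortAssignment:
    """Apply the four screening steps in order; the first trigger wins."""
    config = config or CohortConfig()

    # step 1: hospital procedures/diagnoses
    lo, hi = config.hospital_screen_window
    episodes = bundle.for_person("hospital_episodes", person_id)
    for e in episodes.sort_values("admission_date").itertuples(index=False):
        if not (lo <= e.admission_date <= hi):
            continue
        codes = [c for f in (e.procedures, e.diagnoses) if f for c in f.split(";")]
        hit = NOTIFIABLE_CANCER.any_member(codes)
        if hit:
            return CohortAssignment(person_id, "excluded_screened", "hospital_procedure", hit)

    # step 2: class-L dispensings (exception list; IV fluorouracil)
    lo, hi = config.drug_screen_window
    disp = bundle.for_person("dispensings", person_id)
    for d in disp.sort_values("supply_date").itertuples(index=False):
        if not (lo <= d.supply_date <= hi):
            continue
        reason = config.policy.classify(d.atc_code, d.form)
        if reason:
            return CohortAssignment(person_id, "excluded_screened", reason, d.atc_code)

    # step 3: cancer-indicative services
    lo, hi = config.service_screen_window
    claims = bundle.for_person("service_claims", person_id)
    for s in claims.sort_values("service_date").itertuples(index=False):
        if lo <= s.service_date <= hi and s.item_id in config.cancer_service_items:
            return CohortAssignment(person_id, "excluded_screened", "cancer_service", s.item_id)

    # step 4: non-notifiable cancer cause of death
    for rec in bundle.for_person("deaths", person_id).itertuples(index=False):
        cause = rec.underlying_cause
        if cause and cause in NON_NOTIFIABLE_CANCER_COD:
            return CohortAssignment(person_id, "excluded_screened", "non_notifiable_cod", cause)

    return CohortAssignment(person_id, "non_cancer", "clean")


def build_cohorts(
    bundle: DatasetBundle, config: CohortConfig | None = None
) -> pd.DataFrame:
    """One :class:`CohortAssignment` row per client.

    Columns: person_id, cohort, reason, evidence.  The cohorts and
    exclusion buckets partition the client table.
    """
    config = config or CohortConfig()
    rows = []
    for client in bundle.clients.itertuples(index=False):
        elig = check_base_eligibility(client, bundle, config)
        if not elig.eligible:
            rows.append(CohortAssignment(
                client.person_id, "excluded_ineligible",
                f"base_ineligibility:{elig.failed_criteria[0]}",
                ";".join(elig.failed_criteria),
            ))
            continue
        has_cancer, reason, evidence = assign_cancer(client.person_id, bundle, config)
        if has_cancer:
            rows.append(CohortAssignment(client.person_id, "cancer", reason, evidence))
        else:
            rows.append(screen_non_cancer(client.person_id, bundle, config))
    return pd.DataFrame(
        [(a.person_id, a.cohort, a.reason, a.evidence) for a in rows],
        columns=["person_id", "cohort", "reason", "evidence"],
    )


def cohort_summary(assignments: pd.DataFrame) -> dict:
    """Figure-1-style attrition tallies by cohort and reason."""
    return {
        "by_cohort": assignments["cohort"].value_counts().to_dict(),
        "by_reason": assignments["reason"].value_counts().to_dict(),
        "n_clients": int(len(assignments)),
    }
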