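"""Rule-based cost attribution at the June 2010 (financial year 2009/10) price level.

Every resource event — dispensing, out-of-hospital service claim,
hospital episode, ED presentation — is turned into a
:class:`CostedItem` with an itemized component breakdown, and per-person
totals apply the double-counting corrections: in-hospital service
claims are assumed captured by the episode's casemix cost, and pharmacy
benefits dispensed during private hospital episodes are deducted from
the episode cost.

Inflation
---------
Medicines benefits are inflated monthly within the supply financial
year (July-June), then annually over later financial years, because
pharmaceutical price schedules update monthly.  Service benefits are
inflated over November-October schedule years, because the medical fee
schedule updates every November.  Both factors equal exactly 1 for
spends in the target price year.

Hospital episodes
-----------------
Sub- and non-acute (SNAP) episodes are costed per observed day at the
inlier SNAP weight times the average SNAP cost.  Acute episodes receive
cost-weight x base for inlier days (prorated when the admission predates
the observation window), a per-DRG outlier per-diem for days beyond the
trim point up to day 120, and an uncapped flat rate per day thereafter.
A bed-day is "observed" when its calendar date lies inside the window;
length of stay is separation minus admission in days, with same-day
stays counting as one day.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date, timedelta
from importlib import resources
from pathlib import Path

import yaml

from .bundle import DatasetBundle
from .windows import ObservationWindow

__all__ = [
    "CostConfigurationError",
    "InflationSchedule",
    "DRGParameters",
    "CostParameters",
    "CostedItem",
    "medicines_inflation_factor",
    "service_inflation_factor",
    "cost_dispensing",
    "cost_service",
    "cost_hospital_episode",
    "cost_ed_visit",
    "normalize_ed_weights",
    "total_person_cost",
]

SECTORS = ("mbs", "dental", "other")


class CostConfigurationError(ValueError):
    """Bad or missing costing parameter (unknown DRG, sector, date range)."""


def _fy_label(year_start: int) -> str:
    return f"{year_start}-{(year_start + 1) % 100:02d}"


def _financial_year_start(d: date) -> int:
    """Calendar year in which d's July-June financial year starts."""
    return d.year if d.month >= 7 else d.year - 1


def _schedule_year_start(d: date) -> int:
    """Calendar year in which d's November-October schedule year starts."""
    return d.year if d.month >= 11 else d.year - 1


@dataclass(frozen=True)
class InflationSchedule:
    """Percent inflation rates for medicines and service sectors."""

    medicines_annual: dict[str, float]
    medicines_monthly: dict[str, float]
    sector_annual: dict[str, dict[str, float]]
    final_year: str = "2009-10"

    @classmethod
    def from_dict(cls, raw: dict) -> "InflationSchedule":
        return cls(
            medicines_annual=dict(raw["medicines"]["annual"]),
            medicines_monthly=dict(raw["medicines"]["monthly"]),
            sector_annual={k: dict(v) for k, v in raw["sectors"].items()},
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "InflationSchedule":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "InflationSchedule":
        raw = yaml.safe_load(
            resources.files("eolcare.data").joinpath("inflation.yaml").read_text()
        )
        return cls.from_dict(raw)

    def validate(self) -> None:
        """Monthly rates must compound to roughly the annual rate."""
        for fy, annual in self.medicines_annual.items():
            monthly = self.medicines_monthly[fy]
            compounded = (1 + monthly / 100) ** 12 - 1
            target = annual / 100
            if target > 0 and abs(compounded - target) / target > 0.05:
                raise CostConfigurationError(
                    f"medicines monthly rate for {fy} compounds to "
                    f"{compounded:.6%}, far from annual {target:.6%}"
                )
        for sector, rates in self.sector_annual.items():
            if any(r < 0 for r in rates.values()):
                raise CostConfigurationError(f"negative rate in sector {sector!r}")


def medicines_inflation_factor(supply_date: date, schedule: InflationSchedule) -> float:
    """Cumulative factor taking one AUD at *supply_date* to the June 2010 level.

    The supply year's monthly rate is applied once per month remaining
    in the financial year after the supply month, then each later
    financial year's annual rate is applied once.
    """
    fy = _financial_year_start(supply_date)
    label = _fy_label(fy)
    if label not in schedule.medicines_monthly:
        raise CostConfigurationError(
            f"supply date {supply_date.isoformat()} outside medicines schedule coverage"
        )
    # months after the supply month through June of the supply financial year
    months_remaining = (6 - supply_date.month) % 12
    factor = (1 + schedule.medicines_monthly[label] / 100) ** months_remaining
    for later in range(fy + 1, 2010):
        later_label = _fy_label(later)
        if later_label not in schedule.medicines_annual:
            raise CostConfigurationError(
                f"no medicines annual rate for financial year {later_label}"
            )
        factor *= 1 + schedule.medicines_annual[later_label] / 100
    return factor


def service_inflation_factor(
    service_date: date, sector: str, schedule: InflationSchedule
) -> float:
    """Cumulative factor for a service benefit, chained over November-October
    schedule years strictly after the year containing *service_date*."""
    if sector not in schedule.sector_annual:
        raise CostConfigurationError(
            f"unknown sector {sector!r}; expected one of {sorted(schedule.sector_annual)}"
        )
    rates = schedule.sector_annual[sector]
    year_starts = sorted(int(label[:4]) for label in rates)
    sy = _schedule_year_start(service_date)
    if sy < year_starts[0] - 1 or sy > year_starts[-1]:
        raise CostConfigurationError(
            f"service date {service_date.isoformat()} outside {sector} schedule coverage"
        )
    factor = 1.0
    for later in year_starts:
        if later > sy:
            factor *= 1 + rates[_fy_label(later)] / 100
    return factor


@dataclass(frozen=True)
class DRGParameters:
    drg_code: str
    care_type: str  # acute | snap
    cost_weight: float | None
    trim_point_days: int | None
    outlier_per_diem: float | None


@dataclass
class CostParameters:
    """All costing constants, at the 2009/10 price level."""

    snap_average_cost: float
    snap_inlier_weight: float
    acute_base_excl_ed_icu: float
    acute_base_excl_ed: float
    use_base_excl_ed_icu: bool
    long_stay_flat_rate: float
    long_stay_threshold_days: int
    ed_average_cost: float
    ed_mode_weights: dict[str, float]
    concessional_copay: float
    inflate_copay: bool
    drg_table: dict[str, DRGParameters] = field(default_factory=dict)

    @property
    def acute_base(self) -> float:
        return self.acute_base_excl_ed_icu if self.use_base_excl_ed_icu else self.acute_base_excl_ed

    @classmethod
    def from_files(cls, params_path=None, drg_table_path=None) -> "CostParameters":
        if params_path is None:
            raw = yaml.safe_load(
                resources.files("eolcare.data").joinpath("cost_params.yaml").read_text()
            )
        else:
            with open(params_path) as fh:
                raw = yaml.safe_load(fh)
        if drg_table_path is None:
            text = resources.files("eolcare.data").joinpath("synthetic_drg_table.csv").read_text()
        else:
            text = Path(drg_table_path).read_text()
        drg_table = _parse_drg_table(text)
        params = cls(drg_table=drg_table, **raw)
        params.validate()
        return params

    @classmethod
    def default(cls) -> "CostParameters":
        return cls.from_files()

    def validate(self) -> None:
        for name in (
            "snap_average_cost", "snap_inlier_weight", "acute_base_excl_ed_icu",
            "acute_base_excl_ed", "long_stay_flat_rate", "ed_average_cost",
        ):
            if getattr(self, name) <= 0:
                raise CostConfigurationError(f"{name} must be positive")
        if any(w <= 0 for w in self.ed_mode_weights.values()):
            raise CostConfigurationError("ED mode weights must be positive")

    def drg(self, code: str) -> DRGParameters:
        try:
            return self.drg_table[code]
        except KeyError:
            raise CostConfigurationError(f"DRG code {code!r} not in the DRG table") from None


def _parse_drg_table(text: str) -> dict[str, DRGParameters]:
    rows = [r for r in text.splitlines() if r.strip() and not r.startswith("#")]
    table: dict[str, DRGParameters] = {}
    for row in csv.DictReader(rows):
        code = row["drg_code"]
        if code in table:
            raise CostConfigurationError(f"duplicate DRG code {code!r} in DRG table")
        acute = row["care_type"] == "acute"
        table[code] = DRGParameters(
            drg_code=code,
            care_type=row["care_type"],
            cost_weight=float(row["cost_weight"]) if acute else None,
            trim_point_days=int(float(row["trim_point_days"])) if acute else None,
            outlier_per_diem=float(row["outlier_per_diem"]) if acute else None,
        )
    return table


@dataclass
class CostedItem:
    """One resource event with its 2009/10-AUD cost and breakdown."""

    person_id: str
    source: str  # medicine | service | hospital | ed
    event_date: date
    nominal_cost: float
    inflation_factor: float
    final_cost: float
    components: dict[str, float] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)
    reference: str | None = None

    def __post_init__(self) -> None:
        total = sum(self.components.values())
        if abs(total - self.final_cost) > 1e-6:
            raise ValueError(
                f"components sum to {total}, final_cost is {self.final_cost}"
            )


def cost_dispensing(
    d, params: CostParameters, schedule: InflationSchedule
) -> CostedItem:
    """Cost one dispensing row: inflated benefit plus (optionally inflated)
    concessional co-payment when applicable."""
    factor = medicines_inflation_factor(d.supply_date, schedule)
    benefit = float(d.benefit_paid) * factor
    components = {"benefit_inflated": benefit}
    if d.copay_applicable:
        copay = params.concessional_copay * (factor if params.inflate_copay else 1.0)
        components["copay"] = copay
    flags = {"private_hospital_pharmacy"} if d.private_hospital_flag else set()
    final = sum(components.values())
    return CostedItem(
        person_id=d.person_id, source="medicine", event_date=d.supply_date,
        nominal_cost=float(d.benefit_paid), inflation_factor=factor,
        final_cost=final, components=components, flags=flags,
    )


def cost_service(s, schedule: InflationSchedule) -> CostedItem:
    """Cost one service claim; services are bulk-billed so no co-payment."""
    factor = service_inflation_factor(s.service_date, s.sector, schedule)
    final = float(s.benefit_paid) * factor
    flags = {"in_hospital_service"} if s.in_hospital_flag else set()
    return CostedItem(
        person_id=s.person_id, source="service", event_date=s.service_date,
        nominal_cost=float(s.benefit_paid), inflation_factor=factor,
        final_cost=final, components={"benefit_inflated": final}, flags=flags,
    )


def _episode_days(admission: date, separation: date) -> list[date]:
    los = max((separation - admission).days, 1)
    return [admission + timedelta(days=i) for i in range(los)]


def cost_hospital_episode(
    e, window: ObservationWindow, params: CostParameters
) -> CostedItem:
    """Casemix cost of one hospital episode, restricted to observed days."""
    days = _episode_days(e.admission_date, e.separation_date)
    los = len(days)
    observed = [d in window for d in days]
    n_observed = sum(observed)
    partially_observed = n_observed < los
    components: dict[str, float] = {}
    flags: set[str] = set()
    if partially_observed:
        flags.add("partially_observed")

    if e.care_type == "snap":
        components["snap_per_diem"] = (
            params.snap_inlier_weight * params.snap_average_cost * n_observed
        )
    else:
        drg = params.drg(e.drg_code)
        if drg.care_type != "acute":
            raise CostConfigurationError(
                f"episode {getattr(e, 'episode_id', '?')} is acute but DRG "
                f"{e.drg_code!r} is typed {drg.care_type!r}"
            )
        trim = drg.trim_point_days
        cutoff = params.long_stay_threshold_days
        inlier_total = min(los, trim)
        inlier_observed = sum(observed[:inlier_total])
        prorate = inlier_observed / inlier_total if inlier_total else 0.0
        components["inlier"] = drg.cost_weight * params.acute_base * prorate
        outlier_observed = sum(observed[trim:min(los, cutoff)]) if los > trim else 0
        if outlier_observed:
            components["outlier_per_diem"] = drg.outlier_per_diem * outlier_observed
        flat_observed = sum(observed[cutoff:]) if los > cutoff else 0
        if flat_observed:
            components["long_stay_flat"] = params.long_stay_flat_rate * flat_observed

    final = sum(components.values())
    return CostedItem(
        person_id=e.person_id, source="hospital", event_date=e.admission_date,
        nominal_cost=final, inflation_factor=1.0, final_cost=final,
        components=components, flags=flags,
        reference=getattr(e, "episode_id", None),
    )


def cost_ed_visit(v, params: CostParameters) -> CostedItem:
    """Average presentation cost weighted by mode of separation."""
    try:
        weight = params.ed_mode_weights[v.outcome]
    except KeyError:
        raise CostConfigurationError(f"no ED weight for outcome {v.outcome!r}") from None
    final = params.ed_average_cost * weight
    return CostedItem(
        person_id=v.person_id, source="ed", event_date=v.visit_date,
        nominal_cost=params.ed_average_cost, inflation_factor=weight,
        final_cost=final, components={"weighted_presentation": final},
    )


def normalize_ed_weights(
    raw_weights: dict[str, float], outcome_mix: dict[str, float]
) -> dict[str, float]:
    """Scale relative ED weights so the configured outcome mix averages to 1,
    keeping the mean presentation cost equal to the average cost."""
    mean = sum(outcome_mix[o] * raw_weights[o] for o in outcome_mix)
    if mean <= 0:
        raise CostConfigurationError("outcome mix and weights average to zero")
    return {o: w / mean for o, w in raw_weights.items()}


def total_person_cost(
    person_id: str,
    bundle: DatasetBundle,
    window: ObservationWindow,
    params: CostParameters,
    schedule: InflationSchedule,
) -> tuple[dict[str, float], list[CostedItem]]:
    """Per-person cost breakdown over the observation window.

    Returns ``(breakdown, ledger)``.  The breakdown has keys
    ``medicines``, ``services_out_of_hospital``, ``services_in_hospital``
    (costed but excluded from the total), ``hospital``, ``ed``,
    ``private_pharmacy_deduction`` and ``total``; the ledger holds every
    CostedItem so the total is re-derivable as an accounting identity.
    """
    ledger: list[CostedItem] = []
    episodes = bundle.for_person("hospital_episodes", person_id)
    episode_spans = [
        (row.admission_date, row.separation_date, row.facility_type)
        for row in episodes.itertuples(index=False)
    ]

    medicines = 0.0
    for d in bundle.for_person("dispensings", person_id).itertuples(index=False):
        if d.supply_date in window:
            item = cost_dispensing(d, params, schedule)
            ledger.append(item)
            medicines += item.final_cost

    services_out = services_in = 0.0
    for s in bundle.for_person("service_claims", person_id).itertuples(index=False):
        if s.service_date not in window:
            continue
        item = cost_service(s, schedule)
        in_hospital = s.in_hospital_flag or any(
            adm <= s.service_date <= sep for adm, sep, _ in episode_spans
        )
        if in_hospital:
            item.flags.add("in_hospital_service")
            services_in += item.final_cost
        else:
            services_out += item.final_cost
        ledger.append(item)

    hospital = 0.0
    deduction_total = 0.0
    for e in episodes.itertuples(index=False):
        if window.observed_days(e.admission_date, e.separation_date) == 0:
            continue
        item = cost_hospital_episode(e, window, params)
        if e.facility_type == "private":
            in_episode = bundle.for_person("dispensings", person_id)
            mask = in_episode.apply(
                lambda r: bool(r["private_hospital_flag"])
                and e.admission_date <= r["supply_date"] <= e.separation_date,
                axis=1,
            ) if len(in_episode) else []
            pharmacy = float(in_episode.loc[mask, "benefit_paid"].sum()) if len(in_episode) else 0.0
            deduction = min(pharmacy, item.final_cost)  # floored at zero episode cost
            if deduction > 0:
                item.flags.add("private_pharmacy_deducted")
                item.components["pharmacy_deduction"] = -deduction
                item.final_cost -= deduction
                deduction_total += deduction
        ledger.append(item)
        hospital += item.final_cost

    ed = 0.0
    for v in bundle.for_person("ed_visits", person_id).itertuples(index=False):
        if v.visit_date in window:
            item = cost_ed_visit(v, params)
            ledger.append(item)
            ed += item.final_cost

    breakdown = {
        "medicines": medicines,
        "services_out_of_hospital": services_out,
        "services_in_hospital": services_in,
        "hospital": hospital,
        "ed": ed,
        "private_pharmacy_deduction": deduction_total,
        "total": medicines + services_out + hospital + ed,
    }
    return breakdown, ledger
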