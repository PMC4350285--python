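"""Linked dataset bundle: in-memory container and exact CSV round-trip I/O.

The bundle holds one :class:`pandas.DataFrame` per source dataset of the
linkage (client file, cancer registry, death registry, dispensing
claims, service claims, hospital episodes, ED visits, residential aged
care), keyed throughout by ``person_id``.  Serialization is one UTF-8
CSV per table plus a JSON manifest recording seed, config hash and row
counts; ``read_bundle(write_bundle(b)) == b`` exactly.

Nested period columns (entitlement/residence histories, episode
diagnosis lists) are stored as compact delimited strings so each table
remains a flat CSV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

__all__ = [
    "BundleFormatError",
    "DatasetBundle",
    "TABLE_SCHEMAS",
    "write_bundle",
    "read_bundle",
    "format_periods",
    "parse_periods",
]


class BundleFormatError(ValueError):
    """Missing table file, unknown column, or schema mismatch on read."""


# column kinds: str, date, date_opt, float, int_opt, bool, str_opt
TABLE_SCHEMAS: dict[str, dict[str, str]] = {
    "clients": {
        "person_id": "str",
        "sex": "str",
        "birth_date": "date",
        "death_date": "date",
        "entitlements": "str",   # start|end|level;...
        "residences": "str",     # start|end|state;...
        "remoteness": "str",
        "seifa_decile": "int_opt",
    },
    "cancer_registry": {
        "person_id": "str",
        "cancer_code": "str",
        "diagnosis_date": "date",
        "spread": "str",
        "registry_cod": "str",
    },
    "deaths": {
        "person_id": "str",
        "death_date": "date",
        "underlying_cause": "str_opt",
    },
    "dispensings": {
        "person_id": "str",
        "supply_date": "date",
        "atc_code": "str",
        "form": "str",
        "quantity": "float",
        "benefit_paid": "float",
        "copay_applicable": "bool",
        "private_hospital_flag": "bool",
    },
    "service_claims": {
        "person_id": "str",
        "service_date": "date",
        "item_id": "str",
        "benefit_paid": "float",
        "sector": "str",
        "in_hospital_flag": "bool",
    },
    "hospital_episodes": {
        "episode_id": "str",
        "person_id": "str",
        "admission_date": "date",
        "separation_date": "date",
        "drg_code": "str",
        "care_type": "str",
        "diagnoses": "str_opt",   # ;-separated ICD-10
        "procedures": "str_opt",  # ;-separated ICD-10
        "source_of_referral": "str",
        "separation_mode": "str",
        "facility_type": "str",
    },
    "ed_visits": {
        "person_id": "str",
        "visit_date": "date",
        "outcome": "str",
    },
    "aged_care_stays": {
        "person_id": "str",
        "entry_date": "date",
        "exit_date": "date_opt",
        "care_type": "str",
    },
}

_CLAIMS_TABLES = (
    "cancer_registry", "deaths", "dispensings", "service_claims",
    "hospital_episodes", "ed_visits", "aged_care_stays",
)


def format_periods(periods) -> str:
    """[(start, end, tag), ...] -> 'start|end|tag;...' (ISO-8601 dates)."""
    return ";".join(f"{s.isoformat()}|{e.isoformat()}|{t}" for s, e, t in periods)


def parse_periods(text: str) -> list[tuple[date, date, str]]:
    if not text:
        return []
    out = []
    for chunk in text.split(";"):
        s, e, t = chunk.split("|")
        out.append((date.fromisoformat(s), date.fromisoformat(e), t))
    return out


def empty_table(name: str) -> pd.DataFrame:
    schema = TABLE_SCHEMAS[name]
    return pd.DataFrame({col: pd.Series(dtype=_dtype(kind)) for col, kind in schema.items()})


def _dtype(kind: str) -> str:
    return {
        "str": "object", "str_opt": "object",
        "date": "object", "date_opt": "object",
        "float": "float64", "int_opt": "Int64", "bool": "bool",
    }[kind]


@dataclass
class DatasetBundle:
    """The eight linked source tables for one simulated jurisdiction."""

    clients: pd.DataFrame
    cancer_registry: pd.DataFrame
    deaths: pd.DataFrame
    dispensings: pd.DataFrame
    service_claims: pd.DataFrame
    hospital_episodes: pd.DataFrame
    ed_visits: pd.DataFrame
    aged_care_stays: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_SCHEMAS}

    @classmethod
    def empty(cls) -> "DatasetBundle":
        return cls(**{name: empty_table(name) for name in TABLE_SCHEMAS})

    def copy(self) -> "DatasetBundle":
        return DatasetBundle(
            **{name: df.copy() for name, df in self.tables().items()},
            provenance=dict(self.provenance),
        )

    def validate(self) -> None:
        """Check schemas and referential integrity (no orphan claims)."""
        for name, df in self.tables().items():
            expected = list(TABLE_SCHEMAS[name])
            if list(df.columns) != expected:
                raise BundleFormatError(
                    f"table {name!r}: columns {list(df.columns)} != expected {expected}"
                )
        persons = set(self.clients["person_id"])
        for name in _CLAIMS_TABLES:
            orphans = set(getattr(self, name)["person_id"]) - persons
            if orphans:
                raise BundleFormatError(
                    f"table {name!r} has person_ids absent from clients: {sorted(orphans)[:5]}"
                )

    def death_date_of(self, person_id: str) -> date:
        rows = self.clients.loc[self.clients["person_id"] == person_id]
        if rows.empty:
            raise KeyError(f"person {person_id!r} not found in clients")
        return rows.iloc[0]["death_date"]

    def for_person(self, table: str, person_id: str) -> pd.DataFrame:
        df = getattr(self, table)
        return df.loc[df["person_id"] == person_id]

    def __eq__(self, other) -> bool:
        if not isinstance(other, DatasetBundle):
            return NotImplemented
        return all(
            self.tables()[n].reset_index(drop=True).equals(
                other.tables()[n].reset_index(drop=True)
            )
            for n in TABLE_SCHEMAS
        )


def _serialize(df: pd.DataFrame, schema: dict[str, str]) -> pd.DataFrame:
    out = {}
    for col, kind in schema.items():
        s = df[col]
        if kind in ("date", "date_opt"):
            out[col] = s.map(lambda d: d.isoformat() if isinstance(d, date) else "")
        elif kind == "bool":
            out[col] = s.map({True: "true", False: "false"})
        elif kind == "int_opt":
            out[col] = s.astype("Int64").astype(object).map(
                lambda v: "" if pd.isna(v) else str(int(v))
            )
        elif kind == "float":
            out[col] = s.map(lambda v: repr(float(v)))
        else:
            out[col] = s.fillna("") if kind == "str_opt" else s
    return pd.DataFrame(out)


def _deserialize(df: pd.DataFrame, schema: dict[str, str], path: Path) -> pd.DataFrame:
    out = {}
    for col, kind in schema.items():
        if col not in df.columns:
            raise BundleFormatError(f"{path.name}: missing column {col!r}")
        s = df[col].fillna("").astype(str)
        if kind == "date":
            out[col] = s.map(date.fromisoformat).astype(object)
        elif kind == "date_opt":
            out[col] = s.map(lambda v: date.fromisoformat(v) if v else None).astype(object)
        elif kind == "bool":
            out[col] = s.map({"true": True, "false": False}).astype(bool)
        elif kind == "int_opt":
            out[col] = s.map(lambda v: int(v) if v else None).astype("Int64")
        elif kind == "float":
            out[col] = s.map(float).astype("float64")
        elif kind == "str_opt":
            out[col] = s.map(lambda v: v if v else None).astype(object)
        else:
            out[col] = s.astype(object)
    extra = set(df.columns) - set(schema)
    if extra:
        raise BundleFormatError(f"{path.name}: unknown column(s) {sorted(extra)}")
    return pd.DataFrame(out, columns=list(schema))


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_bundle(bundle: DatasetBundle, directory: str | Path) -> dict:
    """Write one CSV per table plus ``manifest.json``; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    row_counts = {}
    for name, df in bundle.tables().items():
        ser = _serialize(df, TABLE_SCHEMAS[name])
        ser.to_csv(directory / f"{name}.csv", index=False, lineterminator="\n")
        row_counts[name] = int(len(df))
    manifest = {
        "seed": bundle.provenance.get("seed"),
        "config": bundle.provenance.get("config"),
        "config_hash": config_hash(bundle.provenance.get("config", {})),
        "planted_person_ids": bundle.provenance.get("planted_person_ids", []),
        "row_counts": row_counts,
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return manifest


def read_bundle(directory: str | Path) -> DatasetBundle:
    directory = Path(directory)
    tables = {}
    for name, schema in TABLE_SCHEMAS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise BundleFormatError(f"missing table file: {name} ({path})")
        raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
        if raw.empty and list(raw.columns) != list(schema):
            raw = pd.DataFrame(columns=list(schema))
        tables[name] = _deserialize(raw, schema, path)
    provenance = {}
    mpath = directory / "manifest.json"
    if mpath.exists():
        m = json.loads(mpath.read_text())
        provenance = {
            "seed": m.get("seed"),
            "config": m.get("config"),
            "planted_person_ids": m.get("planted_person_ids", []),
        }
    b = DatasetBundle(**tables, provenance=provenance)
    b.validate()
    return b
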