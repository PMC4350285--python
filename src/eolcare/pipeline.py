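"""End-to-end pipeline: simulate -> build-cohorts -> classify -> cost -> report.

Each stage reads the previous stage's on-disk outputs, so downstream
stages can be re-run in isolation and reproduce their outputs
bit-identically from upstream artifacts.  A run manifest records the
config hash, per-stage row counts, wall times and SHA-256 checksums of
every output file; identical (config, seed) runs give identical
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bundle import DatasetBundle, config_hash, read_bundle, write_bundle
from .classify import classify_bundle
from .cohort import CohortConfig, build_cohorts, cohort_summary
from .costs import CostParameters, InflationSchedule, total_person_cost
from .generate import GeneratorConfig, generate_linked_data
from .metrics import (
    ed_admission_crosscheck,
    compute_indicators,
    load_indicator_definitions,
    summarize_resource_use,
)
from .windows import ObservationWindow

log = logging.getLogger("eolcare")

__all__ = ["PipelineError", "RunConfig", "run_pipeline",
           "stage_simulate", "stage_cohorts", "stage_classify",
           "stage_cost", "stage_report"]

STAGES = ("simulate", "cohorts", "classify", "cost", "report")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    window_months: int = 6
    generator: dict = field(default_factory=dict)
    stages: tuple[str, ...] = STAGES
    indicators_path: str | None = None
    stratifiers: tuple[str, ...] = ("sex", "age_band", "cod_group")

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.window_months < 1:
            raise PipelineError("window_months must be a positive integer")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir), "seed": self.seed,
            "window_months": self.window_months, "generator": self.generator,
            "stages": list(self.stages), "indicators_path": self.indicators_path,
            "stratifiers": list(self.stratifiers),
        }


def _round2(x: float) -> float:
    return float(round(x, 2))


def stage_simulate(config: RunConfig) -> dict:
    gen_kwargs = dict(config.generator)
    for key in ("death_window",):
        if key in gen_kwargs:
            gen_kwargs[key] = tuple(date.fromisoformat(v) for v in gen_kwargs[key])
    if "planted_cases" in gen_kwargs:
        gen_kwargs["planted_cases"] = tuple(gen_kwargs["planted_cases"])
    gen = GeneratorConfig(seed=config.seed, **gen_kwargs)
    bundle = generate_linked_data(gen)
    manifest = write_bundle(bundle, config.out_dir / "data")
    log.info("stage=simulate n_clients=%d tables=%s", len(bundle.clients),
             {k: v for k, v in manifest["row_counts"].items()})
    return {"rows": manifest["row_counts"]}


def stage_cohorts(config: RunConfig) -> dict:
    bundle = read_bundle(config.out_dir / "data")
    assignments = build_cohorts(bundle, CohortConfig())
    out = config.out_dir / "cohorts"
    out.mkdir(parents=True, exist_ok=True)
    assignments.to_csv(out / "cohorts.csv", index=False, lineterminator="\n")
    summary = cohort_summary(assignments)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    log.info("stage=cohorts %s", summary["by_cohort"])
    return {"rows": {"cohorts": len(assignments)}, "summary": summary}


def stage_classify(config: RunConfig) -> dict:
    bundle = read_bundle(config.out_dir / "data")
    table = classify_bundle(bundle)
    out = config.out_dir / "classify"
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "classified.csv", index=False, lineterminator="\n")
    log.info("stage=classify n=%d", len(table))
    return {"rows": {"classified": len(table)}}


def stage_cost(config: RunConfig) -> dict:
    bundle = read_bundle(config.out_dir / "data")
    cohorts = pd.read_csv(config.out_dir / "cohorts" / "cohorts.csv")
    params = CostParameters.default()
    schedule = InflationSchedule.default()
    in_cohort = cohorts.loc[cohorts["cohort"].isin(["cancer", "non_cancer"]), "person_id"]
    person_rows, item_rows = [], []
    for pid in in_cohort:
        window = ObservationWindow(bundle.death_date_of(pid), config.window_months)
        breakdown, ledger = total_person_cost(pid, bundle, window, params, schedule)
        person_rows.append({"person_id": pid} | {k: _round2(v) for k, v in breakdown.items()})
        for item in ledger:
            item_rows.append({
                "person_id": item.person_id, "source": item.source,
                "event_date": item.event_date.isoformat(),
                "nominal_cost": _round2(item.nominal_cost),
                "inflation_factor": round(item.inflation_factor, 6),
                "final_cost": _round2(item.final_cost),
                "components": json.dumps({k: _round2(v) for k, v in sorted(item.components.items())}),
                "flags": ";".join(sorted(item.flags)),
            })
    out = config.out_dir / "costs"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(person_rows).to_csv(out / "person_costs.csv", index=False, lineterminator="\n")
    pd.DataFrame(item_rows).to_csv(out / "costed_items.csv", index=False, lineterminator="\n")
    log.info("stage=cost persons=%d items=%d", len(person_rows), len(item_rows))
    return {"rows": {"person_costs": len(person_rows), "costed_items": len(item_rows)}}


def stage_report(config: RunConfig) -> dict:
    bundle = read_bundle(config.out_dir / "data")
    cohorts = pd.read_csv(config.out_dir / "cohorts" / "cohorts.csv")
    out = config.out_dir / "report"
    out.mkdir(parents=True, exist_ok=True)
    rows = {}
    for strat in config.stratifiers:
        table = summarize_resource_use(bundle, cohorts, config.window_months, strat)
        table.to_csv(out / f"summary_{strat}.csv", index=False, lineterminator="\n")
        rows[f"summary_{strat}"] = len(table)
    definitions = load_indicator_definitions(config.indicators_path)
    person_table, cohort_table = compute_indicators(bundle, cohorts, definitions)
    person_table.to_csv(out / "indicators_person.csv", index=False, lineterminator="\n")
    cohort_table.to_csv(out / "indicators_cohort.csv", index=False, lineterminator="\n")
    crosscheck = ed_admission_crosscheck(bundle, config.window_months, cohorts)
    (out / "ed_crosscheck.json").write_text(
        json.dumps(crosscheck, indent=2, sort_keys=True) + "\n")
    rows |= {"indicators_person": len(person_table), "indicators_cohort": len(cohort_table)}
    log.info("stage=report tables=%s", rows)
    return {"rows": rows}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "cohorts": stage_cohorts,
    "classify": stage_classify,
    "cost": stage_cost,
    "report": stage_report,
}


def _checksums(root: Path) -> dict[str, str]:
    sums = {}
    for path in sorted(root.rglob("*")):
        if path.is_file() and path.suffix in {".csv", ".json"} and path.name != "run_manifest.json":
            sums[str(path.relative_to(root))] = hashlib.sha256(path.read_bytes()).hexdigest()
    return sums


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write ``run_manifest.json``."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config_hash(config.to_dict()),
        "stages": {},
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            result = _STAGE_FUNCS[stage](config)
        except Exception as exc:
            (config.out_dir / f"{stage}.partial").write_text(str(exc) + "\n")
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "rows": result.get("rows", {}),
            "wall_seconds": round(time.perf_counter() - t0, 3),
        }
    manifest["checksums"] = _checksums(config.out_dir)
    (config.out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
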