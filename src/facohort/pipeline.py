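"""Configuration-driven end-to-end runner.

One call executes the whole study flow — generate or load a cohort, drop
excluded variables, bin the attendance target, split, train the configured
model families, evaluate each on the held-out rows, and rank cohort-targeted
risk factors — writing every artefact plus a provenance manifest to an
output directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortTable, generate_cohort, load_cohort
from .config import TARGET_COLUMN, GeneratorConfig
from .evaluation import evaluate_model
from .models import MODEL_FAMILIES, FrequentAttendanceClassifier
from .prep import DEFAULT_EXCLUSIONS, bin_attendance, drop_excluded_variables, split_train_test
from .shapley import cohort_risk_factors

logger = logging.getLogger("facohort")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything needed for one full run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cohort_csv: str | None = None  # load instead of generate when set
    exclusions: tuple = DEFAULT_EXCLUSIONS
    test_fraction: float = 0.30
    split_seed: int = 0
    stratified: bool = False
    families: tuple = MODEL_FAMILIES
    model_seed: int = 0
    explain_method: str = "zero_input"
    explain_cohorts: tuple = ("low_mid", "high")
    explain_threshold: float = 0.01
    n_permutations: int = 200
    explain_seed: int = 0
    output_dir: str = "facohort_run"

    def validate(self) -> None:
        if not self.families:
            raise ValueError("at least one model family is required")
        unknown = set(self.families) - set(MODEL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")
        self.generator.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if gen is not None:
            cfg.generator = GeneratorConfig.from_dict(gen)
        return cfg


def _stage(name, manifest, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - stage name is the contract
        manifest["failed_stage"] = name
        raise PipelineError(name, exc) from exc
    dt = time.perf_counter() - t0
    manifest["stage_seconds"][name] = round(dt, 3)
    logger.info("stage %s done in %.2fs", name, dt)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.generator.config_hash(),
        "seeds": {
            "generator": config.generator.seed,
            "split": config.split_seed,
            "model": config.model_seed,
            "explain": config.explain_seed,
        },
        "stage_seconds": {},
        "outputs": [],
    }

    def emit(path: Path):
        manifest["outputs"].append(str(path.name))

    try:
        # cohort ----------------------------------------------------------
        if config.cohort_csv:
            cohort: CohortTable = _stage("load_cohort", manifest, load_cohort, config.cohort_csv)
        else:
            cohort = _stage("generate_cohort", manifest, generate_cohort, config.generator)
        cohort_path = out / "cohort.csv"
        cohort.to_csv(cohort_path)
        emit(cohort_path)

        # prep ------------------------------------------------------------
        table = _stage(
            "drop_excluded_variables", manifest,
            drop_excluded_variables, cohort.table, config.exclusions,
        )
        train, test = _stage(
            "split_train_test", manifest,
            split_train_test, table, config.test_fraction, config.split_seed,
            config.stratified,
        )
        split_manifest = {
            "seed": config.split_seed,
            "test_fraction": config.test_fraction,
            "stratified": config.stratified,
            "n_train": len(train),
            "n_test": len(test),
        }
        with open(out / "split.json", "w") as fh:
            json.dump(split_manifest, fh, indent=2)
        emit(out / "split.json")

        x_train = train.drop(columns=[TARGET_COLUMN])
        x_test = test.drop(columns=[TARGET_COLUMN])
        v_train = train[TARGET_COLUMN].to_numpy()
        y_train = bin_attendance(v_train)
        y_test = bin_attendance(test[TARGET_COLUMN].to_numpy())

        # models + evaluation --------------------------------------------
        reports = {}
        models = {}
        for family in config.families:
            model = _stage(
                f"fit_{family}", manifest,
                lambda fam=family: FrequentAttendanceClassifier(
                    family=fam, random_state=config.model_seed
                ).fit(x_train, y_train, visit_counts=v_train),
            )
            models[family] = model
            report = _stage(
                f"evaluate_{family}", manifest,
                evaluate_model, model, x_test, y_test, family,
            )
            reports[family] = report
            report.to_json(out / f"eval_{family}.json")
            emit(out / f"eval_{family}.json")

        _write_combined_confusion(reports, out / "confusion_combined.csv")
        emit(out / "confusion_combined.csv")
        _write_metrics(reports, out / "metrics.csv")
        emit(out / "metrics.csv")

        # risk factors ----------------------------------------------------
        for family, model in models.items():
            for selector in config.explain_cohorts:
                rft = _stage(
                    f"explain_{family}_{selector}", manifest,
                    cohort_risk_factors, model, x_test, y_test, selector,
                    config.explain_method, config.explain_threshold,
                    "expected_class", config.n_permutations, config.explain_seed,
                    family,
                )
                path = out / f"risk_factors_{family}_{selector}.csv"
                rft.to_csv(path)
                emit(path)
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return manifest


def _write_combined_confusion(reports: dict, path) -> None:
    """Combined confusion table: one block of model rows per actual class."""
    rows = []
    for actual, actual_name in enumerate(["low", "mid", "high"]):
        for family, report in reports.items():
            cm = np.asarray(report.confusion)
            rows.append({
                "actual": actual_name,
                "model": family,
                "predicted_low": int(cm[actual, 0]),
                "predicted_mid": int(cm[actual, 1]),
                "predicted_high": int(cm[actual, 2]),
                "total": int(cm[actual].sum()),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_metrics(reports: dict, path) -> None:
    rows = []
    for family, r in reports.items():
        rows.append({
            "model": family,
            "weighted_precision": round(r.weighted_precision, 4),
            "weighted_recall": round(r.weighted_recall, 4),
            "weighted_f1": round(r.weighted_f1, 4),
            "macro_precision": round(r.macro_precision, 4),
            "macro_recall": round(r.macro_recall, 4),
            "macro_f1": round(r.macro_f1, 4),
            "macro_auc": round(r.macro_auc, 4),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
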