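"""End-to-end orchestration: simulate (or load) -> features -> reliability ->
classification reports.

A run produces a bundle of plain-text reports in the output directory:

* ``features.csv`` — tidy per-trial feature table (subject, session, trial,
  kind, craving score, stdHR..CVP),
* ``craving_check.csv`` — per-subject manipulation check of the self-reported
  craving scores (medians, IQRs, rank-sum p),
* ``reliability.csv`` — per-feature ICC(A,1) and p for each trial kind,
* ``accuracy_per_subject.csv`` / ``accuracy_summary.csv`` — the four-condition
  day-3 accuracies per subject and their across-subject medians/IQRs,
* ``run_summary.json`` — config hash, seed and row counts; identical config
  and seed reproduce the bundle byte for byte.

One global seed is expanded with ``numpy.random.SeedSequence`` into fixed
child streams (simulation, cross-validation fold shuffling, forest seeding),
so adding a consumer does not shift the streams of existing ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import SubjectStudy, ValidationError, load_study
from .features import FeatureConfig, features_table
from .model import (CLASSIFIER_NAMES, ClassifierSpec, SubjectFeatures,
                    evaluate_cohort)
from .preprocess import PreprocessConfig
from .reliability import craving_manipulation_check, reliability_report
from .simulate import SimulationConfig, config_from_dict, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("cravesense")

# fixed child-stream indices of the global seed
_STREAM_SIMULATE = 0
_STREAM_CV = 1
_STREAM_FOREST = 2


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input mode: simulate a cohort (``simulation`` block) or load
    saved studies from ``input_dirs``.
    """

    seed: int = 0
    n_subjects: int = 9
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    input_dirs: list[str] | None = None
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    standardize: bool = True
    icc_unit: str = "subject"
    out_dir: str = "cravesense_out"

    def validate(self) -> None:
        if (self.simulation is None) == (self.input_dirs is None):
            raise ValidationError(
                "PipelineConfig: exactly one of simulation/input_dirs must be set")
        unknown = set(self.classifiers) - set(CLASSIFIER_NAMES)
        if unknown:
            raise ValidationError(f"unknown classifiers: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "simulation" in data and data["simulation"] is not None:
            data["simulation"] = config_from_dict(data["simulation"])
        if "preprocessing" in data:
            data["preprocessing"] = PreprocessConfig(**data["preprocessing"])
        if "features" in data:
            data["features"] = FeatureConfig(**data["features"])
        if "classifiers" in data:
            data["classifiers"] = tuple(data["classifiers"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where the bundle lands does not change it
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _child_seed(seed: int, stream: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(stream,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns paths by name."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    t_start = time.perf_counter()

    def stage(name):
        log.info("stage=%s elapsed=%.1fs", name, time.perf_counter() - t_start)

    try:
        stage("input")
        if config.simulation is not None:
            studies = simulate_cohort(config.simulation, config.n_subjects,
                                      seed=_child_seed(config.seed, _STREAM_SIMULATE))
        else:
            studies = [load_study(d) for d in config.input_dirs]

        stage("features")
        table = features_table(studies, config.features, config.preprocessing)
        n_invalid = int(table.isna().sum().sum())
        if n_invalid:
            log.warning("feature table has %d missing values (degenerate trials)",
                        n_invalid)
        paths["features"] = out / "features.csv"
        _write_csv(table, paths["features"])

        stage("craving_check")
        check = craving_manipulation_check(studies)
        paths["craving_check"] = out / "craving_check.csv"
        _write_csv(check, paths["craving_check"])

        stage("reliability")
        rel = reliability_report(table, unit=config.icc_unit)
        paths["reliability"] = out / "reliability.csv"
        _write_csv(rel, paths["reliability"])

        stage("classification")
        feats = [SubjectFeatures.from_table(table, s.subject_id) for s in studies]
        specs = [ClassifierSpec(name, standardize=config.standardize,
                                seed=_child_seed(config.seed, _STREAM_FOREST))
                 for name in config.classifiers]
        per_subject, summary = evaluate_cohort(
            feats, specs, cv_seed=_child_seed(config.seed, _STREAM_CV))
        paths["accuracy_per_subject"] = out / "accuracy_per_subject.csv"
        paths["accuracy_summary"] = out / "accuracy_summary.csv"
        _write_csv(per_subject, paths["accuracy_per_subject"])
        _write_csv(summary, paths["accuracy_summary"])

        stage("summary")
        summary_json = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_subjects": len(studies),
            "n_trials": int(len(table)),
            "n_missing_feature_values": n_invalid,
            "outputs": {k: p.name for k, p in paths.items()},
        }
        paths["run_summary"] = out / "run_summary.json"
        paths["run_summary"].write_text(json.dumps(summary_json, indent=1))
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    return paths
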