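"""Config-driven orchestration: simulate -> preprocess -> features -> train -> evaluate.

A single top-level seed fans out to independent per-stage streams (cohort
generation, model fitting, CV shuffling), so changing the model seed never
perturbs the cohort. All stage outputs are pure functions of (inputs, config);
the run manifest records sha256 checksums of every artifact, and re-running
with the same config reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from . import features as feat
from . import synth
from .evaluate import CVScheme, compare_models, report_table
from .features import FeatureConfig, build_table
from .model import Cleaner, ModelSpec, fit, optimize_cutpoints, select
from .preprocess import (
    FilterSpec,
    ForceTrace,
    Repetition,
    SegmentationParams,
    lowpass,
    normalize_force,
    segment_reps,
)

__all__ = [
    "PreprocessConfig",
    "RunConfig",
    "run_pipeline",
    "preprocess_cohort",
    "sha256_file",
]

log = logging.getLogger(__name__)

NORMALIZATION_MODES = ("allometric", "per_mass", "none")


@dataclass(frozen=True)
class PreprocessConfig:
    filter: FilterSpec = field(default_factory=FilterSpec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    normalization_mode: str = "allometric"
    allometric_exponent: float = 0.67

    def __post_init__(self) -> None:
        if self.normalization_mode not in NORMALIZATION_MODES:
            raise ConfigError(
                f"normalization_mode must be one of {NORMALIZATION_MODES}, "
                f"got {self.normalization_mode!r}"
            )

    def to_dict(self) -> dict:
        return {
            "filter": dataclasses.asdict(self.filter),
            "segmentation": dataclasses.asdict(self.segmentation),
            "normalization_mode": self.normalization_mode,
            "allometric_exponent": self.allometric_exponent,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(
            filter=FilterSpec(**d.get("filter", {})),
            segmentation=SegmentationParams(**d.get("segmentation", {})),
            normalization_mode=d.get("normalization_mode", "allometric"),
            allometric_exponent=d.get("allometric_exponent", 0.67),
        )


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through JSON."""

    seed: int = 0
    n_subjects: int = 32
    protocol: synth.ProtocolConfig | None = None
    population: synth.PopulationParams = field(default_factory=synth.PopulationParams)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    missing_cap: float = 0.3
    selection_threshold: float = 0.5
    fallback_k: int = 10
    models: tuple[str, ...] = ("rf", "histgbr", "ridge")
    model_hyperparams: dict = field(default_factory=dict)
    cv_kind: str = "groupkfold"
    n_folds: int = 5
    leak_free: bool = True

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(3, dtype=np.uint32)
        return {"synth": int(state[0]), "model": int(state[1]), "cv": int(state[2])}

    def resolved_protocol(self) -> synth.ProtocolConfig:
        if self.protocol is not None:
            return self.protocol
        return synth.ProtocolConfig(seed=self.stage_seeds()["synth"])

    def model_specs(self) -> list[ModelSpec]:
        seed = self.stage_seeds()["model"]
        return [
            ModelSpec(kind=k, hyperparams=dict(self.model_hyperparams.get(k, {})), seed=seed)
            for k in self.models
        ]

    def cv_scheme(self) -> CVScheme:
        return CVScheme(kind=self.cv_kind, n_folds=self.n_folds, seed=self.stage_seeds()["cv"])

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "protocol": self.protocol.to_dict() if self.protocol is not None else None,
            "population": self.population.to_dict(),
            "preprocess": self.preprocess.to_dict(),
            "features": dataclasses.asdict(self.features),
            "missing_cap": self.missing_cap,
            "selection_threshold": self.selection_threshold,
            "fallback_k": self.fallback_k,
            "models": list(self.models),
            "model_hyperparams": dict(self.model_hyperparams),
            "cv_kind": self.cv_kind,
            "n_folds": self.n_folds,
            "leak_free": self.leak_free,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            seed=d.get("seed", 0),
            n_subjects=d.get("n_subjects", 32),
            protocol=(
                synth.ProtocolConfig.from_dict(d["protocol"])
                if d.get("protocol") is not None
                else None
            ),
            population=synth.PopulationParams.from_dict(d.get("population", {})),
            preprocess=PreprocessConfig.from_dict(d.get("preprocess", {})),
            features=FeatureConfig(**d.get("features", {})),
            missing_cap=d.get("missing_cap", 0.3),
            selection_threshold=d.get("selection_threshold", 0.5),
            fallback_k=d.get("fallback_k", 10),
            models=tuple(d.get("models", ("rf", "histgbr", "ridge"))),
            model_hyperparams=dict(d.get("model_hyperparams", {})),
            cv_kind=d.get("cv_kind", "groupkfold"),
            n_folds=d.get("n_folds", 5),
            leak_free=d.get("leak_free", True),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def preprocess_cohort(
    traces: list[ForceTrace],
    config: PreprocessConfig,
) -> tuple[dict[tuple[str, str, int], list[Repetition]], pd.DataFrame]:
    """Filter, segment and normalize every trace.

    Segmentation runs on the filtered, pre-normalization signal (relative
    thresholds make the order immaterial, but the contract is fixed);
    normalization is then applied to each repetition's samples. Returns the
    repetition map and a segmented-sample data frame (rep windows included).
    """
    exponent = {"allometric": config.allometric_exponent, "per_mass": 1.0}.get(
        config.normalization_mode
    )
    reps_map: dict[tuple[str, str, int], list[Repetition]] = {}
    rows = []
    for trace in traces:
        filtered = lowpass(trace, config.filter)
        reps = segment_reps(filtered, config.segmentation)
        if exponent is not None:
            reps = [
                dataclasses.replace(
                    r, forces_N=normalize_force(r.forces_N, trace.body_mass_kg, exponent)
                )
                for r in reps
            ]
        reps_map[(trace.subject_id, trace.limb, trace.set_index)] = reps
        for r in reps:
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "limb": r.limb,
                    "set_index": r.set_index,
                    "rep_index": r.rep_index,
                    "start_sample": r.start_sample,
                    "end_sample": r.end_sample,
                    "t_start": r.t_start,
                    "duration_s": r.duration_s,
                }
            )
    segmented = pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "limb",
            "set_index",
            "rep_index",
            "start_sample",
            "end_sample",
            "t_start",
            "duration_s",
        ],
    )
    return reps_map, segmented


def _write_json(path: Path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline and write all artifacts under ``out_dir``.

    Returns the run manifest (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # --- simulate ---------------------------------------------------------
    protocol = config.resolved_protocol()
    cohort = synth.generate_cohort(config.n_subjects, protocol, config.population)
    cohort_paths = synth.export_cohort(cohort, out / "cohort")
    artifacts.update({f"cohort/{k}": p for k, p in cohort_paths.items()})
    traces = [t for session in cohort.sessions for t in session.traces]
    labels = {
        (s.subject_id, limb, si): rpe
        for s in cohort.sessions
        for (limb, si), rpe in s.rpe_labels.items()
    }

    # --- preprocess -------------------------------------------------------
    reps_map, segmented = preprocess_cohort(traces, config.preprocess)
    seg_path = out / "segmented.csv"
    segmented.to_csv(seg_path, index=False)
    artifacts["segmented"] = seg_path

    # --- features ---------------------------------------------------------
    table = build_table(reps_map, labels, config.features)
    table_path = out / "table.csv"
    table.to_csv(table_path, index=False)
    schema_path = out / "table_schema.json"
    _write_json(
        schema_path,
        {
            "id_columns": list(feat.ID_COLUMNS),
            "label_column": feat.LABEL_COLUMN,
            "feature_columns": feat.feature_columns(config.features),
            "normalization_mode": config.preprocess.normalization_mode,
        },
    )
    artifacts["table"] = table_path
    artifacts["table_schema"] = schema_path

    # --- train (full-data fit, artifacts for deployment-style use) --------
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    feature_df = table.drop(columns=[*feat.ID_COLUMNS, feat.LABEL_COLUMN])
    y = table[feat.LABEL_COLUMN].to_numpy(dtype=int)
    cleaner = Cleaner(config.missing_cap).fit(feature_df)
    X = cleaner.transform(feature_df)
    cols = select(X, y, config.selection_threshold, config.fallback_k)
    for spec in config.model_specs():
        est = fit(X[cols], y, spec)
        train_pred = np.asarray(est.predict(X[cols].to_numpy()), dtype=float)
        cp = optimize_cutpoints(train_pred, y)
        meta_path = models_dir / f"{spec.kind}.json"
        _write_json(
            meta_path,
            {
                "spec": spec.to_dict(),
                "columns": cols,
                "cutpoints": cp.to_dict(),
                "imputation_medians": {
                    c: float(cleaner.medians_[c]) for c in cleaner.columns_
                },
            },
        )
        with open(models_dir / f"{spec.kind}.pkl", "wb") as fh:
            pickle.dump(est, fh)
        artifacts[f"models/{spec.kind}.json"] = meta_path

    # --- evaluate ---------------------------------------------------------
    comparison = compare_models(
        table,
        config.model_specs(),
        config.cv_scheme(),
        selection_threshold=config.selection_threshold,
        fallback_k=config.fallback_k,
        missing_cap=config.missing_cap,
        leak_free=config.leak_free,
    )
    report_path = out / "report.json"
    _write_json(
        report_path,
        {
            "ranking": comparison["ranking"],
            "reports": {k: r.to_dict() for k, r in comparison["reports"].items()},
        },
    )
    artifacts["report"] = report_path
    table_txt = out / "report.txt"
    with open(table_txt, "w") as fh:
        fh.write(report_table(comparison["reports"]).to_string(float_format="%.4f"))
        fh.write("\n")
    artifacts["report_txt"] = table_txt

    # --- manifest ---------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "stage_seeds": config.stage_seeds(),
        "n_rows": int(len(table)),
        "ranking": comparison["ranking"],
        "checksums": {k: sha256_file(p) for k, p in sorted(artifacts.items())},
    }
    _write_json(out / "manifest.json", manifest)
    return manifest
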