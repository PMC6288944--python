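"""End-to-end orchestration: directory of recordings -> features -> model -> CV.

A pipeline run reads skeleton CSVs plus a subjects metadata table, applies
cleaning/segmentation/labeling, extracts the 115-feature vector per subject,
cross-validates the discretize+CFS+Bayes classifier and writes a manifest
capturing the configuration hash so the run can be reproduced exactly.
Feature extraction is deterministic (seed-free); randomness only enters the
cross-validation fold shuffling.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import FEATURE_NAMES, cohort_features
from .learn import CV_FOLDS, CV_RUNS, ModelConfig, cross_validate, fit_pipeline
from .preprocess import PreprocessConfig, preprocess_recording
from .skeleton import Subject, read_recording, read_subjects

logger = logging.getLogger("gaitstage")


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with the published defaults."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    lowess_frac: float = 0.3
    folds: int = CV_FOLDS
    runs: int = CV_RUNS
    seed: int = 0
    classes: str = "stage3"  # stage3 | binary

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        pp = PreprocessConfig(**d.pop("preprocess", {}))
        mc = ModelConfig(**d.pop("model", {}))
        return cls(preprocess=pp, model=mc, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def extract_cohort(
    input_dir: str | Path, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, list[Subject]]:
    """Preprocess every recording in ``input_dir`` and build the feature table.

    Expects ``<subject_id>*.csv`` skeleton files plus ``subjects.csv``;
    multiple recordings (cameras) per subject are pooled.
    """
    cfg = config or PipelineConfig()
    input_dir = Path(input_dir)
    subjects = read_subjects(input_dir / "subjects.csv")
    by_subject: dict[str, list] = {}
    missing = []
    for subj in subjects:
        paths = sorted(input_dir.glob(f"{subj.subject_id}*.csv"))
        paths = [p for p in paths if p.name != "subjects.csv"]
        if not paths:
            missing.append(subj.subject_id)
            continue
        results = []
        for p in paths:
            rec = read_recording(p, subject_id=subj.subject_id)
            res = preprocess_recording(rec, cfg.preprocess)
            logger.info("preprocessed %s: %s", p.name, res.attrition)
            results.append(res)
        by_subject[subj.subject_id] = results
    if missing:
        raise FileNotFoundError(f"no recordings found for subjects: {missing}")
    feats = cohort_features(by_subject)
    return feats, subjects


def run_pipeline(
    input_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Full run: features CSV + fitted model JSON + CV report + manifest."""
    cfg = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    feats, subjects = extract_cohort(input_dir, cfg)
    labels = np.array([s.stage_label for s in subjects])
    if cfg.classes == "binary":
        labels = np.array(["control" if l == "control" else "PD" for l in labels])
    feats.to_csv(out_dir / "features.csv")

    model = fit_pipeline(feats, labels, cfg.model)
    model.to_json(out_dir / "model.json")

    report = cross_validate(
        feats, labels, cfg.model, folds=cfg.folds, runs=cfg.runs, base_seed=cfg.seed
    )
    report.confusion.to_csv(out_dir / "confusion.csv")
    summary = {
        "mean_accuracy_pct": report.mean_accuracy,
        "sd_accuracy_pct": report.sd_accuracy,
        "n_subjects": len(subjects),
        "selected_features": model.features,
    }
    (out_dir / "cv_report.json").write_text(json.dumps(summary, indent=1) + "\n")

    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "n_features": len(FEATURE_NAMES),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return summary
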