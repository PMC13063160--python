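"""End-to-end orchestration: assays + images → grades → features → models.

A single master seed fans out to per-stage seeds through a stable hash, so
toggling one stage does not reshuffle the randomness of the others.  Every
stage appends a line-delimited JSON log entry with its seed, inputs and
outputs; a stage failure leaves the artifacts produced so far in place and
raises a ``StageError`` naming the stage.
"""

from __future__ import annotations

import json
import logging
import platform
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import LabeledDataset, select_features
from .features import FeatureConfig, extract_features, feature_names, read_image
from .grading import (GradeTable, assign_grade, derive_grade_table,
                      read_assay_csv, validate_assays)
from .io import write_features_csv, write_selection_json
from .modeling import ModelSpec, best_rows, evaluate_once, kfold_cv, run_grid
from .pso import DEFAULT_BOUNDS, ParamBounds, tune_model, tuning_report_json
from .dataset import stratified_split

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (zlib.crc32(stage.encode()) ^ (master_seed * 2654435761)) % (2**31 - 1)


@dataclass
class RunConfig:
    images_dir: str | None = None
    assay_csv: str | None = None
    output_dir: str = "run"
    schemes: tuple[int, ...] = (3,)
    derive_tables: bool = True          # False: use the published boundary tables
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    selection_methods: tuple[str, ...] = ("ALL", "COR")
    algorithms: tuple[str, ...] = ("extra_trees", "lightgbm")
    threshold: float = 0.60
    train_fraction: float = 0.8
    smote_target: str | int = "majority"
    pso_enabled: bool = False
    pso_bounds: ParamBounds = DEFAULT_BOUNDS
    pso_swarm_size: int = 10
    pso_iterations: int = 10
    cv_folds: int = 0                   # 0 disables the CV stage
    seed: int = 0

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        cfg = RunConfig()
        for key, value in d.items():
            if key == "feature_config":
                value = FeatureConfig.from_dict(value)
            elif key in ("schemes", "selection_methods", "algorithms"):
                value = tuple(value)
            elif key == "pso_bounds":
                value = ParamBounds(tuple(
                    (b["name"], b["lower"], b["upper"], b["kind"]) for b in value))
            if not hasattr(cfg, key):
                raise ValueError(f"unknown RunConfig key '{key}'")
            setattr(cfg, key, value)
        return cfg


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        path.parent.mkdir(parents=True, exist_ok=True)

    def write(self, stage: str, **payload) -> None:
        entry = {"stage": stage, "time": time.time(),
                 "package_version": __version__,
                 "python": platform.python_version(), **payload}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry, default=str) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full grading pipeline and return the run directory.

    Stages: derive-grades → extract-features → label → grid (split, select,
    balance, fit, evaluate) → optional PSO tuning → optional k-fold CV.
    Artifacts: grade_table.json, features.csv, selection.json, grid.csv,
    eval.json, tuning.json (when PSO is on) and run_log.jsonl.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run_log.jsonl")
    stage = "validate-config"
    try:
        if config.assay_csv is None or config.images_dir is None:
            raise ValueError("assay_csv and images_dir are required")
        assays = read_assay_csv(config.assay_csv)
        images_dir = Path(config.images_dir)
        if not images_dir.is_dir():
            raise ValueError(f"images dir not found: {images_dir}")
        log.write(stage, seed=config.seed, n_samples=len(assays))

        stage = "derive-grades"
        tables: dict[int, GradeTable] = {}
        for scheme in config.schemes:
            if config.derive_tables:
                tables[scheme] = derive_grade_table(assays, scheme)
            else:
                from .grading import PAPER_GRADE_TABLES
                tables[scheme] = PAPER_GRADE_TABLES[scheme]
        with open(out / "grade_table.json", "w") as fh:
            json.dump({str(s): json.loads(t.to_json())
                       for s, t in tables.items()}, fh, indent=2)
        log.write(stage, schemes=list(config.schemes))

        stage = "extract-features"
        ids, rows = [], []
        for sid in assays["sample_id"]:
            matches = sorted(images_dir.glob(f"{sid}.*"))
            if not matches:
                raise FileNotFoundError(f"no image for sample '{sid}'")
            vec = extract_features(read_image(matches[0]), config.feature_config)
            ids.append(sid)
            rows.append(vec.values)
        X = np.vstack(rows)
        names = feature_names(config.feature_config)
        write_features_csv(out / "features.csv", ids, X, names)
        log.write(stage, n_images=len(ids), n_features=X.shape[1])

        stage = "label"
        datasets: dict[int, LabeledDataset] = {}
        pns = assays.set_index("sample_id")["pns"]
        for scheme, table in tables.items():
            y = np.array([assign_grade(float(pns[sid]), table) for sid in ids])
            datasets[scheme] = LabeledDataset(X, y, names,
                                              sample_ids=np.asarray(ids, object))
        log.write(stage, label_counts={s: pd.Series(d.y).value_counts().to_dict()
                                       for s, d in datasets.items()})

        stage = "grid"
        grid_seed = derive_seed(config.seed, "grid")
        grid = run_grid(datasets, feature_sets=config.selection_methods,
                        algorithms=config.algorithms, seed=grid_seed,
                        train_fraction=config.train_fraction,
                        threshold=config.threshold,
                        smote_target=config.smote_target)
        grid.to_csv(out / "grid.csv", index=False, float_format="%.12g")
        best = best_rows(grid)
        log.write(stage, seed=grid_seed, n_cells=len(grid))

        stage = "evaluate-best"
        eval_payload = {}
        for _, row in best.iterrows():
            scheme = int(row["scheme"])
            ds = datasets[scheme]
            train, test = stratified_split(ds, config.train_fraction,
                                           seed=grid_seed)
            sel = select_features(train, row["feature_set"],
                                  threshold=config.threshold, seed=grid_seed)
            write_selection_json(out / "selection.json", sel)
            report = evaluate_once(ModelSpec(row["algorithm"], seed=grid_seed),
                                   train, test, feature_set=row["feature_set"],
                                   threshold=config.threshold,
                                   smote_target=config.smote_target,
                                   seed=grid_seed)
            eval_payload[str(scheme)] = {"feature_set": row["feature_set"],
                                         "algorithm": row["algorithm"],
                                         **report.to_dict()}
        with open(out / "eval.json", "w") as fh:
            json.dump(eval_payload, fh, indent=2)
        log.write(stage)

        if config.pso_enabled:
            stage = "tune"
            tune_seed = derive_seed(config.seed, "tune")
            tuning_payload = {}
            for _, row in best.iterrows():
                scheme = int(row["scheme"])
                train, _ = stratified_split(datasets[scheme],
                                            config.train_fraction,
                                            seed=grid_seed)
                sel = select_features(train, row["feature_set"],
                                      threshold=config.threshold,
                                      seed=grid_seed)
                tuned, fitness, trace = tune_model(
                    ModelSpec(row["algorithm"], seed=tune_seed),
                    train.select_columns(sel.selected),
                    bounds=config.pso_bounds,
                    swarm_size=config.pso_swarm_size,
                    iterations=config.pso_iterations, seed=tune_seed,
                    smote_target=config.smote_target)
                tuning_payload[str(scheme)] = json.loads(tuning_report_json(
                    config.pso_bounds, trace, tuned.hyperparameters))
                tuning_payload[str(scheme)]["fitness"] = fitness
            with open(out / "tuning.json", "w") as fh:
                json.dump(tuning_payload, fh, indent=2)
            log.write(stage, seed=tune_seed)

        if config.cv_folds >= 2:
            stage = "cv"
            cv_seed = derive_seed(config.seed, "cv")
            cv_payload = {}
            for _, row in best.iterrows():
                scheme = int(row["scheme"])
                _, summary = kfold_cv(ModelSpec(row["algorithm"], seed=cv_seed),
                                      datasets[scheme], k=config.cv_folds,
                                      seed=cv_seed,
                                      feature_set=row["feature_set"],
                                      threshold=config.threshold,
                                      smote_target=config.smote_target)
                cv_payload[str(scheme)] = summary
            with open(out / "cv.json", "w") as fh:
                json.dump(cv_payload, fh, indent=2)
            log.write(stage, seed=cv_seed)

    except Exception as exc:
        log.write(stage, error=str(exc))
        raise StageError(stage, exc) from exc
    return out
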