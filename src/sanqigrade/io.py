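"""CSV/JSON artifact round-trips with schema checks.

Feature tables are written with 12 significant digits so a write-then-read
cycle reproduces the in-memory values at that precision.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .dataset import FeatureSelection, LabeledDataset
from .grading import GradeTable
from .modeling import EvalReport


def write_features_csv(path, sample_ids, values: np.ndarray, names) -> None:
    """One row per image: sample id first, then the named feature columns."""
    df = pd.DataFrame(np.asarray(values, float), columns=list(names))
    df.insert(0, "sample_id", list(sample_ids))
    df.to_csv(path, index=False, float_format="%.12g")


def read_features_csv(path) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Returns (sample_ids, values, feature_names); validates the header."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError("features CSV missing column 'sample_id'")
    names = tuple(c for c in df.columns if c != "sample_id")
    if not names:
        raise ValueError("features CSV has no feature columns")
    return (df["sample_id"].to_numpy(object),
            df[list(names)].to_numpy(float), names)


def write_grade_table_json(path, table: GradeTable) -> None:
    with open(path, "w") as fh:
        fh.write(table.to_json())


def read_grade_table_json(path) -> GradeTable:
    with open(path) as fh:
        return GradeTable.from_json(fh.read())


def write_eval_report_json(path, report: EvalReport) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)


def read_eval_report_json(path) -> dict:
    with open(path) as fh:
        d = json.load(fh)
    for key in ("confusion", "accuracy", "f1"):
        if key not in d:
            raise ValueError(f"eval report JSON missing field '{key}'")
    return d


def write_selection_json(path, selection: FeatureSelection) -> None:
    with open(path, "w") as fh:
        fh.write(selection.to_json())


def read_selection_json(path) -> dict:
    with open(path) as fh:
        d = json.load(fh)
    for key in ("method", "threshold", "importances", "selected"):
        if key not in d:
            raise ValueError(f"selection JSON missing field '{key}'")
    return d


def write_dataset_csv(path, ds: LabeledDataset) -> None:
    ds.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_dataset_csv(path) -> LabeledDataset:
    return LabeledDataset.from_frame(pd.read_csv(path))
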