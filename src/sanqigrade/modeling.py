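"""Classifier registry, evaluation metrics, comparison grid and k-fold CV.

The grading comparison crosses tree-ensemble algorithms × feature-selection
methods × grading schemes.  The registry ships five learners: extremely
randomized trees, a random-forest baseline, gradient-boosted trees (XGBoost),
histogram gradient-boosted trees (LightGBM) and scikit-learn's histogram GBDT.
Hyperparameters use canonical names (learning_rate, depth, iterations,
l2_leaf_reg) translated per algorithm, so one search box drives all tuners.

Metrics: overall accuracy (trace of the confusion matrix over the total),
macro one-vs-rest precision/recall/F1, per-class average precision computed by
precision-weighted recall increments along the descending-score ranking, their
mean (mAP), and run-to-run variability as the sample standard deviation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (ExtraTreesClassifier, HistGradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .dataset import (SYNTHETIC, LabeledDataset, select_features, smote_balance,
                      stratified_split)

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# registry
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class AlgorithmEntry:
    """Factory plus the translation from canonical hyperparameter names."""

    factory: object
    param_map: dict
    defaults: dict = field(default_factory=dict)


def _xgb_factory(**kw):
    from xgboost import XGBClassifier
    kw.setdefault("verbosity", 0)
    kw.setdefault("n_jobs", 1)
    return XGBClassifier(**kw)


def _lgbm_factory(**kw):
    from lightgbm import LGBMClassifier
    kw.setdefault("verbose", -1)
    kw.setdefault("n_jobs", 1)
    return LGBMClassifier(**kw)


REGISTRY: dict[str, AlgorithmEntry] = {
    "extra_trees": AlgorithmEntry(
        ExtraTreesClassifier,
        {"iterations": "n_estimators", "depth": "max_depth"},
        {"n_estimators": 300, "n_jobs": 1},
    ),
    "random_forest": AlgorithmEntry(
        RandomForestClassifier,
        {"iterations": "n_estimators", "depth": "max_depth"},
        {"n_estimators": 300, "n_jobs": 1},
    ),
    "xgboost": AlgorithmEntry(
        _xgb_factory,
        {"learning_rate": "learning_rate", "depth": "max_depth",
         "iterations": "n_estimators", "l2_leaf_reg": "reg_lambda"},
        {"n_estimators": 300, "max_depth": 6, "learning_rate": 0.1},
    ),
    "lightgbm": AlgorithmEntry(
        _lgbm_factory,
        {"learning_rate": "learning_rate", "depth": "max_depth",
         "iterations": "n_estimators", "l2_leaf_reg": "reg_lambda"},
        {"n_estimators": 300, "max_depth": 6, "learning_rate": 0.1,
         "min_child_samples": 5},
    ),
    "hist_gbdt": AlgorithmEntry(
        HistGradientBoostingClassifier,
        {"learning_rate": "learning_rate", "depth": "max_depth",
         "iterations": "max_iter", "l2_leaf_reg": "l2_regularization"},
        {"max_iter": 300, "learning_rate": 0.1},
    ),
}


@dataclass(frozen=True)
class ModelSpec:
    """An algorithm key plus canonical hyperparameters and a seed."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in REGISTRY:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; "
                             f"registered: {sorted(REGISTRY)}")

    def build(self):
        entry = REGISTRY[self.algorithm]
        kw = dict(entry.defaults)
        for canon, value in self.hyperparameters.items():
            target = entry.param_map.get(canon, canon)
            kw[target] = value
        kw["random_state"] = self.seed
        return entry.factory(**kw)


class FittedModel:
    """A fitted classifier handle with label and per-class score prediction."""

    def __init__(self, estimator, classes: np.ndarray):
        self.estimator = estimator
        self.classes = classes

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[self.estimator.predict(np.asarray(X, float))]

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(np.asarray(X, float))


def train_model(spec: ModelSpec, train: LabeledDataset) -> FittedModel:
    """Fit the spec's estimator; labels are encoded so any grade dtype works."""
    classes, y_enc = np.unique(train.y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    est = spec.build()
    est.fit(train.X, y_enc)
    return FittedModel(est, classes)


# --------------------------------------------------------------------------- #
# metrics
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class EvalReport:
    confusion: np.ndarray
    classes: tuple
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class_AP: tuple
    mAP: float
    variability: float | None = None

    def to_dict(self) -> dict:
        return {
            "classes": [int(c) if isinstance(c, (int, np.integer)) else c
                        for c in self.classes],
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "per_class_AP": [None if v is None or np.isnan(v) else float(v)
                             for v in self.per_class_AP],
            "mAP": self.mAP, "variability": self.variability,
        }


def average_precision(y_true_binary: np.ndarray, scores: np.ndarray) -> float:
    """AP = Σ_k P(k)·ΔR(k) along the descending-score ranking.

    P(k) is the precision of the top-k samples and ΔR(k) the recall increment
    at rank k (1/n_pos when the k-th sample is positive, else 0).  Score ties
    are broken by sample index (stable sort).
    """
    y = np.asarray(y_true_binary, dtype=bool)
    n_pos = int(y.sum())
    if n_pos == 0:
        return float("nan")
    order = np.argsort(-np.asarray(scores, float), kind="stable")
    hits = y[order]
    cum_tp = np.cumsum(hits)
    ranks = np.arange(1, len(y) + 1)
    precision_at_k = cum_tp / ranks
    return float((precision_at_k[hits]).sum() / n_pos)


def compute_metrics(y_true, y_pred, y_scores=None, classes=None) -> EvalReport:
    """Confusion matrix, accuracy, macro P/R/F1, per-class AP and mAP.

    ``y_scores`` is an n × C per-class score/probability matrix (columns in
    ``classes`` order); without it the AP block is NaN.  Classes absent from
    ``y_true`` get undefined AP and are excluded from the mAP mean.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must be aligned")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total)

    # macro one-vs-rest precision / recall / F1
    precs, recs, f1s = [], [], []
    for i in range(len(classes)):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        f = 2 * p * r / (p + r) if p + r > 0 else 0.0
        precs.append(p); recs.append(r); f1s.append(f)

    aps = []
    if y_scores is not None:
        y_scores = np.asarray(y_scores, float)
        for i, cls in enumerate(classes):
            pos = y_true == cls
            if not pos.any():
                warnings.warn(f"class {cls!r} absent from y_true; AP undefined")
                aps.append(float("nan"))
            else:
                aps.append(average_precision(pos, y_scores[:, i]))
        defined = [a for a in aps if not np.isnan(a)]
        mAP = float(np.mean(defined)) if defined else float("nan")
    else:
        aps = [float("nan")] * len(classes)
        mAP = float("nan")

    return EvalReport(confusion=cm, classes=tuple(classes.tolist()),
                      accuracy=accuracy, precision=float(np.mean(precs)),
                      recall=float(np.mean(recs)), f1=float(np.mean(f1s)),
                      per_class_AP=tuple(aps), mAP=mAP)


def variability(values) -> float:
    """Sample standard deviation (1/(n−1)) of a run-level metric."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("variability needs at least 2 values")
    return float(values.std(ddof=1))


# --------------------------------------------------------------------------- #
# comparison grid
# --------------------------------------------------------------------------- #

def evaluate_once(
    spec: ModelSpec,
    train: LabeledDataset,
    test: LabeledDataset,
    feature_set: str = "ALL",
    threshold: float = 0.60,
    smote_target="majority",
    seed: int = 0,
) -> EvalReport:
    """Select features on train, balance train, fit, evaluate on the test set."""
    sel = select_features(train, feature_set, threshold=threshold, seed=seed)
    train_sel = train.select_columns(sel.selected)
    test_sel = test.select_columns(sel.selected)
    balanced = smote_balance(train_sel, target_count=smote_target, seed=seed)
    model = train_model(spec, balanced)
    y_pred = model.predict(test_sel.X)
    scores = model.predict_scores(test_sel.X)
    return compute_metrics(test_sel.y, y_pred, scores, classes=model.classes)


def run_grid(
    datasets: dict[int, LabeledDataset],
    feature_sets=("ALL", "RFI", "COR", "MI", "RFE", "XGB"),
    algorithms=tuple(REGISTRY),
    seed: int = 0,
    train_fraction: float = 0.8,
    threshold: float = 0.60,
    smote_target="majority",
) -> pd.DataFrame:
    """Evaluate every scheme × feature-set × algorithm cell on a shared split.

    ``datasets`` maps a grading scheme (3/5/6) to its labelled feature table.
    Each scheme is split once; feature selection and balancing see training
    rows only; the test split stays untouched until evaluation.  A failed cell
    is recorded (error column) and the grid continues.
    """
    rows = []
    for scheme, ds in datasets.items():
        train, test = stratified_split(ds, train_fraction, seed=seed)
        for fs in feature_sets:
            for algo in algorithms:
                spec = ModelSpec(algorithm=algo, seed=seed)
                try:
                    report = evaluate_once(spec, train, test, feature_set=fs,
                                           threshold=threshold,
                                           smote_target=smote_target, seed=seed)
                    rows.append({"scheme": scheme, "feature_set": fs,
                                 "algorithm": algo, "accuracy": report.accuracy,
                                 "precision": report.precision,
                                 "recall": report.recall, "f1": report.f1,
                                 "mAP": report.mAP, "error": ""})
                except Exception as exc:  # cell failure must not kill the grid
                    logger.warning("grid cell (%s, %s, %s) failed: %s",
                                   scheme, fs, algo, exc)
                    rows.append({"scheme": scheme, "feature_set": fs,
                                 "algorithm": algo, "accuracy": np.nan,
                                 "precision": np.nan, "recall": np.nan,
                                 "f1": np.nan, "mAP": np.nan, "error": str(exc)})
    return pd.DataFrame(rows)


def best_rows(grid: pd.DataFrame, metric: str = "accuracy") -> pd.DataFrame:
    """The best cell per scheme by the given metric."""
    ok = grid[grid["error"] == ""]
    idx = ok.groupby("scheme")[metric].idxmax()
    return ok.loc[idx].reset_index(drop=True)


# --------------------------------------------------------------------------- #
# k-fold cross-validation
# --------------------------------------------------------------------------- #

def kfold_cv(
    spec: ModelSpec,
    ds: LabeledDataset,
    k: int = 10,
    seed: int = 0,
    smote_inside_folds: bool = True,
    feature_set: str = "ALL",
    threshold: float = 0.60,
    smote_target="majority",
) -> tuple[list[EvalReport], dict]:
    """Stratified k-fold CV with per-fold reports and mean ± σ summaries.

    Default (``smote_inside_folds``): balancing and feature selection are
    refit inside each training fold, so no synthetic sample ever reaches an
    evaluation fold.  The compatibility mode (``smote_inside_folds=False``)
    balances the whole dataset before partitioning — methodologically weaker
    (synthetic rows land in evaluation folds) but mirrors protocols that
    report CV on a pre-balanced dataset.
    """
    if k > len(ds):
        raise ValueError("k cannot exceed the number of samples")
    reports: list[EvalReport] = []
    if smote_inside_folds:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for fold, (tr, te) in enumerate(skf.split(ds.X, ds.y)):
            train, test = ds.subset(tr), ds.subset(te)
            if np.any(test.provenance == SYNTHETIC):
                raise AssertionError("synthetic row leaked into an evaluation fold")
            reports.append(evaluate_once(spec, train, test, feature_set=feature_set,
                                         threshold=threshold,
                                         smote_target=smote_target,
                                         seed=seed + fold))
    else:
        balanced = smote_balance(ds, target_count=smote_target, seed=seed)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for fold, (tr, te) in enumerate(skf.split(balanced.X, balanced.y)):
            train, test = balanced.subset(tr), balanced.subset(te)
            sel = select_features(train, feature_set, threshold=threshold,
                                  seed=seed + fold)
            model = train_model(spec, train.select_columns(sel.selected))
            tX = test.select_columns(sel.selected).X
            reports.append(compute_metrics(test.y, model.predict(tX),
                                           model.predict_scores(tX),
                                           classes=model.classes))
    summary = {}
    for metric in ("accuracy", "precision", "recall", "f1", "mAP"):
        vals = np.array([getattr(r, metric) for r in reports], dtype=float)
        summary[metric] = {"mean": float(np.nanmean(vals)),
                           "sd": variability(vals[~np.isnan(vals)])
                           if np.sum(~np.isnan(vals)) >= 2 else None}
    return reports, summary
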