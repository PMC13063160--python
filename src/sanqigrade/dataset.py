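"""Leakage-safe dataset construction: stratified split, SMOTE, feature selection.

The grading study design demands that class balancing and feature selection see
only training data; the test partition contains original samples exclusively.
Every row carries a provenance flag (``original`` / ``synthetic``) so leakage
can be audited end-to-end.

SMOTE is implemented directly from its interpolation rule — a synthetic
minority sample is ``x_i + u · (x_nn − x_i)`` with ``u ~ U(0, 1)`` and x_nn one
of the k nearest same-class neighbors of x_i — since that rule is the entire
algorithm.  Nearest neighbors are found in z-scored feature space.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, mutual_info_classif
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

SELECTION_METHODS = ("ALL", "RFI", "COR", "MI", "RFE", "XGB")

ORIGINAL = "original"
SYNTHETIC = "synthetic"


@dataclass
class LabeledDataset:
    """Feature matrix + grade labels + per-row provenance."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    provenance: np.ndarray | None = None
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X and y must be aligned (n rows each)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains missing/non-finite values")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match X columns")
        if self.provenance is None:
            self.provenance = np.full(len(self.y), ORIGINAL, dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i:04d}" for i in range(len(self.y))],
                                       dtype=object)
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.X[idx], self.y[idx], self.feature_names,
                              self.provenance[idx], self.sample_ids[idx])

    def select_columns(self, cols) -> "LabeledDataset":
        cols = np.asarray(cols, dtype=int)
        return LabeledDataset(self.X[:, cols], self.y,
                              tuple(self.feature_names[i] for i in cols),
                              self.provenance, self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "sample_id", self.sample_ids)
        df["grade"] = self.y
        df["provenance"] = self.provenance
        return df

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "LabeledDataset":
        meta = ["sample_id", "grade", "provenance"]
        for col in meta:
            if col not in df.columns:
                raise ValueError(f"dataset frame missing column '{col}'")
        feats = [c for c in df.columns if c not in meta]
        return LabeledDataset(df[feats].to_numpy(float), df["grade"].to_numpy(),
                              tuple(feats), df["provenance"].to_numpy(object),
                              df["sample_id"].to_numpy(object))


# --------------------------------------------------------------------------- #
# stratified split
# --------------------------------------------------------------------------- #

def stratified_split(
    ds: LabeledDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Per-class proportional train/test split with largest-remainder rounding.

    The total training size is round(n · train_fraction); class quotas are
    floor(n_c · train_fraction) with the remaining seats going to the classes
    with the largest fractional remainders (ties by class order).  Synthetic
    rows are not allowed here — balancing happens after splitting.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if np.any(ds.provenance == SYNTHETIC):
        raise ValueError("split before balancing: synthetic rows present")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(ds.y, return_counts=True)
    if counts.min() < 2:
        singles = classes[counts < 2].tolist()
        raise ValueError(f"classes with a single member cannot be split: {singles}")
    total_train = int(round(len(ds) * train_fraction))
    quotas = counts * train_fraction
    base = np.floor(quotas).astype(int)
    base = np.minimum(np.maximum(base, 1), counts - 1)  # both sides non-empty
    remainder = quotas - np.floor(quotas)
    short = total_train - base.sum()
    if short > 0:
        for i in np.argsort(-remainder, kind="stable"):
            if short == 0:
                break
            if base[i] < counts[i] - 1:
                base[i] += 1
                short -= 1
    elif short < 0:  # floor-clamping overshot (many tiny classes)
        for i in np.argsort(remainder, kind="stable"):
            if short == 0:
                break
            if base[i] > 1:
                base[i] -= 1
                short += 1
    train_idx, test_idx = [], []
    for cls, take in zip(classes, base):
        members = np.where(ds.y == cls)[0]
        perm = rng.permutation(members)
        train_idx.extend(perm[:take])
        test_idx.extend(perm[take:])
    return ds.subset(np.sort(train_idx)), ds.subset(np.sort(test_idx))


# --------------------------------------------------------------------------- #
# SMOTE
# --------------------------------------------------------------------------- #

def _zscore_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def smote_balance(
    train: LabeledDataset,
    target_count: int | str = "majority",
    k_neighbors: int = 5,
    seed: int = 0,
) -> LabeledDataset:
    """Oversample minority classes to ``target_count`` by SMOTE interpolation.

    Each synthetic sample lies on the segment between a minority sample and
    one of its k nearest same-class neighbors (neighbors in z-scored space,
    interpolation in the original space).  Classes at or above the target are
    untouched; synthetic rows are provenance-flagged.
    """
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(train.y, return_counts=True)
    target = int(counts.max()) if target_count == "majority" else int(target_count)
    mu, sd = _zscore_stats(train.X)
    Xz = (train.X - mu) / sd

    new_X, new_y = [], []
    for cls, count in zip(classes, counts):
        deficit = target - count
        if deficit <= 0:
            continue
        if count < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members; cannot SMOTE")
        members = np.where(train.y == cls)[0]
        k = min(k_neighbors, count - 1)
        if k < k_neighbors:
            warnings.warn(f"class {cls!r}: shrinking k_neighbors to {k}")
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xz[members])
        neigh = nn.kneighbors(Xz[members], return_distance=False)[:, 1:]
        base = rng.integers(0, count, size=deficit)
        pick = rng.integers(0, k, size=deficit)
        u = rng.random(deficit)
        xi = train.X[members[base]]
        xn = train.X[members[neigh[base, pick]]]
        new_X.append(xi + u[:, None] * (xn - xi))
        new_y.extend([cls] * deficit)

    if not new_X:
        return train
    X = np.vstack([train.X] + new_X)
    y = np.concatenate([train.y, np.asarray(new_y, dtype=train.y.dtype)])
    prov = np.concatenate([train.provenance,
                           np.full(len(new_y), SYNTHETIC, dtype=object)])
    ids = np.concatenate([train.sample_ids,
                          np.array([f"smote{i:04d}" for i in range(len(new_y))],
                                   dtype=object)])
    return LabeledDataset(X, y, train.feature_names, prov, ids)


# --------------------------------------------------------------------------- #
# feature selection
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class FeatureSelection:
    """Per-feature importances (normalized to sum 1) and the selected prefix."""

    method: str
    importances: np.ndarray
    selected: tuple[int, ...]
    threshold: float
    feature_names: tuple[str, ...] = field(default=())

    @property
    def selected_names(self) -> tuple[str, ...]:
        return tuple(self.feature_names[i] for i in self.selected)

    def to_json(self) -> str:
        return json.dumps({
            "method": self.method,
            "threshold": self.threshold,
            "importances": {n: float(v) for n, v in
                            zip(self.feature_names, self.importances)},
            "selected": list(self.selected_names),
        }, indent=2)


def _numeric_labels(y: np.ndarray) -> np.ndarray:
    try:
        return np.asarray(y, dtype=float)
    except (TypeError, ValueError):
        _, inv = np.unique(y, return_inverse=True)
        return inv.astype(float)


def _importances(train: LabeledDataset, method: str, seed: int) -> np.ndarray:
    X, y = train.X, train.y
    p = X.shape[1]
    if method == "ALL":
        return np.full(p, 1.0 / p)
    if method == "RFI":
        rf = RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
        return rf.fit(X, y).feature_importances_
    if method == "COR":
        # |Pearson r| against the numeric grade label; constant features get 0
        yn = _numeric_labels(y)
        Xc = X - X.mean(axis=0)
        yc = yn - yn.mean()
        sx = np.sqrt((Xc**2).sum(axis=0))
        sy = np.sqrt((yc**2).sum())
        # scale-relative zero test: a constant column's centered norm is only
        # rounding noise
        const = sx <= 1e-9 * np.sqrt(len(X)) * (np.abs(X).max(axis=0) + 1.0)
        if const.any():
            warnings.warn(f"{const.sum()} constant feature(s) get zero correlation")
        r = np.zeros(p)
        ok = ~const
        if sy > 0:
            r[ok] = np.abs(Xc[:, ok].T @ yc / (sx[ok] * sy))
        return r
    if method == "MI":
        mu, sd = _zscore_stats(X)
        return mutual_info_classif((X - mu) / sd, y, n_neighbors=3,
                                   random_state=seed)
    if method == "RFE":
        est = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
        rfe = RFE(est, n_features_to_select=1, step=1).fit(X, y)
        # ranking_ = 1 for the last surviving feature; invert so importance
        # decreases along the elimination order
        return (p - rfe.ranking_ + 1).astype(float)
    if method == "XGB":
        from xgboost import XGBClassifier
        _, y_enc = np.unique(y, return_inverse=True)
        model = XGBClassifier(n_estimators=200, max_depth=4, learning_rate=0.1,
                              random_state=seed, verbosity=0,
                              importance_type="total_gain", n_jobs=1)
        model.fit(X, y_enc)
        return model.feature_importances_.astype(float)
    raise ValueError(f"unknown selection method {method!r}; "
                     f"expected one of {SELECTION_METHODS}")


def select_features(
    train: LabeledDataset,
    method: str = "ALL",
    threshold: float = 0.60,
    seed: int = 0,
) -> FeatureSelection:
    """Rank features by one of the six methods; keep the top-60%-cumulative set.

    Importances are normalized to sum 1 and sorted descending (ties broken by
    original index); the minimal prefix whose cumulative mass reaches
    ``threshold`` is selected.  ALL selects every feature.
    """
    imp = np.asarray(_importances(train, method, seed), dtype=float)
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    if method == "ALL":
        selected = tuple(range(len(imp)))
    else:
        order = np.argsort(-imp, kind="stable")
        cum = np.cumsum(imp[order])
        n_keep = int(np.searchsorted(cum, threshold - 1e-12) + 1)
        selected = tuple(int(i) for i in order[:n_keep])
    return FeatureSelection(method=method, importances=imp, selected=selected,
                            threshold=threshold, feature_names=train.feature_names)


def standardize(train: LabeledDataset, *others: LabeledDataset):
    """Z-score datasets using training-fold statistics."""
    mu, sd = _zscore_stats(train.X)
    out = [replace_X(train, (train.X - mu) / sd)]
    out += [replace_X(o, (o.X - mu) / sd) for o in others]
    return out[0] if not others else tuple(out)


def replace_X(ds: LabeledDataset, X: np.ndarray) -> LabeledDataset:
    return LabeledDataset(X, ds.y, ds.feature_names, ds.provenance, ds.sample_ids)
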