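"""Saponin-content grade derivation by hierarchical clustering and the elbow rule.

Total saponin (PNS) assay values, in mg per g of dried powder, are clustered
agglomeratively with squared-Euclidean distance and average (between-groups,
UPGMA) linkage.  The within-cluster sum of squares J(K) over dendrogram cuts
gives an elbow curve; the most prominent elbows pick the grade counts, and the
cluster extents become contiguous grade intervals (grade 1 = lowest content).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# assay tables
# --------------------------------------------------------------------------- #

def validate_assays(assays: pd.DataFrame) -> pd.DataFrame:
    """Check an assay table: columns sample_id / pns, unique ids, pns > 0."""
    missing = {"sample_id", "pns"} - set(assays.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    if assays["sample_id"].duplicated().any():
        raise ValueError("sample ids must be unique")
    pns = assays["pns"].to_numpy(dtype=float)
    if not np.all(np.isfinite(pns)) or np.any(pns <= 0):
        raise ValueError("pns values must be finite and positive")
    return assays


def read_assay_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "pns_mg_per_g" in df.columns:
        df = df.rename(columns={"pns_mg_per_g": "pns"})
    return validate_assays(df)


def write_assay_csv(assays: pd.DataFrame, path) -> None:
    validate_assays(assays)
    assays.rename(columns={"pns": "pns_mg_per_g"}).to_csv(path, index=False)


# --------------------------------------------------------------------------- #
# hierarchical clustering
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ClusterResult:
    """Labels of a K-cut of the average-linkage dendrogram plus the merge record."""

    labels: np.ndarray
    K: int
    linkage_record: np.ndarray  # scipy linkage matrix (merges and heights)


def hca_cluster(assays: pd.DataFrame, K: int) -> ClusterResult:
    """Cut the average-linkage / squared-Euclidean dendrogram into K clusters.

    Clustering is univariate on the pns column; cuts are nested across K
    because they come from one dendrogram.
    """
    validate_assays(assays)
    x = assays["pns"].to_numpy(dtype=float)
    n = len(x)
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, {n}], got {K}")
    if n == 1:
        return ClusterResult(labels=np.zeros(1, dtype=int), K=1,
                             linkage_record=np.empty((0, 4)))
    Z = linkage(pdist(x[:, None], metric="sqeuclidean"), method="average")
    labels = fcluster(Z, t=K, criterion="maxclust") - 1
    return ClusterResult(labels=labels, K=K, linkage_record=Z)


def wss_curve(assays: pd.DataFrame, Kmax: int) -> np.ndarray:
    """Total within-cluster sum of squares J(K) for K = 1..Kmax.

    J(K) = Σ_k Σ_{i∈C_k} (x_i − μ_k)² over the dendrogram cut at K.
    """
    validate_assays(assays)
    x = assays["pns"].to_numpy(dtype=float)
    if Kmax > len(x):
        raise ValueError("Kmax cannot exceed the number of samples")
    J = np.empty(Kmax)
    for K in range(1, Kmax + 1):
        labels = hca_cluster(assays, K).labels
        J[K - 1] = sum(
            ((x[labels == c] - x[labels == c].mean()) ** 2).sum()
            for c in np.unique(labels)
        )
    return J


def detect_elbows(J: np.ndarray, n_elbows: int = 3, normalize: bool = True) -> list[int]:
    """Rank candidate cluster counts by the prominence of the elbow at each K.

    The curvature statistic at K is the second forward difference
    Δ²J(K) = J(K−1) − 2·J(K) + J(K+1); with ``normalize`` (default) it is
    divided by J(K), which measures the bend relative to the remaining
    distortion and recovers the visually prominent elbow even when the K=1→2
    drop dominates the raw differences.  Returns the top ``n_elbows`` K values
    (K indexes from 1), descending by prominence; a flat or exactly linear
    curve yields an empty list.
    """
    J = np.asarray(J, dtype=float)
    if len(J) < 4:
        raise ValueError("elbow detection needs a WSS curve with at least 4 points")
    d2 = J[:-2] - 2.0 * J[1:-1] + J[2:]  # curvature at K = 2..Kmax-1
    if normalize:
        denom = np.maximum(J[1:-1], 1e-12 * max(J[0], 1.0))
        score = d2 / denom
    else:
        score = d2
    if np.all(np.abs(score) < 1e-12):
        logger.warning("WSS curve is flat or linear; no elbow found")
        return []
    order = np.argsort(-score, kind="stable")
    return [int(i) + 2 for i in order[:n_elbows] if score[i] > 0]


# --------------------------------------------------------------------------- #
# grade tables
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class GradeTable:
    """Ordered, contiguous saponin-content intervals mapping mg/g to grades.

    Grade 1 covers the lowest content band.  Intervals are lower-closed,
    upper-open, except the top interval which is closed.
    """

    scheme: int
    rows: tuple[tuple[int, float, float], ...]  # (grade, lo, hi)

    def __post_init__(self) -> None:
        grades = [r[0] for r in self.rows]
        if grades != list(range(1, len(self.rows) + 1)):
            raise ValueError("grades must be 1..K ascending")
        for (g, lo, hi) in self.rows:
            if not lo < hi:
                raise ValueError(f"grade {g}: bounds must be increasing")
        for prev, cur in zip(self.rows, self.rows[1:]):
            if prev[2] != cur[1]:
                raise ValueError("grade intervals must be contiguous")

    def to_json(self) -> str:
        return json.dumps({
            "scheme": self.scheme,
            "rows": [{"grade": g, "lo": lo, "hi": hi} for g, lo, hi in self.rows],
        }, indent=2)

    @staticmethod
    def from_json(text: str) -> "GradeTable":
        d = json.loads(text)
        for key in ("scheme", "rows"):
            if key not in d:
                raise ValueError(f"grade table JSON missing field '{key}'")
        rows = tuple((int(r["grade"]), float(r["lo"]), float(r["hi"])) for r in d["rows"])
        return GradeTable(scheme=int(d["scheme"]), rows=rows)


def derive_grade_table(assays: pd.DataFrame, K: int, precision: int = 0) -> GradeTable:
    """Turn the K-cluster solution into K contiguous grade intervals.

    Clusters are ordered by mean pns (ascending → grades 1..K); each internal
    boundary is the midpoint between adjacent cluster extents, rounded to
    ``precision`` decimals; the outer bounds are the observed min and max.
    """
    result = hca_cluster(assays, K)
    x = assays["pns"].to_numpy(dtype=float)
    clusters = []
    for c in np.unique(result.labels):
        vals = x[result.labels == c]
        clusters.append((vals.mean(), vals.min(), vals.max()))
    clusters.sort()
    for (_, _, hi_prev), (_, lo_next, _) in zip(clusters, clusters[1:]):
        if hi_prev > lo_next:
            raise ValueError("clusters interleave along the pns axis")
    bounds = [float(np.round(x.min(), precision))]
    for (_, _, hi_prev), (_, lo_next, _) in zip(clusters, clusters[1:]):
        bounds.append(float(np.round(0.5 * (hi_prev + lo_next), precision)))
    bounds.append(float(np.round(x.max(), precision)))
    rows = tuple((g + 1, bounds[g], bounds[g + 1]) for g in range(K))
    return GradeTable(scheme=K, rows=rows)


def assign_grade(pns: float, table: GradeTable) -> int:
    """Grade of an assay value: lower-closed / upper-open intervals, top closed.

    Out-of-range values clamp to the boundary grades (logged).
    """
    if not np.isfinite(pns):
        raise ValueError("pns must be finite")
    rows = table.rows
    if pns < rows[0][1]:
        logger.info("pns %.3g below grading range; clamped to grade 1", pns)
        return rows[0][0]
    if pns >= rows[-1][2]:
        if pns > rows[-1][2]:
            logger.info("pns %.3g above grading range; clamped to grade %d",
                        pns, rows[-1][0])
        return rows[-1][0]
    for g, lo, hi in rows:
        if lo <= pns < hi:
            return g
    raise AssertionError("unreachable: contiguous intervals cover the range")


# Published grade boundary tables for *P. notoginseng* total saponins (mg/g).
# The underlying 143 raw assay values are not deposited, so these boundaries
# ship as reference tables rather than being re-derived.
PAPER_GRADE_TABLES: dict[int, GradeTable] = {
    3: GradeTable(3, ((1, 54.0, 101.0), (2, 101.0, 129.0), (3, 129.0, 162.0))),
    5: GradeTable(5, ((1, 54.0, 85.0), (2, 85.0, 101.0), (3, 101.0, 129.0),
                      (4, 129.0, 150.0), (5, 150.0, 162.0))),
    6: GradeTable(6, ((1, 54.0, 66.0), (2, 66.0, 85.0), (3, 85.0, 101.0),
                      (4, 101.0, 129.0), (5, 129.0, 150.0), (6, 150.0, 162.0))),
}
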