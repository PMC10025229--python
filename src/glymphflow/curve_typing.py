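"""K-means typing of concentration-time curves.

Curves are clustered on two features — wash-in rate and peak concentration —
after z-scoring.  The number of clusters is chosen by the elbow method
(maximum second difference of the within-cluster sum of squares, WCSS).  With
k = 2 the clusters are labelled type I (periarterial flow pattern: higher
peak, steeper wash-in) and type II (perivenous pattern) by comparing the
cluster centroids.

K-means is scikit-learn's k-means++ with multiple restarts.  To make the
assignment invariant to the ordering of the input rows, the model is fitted
on a lexicographically sorted copy of the feature matrix and every row is
then assigned to its nearest fitted centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "CurveTypeAssignment",
    "cluster_ctcs",
    "label_types",
    "select_k_elbow",
    "type_summary",
]

FEATURE_NAMES = ("wash_in_rate", "peak_concentration")


@dataclass
class CurveTypeAssignment:
    """Cluster assignment of CTC feature vectors, optionally type-labelled."""

    cluster: np.ndarray  # (n,) integer cluster index
    centroids_std: np.ndarray  # (k, 2) centroids in standardized space
    centroids_raw: np.ndarray  # (k, 2) centroids in raw feature units
    wcss: float
    k: int
    feature_means: np.ndarray
    feature_sds: np.ndarray
    standardized: bool
    type_of_cluster: dict[int, str] = field(default_factory=dict)

    @property
    def types(self) -> np.ndarray:
        """Per-curve type labels ('I'/'II'); requires :func:`label_types`."""
        if not self.type_of_cluster:
            raise ValueError("clusters have not been labelled; call label_types")
        return np.array([self.type_of_cluster[c] for c in self.cluster])


def _validate_features(features: np.ndarray) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("features must be an n x 2 matrix (wash-in, peak)")
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    return x


def _standardize(x: np.ndarray, standardize: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = x.mean(axis=0)
    sds = x.std(axis=0)
    if not standardize:
        return x.copy(), np.zeros(2), np.ones(2)
    safe = np.where(sds > 0, sds, 1.0)
    return (x - means) / safe, means, safe


def _kmeans_fit(z: np.ndarray, k: int, seed: int, n_restarts: int) -> np.ndarray:
    """Row-order-invariant k-means: fit on sorted rows, return centroids."""
    order = np.lexsort(z.T[::-1])
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    km.fit(z[order])
    return km.cluster_centers_


def _assign(z: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, float]:
    d2 = ((z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    wcss = float(d2[np.arange(z.shape[0]), labels].sum())
    return labels, wcss


def cluster_ctcs(
    features: np.ndarray,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 10,
    standardize: bool = True,
) -> CurveTypeAssignment:
    """Cluster (wash-in, peak) feature vectors into k groups."""
    x = _validate_features(features)
    if k < 1 or k > x.shape[0]:
        raise ValueError("k must satisfy 1 <= k <= n")
    if k > 1 and np.all(x == x[0]):
        raise ValueError("all feature vectors identical: cannot form k > 1 clusters")
    z, means, sds = _standardize(x, standardize)
    centroids = _kmeans_fit(z, k, seed, n_restarts)
    labels, wcss = _assign(z, centroids)
    return CurveTypeAssignment(
        cluster=labels,
        centroids_std=centroids,
        centroids_raw=centroids * sds + means,
        wcss=wcss,
        k=k,
        feature_means=means,
        feature_sds=sds,
        standardized=standardize,
    )


def select_k_elbow(
    features: np.ndarray,
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    seed: int = 0,
    n_restarts: int = 10,
    standardize: bool = True,
) -> tuple[int, dict[int, float]]:
    """Pick the cluster count at the elbow of the WCSS curve.

    The elbow is operationalised as the k maximising the second difference
    WCSS(k-1) - 2 WCSS(k) + WCSS(k+1) over the interior of ``k_range``;
    ties resolve to the smallest k.  With fewer than three candidate values
    the smallest k is returned.
    """
    x = _validate_features(features)
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    if x.shape[0] < max(ks):
        raise ValueError("n must be at least max(k_range)")
    wcss: dict[int, float] = {}
    for k in ks:
        wcss[k] = cluster_ctcs(x, k=k, seed=seed, n_restarts=n_restarts,
                               standardize=standardize).wcss
    if len(ks) < 3:
        return ks[0], wcss
    best_k, best_curv = ks[0], -np.inf
    for prev, cur, nxt in zip(ks, ks[1:], ks[2:]):
        curv = wcss[prev] - 2.0 * wcss[cur] + wcss[nxt]
        if curv > best_curv + 1e-12:
            best_k, best_curv = cur, curv
    return best_k, wcss


def label_types(assignment: CurveTypeAssignment) -> CurveTypeAssignment:
    """Label the two clusters as type I / type II.

    Type I is the cluster with the greater centroid peak concentration
    (ties broken by greater centroid wash-in rate); type II is the other.
    Requires k = 2.
    """
    if assignment.k != 2:
        raise ValueError("type labelling requires exactly 2 clusters")
    peaks = assignment.centroids_raw[:, 1]
    washins = assignment.centroids_raw[:, 0]
    if peaks[0] != peaks[1]:
        type1 = int(np.argmax(peaks))
    else:
        type1 = int(np.argmax(washins))
    assignment.type_of_cluster = {type1: "I", 1 - type1: "II"}
    return assignment


def type_summary(
    types: np.ndarray, curve_subjects: np.ndarray, subjects: pd.DataFrame
) -> dict:
    """Per-group type proportions, per-subject type-I counts, pooled counts.

    ``subjects`` needs ``subject_id`` and ``group`` columns; every curve must
    map to a known subject.
    """
    types = np.asarray(types)
    curve_subjects = np.asarray(curve_subjects)
    if types.shape != curve_subjects.shape:
        raise ValueError("types and curve_subjects must align")
    group_of = dict(zip(subjects["subject_id"], subjects["group"]))
    missing = set(curve_subjects) - set(group_of)
    if missing:
        raise ValueError(f"curves reference unknown subjects: {sorted(missing)[:5]}")
    df = pd.DataFrame({
        "subject_id": curve_subjects,
        "type": types,
        "group": [group_of[s] for s in curve_subjects],
    })
    proportions = {
        g: {t: float((sub["type"] == t).mean()) for t in ("I", "II")}
        for g, sub in df.groupby("group")
    }
    per_group_counts = {
        g: {t: int((sub["type"] == t).sum()) for t in ("I", "II")}
        for g, sub in df.groupby("group")
    }
    per_subject_type1 = (
        df[df["type"] == "I"].groupby("subject_id").size().to_dict()
    )
    per_subject_type1 = {
        s: int(per_subject_type1.get(s, 0)) for s in df["subject_id"].unique()
    }
    pooled = {
        t: int(sum(c[t] for c in per_group_counts.values())) for t in ("I", "II")
    }
    pooled["total"] = pooled["I"] + pooled["II"]
    return {
        "proportions": proportions,
        "per_group_counts": per_group_counts,
        "per_subject_type1_counts": per_subject_type1,
        "pooled_counts": pooled,
    }
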