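"""Mutual-information feature screening.

Reduces a large set of candidate molecular features (e.g. ligand-to-residue
distances) to a small non-redundant representative set.  Features are
compared by an information-based dissimilarity ``d = 1 - I(X;Y)/H(X,Y)``
estimated from equal-width 2-D histograms, clustered by k-medoids on that
dissimilarity, and each cluster is summarised by its medoid feature.  The
number of clusters is chosen by the sharpest elbow of the distortion curve,
capped at ``max_clusters``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import TimeSeriesTable

__all__ = [
    "FeatureMatrix",
    "FeatureClustering",
    "mutual_information",
    "feature_dissimilarity",
    "dissimilarity_matrix",
    "cluster_features",
]

DEFAULT_BINS = 50


@dataclass
class FeatureMatrix:
    """Frames x features matrix with labels, time stamps and optional weights."""

    values: np.ndarray
    names: list[str]
    frame_times: np.ndarray | None = None
    frame_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames x features)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in feature matrix")
        if len(self.names) != self.values.shape[1]:
            raise ValueError("one name per feature required")
        if self.frame_times is None:
            self.frame_times = np.arange(self.values.shape[0], dtype=float)
        self.frame_times = np.asarray(self.frame_times, float)
        if self.frame_weights is not None:
            self.frame_weights = np.asarray(self.frame_weights, float)
            if np.any(self.frame_weights < 0) or self.frame_weights.sum() <= 0:
                raise ValueError("frame weights must be non-negative with positive sum")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_table(cls, table: TimeSeriesTable, columns: list[str] | None = None) -> "FeatureMatrix":
        cols = columns if columns is not None else table.columns
        return cls(values=table.values(cols), names=list(cols), frame_times=table.times)


@dataclass
class FeatureClustering:
    """k-medoids partition of features with one representative per cluster."""

    cluster_assignments: dict[str, int]
    representatives: list[str]
    dissimilarity_matrix: np.ndarray
    names: list[str] = field(default_factory=list)
    distortions: dict[int, float] = field(default_factory=dict)
    n_clusters: int = 0

    def to_dict(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "representatives": self.representatives,
            "cluster_assignments": self.cluster_assignments,
            "distortions": {str(k): v for k, v in self.distortions.items()},
        }


# -- information estimates ------------------------------------------------

def _joint_hist(x: np.ndarray, y: np.ndarray, n_bins: int) -> np.ndarray:
    h, _, _ = np.histogram2d(x, y, bins=n_bins)
    return h


def _entropies(counts: np.ndarray) -> tuple[float, float, float]:
    """(H(X), H(Y), H(X,Y)) in bits from a joint count table."""
    p = counts / counts.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)

    def h(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    return h(px), h(py), h(p.ravel())


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int = DEFAULT_BINS) -> float:
    """Histogram estimate of I(X;Y) in bits.

    Constant series carry no information: I = 0 by convention (with a
    warning), since a single occupied bin has zero entropy.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant series: mutual information defined as 0")
        return 0.0
    hx, hy, hxy = _entropies(_joint_hist(x, y, n_bins))
    return max(0.0, hx + hy - hxy)


def feature_dissimilarity(x: np.ndarray, y: np.ndarray, n_bins: int = DEFAULT_BINS) -> float:
    """Information distance d = 1 - I(X;Y)/H(X,Y) in [0, 1].

    d = 0 for deterministic mutual dependence, d -> 1 for independence.
    Two constant series have H(X,Y) = 0; d is then defined as 0 (warned).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        warnings.warn("both series constant: dissimilarity defined as 0")
        return 0.0
    hx, hy, hxy = _entropies(_joint_hist(x, y, n_bins))
    if hxy == 0:
        warnings.warn("zero joint entropy: dissimilarity defined as 0")
        return 0.0
    mi = max(0.0, hx + hy - hxy)
    return float(min(1.0, max(0.0, 1.0 - mi / hxy)))


def dissimilarity_matrix(fm: FeatureMatrix, n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """Symmetric zero-diagonal dissimilarity matrix over all feature pairs."""
    k = fm.n_features
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = feature_dissimilarity(
                fm.values[:, i], fm.values[:, j], n_bins
            )
    return d


# -- k-medoids ------------------------------------------------------------

def _farthest_point_init(d: np.ndarray, k: int) -> list[int]:
    """Deterministic seeding: most-central point first, then farthest points."""
    first = int(np.argmin(d.sum(axis=1)))
    medoids = [first]
    while len(medoids) < k:
        dist_to_set = d[:, medoids].min(axis=1)
        dist_to_set[medoids] = -1.0
        medoids.append(int(np.argmax(dist_to_set)))
    return medoids


def _kmedoids(d: np.ndarray, k: int, max_iter: int = 200) -> tuple[np.ndarray, list[int], float]:
    """PAM-style alternation: assign to nearest medoid, re-center each cluster."""
    medoids = _farthest_point_init(d, k)
    labels = np.argmin(d[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = []
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                new_medoids.append(medoids[c])
                continue
            within = d[np.ix_(members, members)].sum(axis=1)
            new_medoids.append(int(members[np.argmin(within)]))
        new_labels = np.argmin(d[:, new_medoids], axis=1)
        if new_medoids == medoids and np.array_equal(new_labels, labels):
            break
        medoids, labels = new_medoids, new_labels
    distortion = float(d[np.arange(d.shape[0]), np.asarray(medoids)[labels]].sum())
    return labels, medoids, distortion


def _select_k(distortions: dict[int, float], tol: float = 1e-12) -> int:
    """Sharpest elbow (maximal second difference) of the distortion curve.

    Smallest k wins among ties.  A single cluster that already achieves
    (near-)zero distortion means all features are redundant: k = 1.
    """
    ks = sorted(distortions)
    if distortions[ks[0]] <= tol:
        return ks[0]
    if len(ks) == 1:
        return ks[0]
    if len(ks) == 2:
        # no interior point: split only if it removes most of the distortion
        return ks[1] if distortions[ks[1]] < 0.5 * distortions[ks[0]] else ks[0]
    best_k, best_curv = ks[1], -np.inf
    for i in range(1, len(ks) - 1):
        curv = (
            distortions[ks[i - 1]] - 2 * distortions[ks[i]] + distortions[ks[i + 1]]
        )
        if curv > best_curv + tol:
            best_curv = curv
            best_k = ks[i]
    return best_k


def cluster_features(
    fm: FeatureMatrix,
    max_clusters: int = 20,
    n_bins: int = DEFAULT_BINS,
) -> FeatureClustering:
    """Cluster features on mutual-information dissimilarity; pick k by elbow.

    k-medoids is run for k = 1..max_clusters with deterministic farthest-point
    seeding, the cluster count is the sharpest elbow of the distortion curve
    (never exceeding ``max_clusters``), and each cluster is represented by its
    medoid feature.
    """
    if fm.n_features < 2:
        raise ValueError("at least 2 features required")
    if fm.n_frames < 10 * fm.n_features:
        warnings.warn(
            "fewer than 10 frames per feature: histogram MI estimates may be biased"
        )
    d = dissimilarity_matrix(fm, n_bins)
    kmax = min(max_clusters, fm.n_features)
    results = {}
    distortions = {}
    for k in range(1, kmax + 1):
        labels, medoids, distortion = _kmedoids(d, k)
        results[k] = (labels, medoids)
        distortions[k] = distortion
    k_star = _select_k(distortions)
    labels, medoids = results[k_star]
    # canonical cluster numbering: by first feature occurrence
    order: dict[int, int] = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order)
    assignments = {fm.names[i]: order[labels[i]] for i in range(fm.n_features)}
    reps = [""] * k_star
    for old, new in order.items():
        reps[new] = fm.names[medoids[old]]
    return FeatureClustering(
        cluster_assignments=assignments,
        representatives=reps,
        dissimilarity_matrix=d,
        names=list(fm.names),
        distortions=distortions,
        n_clusters=k_star,
    )
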