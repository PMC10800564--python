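"""Clustering and partition-agreement metrics: k-means, mean silhouette
coefficient, pair counts over sample pairs, and the adjusted Rand index.

The silhouette and ARI are implemented from their definitions (the formulas
these metrics are usually quoted by); scikit-learn's versions serve only as
independent cross-checks in the test suite.  k-means itself is delegated to
scikit-learn (Lloyd's algorithm with k-means++ seeding and restarts), since
the clustering step is standard machinery, not part of the method under
study.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

__all__ = [
    "ClusterLabels",
    "PairCounts",
    "SilhouetteReport",
    "kmeans",
    "mean_silhouette",
    "pair_counts",
    "adjusted_rand",
    "ari_pair_expression",
]


@dataclass
class ClusterLabels:
    """Integer labels in [0, k) with every cluster nonempty."""

    labels: np.ndarray
    k: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D integer vector")
        distinct = np.unique(self.labels)
        if self.k == 0:
            self.k = len(distinct)
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be nonnegative")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class PairCounts:
    """Agreement counts over unordered sample pairs between partitions X
    and Y: ``a`` same/same, ``b`` different/different, ``c`` same in X only,
    ``d`` same in Y only.  They always sum to n(n−1)/2."""

    a: int
    b: int
    c: int
    d: int

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class SilhouetteReport:
    per_sample: np.ndarray
    mean_sh: float


def _as_labels(labels) -> np.ndarray:
    if isinstance(labels, ClusterLabels):
        return labels.labels
    return np.asarray(labels, dtype=np.int64)


def kmeans(X: np.ndarray, k: int, seed: int = 0, n_init: int = 10) -> ClusterLabels:
    """k-means clustering (Lloyd + k-means++, best of ``n_init`` restarts),
    deterministic for a given seed."""
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range [1, {n}]")
    km = KMeans(
        n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd"
    ).fit(X)
    return ClusterLabels(labels=km.labels_, k=k)


def mean_silhouette(X: np.ndarray, labels) -> SilhouetteReport:
    """Mean silhouette coefficient with Euclidean dissimilarity.

    For sample i, ``a_i`` is its average distance to the other members of its
    own cluster and ``b_i`` the smallest average distance to any other
    cluster; SH(i) = (b_i − a_i)/max(a_i, b_i).  Samples in singleton
    clusters score 0 by convention.
    """
    X = np.asarray(X, dtype=np.float64)
    lab = _as_labels(labels)
    if len(lab) != X.shape[0]:
        raise ValueError("labels length must match number of samples")
    clusters = np.unique(lab)
    if len(clusters) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = cdist(X, X)
    n = X.shape[0]
    sh = np.zeros(n)
    # mean distance from every sample to each cluster
    mean_to = np.column_stack([D[:, lab == c].mean(axis=1) for c in clusters])
    sizes = {c: int((lab == c).sum()) for c in clusters}
    col = {c: j for j, c in enumerate(clusters)}
    for i in range(n):
        ci = lab[i]
        size = sizes[ci]
        if size == 1:
            sh[i] = 0.0
            continue
        # exclude self from the intra-cluster average
        a_i = mean_to[i, col[ci]] * size / (size - 1)
        b_i = min(mean_to[i, col[c]] for c in clusters if c != ci)
        sh[i] = (b_i - a_i) / max(a_i, b_i)
    return SilhouetteReport(per_sample=sh, mean_sh=float(sh.mean()))


def _contingency(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    table = np.zeros((xi.max() + 1, yi.max() + 1), dtype=np.int64)
    np.add.at(table, (xi, yi), 1)
    return table


def pair_counts(A, B) -> PairCounts:
    """Exact pair-agreement counts, computed in O(n + |A|·|B|) from the
    contingency table (equivalent to enumerating all n(n−1)/2 pairs)."""
    x, y = _as_labels(A), _as_labels(B)
    if len(x) != len(y):
        raise ValueError("label vectors must have equal length")
    n = len(x)
    table = _contingency(x, y)
    same_both = int(sum(comb(int(v), 2) for v in table.ravel()))
    same_x = int(sum(comb(int(v), 2) for v in table.sum(axis=1)))
    same_y = int(sum(comb(int(v), 2) for v in table.sum(axis=0)))
    total = comb(n, 2)
    a = same_both
    c = same_x - same_both
    d = same_y - same_both
    b = total - a - c - d
    return PairCounts(a=a, b=b, c=c, d=d)


def adjusted_rand(A, B) -> float:
    """Hubert–Arabie adjusted Rand index from the contingency table.

    ARI = (Σᵢⱼ C(nᵢⱼ,2) − E) / (½(Σᵢ C(aᵢ,2) + Σⱼ C(bⱼ,2)) − E) with
    E = Σᵢ C(aᵢ,2)·Σⱼ C(bⱼ,2)/C(n,2); equals 1 for identical partitions and
    has expectation 0 under independent random labelings.
    """
    x, y = _as_labels(A), _as_labels(B)
    if len(x) != len(y):
        raise ValueError("label vectors must have equal length")
    n = len(x)
    if n < 2:
        raise ValueError("ARI needs at least 2 samples")
    table = _contingency(x, y)
    index = sum(comb(int(v), 2) for v in table.ravel())
    sum_a = sum(comb(int(v), 2) for v in table.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in table.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial (all-singletons or one cluster)
        return 1.0
    return float((index - expected) / (max_index - expected))


def ari_pair_expression(pc: PairCounts, n: int) -> float:
    """A pair-count ARI formulation sometimes quoted in the literature,
    kept only as a documented cross-check:

    ``[C(n,2)(a+b) − ((a+b)(a+c)+(c+d)(b+d))] /
    [C(n,2)² − ((a+b)(a+c)+(c+d)(b+d))]``

    The contingency-table form in :func:`adjusted_rand` is authoritative;
    this expression does not reduce to it in general.
    """
    t = comb(n, 2)
    cross = (pc.a + pc.b) * (pc.a + pc.c) + (pc.c + pc.d) * (pc.b + pc.d)
    return float((t * (pc.a + pc.b) - cross) / (t**2 - cross))
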