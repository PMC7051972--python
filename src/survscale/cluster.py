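"""Consensus k-medians clustering under the Manhattan metric.

k-medians is the L1 analogue of k-means: points join their nearest centroid
by Manhattan distance and each centroid is recomputed as the coordinate-wise
median of its members, which makes the fit robust to outliers and natural
for one-hot encoded categorical features.  A single run depends on its
initialization, so the production path resamples subjects and reruns
k-medians many times, accumulating a consensus matrix

    consensus(i, j) = (# runs where i and j landed in the same cluster)
                      / (# runs where both were sampled),

and extracts the final clusters by average-linkage agglomerative clustering
on ``1 - consensus``.  Cluster labels are 1-based throughout (1..k), and for
k = 2 labelings from different cross-validation folds can be aligned by
majority agreement on their shared subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering

__all__ = ["KMedians", "ConsensusKMedians", "match_fold_labels"]


def _as_points(X) -> np.ndarray:
    pts = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if pts.ndim != 2 or pts.size == 0:
        raise ValueError("expected a non-empty 2-d point matrix")
    return pts


def _columnwise_median(points: np.ndarray) -> np.ndarray:
    # even-sized sets: mean of the two middle values (numpy's convention)
    return np.median(points, axis=0)


def _manhattan_cost(points, medians, labels) -> float:
    return float(np.abs(points - medians[labels]).sum())


class KMedians(ClusterMixin, BaseEstimator):
    """Single-run k-medians with k-means++-style seeding (Manhattan D^2).

    ``n_init`` restarts keep the solution with the lowest total Manhattan
    cost.  Assignment ties go to the lowest cluster index; an emptied
    cluster is reseeded with the point currently farthest from its own
    median.  Labels are 1-based.

    ``init="exhaustive"`` restarts the alternating loop from every
    bipartition's medians when k = 2 (every size-k point subset otherwise)
    instead of random seeding.  Only sensible for very small instances; for
    k = 2 it provably attains the global-optimum cost, because neither the
    assignment step nor the median step can increase the cost, so the
    restart seeded at the optimal partition converges at the optimum.
    """

    def __init__(self, n_clusters: int = 2, n_init: int = 1, max_iter: int = 300,
                 init: str = "k-means++", random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.init = init
        self.random_state = random_state

    def fit(self, X, y=None):
        points = _as_points(X)
        n, k = len(points), self.n_clusters
        if k < 1 or k > n:
            raise ValueError(f"n_clusters={k} must lie in [1, n={n}]")
        rng = np.random.default_rng(self.random_state)
        best = None
        for start in self._starts(points, k, rng):
            labels, medians, cost = self._run(points, k, start)
            if best is None or cost < best[2]:
                best = (labels, medians, cost)
        self.labels_, self.medians_, self.inertia_ = best
        self.labels_ = self.labels_ + 1
        return self

    def _starts(self, points, k, rng):
        if self.init == "exhaustive":
            from itertools import combinations
            from math import comb

            n = len(points)
            if k == 2:
                if n > 18:
                    raise ValueError("exhaustive init is only for tiny instances")
                for bits in range(1, 2 ** (n - 1)):
                    mask = (bits >> np.arange(n)) & 1 == 1
                    yield np.vstack([
                        _columnwise_median(points[mask]),
                        _columnwise_median(points[~mask]),
                    ])
            else:
                if comb(n, k) > 100_000:
                    raise ValueError("exhaustive init is only for tiny instances")
                for subset in combinations(range(n), k):
                    yield points[list(subset)].astype(float).copy()
        elif self.init == "k-means++":
            for _ in range(self.n_init):
                yield self._plusplus_init(points, k, rng)
        else:
            raise ValueError(f"unknown init {self.init!r}")

    def _run(self, points, k, medians):
        medians = medians.copy()
        labels = np.full(len(points), -1)
        history = []
        for _ in range(self.max_iter):
            dist = cdist(points, medians, metric="cityblock")
            new_labels = dist.argmin(axis=1)
            new_labels = self._repair_empty(points, medians, new_labels, k)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                medians[c] = _columnwise_median(points[labels == c])
            history.append(_manhattan_cost(points, medians, labels))
        self.cost_history_ = history
        return labels, medians, _manhattan_cost(points, medians, labels)

    @staticmethod
    def _plusplus_init(points, k, rng) -> np.ndarray:
        n = len(points)
        centers = [points[rng.integers(n)]]
        for _ in range(1, k):
            d = cdist(points, np.asarray(centers), metric="cityblock").min(axis=1)
            weights = d**2
            total = weights.sum()
            if total == 0:  # all points coincide with a center
                idx = rng.integers(n)
            else:
                idx = rng.choice(n, p=weights / total)
            centers.append(points[idx])
        return np.asarray(centers, dtype=float)

    @staticmethod
    def _repair_empty(points, medians, labels, k):
        for c in range(k):
            if np.any(labels == c):
                continue
            # reseed with the point farthest from its current median
            dist_own = np.abs(points - medians[labels]).sum(axis=1)
            labels = labels.copy()
            labels[int(np.argmax(dist_own))] = c
        return labels

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def predict(self, X) -> np.ndarray:
        points = _as_points(X)
        if points.shape[1] != self.medians_.shape[1]:
            raise ValueError("point dimension does not match the fitted medians")
        return cdist(points, self.medians_, metric="cityblock").argmin(axis=1) + 1


class ConsensusKMedians(ClusterMixin, BaseEstimator):
    """Consensus clustering over repeated subsampled k-medians runs.

    Each of ``n_runs`` draws a without-replacement subsample of
    ``subsample_fraction`` of the subjects, runs :class:`KMedians` with a
    fresh seed, and increments the pairwise co-clustered (M) and co-sampled
    (I) counters.  The consensus matrix M / I is symmetric with entries in
    [0, 1] and unit diagonal; clusters are extracted from it by
    average-linkage agglomerative clustering on ``1 - consensus`` cut at
    ``n_clusters``, and the final medians are recomputed from the extracted
    member sets.  New points are assigned to the nearest median (ties to
    the lowest label).
    """

    def __init__(self, n_clusters: int = 2, n_runs: int = 1000,
                 subsample_fraction: float = 0.8, max_iter: int = 300,
                 random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_runs = n_runs
        self.subsample_fraction = subsample_fraction
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        points = _as_points(X)
        n, k = len(points), self.n_clusters
        if k > n:
            raise ValueError(f"n_clusters={k} exceeds n={n}")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        size = max(k, int(round(self.subsample_fraction * n)))
        rng = np.random.default_rng(self.random_state)

        co_clustered = np.zeros((n, n))
        co_sampled = np.zeros((n, n))
        for _ in range(self.n_runs):
            sample = (np.arange(n) if size == n
                      else rng.choice(n, size=size, replace=False))
            km = KMedians(
                n_clusters=k, max_iter=self.max_iter,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(points[sample])
            onehot = np.equal.outer(km.labels_, np.arange(1, k + 1)).astype(float)
            ix = np.ix_(sample, sample)
            co_sampled[ix] += 1.0
            co_clustered[ix] += onehot @ onehot.T
        if np.any(co_sampled == 0):
            raise RuntimeError(
                "some subject pair was never co-sampled; increase n_runs or "
                "subsample_fraction"
            )
        self.consensus_ = co_clustered / co_sampled

        agglo = AgglomerativeClustering(
            n_clusters=k, metric="precomputed", linkage="average"
        ).fit(1.0 - self.consensus_)
        self.labels_ = agglo.labels_ + 1
        self.medians_ = np.vstack([
            _columnwise_median(points[self.labels_ == c]) for c in range(1, k + 1)
        ])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def predict(self, X) -> np.ndarray:
        points = _as_points(X)
        if points.shape[1] != self.medians_.shape[1]:
            raise ValueError("point dimension does not match the fitted medians")
        return cdist(points, self.medians_, metric="cityblock").argmin(axis=1) + 1


def match_fold_labels(labels: pd.Series, reference: pd.Series) -> pd.Series:
    """Align a 2-cluster labeling with a reference labeling.

    Cluster numbering is arbitrary per fold, so labelings from different
    folds are compared on the subjects they share: if agreement there is
    below one half the labels are inverted (1 <-> 2), otherwise (including
    an exact tie) they are kept.  Only defined for two clusters.
    """
    labels = pd.Series(labels)
    reference = pd.Series(reference)
    if not set(labels.unique()) <= {1, 2} or not set(reference.unique()) <= {1, 2}:
        raise ValueError("label matching is defined for two clusters labelled 1/2")
    shared = labels.index.intersection(reference.index)
    if len(shared) == 0:
        raise ValueError("labelings share no subjects")
    agreement = float((labels.loc[shared] == reference.loc[shared]).mean())
    if agreement < 0.5:
        return labels.map({1: 2, 2: 1})
    return labels.copy()
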