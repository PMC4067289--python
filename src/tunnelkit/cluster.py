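"""Clustering estimators used across the pipeline.

Both operate on precomputed, symmetric, zero-diagonal dissimilarity matrices
and follow the scikit-learn estimator protocol (``fit``, ``labels_``,
``get_params``/``set_params``), so they compose with sklearn tooling.

- :class:`KMedoids`: PAM with a deterministic greedy BUILD initialization
  followed by SWAP to a local optimum.  No randomness, so runs reproduce.
- :class:`GromosClustering`: iterative neighbor counting -- the point with the
  most neighbors within the cutoff becomes a cluster center and is removed
  together with its neighbors; repeats until no points remain.  When given a
  ``target_size`` instead of a cutoff, the smallest cutoff whose cluster count
  is <= target is located by bisection (the count is non-increasing in the
  cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise dissimilarities with row labels."""

    values: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not self.labels:
            self.labels = [str(i) for i in range(self.values.shape[0])]

    def __len__(self):
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)


def _check_dissimilarity(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError("expected a square dissimilarity matrix")
    if not np.allclose(X, X.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(np.diag(X) > 1e-8):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    if np.any(X < -1e-12):
        raise ValueError("dissimilarities must be non-negative")
    return X


class KMedoids(BaseEstimator, ClusterMixin):
    """Partitioning Around Medoids on a precomputed dissimilarity matrix.

    Deterministic: BUILD greedily adds the medoid giving the largest decrease
    in total dissimilarity (ties to the lowest index); SWAP applies the best
    improving (medoid, non-medoid) exchange until none improves.  Points are
    assigned to the nearest medoid, ties to the lower medoid index.

    Attributes
    ----------
    medoid_indices_ : ndarray of shape (n_clusters,)
    labels_ : ndarray of shape (n,) cluster index per point
    inertia_ : float, total within-cluster dissimilarity to medoids
    """

    def __init__(self, n_clusters: int = 2, max_iter: int = 300):
        self.n_clusters = n_clusters
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = _check_dissimilarity(X)
        n = X.shape[0]
        k = self.n_clusters
        if not 1 <= k <= n:
            raise ValueError(f"n_clusters must be in [1, {n}], got {k}")

        # BUILD
        medoids = [int(np.argmin(X.sum(axis=1)))]
        while len(medoids) < k:
            dmin = X[:, medoids].min(axis=1)
            # gain of adding candidate c: sum of improvements over dmin
            gains = np.maximum(dmin[None, :] - X, 0.0).sum(axis=1)
            gains[medoids] = -np.inf
            medoids.append(int(np.argmax(gains)))

        def objective(meds):
            return float(X[:, meds].min(axis=1).sum())

        # SWAP
        current = objective(medoids)
        for _ in range(self.max_iter):
            best = (0.0, None, None)
            med_set = set(medoids)
            for mi, m in enumerate(medoids):
                for h in range(n):
                    if h in med_set:
                        continue
                    trial = medoids.copy()
                    trial[mi] = h
                    delta = objective(trial) - current
                    if delta < best[0] - 1e-12:
                        best = (delta, mi, h)
            if best[1] is None:
                break
            medoids[best[1]] = best[2]
            current += best[0]
        medoids = sorted(medoids)

        D = X[:, medoids]
        self.medoid_indices_ = np.array(medoids, dtype=int)
        self.labels_ = np.argmin(D, axis=1).astype(int)  # argmin ties -> lower index
        self.inertia_ = float(D[np.arange(n), self.labels_].sum())
        return self


class GromosClustering(BaseEstimator, ClusterMixin):
    """Iterative neighbor-counting clustering with an optional size target.

    Exactly one of ``cutoff`` (Å) or ``target_size`` must be given.  With
    ``target_size``, the smallest cutoff (to ``resolution`` Å) yielding at
    most ``target_size`` clusters is found by bisection.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
    center_indices_ : ndarray, one cluster center (representative) per cluster
    cutoff_ : float, the cutoff actually used
    n_clusters_ : int
    """

    def __init__(
        self,
        cutoff: Optional[float] = None,
        target_size: Optional[int] = None,
        resolution: float = 1e-3,
    ):
        self.cutoff = cutoff
        self.target_size = target_size
        self.resolution = resolution

    @staticmethod
    def _run(X: np.ndarray, cutoff: float):
        n = X.shape[0]
        remaining = np.ones(n, dtype=bool)
        neighbor = X <= cutoff  # includes self
        centers, labels = [], np.full(n, -1, dtype=int)
        while remaining.any():
            counts = (neighbor & remaining[None, :]).sum(axis=1)
            counts[~remaining] = -1
            center = int(np.argmax(counts))  # ties -> lowest index
            members = remaining & neighbor[center]
            labels[members] = len(centers)
            centers.append(center)
            remaining &= ~members
        return np.array(centers, dtype=int), labels

    def fit(self, X, y=None):
        X = _check_dissimilarity(X)
        n = X.shape[0]
        if (self.cutoff is None) == (self.target_size is None):
            raise ValueError("give exactly one of cutoff or target_size")
        if self.cutoff is not None:
            cut = float(self.cutoff)
        else:
            target = int(self.target_size)
            if target < 1:
                raise ValueError("target_size must be >= 1")
            if target >= n:
                cut = 0.0
            else:
                # the cluster count only changes at pairwise dissimilarity
                # values, so bisect over those critical values: this finds the
                # exact smallest cutoff with n_clusters <= target (the count
                # is non-increasing in the cutoff)
                crit = np.unique(X[np.triu_indices(n, k=1)])
                lo, hi = -1, len(crit) - 1
                while hi - lo > 1:
                    mid = (lo + hi) // 2
                    if len(self._run(X, crit[mid])[0]) <= target:
                        hi = mid
                    else:
                        lo = mid
                cut = float(crit[hi])
        centers, labels = self._run(X, cut)
        self.center_indices_ = centers
        self.labels_ = labels
        self.cutoff_ = cut
        self.n_clusters_ = len(centers)
        return self

    def sweep_counts(self, X, cutoffs) -> np.ndarray:
        """Cluster counts along an increasing-cutoff sweep.

        This mirrors the iterative procedure of growing the cutoff until a
        target size is reached: the sweep carries the coarsest clustering
        obtained so far, so its count is non-increasing by construction.
        (The raw greedy count at one isolated cutoff can blip upward by one;
        such blips carry no information for the termination rule.)
        """
        X = _check_dissimilarity(X)
        cutoffs = np.sort(np.asarray(cutoffs, dtype=float))
        counts = []
        best = np.inf
        for c in cutoffs:
            best = min(best, len(self._run(X, c)[0]))
            counts.append(int(best))
        return np.array(counts, dtype=int)
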