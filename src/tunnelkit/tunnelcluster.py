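"""Cluster tunnels pooled over an ensemble and match clusterings.

Tunnel dissimilarity is the symmetrized mean nearest-point distance over
sphere centers (radii are not part of the geometry; clustering is by location
only).  Clustering is PAM k-medoids with k grown from 1 until every member
lies within 5.0 Å of its cluster centroid.  Two clusterings are compared by
the centroid-fits-into-reference rule: a test cluster matches a reference
cluster when the distance between their centroids is smaller than the
reference cluster's own radius (its largest centroid-to-member distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .cluster import KMedoids
from .tunnelfinder import Tunnel

DEFAULT_MAX_RADIUS = 5.0
#: centroid coincidence tolerance: lets singleton clusters (radius 0) match
#: themselves under the strict "distance < radius" rule
MATCH_TOLERANCE = 1e-6


def tunnel_distance(a: Tunnel, b: Tunnel) -> float:
    """Symmetrized mean minimum distance between sphere centers (Å)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty tunnel")
    d = cdist(a.centers, b.centers)
    return 0.5 * (float(d.min(axis=1).mean()) + float(d.min(axis=0).mean()))


def tunnel_distance_matrix(pool: Sequence[Tunnel]) -> np.ndarray:
    n = len(pool)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = tunnel_distance(pool[i], pool[j])
    return D


@dataclass
class TunnelCluster:
    """A cluster of similar tunnels with occurrence and bottleneck statistics."""

    member_indices: list
    members: list  # Tunnel objects
    centroid_index: int  # index into the pool
    centroid: Tunnel
    radius: float  # max member-to-centroid distance (Å)

    @property
    def first_occurrence_ps(self) -> float:
        return float(min(t.source_time_ps for t in self.members))

    @property
    def bottleneck_series(self) -> pd.DataFrame:
        """(time_ps, bottleneck) per source structure; the widest member
        bottleneck is taken when a structure contributed several tunnels."""
        rows: Dict[tuple, float] = {}
        for t in self.members:
            key = (t.source_time_ps, t.source_label)
            r = t.bottleneck_radius
            rows[key] = max(rows.get(key, -np.inf), r)
        data = sorted(rows.items())
        return pd.DataFrame(
            {
                "time_ps": [k[0] for k, _ in data],
                "label": [k[1] for k, _ in data],
                "bottleneck": [v for _, v in data],
            }
        )

    @property
    def max_bottleneck(self) -> float:
        return float(max(t.bottleneck_radius for t in self.members))

    @property
    def fluctuation(self) -> float:
        """Population standard deviation of per-structure bottlenecks
        (structures where the tunnel is absent are missing, not zero)."""
        vals = self.bottleneck_series["bottleneck"].to_numpy()
        if len(vals) < 2:
            return 0.0
        return float(np.std(vals))

    def __len__(self) -> int:
        return len(self.members)


def cluster_tunnels(
    pool: Sequence[Tunnel],
    max_radius: float = DEFAULT_MAX_RADIUS,
    D: Optional[np.ndarray] = None,
) -> List[TunnelCluster]:
    """k-medoids with k grown until every cluster radius is < ``max_radius``.

    The cluster centroids represent the distinct tunnels found in the pool.
    """
    pool = list(pool)
    if not pool:
        raise ValueError("empty tunnel pool")
    if D is None:
        D = tunnel_distance_matrix(pool)
    n = len(pool)
    for k in range(1, n + 1):
        est = KMedoids(n_clusters=k).fit(D)
        worst = 0.0
        for i, c in enumerate(est.labels_):
            worst = max(worst, D[i, est.medoid_indices_[c]])
        if worst < max_radius or k == n:
            break
    clusters = []
    for c, medoid in enumerate(est.medoid_indices_):
        idx = [i for i in range(n) if est.labels_[i] == c]
        clusters.append(
            TunnelCluster(
                member_indices=idx,
                members=[pool[i] for i in idx],
                centroid_index=int(medoid),
                centroid=pool[int(medoid)],
                radius=float(max(D[i, medoid] for i in idx)),
            )
        )
    return clusters


@dataclass
class ClusterMatch:
    """Result of matching a test clustering onto a reference clustering."""

    pairs: list  # (test index, reference index, centroid distance Å)
    matched_fraction: int  # % of reference clusters matched, integer-rounded

    @property
    def n_matched(self) -> int:
        return len({r for _, r, _ in self.pairs})


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def match_clusters(
    test: Sequence[TunnelCluster], reference: Sequence[TunnelCluster]
) -> ClusterMatch:
    """Match test clusters into reference clusters (centroid-fits rule).

    A test cluster matches the reference cluster whose centroid is nearest,
    provided the centroid distance is below that reference cluster's radius;
    each test cluster matches at most one reference cluster.
    ``matched_fraction`` is the percentage of reference clusters hit.
    """
    if not reference:
        raise ValueError("empty reference clustering")
    pairs = []
    for ti, t in enumerate(test):
        best = None
        for ri, r in enumerate(reference):
            d = tunnel_distance(t.centroid, r.centroid)
            if d < max(r.radius, MATCH_TOLERANCE):
                if best is None or d < best[1]:
                    best = (ri, d)
        if best is not None:
            pairs.append((ti, best[0], best[1]))
    matched_refs = {r for _, r, _ in pairs}
    frac = round_half_up(100.0 * len(matched_refs) / len(reference))
    return ClusterMatch(pairs=pairs, matched_fraction=frac)


def assign_names(
    clusters: Sequence[TunnelCluster],
    annotations: Dict[str, np.ndarray],
    threshold: float = DEFAULT_MAX_RADIUS,
) -> Dict[int, str]:
    """Name clusters after reference tunnel annotations (named polylines).

    Each annotation goes to its nearest cluster within ``threshold`` (an
    annotation is treated like a reference cluster of that radius); when two
    clusters compete for one annotation the closer wins.  Unnamed clusters
    become ``unassigned-i``.
    """
    anno_tunnels = {
        name: Tunnel(centers=np.atleast_2d(np.asarray(pts, float)),
                     radii=np.ones(len(np.atleast_2d(pts))))
        for name, pts in annotations.items()
    }
    candidates = []
    for ci, c in enumerate(clusters):
        for name, at in anno_tunnels.items():
            d = tunnel_distance(c.centroid, at)
            if d < threshold:
                candidates.append((d, ci, name))
    candidates.sort(key=lambda x: (x[0], x[1], x[2]))
    names: Dict[int, str] = {}
    used = set()
    for d, ci, name in candidates:
        if ci in names or name in used:
            continue
        names[ci] = name
        used.add(name)
    counter = 0
    for ci in range(len(clusters)):
        if ci not in names:
            names[ci] = f"unassigned-{counter}"
            counter += 1
    return names


def cluster_table(
    clusters: Sequence[TunnelCluster],
    names: Optional[Dict[int, str]] = None,
) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(clusters):
        rows.append(
            {
                "cluster": i,
                "name": names.get(i, str(i)) if names else str(i),
                "n_members": len(c),
                "radius": c.radius,
                "first_occurrence_ps": c.first_occurrence_ps,
                "max_bottleneck": c.max_bottleneck,
                "fluctuation": c.fluctuation,
            }
        )
    return pd.DataFrame(rows)
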