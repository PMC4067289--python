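"""Comparative statistics over clustered tunnels.

Covers the standard ensemble questions: how the cumulative number of distinct
tunnels grows with trajectory time, how each tunnel's bottleneck behaves over
time (preferred tunnels are typically wide with strongly fluctuating
bottlenecks; rare tunnels narrow and static), and how well a pseudo-apo or
pseudo-holo ensemble reproduces the tunnels of the corresponding true
ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .structures import Ensemble
from .tunnelcluster import TunnelCluster, match_clusters, round_half_up


@dataclass
class DiscoveryCurve:
    """Cumulative count of distinct tunnel clusters versus ensemble time."""

    points: pd.DataFrame  # columns: time_ps, cumulative
    crystal_count: int

    @property
    def total(self) -> int:
        return int(self.points["cumulative"].iloc[-1]) if len(self.points) else 0


def discovery_curve(clusters: Sequence[TunnelCluster], ensemble: Ensemble) -> DiscoveryCurve:
    """First-appearance cumulative curve over the ensemble's member times.

    Crystal/minimized sentinel times (-2/-1 ps) order before frame 0, matching
    their role as pre-trajectory structures.
    """
    times = sorted(set(float(m.time_ps) for m in ensemble))
    firsts = [c.first_occurrence_ps for c in clusters]
    rows = [
        {"time_ps": t, "cumulative": sum(1 for f in firsts if f <= t)} for t in times
    ]
    crystal_labels = {m.label for m in ensemble if m.source_tag == "crystal"}
    crystal_count = sum(
        1
        for c in clusters
        if any(t.source_label in crystal_labels for t in c.members)
    )
    return DiscoveryCurve(points=pd.DataFrame(rows), crystal_count=crystal_count)


def bottleneck_series(cluster: TunnelCluster, ensemble: Ensemble) -> pd.DataFrame:
    """One row per ensemble member: bottleneck radius or NaN when absent."""
    present = {
        (row.label, row.time_ps): row.bottleneck
        for row in cluster.bottleneck_series.itertuples()
    }
    rows = []
    for m in ensemble:
        rows.append(
            {
                "time_ps": m.time_ps,
                "label": m.label,
                "bottleneck": present.get((m.label, m.time_ps), np.nan),
            }
        )
    return pd.DataFrame(rows)


def occurrence_summary(
    clusters: Sequence[TunnelCluster],
    names: Optional[Dict[int, str]] = None,
) -> pd.DataFrame:
    """Per-cluster first occurrence, widest bottleneck and fluctuation."""
    rows = []
    for i, c in enumerate(clusters):
        rows.append(
            {
                "name": names.get(i, str(i)) if names else str(i),
                "first_occurrence_ps": c.first_occurrence_ps,
                "max_bottleneck": c.max_bottleneck,
                "fluctuation": c.fluctuation,
            }
        )
    return pd.DataFrame(rows)


def preferred_identification(
    clusters: Sequence[TunnelCluster],
    preferred_names: Set[str],
    names: Dict[int, str],
) -> int:
    """% of the preferred tunnel names present among cluster names."""
    if not preferred_names:
        raise ValueError("empty preferred-name set")
    found = set(names.values()) & set(preferred_names)
    return round_half_up(100.0 * len(found) / len(preferred_names))


@dataclass
class AccuracyReport:
    prediction_accuracy: int  # % of true-target clusters found by the pseudo run
    baseline_accuracy: int  # % found by the original, unaltered ensemble

    def __post_init__(self):
        for v in (self.prediction_accuracy, self.baseline_accuracy):
            if not 0 <= v <= 100:
                raise ValueError("percentages must lie in [0, 100]")


def pseudo_accuracy(
    pseudo: Sequence[TunnelCluster],
    true_target: Sequence[TunnelCluster],
    original: Sequence[TunnelCluster],
) -> AccuracyReport:
    """How well a pseudo-ensemble reproduces the true target ensemble.

    ``original`` is the unaltered ensemble the pseudo structure was built
    from; its overlap with the target is the baseline the pseudo run should
    beat (the effect of adding/removing the ligand alone).
    """
    pred = match_clusters(pseudo, true_target).matched_fraction
    base = match_clusters(original, true_target).matched_fraction
    return AccuracyReport(prediction_accuracy=pred, baseline_accuracy=base)
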