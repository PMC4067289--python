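"""Tunnel dissimilarity, tunnel clustering, cluster matching, naming."""

import numpy as np
import pytest

from tunnelkit.tunnelcluster import (
    assign_names,
    cluster_tunnels,
    match_clusters,
    tunnel_distance,
)
from tunnelkit.tunnelfinder import Tunnel


def polyline_tunnel(points, label="", time_ps=0.0, bottleneck=1.5):
    points = np.atleast_2d(np.asarray(points, float))
    return Tunnel(
        centers=points,
        radii=np.full(len(points), bottleneck),
        source_label=label,
        source_time_ps=time_ps,
    )


def straight_tunnel(direction, n=10, jitter=0.0, seed=0, **kw):
    rng = np.random.default_rng(seed)
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    pts = np.arange(n)[:, None] * u[None, :] + rng.normal(scale=jitter, size=(n, 3))
    return polyline_tunnel(pts, **kw)


class TestTunnelDistance:
    def test_identical_is_zero(self):
        t = straight_tunnel((1, 0, 0))
        assert tunnel_distance(t, t) == 0.0

    def test_single_sphere_separation(self):
        a = polyline_tunnel([(0, 0, 0)])
        b = polyline_tunnel([(3, 0, 0)])
        assert tunnel_distance(a, b) == 3.0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = polyline_tunnel(rng.normal(size=(10, 3)) * 4)
        b = polyline_tunnel(rng.normal(size=(10, 3)) * 4 + 2)
        ours = tunnel_distance(a, b)
        mins_ab = [
            min(np.linalg.norm(p - q) for q in b.centers) for p in a.centers
        ]
        mins_ba = [
            min(np.linalg.norm(q - p) for p in a.centers) for q in b.centers
        ]
        oracle = 0.5 * (np.mean(mins_ab) + np.mean(mins_ba))
        assert np.isclose(ours, oracle, atol=1e-12)

    def test_symmetric_nonnegative(self):
        a = straight_tunnel((1, 0, 0), seed=1)
        b = straight_tunnel((0, 1, 0), seed=2)
        assert tunnel_distance(a, b) == tunnel_distance(b, a) >= 0.0


class TestClusterTunnels:
    def test_single_tunnel_single_cluster(self):
        clusters = cluster_tunnels([straight_tunnel((1, 0, 0))])
        assert len(clusters) == 1
        assert clusters[0].radius == 0.0

    def test_duplicate_pair_plus_distant_tunnel(self):
        a1 = straight_tunnel((1, 0, 0), label="s0")
        a2 = straight_tunnel((1, 0, 0), label="s1")
        b = polyline_tunnel(np.arange(10)[:, None] * [1, 0, 0] + [0, 20, 0], label="s2")
        clusters = cluster_tunnels([a1, b, a2])
        assert len(clusters) == 2
        sizes = sorted(len(c) for c in clusters)
        assert sizes == [1, 2]

    def test_tight_pool_stays_one_cluster(self):
        pool = [straight_tunnel((1, 0, 0), jitter=0.3, seed=s) for s in range(5)]
        clusters = cluster_tunnels(pool)
        assert len(clusters) == 1

    def test_every_cluster_satisfies_radius_contract(self, gated_run):
        for c in gated_run["clusters"]:
            assert c.radius < 5.0

    def test_k_well_separated_groups_recovered(self):
        directions = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (-1, 0, 0)]
        pool = []
        for d in directions:
            for s in range(3):
                pool.append(straight_tunnel(d, n=20, jitter=0.4, seed=s))
        clusters = cluster_tunnels(pool)
        assert len(clusters) == len(directions)

    def test_boundary_tunnels_can_change_count_but_not_contract(self):
        """Tunnels between two groups may merge or split clusters; the 5 Å
        radius contract always survives."""
        base = [
            straight_tunnel((1, 0, 0), n=20),
            polyline_tunnel(np.arange(20)[:, None] * [1, 0, 0] + [0, 8, 0]),
        ]
        n_before = len(cluster_tunnels(base))
        bridge = polyline_tunnel(np.arange(20)[:, None] * [1, 0, 0] + [0, 4, 0])
        after = cluster_tunnels(base + [bridge])
        for c in after:
            assert c.radius < 5.0
        assert len(after) >= 1  # the count itself is allowed to move


class TestMatchClusters:
    def test_self_match_is_complete(self, basic_run):
        clusters = basic_run["clusters"]
        match = match_clusters(clusters, clusters)
        assert match.matched_fraction == 100

    def test_distant_clusterings_do_not_match(self):
        ref = cluster_tunnels([straight_tunnel((1, 0, 0), jitter=0.3, seed=s) for s in range(3)])
        test = cluster_tunnels(
            [polyline_tunnel(np.arange(10)[:, None] * [1, 0, 0] + [0, 30, 0])]
        )
        assert match_clusters(test, ref).matched_fraction == 0

    def test_five_of_six_rounds_to_83(self):
        refs, tests = [], []
        for k in range(6):
            offset = np.array([0.0, 15.0 * k, 0.0])
            members = [
                polyline_tunnel(
                    np.arange(10)[:, None] * [1, 0, 0] + offset + [0, dy, 0],
                    label=f"r{k}{dy}",
                )
                for dy in (-1.0, 0.0, 1.0)
            ]
            refs.extend(members)
            if k < 5:  # the test clustering misses the last reference group
                tests.append(members[1])
        ref_clusters = cluster_tunnels(refs)
        test_clusters = cluster_tunnels(tests)
        match = match_clusters(test_clusters, ref_clusters)
        assert len(ref_clusters) == 6
        assert match.matched_fraction == 83

    def test_each_test_cluster_matches_at_most_one_reference(self, basic_run):
        clusters = basic_run["clusters"]
        match = match_clusters(clusters, clusters)
        test_ids = [t for t, _, _ in match.pairs]
        assert len(test_ids) == len(set(test_ids))

    def test_empty_reference_rejected(self, basic_run):
        with pytest.raises(ValueError):
            match_clusters(basic_run["clusters"], [])


class TestAssignNames:
    def test_centroid_on_annotation_axis_gets_name(self):
        clusters = cluster_tunnels([straight_tunnel((1, 0, 0), n=12)])
        names = assign_names(
            clusters, {"east": np.arange(12)[:, None] * [1, 0, 0]}
        )
        assert names[0] == "east"

    def test_far_cluster_unassigned(self):
        clusters = cluster_tunnels(
            [polyline_tunnel(np.arange(10)[:, None] * [1, 0, 0] + [0, 25, 0])]
        )
        names = assign_names(clusters, {"east": np.arange(10)[:, None] * [1, 0, 0]})
        assert names[0].startswith("unassigned")

    def test_nearest_cluster_wins_competition(self):
        near = cluster_tunnels([straight_tunnel((1, 0, 0), n=10)])[0]
        shifted = cluster_tunnels(
            [polyline_tunnel(np.arange(10)[:, None] * [1, 0, 0] + [0, 3, 0])]
        )[0]
        names = assign_names(
            [shifted, near], {"east": np.arange(10)[:, None] * [1, 0, 0]}
        )
        assert names[1] == "east"
        assert names[0].startswith("unassigned")
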