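"""Grid construction, start placement, Dijkstra paths, tunnel extraction."""

import numpy as np
import pytest

from tunnelkit.synth import SyntheticSystem, ChannelSpec, generate_system
from tunnelkit.tunnelfinder import (
    GridField,
    NoStartPointError,
    Tunnel,
    build_grid,
    clearance_to_surface,
    cumulative_costs,
    find_tunnels,
    place_start,
    tunnel_profile,
    tunnels_for_structure,
    _shell_offsets,
)

from conftest import ORIGIN_START, build_structure


class TestClearance:
    def test_single_atom_arithmetic(self):
        cl = clearance_to_surface(
            np.array([[5.0, 0, 0]]), np.zeros((1, 3)), np.array([1.7])
        )
        assert np.isclose(cl[0], 3.3)

    def test_inside_atom_negative(self):
        cl = clearance_to_surface(
            np.array([[0.5, 0, 0]]), np.zeros((1, 3)), np.array([1.7])
        )
        assert cl[0] < 0

    def test_matches_brute_force_on_random_nodes(self):
        rng = np.random.default_rng(0)
        centers = rng.normal(size=(200, 3)) * 8
        radii = rng.uniform(1.4, 1.8, size=200)
        pts = rng.normal(size=(500, 3)) * 10
        ours = clearance_to_surface(pts, centers, radii)
        brute = np.array(
            [np.min(np.linalg.norm(centers - p, axis=1) - radii) for p in pts]
        )
        assert np.max(np.abs(ours - brute)) < 1e-9


class TestGrid:
    def test_invalid_spacing_rejected(self):
        s = build_structure(np.eye(3) * 3)
        with pytest.raises(ValueError):
            build_grid(s, spacing=0.0)

    def test_node_inside_atom_is_protein(self):
        s = build_structure([(0.0, 0.0, 0.0)])
        g = build_grid(s, spacing=1.0, padding=4.0)
        passable, bulk, interior = g.classify(0.75)
        assert not passable[g.nearest_node((0, 0, 0))]

    def test_covers_bounding_box_plus_padding(self):
        s = build_structure([(0, 0, 0), (10, 0, 0)])
        g = build_grid(s, spacing=0.8, padding=6.0)
        assert g.origin[0] <= -6.0
        hi = g.origin + g.spacing * (np.array(g.dims) - 1)
        assert hi[0] >= 16.0 - 0.8


class TestPlaceStart:
    def test_clear_point_unchanged(self):
        s = build_structure([(0.0, 0.0, 0.0)])
        sp = place_start(s, (5.0, 0.0, 0.0))
        assert np.allclose(sp.effective, (5, 0, 0))
        assert sp.adjustments == []

    def test_shell_order_axes_first(self):
        offs = _shell_offsets(1)
        assert offs[:6] == [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        assert len(offs) == 26

    def test_buried_point_adjusted_along_plus_x(self):
        # a wall of atoms blocks every direction except +x
        wall = []
        for y in range(-3, 4):
            for z in range(-3, 4):
                for x in (-1, 0):
                    if not (x == 0 and y == 0 and z == 0):
                        wall.append((x * 2.0, y * 2.0, z * 2.0))
        s = build_structure(wall)
        # requested sits between wall atoms; +1 Å in x is the first clear offset
        sp = place_start(s, (0.0, 0.0, 0.0), probe_radius=0.75)
        assert sp.adjustments[-1] == tuple(np.rint(sp.effective - (0, 0, 0)).astype(int))
        assert clearance_to_surface(
            sp.effective[None, :], s.coords, s.vdw_radii
        )[0] >= 0.75

    def test_fully_occluded_errors(self):
        # dense cage: no clear point within the shell cap
        pts = []
        for x in np.arange(-7, 8, 1.5):
            for y in np.arange(-7, 8, 1.5):
                for z in np.arange(-7, 8, 1.5):
                    pts.append((x, y, z))
        s = build_structure(pts)
        with pytest.raises(NoStartPointError):
            place_start(s, (0.0, 0.0, 0.0))


class TestDijkstra:
    def test_costs_match_exhaustive_path_enumeration(self):
        """Cumulative Dijkstra costs equal brute-force minimization over all
        simple paths on a tiny hand-set grid."""
        rng = np.random.default_rng(3)
        clearance = np.full((3, 3, 3), -1.0)
        # a passable L-shaped corridor with varied clearances
        corridor = [
            (0, 0, 0), (1, 0, 0), (2, 0, 0), (2, 1, 0), (2, 2, 0),
            (1, 2, 0), (1, 1, 0), (2, 2, 1), (2, 2, 2),
        ]
        for node in corridor:
            clearance[node] = rng.uniform(0.8, 3.0)
        g = GridField(
            origin=np.zeros(3), spacing=0.8, dims=(3, 3, 3), clearance=clearance
        )
        alpha = 1.0
        dist = cumulative_costs(g, (0, 0, 0), probe_radius=0.75, alpha=alpha)

        # oracle: recursive enumeration of all simple paths
        nodes = set(corridor)
        cost = {n: np.exp(-alpha * clearance[n]) for n in nodes}

        def neighbors(n):
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        if (dx, dy, dz) == (0, 0, 0):
                            continue
                        m = (n[0] + dx, n[1] + dy, n[2] + dz)
                        if m in nodes:
                            yield m, 0.8 * np.sqrt(dx * dx + dy * dy + dz * dz)

        best = {n: np.inf for n in nodes}
        best[(0, 0, 0)] = 0.0

        def dfs(n, acc, visited):
            for m, step in neighbors(n):
                if m in visited:
                    continue
                w = acc + step * 0.5 * (cost[n] + cost[m])
                if w < best[m]:
                    best[m] = w
                dfs(m, w, visited | {m})

        dfs((0, 0, 0), 0.0, {(0, 0, 0)})
        for n in nodes:
            assert np.isclose(dist[n], best[n], atol=1e-12), n


def single_channel_structure(gate_radius=2.0, seed=0):
    spec = SyntheticSystem(
        channels=[
            ChannelSpec("only", (1.0, 0, 0), base_radius=gate_radius + 0.6,
                        gate_open_radius=gate_radius)
        ],
        jitter_sigma=0.0,
        n_frames=1,
        seed=seed,
    )
    bundle, truth = generate_system(spec, check=False)
    return bundle["trajectory"][0], truth


class TestFindTunnels:
    def test_single_drilled_channel_recovered(self):
        s, truth = single_channel_structure(2.0)
        tunnels = tunnels_for_structure(s, ORIGIN_START)
        assert len(tunnels) == 1
        assert abs(tunnels[0].bottleneck_radius - 2.0) <= 0.8  # grid spacing

    def test_gate_below_probe_finds_nothing(self):
        s, _ = single_channel_structure(0.5)
        assert tunnels_for_structure(s, ORIGIN_START) == []

    def test_bottlenecks_at_least_probe(self, basic_run):
        for t in basic_run["pool"]:
            assert t.bottleneck_radius >= 0.75

    def test_raising_probe_never_increases_count(self, basic_bundle):
        s = basic_bundle["apo"]["trajectory"][0]
        n_low = len(tunnels_for_structure(s, ORIGIN_START, probe_radius=0.75))
        n_high = len(tunnels_for_structure(s, ORIGIN_START, probe_radius=1.25))
        assert n_high <= n_low

    def test_overshadow_count_at_most_raw(self, basic_bundle):
        s = basic_bundle["apo"]["trajectory"][0]
        raw = tunnels_for_structure(s, ORIGIN_START, mode="raw")
        merged = tunnels_for_structure(s, ORIGIN_START, mode="overshadow")
        assert len(merged) <= len(raw)

    def test_ranked_by_cost_wider_first(self, basic_bundle):
        s = basic_bundle["apo"]["trajectory"][0]
        tunnels = tunnels_for_structure(s, ORIGIN_START)
        costs = [t.cost for t in tunnels]
        assert costs == sorted(costs)
        # the widest drilled channel is rank 1 here (equal lengths by design)
        assert tunnels[0].bottleneck_radius == max(t.bottleneck_radius for t in tunnels)

    def test_rigid_motion_leaves_bottlenecks_unchanged(self):
        from scipy.spatial.transform import Rotation

        s, _ = single_channel_structure(2.0)
        before = tunnels_for_structure(s, ORIGIN_START)
        R = Rotation.from_euler("xyz", [0.3, 0.6, -0.2]).as_matrix()
        t = np.array([3.0, -2.0, 1.0])
        moved = s.transformed(R, t)
        after = tunnels_for_structure(moved, R @ np.zeros(3) + t)
        assert len(before) == len(after) == 1
        assert abs(before[0].bottleneck_radius - after[0].bottleneck_radius) <= 0.8


class TestTunnelProfile:
    def test_straight_tunnel_arc_lengths(self):
        centers = np.column_stack([np.arange(5) * 0.8, np.zeros(5), np.zeros(5)])
        t = Tunnel(centers=centers, radii=np.full(5, 1.5))
        prof = tunnel_profile(t)
        assert np.allclose(prof["arc_length"], [0.0, 0.8, 1.6, 2.4, 3.2])

    def test_profile_minimum_is_bottleneck(self, basic_run):
        t = basic_run["pool"][0]
        prof = tunnel_profile(t)
        assert np.isclose(prof["radius"].min(), t.bottleneck_radius)

    def test_tapered_channel_profile_decreases(self):
        n = 8
        centers = np.column_stack([np.arange(n) * 0.8, np.zeros(n), np.zeros(n)])
        radii = np.linspace(3.0, 1.0, n)
        prof = tunnel_profile(Tunnel(centers=centers, radii=radii))
        assert np.all(np.diff(prof["radius"]) < 0)
        assert np.isclose(prof["radius"].iloc[-1], 1.0)

    def test_single_sphere_profile(self):
        t = Tunnel(centers=np.zeros((1, 3)), radii=np.array([2.0]))
        prof = tunnel_profile(t)
        assert len(prof) == 1 and prof["arc_length"].iloc[0] == 0.0
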