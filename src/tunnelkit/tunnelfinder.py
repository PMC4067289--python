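"""Geometric tunnel prediction in a single structure.

The protein interior is discretized on a regular grid; each node carries its
*clearance*, the distance to the nearest atom's van der Waals surface
(negative inside an atom).  Nodes with clearance below the probe radius are
impassable; nodes with large clearance connected to the box boundary are bulk
solvent.  Each node is assigned a cost ``exp(-alpha * clearance)`` so that
narrow passages are expensive, and lowest-total-cost paths from a buried start
point to every bulk exit patch are found with Dijkstra over the 26-neighbor
grid graph.  A path's sphere profile records the clearance along it; the
minimum is the tunnel bottleneck.

Two reporting modes mirror the behavioral contrast between unclustered
(Caver-like, ``raw``) and exit-merged (MolAxis-like, ``overshadow``)
reporting: overshadow merges tunnels whose exits lie within 6 Å and keeps only
the widest-bottleneck one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra as _dijkstra
from scipy.spatial import cKDTree

from .structures import Structure

DEFAULT_PROBE_RADIUS = 0.75
DEFAULT_SPACING = 0.8
DEFAULT_PADDING = 6.0
DEFAULT_BULK_CLEARANCE = 3.0
DEFAULT_ALPHA = 1.0
EXIT_MERGE_DISTANCE = 6.0
#: loop-back filter: after first coming within one cell of bulk, a tunnel with
#: this many further interior nodes is truncated there; short stubs are dropped
LOOPBACK_OVERHANG = 5
MIN_SPHERES = 3

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class NoStartPointError(RuntimeError):
    pass


def clearance_to_surface(points: np.ndarray, centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """min over atoms of (|p - center| - vdw_radius), exactly.

    Uses a k-nearest query plus a guaranteed-correct widening fallback for the
    rare nodes where an atom beyond the k-th neighbor could still be closer in
    surface distance.
    """
    points = np.atleast_2d(np.asarray(points, float))
    centers = np.asarray(centers, float)
    radii = np.asarray(radii, float)
    n_atoms = len(centers)
    if n_atoms == 0:
        raise ValueError("no atoms")
    if n_atoms <= 16:
        d = np.linalg.norm(points[:, None, :] - centers[None, :, :], axis=2)
        return (d - radii[None, :]).min(axis=1)
    tree = cKDTree(centers)
    k = 8
    d, idx = tree.query(points, k=k, workers=-1)
    cl = (d - radii[idx]).min(axis=1)
    rmax = float(radii.max())
    # exact unless a farther atom could beat the current minimum
    suspect = np.flatnonzero(cl > d[:, -1] - rmax)
    for i in suspect:
        js = tree.query_ball_point(points[i], cl[i] + rmax + 1e-9)
        dd = np.linalg.norm(centers[js] - points[i], axis=1) - radii[js]
        cl[i] = dd.min()
    return cl


@dataclass
class GridField:
    """Regular grid with per-node clearance and node classification."""

    origin: np.ndarray  # (3,)
    spacing: float
    dims: tuple  # (nx, ny, nz)
    clearance: np.ndarray  # shape dims
    probe_radius: float = DEFAULT_PROBE_RADIUS
    bulk_clearance: float = DEFAULT_BULK_CLEARANCE
    #: nodes outside the structure's convex hull (None: fall back to a purely
    #: clearance-based bulk definition)
    outside_hull: Optional[np.ndarray] = None

    def node_coords(self, index3) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(index3, float)

    def nearest_node(self, point) -> tuple:
        idx = np.rint((np.asarray(point, float) - self.origin) / self.spacing).astype(int)
        idx = np.clip(idx, 0, np.array(self.dims) - 1)
        return tuple(idx)

    def classify(self, probe_radius: Optional[float] = None):
        """Return (passable, bulk, interior_void) boolean grids.

        protein: clearance < probe.  bulk: passable space outside the
        structure's convex hull, together with wide regions
        (clearance >= bulk_clearance) 26-connected to it or to the grid
        boundary.  interior_void: the passable remainder (cavity and channel
        interiors).
        """
        probe = self.probe_radius if probe_radius is None else probe_radius
        passable = self.clearance >= probe
        wide = self.clearance >= self.bulk_clearance
        seed = wide if self.outside_hull is None else (
            wide | (self.outside_hull & passable)
        )
        labels, _ = ndimage.label(seed, structure=_STRUCT26)
        bulk_labels = set()
        for axis in range(3):
            for sl in (0, -1):
                face = np.take(labels, sl, axis=axis)
                bulk_labels.update(np.unique(face[face > 0]).tolist())
        if self.outside_hull is not None:
            out = labels[self.outside_hull & passable]
            bulk_labels.update(np.unique(out[out > 0]).tolist())
        bulk = np.isin(labels, sorted(bulk_labels)) & seed & passable
        interior = passable & ~bulk
        return passable, bulk, interior

    @property
    def node_class(self) -> np.ndarray:
        """Per-node class at the defaults: 0=protein, 1=interior_void, 2=bulk."""
        passable, bulk, interior = self.classify()
        out = np.zeros(self.dims, dtype=np.int8)
        out[interior] = 1
        out[bulk] = 2
        return out


@dataclass
class StartPoint:
    requested: np.ndarray
    effective: np.ndarray
    adjustments: list = field(default_factory=list)


@dataclass
class Tunnel:
    """Ordered sphere list from the start point to a surface exit."""

    centers: np.ndarray  # (n, 3)
    radii: np.ndarray  # (n,)
    source_label: str = ""
    source_time_ps: float = 0.0
    cost: float = 0.0

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, float))
        self.radii = np.atleast_1d(np.asarray(self.radii, float))
        if len(self.centers) != len(self.radii):
            raise ValueError("centers and radii must have the same length")
        if len(self.centers) == 0:
            raise ValueError("empty tunnel")

    def __len__(self) -> int:
        return len(self.radii)

    @property
    def bottleneck_index(self) -> int:
        return int(np.argmin(self.radii))

    @property
    def bottleneck_radius(self) -> float:
        return float(self.radii.min())

    @property
    def length(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.centers, axis=0), axis=1).sum())

    @property
    def exit_point(self) -> np.ndarray:
        return self.centers[-1]

    def transformed(self, rotation, translation) -> "Tunnel":
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return Tunnel(self.centers @ R.T + t, self.radii.copy(),
                      self.source_label, self.source_time_ps, self.cost)


def tunnel_profile(t: Tunnel):
    """Table of (arc_length Å, radius Å) along the tunnel."""
    import pandas as pd

    if len(t) < 2:
        arc = np.zeros(len(t))
    else:
        steps = np.linalg.norm(np.diff(t.centers, axis=0), axis=1)
        arc = np.concatenate(([0.0], np.cumsum(steps)))
    return pd.DataFrame({"arc_length": arc, "radius": t.radii})


def build_grid(
    s: Structure,
    spacing: float = DEFAULT_SPACING,
    padding: float = DEFAULT_PADDING,
    bulk_clearance: float = DEFAULT_BULK_CLEARANCE,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
) -> GridField:
    """Axis-aligned clearance grid over the structure's bounding box + padding.

    The structure is expected to be already stripped of hydrogens, solvent and
    ions (see :meth:`Structure.prepared_for_tunnels`).
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    coords = s.coords
    radii = s.vdw_radii
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    dims = tuple(int(np.floor((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    ax = [lo[i] + spacing * np.arange(dims[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack((X.ravel(), Y.ravel(), Z.ravel()))
    cl = clearance_to_surface(pts, coords, radii).reshape(dims)
    outside = _outside_hull_mask(pts, coords).reshape(dims)
    return GridField(
        origin=lo,
        spacing=spacing,
        dims=dims,
        clearance=cl,
        probe_radius=probe_radius,
        bulk_clearance=bulk_clearance,
        outside_hull=outside,
    )


def _outside_hull_mask(points: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Nodes strictly outside the convex hull of the atom centers."""
    from scipy.spatial import ConvexHull

    try:
        hull = ConvexHull(coords)
    except Exception:  # degenerate (planar/collinear) atom sets
        return np.zeros(len(points), dtype=bool)
    A = hull.equations[:, :3]
    b = hull.equations[:, 3]
    outside = np.zeros(len(points), dtype=bool)
    chunk = 65536
    for i in range(0, len(points), chunk):
        p = points[i : i + chunk]
        outside[i : i + chunk] = ((p @ A.T) + b > 1e-9).any(axis=1)
    return outside


def _shell_offsets(radius: int):
    """Integer-Å offsets on the L-infinity shell, axes first then lexicographic."""
    r = radius
    axes = [(r, 0, 0), (-r, 0, 0), (0, r, 0), (0, -r, 0), (0, 0, r), (0, 0, -r)]
    rest = []
    rng = range(-r, r + 1)
    for dx in rng:
        for dy in rng:
            for dz in rng:
                off = (dx, dy, dz)
                if max(abs(dx), abs(dy), abs(dz)) == r and off not in axes:
                    rest.append(off)
    return axes + rest


def place_start(
    s: Structure,
    requested,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    max_shell: int = 5,
) -> StartPoint:
    """Adjust the requested start point until it has probe-sized clearance.

    Offsets are tried on integer-Å L-infinity shells of growing radius
    (axis directions first, then lexicographic), as re-running a tunnel
    program with +/- 1 Å nudges would.
    """
    requested = np.asarray(requested, float)
    coords, radii = s.coords, s.vdw_radii
    tried = []

    def ok(p):
        return clearance_to_surface(p[None, :], coords, radii)[0] >= probe_radius

    if ok(requested):
        return StartPoint(requested, requested.copy(), [])
    for r in range(1, max_shell + 1):
        for off in _shell_offsets(r):
            tried.append(off)
            p = requested + np.asarray(off, float)
            if ok(p):
                return StartPoint(requested, p, tried)
    raise NoStartPointError(
        f"no point with clearance >= {probe_radius} Å within {max_shell} Å of "
        f"{np.round(requested, 2).tolist()}"
    )


def heme_start_point(s: Structure, offset: float = 3.0) -> np.ndarray:
    """Start point 3 Å above the ligand-binding face of the heme.

    Computed as Fe + offset * unit(Fe - S) with Fe the heme iron and S the
    nearest cysteine SG (the proximal thiolate).
    """
    fe = next(
        (a for a in s.atoms if a.residue_name == "HEM" and a.element.upper() == "FE"),
        None,
    )
    if fe is None:
        raise ValueError("no heme iron found")
    sgs = [a for a in s.atoms if a.name.strip() == "SG" and a.residue_name == "CYS"]
    if not sgs:
        raise ValueError("no cysteine SG found")
    sg = min(sgs, key=lambda a: np.linalg.norm(a.coord - fe.coord))
    u = fe.coord - sg.coord
    u = u / np.linalg.norm(u)
    return fe.coord + offset * u


_NEIGHBOR_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]  # 13 unique half-offsets; symmetry gives the full 26-neighborhood


def find_tunnels(
    g: GridField,
    start: StartPoint,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "raw",
    source_label: str = "",
    source_time_ps: float = 0.0,
) -> List[Tunnel]:
    """Lowest-cost tunnels from the start point to every bulk exit patch.

    Node cost is ``exp(-alpha * clearance)``; edge weight is the step length
    times the mean of the endpoint costs.  One tunnel per exit patch in
    ``raw`` mode; ``overshadow`` merges exits within 6 Å keeping the
    widest-bottleneck tunnel.  Tunnels that loop back along the surface are
    truncated at their first bulk contact and dropped if fewer than 3 spheres
    remain.
    """
    if mode not in ("raw", "overshadow"):
        raise ValueError(f"unknown mode {mode!r}")
    passable, bulk, interior = g.classify(probe_radius)
    dims = g.dims
    n = int(np.prod(dims))

    start_idx = g.nearest_node(start.effective)
    if not passable[start_idx]:
        return []
    start_flat = int(np.ravel_multi_index(start_idx, dims))

    cost = np.exp(-alpha * g.clearance)
    cost_flat = cost.ravel()

    # Dijkstra runs over interior void only; bulk nodes terminate tunnels.
    # (Routing through bulk would let one channel's path re-enter another
    # mouth from the outside.)
    graphable = interior.copy()
    graphable[start_idx] = passable[start_idx]
    flat_index = np.arange(n).reshape(dims)
    rows, cols, weights = [], [], []
    for off in _NEIGHBOR_OFFSETS:
        sl_a = tuple(slice(max(0, -o), dims[i] - max(0, o)) for i, o in enumerate(off))
        sl_b = tuple(slice(max(0, o), dims[i] + min(0, o)) for i, o in enumerate(off))
        ok = graphable[sl_a] & graphable[sl_b]
        if not ok.any():
            continue
        ia = flat_index[sl_a][ok]
        ib = flat_index[sl_b][ok]
        step = g.spacing * float(np.linalg.norm(off))
        w = step * 0.5 * (cost_flat[ia] + cost_flat[ib])
        rows.append(ia)
        cols.append(ib)
        weights.append(w)
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        weights = np.concatenate(weights)
        graph = sparse.csr_matrix((weights, (rows, cols)), shape=(n, n))
    else:
        graph = sparse.csr_matrix((n, n))

    dist, pred = _dijkstra(
        graph, directed=False, indices=start_flat, return_predecessors=True
    )

    reachable = np.isfinite(dist)
    reached_interior = reachable.reshape(dims) & graphable

    # exit patches: connected components of the bulk nodes adjacent to
    # reachable interior void (the channel mouths) -- the bulk as a whole is
    # one component, the individual mouths are not
    exit_mask = bulk & ndimage.binary_dilation(reached_interior, structure=_STRUCT26)
    labels, n_patches = ndimage.label(exit_mask, structure=_STRUCT26)
    if n_patches == 0:
        return []
    near_bulk = ndimage.binary_dilation(bulk, structure=_STRUCT26)
    near_bulk_flat = near_bulk.ravel()
    bulk_flat = bulk.ravel()

    dist3 = dist.reshape(dims)
    tunnels = []
    for patch in range(1, n_patches + 1):
        patch_mask = labels == patch
        # interior nodes adjacent to this mouth; pick the lowest-cost one
        rim = ndimage.binary_dilation(patch_mask, structure=_STRUCT26) & reached_interior
        rim_nodes = np.flatnonzero(rim.ravel())
        if len(rim_nodes) == 0:
            continue
        mouth = int(rim_nodes[np.argmin(dist[rim_nodes])])
        # terminal bulk node: the widest patch node adjacent to the mouth, so
        # a narrow rim node does not masquerade as the bottleneck
        mouth3 = np.array(np.unravel_index(mouth, dims))
        patch_nodes3 = np.array(np.nonzero(patch_mask)).T
        steps = np.abs(patch_nodes3 - mouth3).max(axis=1)
        adjacent = patch_nodes3[steps == steps.min()]
        cl3 = g.clearance[tuple(adjacent.T)]
        end3 = adjacent[np.argmax(cl3)]
        end_flat = int(np.ravel_multi_index(tuple(end3), dims))

        path = [mouth]
        while path[-1] != start_flat:
            p = pred[path[-1]]
            if p < 0:
                break
            path.append(int(p))
        path.reverse()
        if path[0] != start_flat:
            continue
        path.append(end_flat)
        total_cost = float(
            dist[mouth]
            + g.spacing
            * np.linalg.norm(end3 - mouth3)
            * 0.5
            * (cost_flat[mouth] + cost_flat[end_flat])
        )
        # loop-back filter: a path that first grazes the surface and then
        # keeps wandering through the interior is truncated at that contact
        first_near = next((i for i, f in enumerate(path) if near_bulk_flat[f]), None)
        if first_near is not None:
            overhang = sum(1 for f in path[first_near + 1 :] if not bulk_flat[f])
            if overhang >= LOOPBACK_OVERHANG:
                path = path[: first_near + 1]
        if len(path) < MIN_SPHERES:
            continue
        idx3 = np.array(np.unravel_index(path, dims)).T
        centers = g.origin + g.spacing * idx3.astype(float)
        radii = g.clearance.ravel()[path]
        tunnels.append(
            Tunnel(
                centers=centers,
                radii=radii,
                source_label=source_label,
                source_time_ps=source_time_ps,
                cost=total_cost,
            )
        )

    tunnels.sort(key=lambda t: t.cost)

    if mode == "overshadow" and len(tunnels) > 1:
        tunnels = _overshadow(tunnels)
        tunnels.sort(key=lambda t: t.cost)
    return tunnels


def cumulative_costs(
    g: GridField,
    start_index3,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    alpha: float = DEFAULT_ALPHA,
    restrict_to_interior: bool = False,
) -> np.ndarray:
    """Dijkstra cumulative cost from a start node to every passable node.

    Exposed for verification: on tiny grids the values can be compared against
    exhaustive enumeration of simple paths.
    """
    passable, bulk, interior = g.classify(probe_radius)
    mask = interior if restrict_to_interior else passable
    mask = mask.copy()
    mask[tuple(start_index3)] |= passable[tuple(start_index3)]
    dims = g.dims
    n = int(np.prod(dims))
    cost_flat = np.exp(-alpha * g.clearance).ravel()
    flat_index = np.arange(n).reshape(dims)
    rows, cols, weights = [], [], []
    for off in _NEIGHBOR_OFFSETS:
        sl_a = tuple(slice(max(0, -o), dims[i] - max(0, o)) for i, o in enumerate(off))
        sl_b = tuple(slice(max(0, o), dims[i] + min(0, o)) for i, o in enumerate(off))
        ok = mask[sl_a] & mask[sl_b]
        if not ok.any():
            continue
        ia = flat_index[sl_a][ok]
        ib = flat_index[sl_b][ok]
        step = g.spacing * float(np.linalg.norm(off))
        rows.append(ia)
        cols.append(ib)
        weights.append(step * 0.5 * (cost_flat[ia] + cost_flat[ib]))
    if rows:
        graph = sparse.csr_matrix(
            (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
    else:
        graph = sparse.csr_matrix((n, n))
    start_flat = int(np.ravel_multi_index(tuple(start_index3), dims))
    return _dijkstra(graph, directed=False, indices=start_flat).reshape(dims)


def _overshadow(tunnels: List[Tunnel]) -> List[Tunnel]:
    """Merge tunnels with exits within 6 Å; keep the widest bottleneck of each
    merged group."""
    exits = np.array([t.exit_point for t in tunnels])
    m = len(tunnels)
    d = np.linalg.norm(exits[:, None, :] - exits[None, :, :], axis=2)
    adj = sparse.csr_matrix(d <= EXIT_MERGE_DISTANCE)
    n_comp, comp = sparse.csgraph.connected_components(adj, directed=False)
    keep = []
    for c in range(n_comp):
        group = [tunnels[i] for i in range(m) if comp[i] == c]
        keep.append(max(group, key=lambda t: t.bottleneck_radius))
    return keep


def tunnels_for_structure(
    s: Structure,
    requested_start,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    spacing: float = DEFAULT_SPACING,
    padding: float = DEFAULT_PADDING,
    bulk_clearance: float = DEFAULT_BULK_CLEARANCE,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "raw",
    keep_ligand: bool = False,
) -> List[Tunnel]:
    """Prepare the structure, build the grid, place the start, find tunnels."""
    prepared = s.prepared_for_tunnels(keep_ligand=keep_ligand)
    grid = build_grid(
        prepared,
        spacing=spacing,
        padding=padding,
        bulk_clearance=bulk_clearance,
        probe_radius=probe_radius,
    )
    try:
        start = place_start(prepared, requested_start, probe_radius)
    except NoStartPointError:
        return []
    return find_tunnels(
        grid,
        start,
        probe_radius=probe_radius,
        alpha=alpha,
        mode=mode,
        source_label=s.label,
        source_time_ps=s.time_ps,
    )
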