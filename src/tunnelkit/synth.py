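"""Synthetic gated-channel systems with known ground truth.

The generator emulates, in pure geometry, the features of a buried-cavity
enzyme that ensemble tunnel prediction depends on: a central cavity enclosed
by a pseudo-atom shell, several channels of distinct direction and radius,
per-frame gate fluctuations that open and close channel bottlenecks on a
schedule, an apo/holo contrast where a cavity ligand pins gate geometry, and
the contrast between wide, strongly fluctuating "preferred" channels and
narrow static "rare" ones.

Each channel is a carved cylinder sealed by a gate: an annular disc of atoms
in a plane across the channel whose inner aperture radius follows
``gate_closed + openness(t) * (gate_open - gate_closed)``.  The theoretical
bottleneck of an open channel is its aperture radius, which is what a grid
tunnel finder should recover to within grid spacing.

All randomness is seeded; generation is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from .structures import Atom, Ensemble, Structure, CRYSTAL_TIME_PS, MINIMIZED_TIME_PS

ATOM_VDW = 1.7
RING_DR = 2.2  # radial spacing of gate-disc rings (Å)
RING_CHORD = 2.0  # target circumferential spacing of gate atoms (Å)
CARVE_MARGIN = 0.3  # extra carve radius beyond base_radius + vdw (Å)


class ImpermeabilityError(RuntimeError):
    """The shell leaks at the requested lattice density."""


@dataclass
class ChannelSpec:
    """One channel: direction, width, and a gate schedule."""

    name: str
    axis: np.ndarray  # unit 3-vector
    base_radius: float  # carved channel radius (Å); should exceed gate_open
    gate_open_radius: float
    gate_closed_radius: float = 0.0
    gate_depth: float = 2.0  # gate plane distance from the cavity wall (Å)
    schedule: object = 1.0  # per-frame openness in [0,1], or a constant
    blocked_by_ligand: bool = False
    #: openness the gate is pinned to while the ligand is present
    ligand_pinned_openness: float = 0.0
    preferred: bool = False

    def __post_init__(self):
        self.axis = np.asarray(self.axis, float)
        self.axis = self.axis / np.linalg.norm(self.axis)
        if self.gate_closed_radius > self.gate_open_radius:
            raise ValueError("gate_closed_radius must be <= gate_open_radius")

    def openness(self, n_frames: int, state: str) -> np.ndarray:
        """Per-frame openness under a given state.

        apo follows the schedule; holo pins blocked gates to the
        ligand-conditioned openness; pseudo states start in the source state
        and relax to the target state from the second frame on.
        """
        sched = np.broadcast_to(np.asarray(self.schedule, float), (n_frames,)).copy()
        if not self.blocked_by_ligand:
            return sched
        pinned = np.full(n_frames, float(self.ligand_pinned_openness))
        if state == "apo":
            return sched
        if state == "holo":
            return pinned
        if state == "pseudo_apo":  # ligand removed from holo; gates relax
            out = sched.copy()
            out[0] = pinned[0]
            return out
        if state == "pseudo_holo":  # ligand grafted into apo; gates pinned
            out = pinned.copy()
            out[0] = sched[0]
            return out
        raise ValueError(f"unknown state {state!r}")

    def gate_radius(self, openness) -> np.ndarray:
        return self.gate_closed_radius + np.asarray(openness, float) * (
            self.gate_open_radius - self.gate_closed_radius
        )


@dataclass
class SyntheticSystem:
    """Shell + channels + optional ligand; the study conditions for a run."""

    channels: List[ChannelSpec] = field(default_factory=list)
    cavity_radius: float = 7.0  # innermost shell-atom radius (Å)
    outer_radius: float = 13.0
    lattice_spacing: float = 2.6  # nearest-neighbor shell spacing (Å)
    jitter_sigma: float = 0.05  # per-frame isotropic coordinate noise (Å)
    #: per-frame random-walk step (Å) of a cumulative per-atom drift,
    #: emulating slow conformational diffusion along a trajectory
    drift_sigma: float = 0.0
    n_frames: int = 10
    dt_ps: float = 100.0
    seed: int = 0
    with_ligand: bool = False  # filled per state by generate_system


@dataclass
class ChannelTruth:
    name: str
    axis: np.ndarray
    preferred: bool
    blocked_by_ligand: bool
    bottleneck_per_frame: np.ndarray  # theoretical gate radius per frame (Å)
    crystal_bottleneck: float

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "axis": self.axis.tolist(),
            "preferred": self.preferred,
            "blocked_by_ligand": self.blocked_by_ligand,
            "bottleneck_per_frame": self.bottleneck_per_frame.tolist(),
            "crystal_bottleneck": self.crystal_bottleneck,
        }


@dataclass
class GroundTruth:
    channels: List[ChannelTruth]
    n_frames: int
    dt_ps: float
    cavity_radius: float
    outer_radius: float
    state: str

    def channel(self, name: str) -> ChannelTruth:
        return next(c for c in self.channels if c.name == name)

    def open_channels_at(self, frame: int, probe: float = 0.75) -> set:
        return {
            c.name
            for c in self.channels
            if c.bottleneck_per_frame[frame] >= probe
        }

    def first_open_time_ps(self, name: str, probe: float = 0.75) -> Optional[float]:
        b = self.channel(name).bottleneck_per_frame
        idx = np.flatnonzero(b >= probe)
        return None if len(idx) == 0 else float(idx[0] * self.dt_ps)

    def annotation_polylines(self, step: float = 1.0) -> Dict[str, np.ndarray]:
        """Named channel-axis polylines usable as reference annotations."""
        out = {}
        ts = np.arange(0.0, self.outer_radius + 2.0, step)
        for c in self.channels:
            out[c.name] = ts[:, None] * c.axis[None, :]
        return out

    def to_json(self, path) -> None:
        payload = {
            "n_frames": self.n_frames,
            "dt_ps": self.dt_ps,
            "cavity_radius": self.cavity_radius,
            "outer_radius": self.outer_radius,
            "state": self.state,
            "channels": [c.to_dict() for c in self.channels],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        chans = [
            ChannelTruth(
                name=c["name"],
                axis=np.asarray(c["axis"], float),
                preferred=c["preferred"],
                blocked_by_ligand=c["blocked_by_ligand"],
                bottleneck_per_frame=np.asarray(c["bottleneck_per_frame"], float),
                crystal_bottleneck=c["crystal_bottleneck"],
            )
            for c in d["channels"]
        ]
        return cls(
            channels=chans,
            n_frames=d["n_frames"],
            dt_ps=d["dt_ps"],
            cavity_radius=d["cavity_radius"],
            outer_radius=d["outer_radius"],
            state=d["state"],
        )


# ---------------------------------------------------------------------------
# geometry


def _shell_lattice(cavity_radius: float, outer_radius: float, spacing: float) -> np.ndarray:
    n = int(np.ceil(outer_radius / spacing))
    ax = spacing * np.arange(-n, n + 1)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack((X.ravel(), Y.ravel(), Z.ravel()))
    r = np.linalg.norm(pts, axis=1)
    return pts[(r >= cavity_radius) & (r <= outer_radius)]


def _carve(points: np.ndarray, channel: ChannelSpec) -> np.ndarray:
    u = channel.axis
    proj = points @ u
    perp = np.linalg.norm(points - proj[:, None] * u[None, :], axis=1)
    carve_r = channel.base_radius + ATOM_VDW + CARVE_MARGIN
    remove = (proj > 0) & (perp < carve_r)
    return points[~remove]


def _orthonormal_basis(u: np.ndarray):
    a = np.array([1.0, 0.0, 0.0])
    if abs(u @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _gate_layout(channel: ChannelSpec):
    """Fixed per-channel gate topology: (ring index, angle) per atom.

    Ring radii depend on the per-frame aperture; the layout (ring count and
    atoms per ring) is fixed over the trajectory so topology is constant.
    """
    g_min = channel.gate_closed_radius
    g_max = channel.gate_open_radius
    outer_target = channel.base_radius + ATOM_VDW + CARVE_MARGIN + 1.0
    n_rings = max(2, int(np.ceil((outer_target - g_min - ATOM_VDW) / RING_DR)) + 1)
    layout = []
    for k in range(n_rings):
        r_max = g_max + ATOM_VDW + k * RING_DR
        n_pts = max(6, int(np.ceil(2 * np.pi * r_max / RING_CHORD)))
        for j in range(n_pts):
            theta = 2 * np.pi * j / n_pts + 0.5 * k
            layout.append((k, theta))
    return layout


def _gate_coords(channel: ChannelSpec, aperture: float, cavity_radius: float) -> np.ndarray:
    u = channel.axis
    e1, e2 = _orthonormal_basis(u)
    t0 = cavity_radius + channel.gate_depth
    coords = []
    for k, theta in _gate_layout(channel):
        r = aperture + ATOM_VDW + k * RING_DR
        coords.append(t0 * u + r * (np.cos(theta) * e1 + np.sin(theta) * e2))
    return np.array(coords)


def _ligand_coords() -> np.ndarray:
    d = 1.5 / np.sqrt(3.0)
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [d, d, d],
            [-d, -d, d],
            [-d, d, -d],
            [d, -d, -d],
        ]
    )


def _build_atoms(shell: np.ndarray, gates: Dict[str, np.ndarray], ligand: Optional[np.ndarray]):
    atoms = []
    serial = 0
    resseq = 0

    def add_group(coords, resname, chain, hetatm=False):
        nonlocal serial, resseq
        for start in range(0, len(coords), 8):
            resseq += 1
            for i, c in enumerate(coords[start : start + 8]):
                serial += 1
                atoms.append(
                    Atom(
                        serial=serial,
                        name=f"C{i + 1}",
                        element="C",
                        residue_id=(chain, resseq, ""),
                        residue_name=resname,
                        coord=c,
                        vdw_radius=ATOM_VDW,
                        is_hetatm=hetatm,
                    )
                )

    add_group(shell, "SHL", "A")
    for name in sorted(gates):
        add_group(gates[name], "GAT", "A")
    if ligand is not None:
        add_group(ligand, "LIG", "L", hetatm=True)
    return atoms


_IMPERMEABILITY_CACHE: dict = {}


def check_impermeable(spec: SyntheticSystem, probe: float = 0.75) -> None:
    """Verify the bare shell (no channels) seals the cavity from bulk."""
    key = (spec.cavity_radius, spec.outer_radius, spec.lattice_spacing)
    if key in _IMPERMEABILITY_CACHE:
        ok = _IMPERMEABILITY_CACHE[key]
    else:
        from .tunnelfinder import build_grid
        from scipy import ndimage

        shell = _shell_lattice(*key)
        atoms = _build_atoms(shell, {}, None)
        s = Structure(atoms, "sealed", 0.0, "frame", "synthetic")
        g = build_grid(s, probe_radius=probe)
        passable = g.clearance >= probe
        labels, _ = ndimage.label(passable, structure=np.ones((3, 3, 3), bool))
        center = labels[g.nearest_node((0.0, 0.0, 0.0))]
        boundary = set()
        for axis in range(3):
            for sl in (0, -1):
                face = np.take(labels, sl, axis=axis)
                boundary.update(np.unique(face[face > 0]).tolist())
        ok = center not in boundary
        _IMPERMEABILITY_CACHE[key] = ok
    if not ok:
        raise ImpermeabilityError(
            "shell leaks at lattice spacing "
            f"{spec.lattice_spacing} Å; use a denser shell"
        )


def generate_system(
    spec: SyntheticSystem,
    state: str = "apo",
    check: bool = True,
) -> tuple:
    """Build the trajectory, crystal and minimized structures plus truth.

    Returns ``(bundle, ground_truth)`` where bundle is a dict with keys
    ``trajectory`` (Ensemble of n_frames Structures), ``crystal`` and
    ``minimized`` (Structures with sentinel times).  ``state`` selects the
    gating regime: apo, holo, pseudo_apo or pseudo_holo; the ligand blob is
    present in holo and pseudo_holo structures.
    """
    axes = [c.axis for c in spec.channels]
    for i in range(len(axes)):
        for j in range(i + 1, len(axes)):
            ang = np.degrees(np.arccos(np.clip(axes[i] @ axes[j], -1, 1)))
            if ang < 30.0:
                raise ValueError(
                    f"channel axes {spec.channels[i].name}/{spec.channels[j].name} "
                    f"are only {ang:.1f}° apart (need >= 30°)"
                )
    if check:
        check_impermeable(spec)

    shell = _shell_lattice(spec.cavity_radius, spec.outer_radius, spec.lattice_spacing)
    for c in spec.channels:
        shell = _carve(shell, c)

    has_ligand = state in ("holo", "pseudo_holo")
    ligand = _ligand_coords() if has_ligand else None

    openness = {
        c.name: c.openness(spec.n_frames, state) for c in spec.channels
    }
    # crystal/minimized adopt the frame-0 gating of the *source* state:
    # for pseudo states that is the structure the run was built from
    crystal_openness = {name: o[0] for name, o in openness.items()}

    rng = np.random.default_rng(spec.seed)

    drift = None

    def frame_structure(frame_openness, label, time_ps, source_tag, jitter,
                        advance_drift=False):
        nonlocal drift
        gates = {
            c.name: _gate_coords(c, float(c.gate_radius(frame_openness[c.name])),
                                 spec.cavity_radius)
            for c in spec.channels
        }
        atoms = _build_atoms(shell, gates, ligand)
        if advance_drift and spec.drift_sigma > 0:
            # irregular per-frame step size: conformational diffusion is not
            # time-homogeneous, and exact homogeneity makes all pairwise
            # dissimilarities collapse onto a function of the time lag
            scale = spec.drift_sigma * rng.uniform(0.5, 1.5)
            step = rng.normal(0.0, scale, size=(len(atoms), 3))
            drift = step if drift is None else drift + step
        offset = np.zeros((len(atoms), 3)) if drift is None or not advance_drift else drift
        if jitter > 0:
            offset = offset + rng.normal(0.0, jitter, size=(len(atoms), 3))
        if np.any(offset):
            atoms = [a.moved_to(a.coord + o) for a, o in zip(atoms, offset)]
        tag = "synthetic" if state in ("apo", "holo") else state
        return Structure(atoms, label, time_ps, source_tag, tag)

    crystal = frame_structure(crystal_openness, f"{state}-crystal",
                              CRYSTAL_TIME_PS, "crystal", 0.0)
    minimized = frame_structure(crystal_openness, f"{state}-minimized",
                                MINIMIZED_TIME_PS, "minimized", spec.jitter_sigma)
    frames = []
    for f in range(spec.n_frames):
        fo = {name: o[f] for name, o in openness.items()}
        frames.append(
            frame_structure(fo, f"{state}-frame{f}", f * spec.dt_ps, "frame",
                            spec.jitter_sigma, advance_drift=True)
        )
    truth = GroundTruth(
        channels=[
            ChannelTruth(
                name=c.name,
                axis=c.axis.copy(),
                preferred=c.preferred,
                blocked_by_ligand=c.blocked_by_ligand,
                bottleneck_per_frame=np.asarray(c.gate_radius(openness[c.name]), float),
                crystal_bottleneck=float(c.gate_radius(crystal_openness[c.name])),
            )
            for c in spec.channels
        ],
        n_frames=spec.n_frames,
        dt_ps=spec.dt_ps,
        cavity_radius=spec.cavity_radius,
        outer_radius=spec.outer_radius,
        state=state,
    )
    bundle = {
        "trajectory": Ensemble(frames, name=f"{state}-trajectory"),
        "crystal": crystal,
        "minimized": minimized,
    }
    return bundle, truth


# ---------------------------------------------------------------------------
# presets

PRESETS = ("basic", "gated", "apo_holo", "preferred_vs_rare")


def make_benchmark(
    preset: str,
    n_frames: Optional[int] = None,
    seed: int = 0,
    out_dir=None,
) -> dict:
    """Generate one of the benchmark bundles.

    - ``basic``: three static channels of distinct direction and radius.
    - ``gated``: one always-open channel plus one that opens halfway through
      the trajectory (a sharp discovery-curve step).
    - ``apo_holo``: an apo-only gate, a holo-only gate and a shared solvent
      channel, in all four gating states (apo/holo/pseudo_apo/pseudo_holo).
    - ``preferred_vs_rare``: a wide oscillating channel versus a narrow
      static one.

    Returns ``{state: {"trajectory", "crystal", "minimized", "ground_truth"}}``.
    """
    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    ez = np.array([0.0, 0.0, 1.0])

    if preset == "basic":
        nf = n_frames or 3
        spec = SyntheticSystem(
            channels=[
                ChannelSpec("A", ex, base_radius=3.1, gate_open_radius=2.5),
                ChannelSpec("B", ey, base_radius=2.6, gate_open_radius=2.0),
                ChannelSpec("C", ez, base_radius=2.1, gate_open_radius=1.5),
            ],
            jitter_sigma=0.0,
            n_frames=nf,
            seed=seed,
        )
        states = ["apo"]
    elif preset == "gated":
        nf = n_frames or 101
        switch = nf // 2
        schedule = (np.arange(nf) >= switch).astype(float)
        spec = SyntheticSystem(
            channels=[
                ChannelSpec("open", ex, base_radius=2.6, gate_open_radius=2.0),
                ChannelSpec(
                    "gated", ey, base_radius=2.6, gate_open_radius=2.0,
                    gate_closed_radius=0.0, schedule=schedule,
                ),
            ],
            jitter_sigma=0.05,
            n_frames=nf,
            seed=seed,
        )
        states = ["apo"]
    elif preset == "apo_holo":
        nf = n_frames or 6
        spec = SyntheticSystem(
            channels=[
                # open in apo; the ligand pins it shut (PHE-gate style)
                ChannelSpec(
                    "A", ex, base_radius=2.8, gate_open_radius=2.2,
                    blocked_by_ligand=True, ligand_pinned_openness=0.0,
                    preferred=True,
                ),
                # closed in apo; the ligand props it open
                ChannelSpec(
                    "D", ey, base_radius=2.8, gate_open_radius=2.2,
                    schedule=0.0, blocked_by_ligand=True,
                    ligand_pinned_openness=1.0, preferred=True,
                ),
                # solvent-like channel shared by both states
                ChannelSpec("S", ez, base_radius=2.4, gate_open_radius=1.8,
                            preferred=True),
            ],
            jitter_sigma=0.05,
            n_frames=nf,
            dt_ps=2000.0,
            seed=seed,
        )
        states = ["apo", "holo", "pseudo_apo", "pseudo_holo"]
    elif preset == "preferred_vs_rare":
        nf = n_frames or 12
        osc = np.tile([1.0, 1.0, 0.0, 0.0], (nf + 3) // 4)[:nf]
        spec = SyntheticSystem(
            channels=[
                ChannelSpec(
                    "preferred", ex, base_radius=3.1, gate_open_radius=2.5,
                    gate_closed_radius=1.3, schedule=osc, preferred=True,
                ),
                ChannelSpec("rare", ey, base_radius=1.7, gate_open_radius=1.15,
                            gate_closed_radius=1.15),
            ],
            jitter_sigma=0.05,
            n_frames=nf,
            dt_ps=500.0,
            seed=seed,
        )
        states = ["apo"]
    else:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")

    bundle = {}
    for state in states:
        b, truth = generate_system(spec, state=state)
        b["ground_truth"] = truth
        bundle[state] = b

    if out_dir is not None:
        from .io import write_manifest, write_structures

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for state, b in bundle.items():
            write_structures(b["trajectory"], out_dir / f"{state}_trajectory.pdb")
            write_structures(b["crystal"], out_dir / f"{state}_crystal.pdb")
            write_structures(b["minimized"], out_dir / f"{state}_minimized.pdb")
            b["ground_truth"].to_json(out_dir / f"{state}_ground_truth.json")
            write_manifest(b["trajectory"], out_dir / f"{state}_manifest.json")
    return bundle
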