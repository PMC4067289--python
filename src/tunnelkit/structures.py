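"""Core domain containers: atoms, single conformations, and ordered ensembles.

A :class:`Structure` is one protein conformation tagged with a time stamp and
provenance (crystal / minimized / trajectory frame / pseudo structure).  Crystal
and minimized structures carry sentinel times (-2 ps and -1 ps) so that
"first occurrence" orderings place them before the trajectory's frame 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

# van der Waals radii by element (Å); fallback used for unknown elements.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
    "FE": 1.40,
}
DEFAULT_VDW = 1.70

#: HETATM residue names that are *not* treated as ligand: water, common ions,
#: and the heme cofactor (part of the protein wall in P450s).
LIGAND_EXCLUDE = {"HOH", "WAT", "NA", "CL", "HEM"}

#: residue names treated as solvent/ions and stripped before tunnel calculation
SOLVENT_RESNAMES = {"HOH", "WAT", "NA", "CL"}

CRYSTAL_TIME_PS = -2.0
MINIMIZED_TIME_PS = -1.0

SOURCE_TAGS = ("crystal", "minimized", "frame", "pseudo")
STATE_TAGS = ("apo", "holo", "pseudo_apo", "pseudo_holo", "synthetic")


class TopologyError(ValueError):
    """Atom topologies of two structures (or models) do not correspond."""


def vdw_radius_for(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def element_from_name(name: str) -> str:
    """Infer the element symbol from a PDB atom name.

    Handles the common conventions: leading digits (e.g. ``1HG1``), two-letter
    elements occupying columns 13-14 (``FE``), and single-letter elements.
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    two = stripped[:2].upper()
    # two-letter metals are unambiguous; NA/CL clash with heme/sidechain
    # nitrogen and carbon names, so ions are resolved by residue name in io.
    if two in ("FE", "ZN", "MG"):
        return two
    return stripped[0].upper()


@dataclass(frozen=True)
class Atom:
    """One atom: identity, coordinates and a fixed van der Waals radius."""

    serial: int
    name: str
    element: str
    residue_id: tuple  # (chain, resseq, icode)
    residue_name: str
    coord: np.ndarray  # shape (3,), Å
    vdw_radius: float
    is_hetatm: bool = False

    def __post_init__(self):
        object.__setattr__(self, "coord", np.asarray(self.coord, dtype=float))
        if self.vdw_radius <= 0:
            raise ValueError(f"vdw_radius must be > 0 (atom {self.serial})")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate (atom {self.serial})")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def is_water(self) -> bool:
        return self.residue_name in ("HOH", "WAT")

    @property
    def is_ligand(self) -> bool:
        return self.is_hetatm and self.residue_name not in LIGAND_EXCLUDE

    def moved_to(self, coord) -> "Atom":
        return replace(self, coord=np.asarray(coord, dtype=float))


class Structure:
    """One conformation: an ordered atom list plus time and provenance tags."""

    def __init__(
        self,
        atoms: Sequence[Atom],
        label: str = "",
        time_ps: float = 0.0,
        source_tag: str = "frame",
        state_tag: str = "synthetic",
    ):
        atoms = list(atoms)
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique")
        if not any(a.is_heavy for a in atoms):
            raise ValueError("structure must contain at least one heavy atom")
        if source_tag not in SOURCE_TAGS:
            raise ValueError(f"unknown source_tag {source_tag!r}")
        if state_tag not in STATE_TAGS:
            raise ValueError(f"unknown state_tag {state_tag!r}")
        self.atoms = atoms
        self.label = label
        self.time_ps = float(time_ps)
        self.source_tag = source_tag
        self.state_tag = state_tag

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return (
            f"<Structure {self.label!r} n_atoms={len(self)} t={self.time_ps} ps "
            f"{self.source_tag}/{self.state_tag}>"
        )

    # ---- array views -------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    def atom_keys(self) -> list:
        """(residue_id, atom name) keys used for topology correspondence."""
        return [(a.residue_id, a.name) for a in self.atoms]

    # ---- selections --------------------------------------------------
    def subset(self, mask: Iterable[bool], **tags) -> "Structure":
        atoms = [a for a, keep in zip(self.atoms, mask) if keep]
        kw = dict(
            label=self.label,
            time_ps=self.time_ps,
            source_tag=self.source_tag,
            state_tag=self.state_tag,
        )
        kw.update(tags)
        return Structure(atoms, **kw)

    def heavy_atoms(self) -> "Structure":
        return self.subset([a.is_heavy for a in self.atoms])

    def without_ligand(self) -> "Structure":
        return self.subset([not a.is_ligand for a in self.atoms])

    def prepared_for_tunnels(self, keep_ligand: bool = False) -> "Structure":
        """Strip hydrogens, solvent and ions (and the ligand unless kept).

        The heme cofactor and other excluded HETATM groups stay: they form
        part of the wall of the active-site cavity.
        """

        def keep(a: Atom) -> bool:
            if not a.is_heavy:
                return False
            if a.residue_name in SOLVENT_RESNAMES:
                return False
            if a.is_ligand and not keep_ligand:
                return False
            return True

        return self.subset([keep(a) for a in self.atoms])

    def ca_mask(self) -> np.ndarray:
        return np.array([a.name.strip() == "CA" for a in self.atoms], dtype=bool)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with coordinates mapped through x -> R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        atoms = [a.moved_to(R @ a.coord + t) for a in self.atoms]
        return Structure(atoms, self.label, self.time_ps, self.source_tag, self.state_tag)

    def with_tags(self, **tags) -> "Structure":
        kw = dict(
            label=self.label,
            time_ps=self.time_ps,
            source_tag=self.source_tag,
            state_tag=self.state_tag,
        )
        kw.update(tags)
        return Structure(self.atoms, **kw)


@dataclass
class Ensemble:
    """Ordered collection of structures with a name."""

    members: list = field(default_factory=list)
    name: str = ""

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i):
        return self.members[i]

    def labels(self) -> list:
        return [m.label for m in self.members]

    def times(self) -> np.ndarray:
        return np.array([m.time_ps for m in self.members], dtype=float)

    def check_uniform_topology(self, heavy_only: bool = True) -> None:
        """Raise TopologyError unless all members share atom count and names."""
        if not self.members:
            return
        ref = self.members[0].heavy_atoms() if heavy_only else self.members[0]
        ref_keys = ref.atom_keys()
        for m in self.members[1:]:
            s = m.heavy_atoms() if heavy_only else m
            keys = s.atom_keys()
            if len(keys) != len(ref_keys):
                raise TopologyError(
                    f"member {m.label!r} has {len(keys)} atoms, expected {len(ref_keys)}"
                )
            for k, (ka, kb) in enumerate(zip(ref_keys, keys)):
                if ka != kb:
                    raise TopologyError(
                        f"member {m.label!r} first mismatched atom at index {k}: "
                        f"{kb} != {ka}"
                    )

    def manifest(self) -> dict:
        """JSON-serializable description of the ensemble members."""
        return {
            "name": self.name,
            "members": [
                {
                    "label": m.label,
                    "time_ps": m.time_ps,
                    "source_tag": m.source_tag,
                    "state_tag": m.state_tag,
                    "n_atoms": len(m),
                }
                for m in self.members
            ],
        }
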