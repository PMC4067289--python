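"""Surface-exposed residue detection via Shrake-Rupley SASA.

Highly flexible surface residues add noise to conformational clustering, so a
mask of surface-exposed residues is computed once on the crystal (reference)
structure and excluded from every structure-similarity computation.

Relative accessibility of a residue is its side-chain SASA divided by the
side-chain SASA of that residue type X in an extended Gly-X-Gly tripeptide.
Residue types without a table entry (synthetic pseudo-residues) fall back to a
generic reference area, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import Structure

#: reference side-chain accessible areas (Å^2) in extended Gly-X-Gly
#: tripeptides (theoretical-maximum style table; glycine uses its CA).
SIDECHAIN_REFERENCE_AREA = {
    "ALA": 67.0, "ARG": 196.0, "ASN": 113.0, "ASP": 106.0, "CYS": 104.0,
    "GLN": 144.0, "GLU": 138.0, "GLY": 47.0, "HIS": 151.0, "ILE": 140.0,
    "LEU": 137.0, "LYS": 167.0, "MET": 160.0, "PHE": 175.0, "PRO": 105.0,
    "SER": 80.0, "THR": 102.0, "TRP": 217.0, "TYR": 187.0, "VAL": 117.0,
}
GENERIC_REFERENCE_AREA = 150.0

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


def sphere_points(n: int) -> np.ndarray:
    """n approximately uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å^2)."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    pts = sphere_points(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    sasa = np.zeros(n)
    for i in range(n):
        ri = expanded[i]
        surface = coords[i] + ri * pts
        neighbors = [j for j in tree.query_ball_point(coords[i], ri + max_reach / 2.0)
                     if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            dj = np.linalg.norm(surface - coords[j], axis=1)
            exposed &= dj >= expanded[j]
            if not exposed.any():
                break
        sasa[i] = 4.0 * np.pi * ri * ri * exposed.mean()
    return sasa


@dataclass
class SurfaceMask:
    """Residues flagged as surface-exposed on the reference structure."""

    surface_residues: set = field(default_factory=set)
    rel_sasa: dict = field(default_factory=dict)  # residue_id -> relative SASA
    threshold: float = 0.30

    def is_surface(self, residue_id) -> bool:
        return residue_id in self.surface_residues

    def to_rows(self):
        return [
            (rid, rel, rid in self.surface_residues)
            for rid, rel in sorted(self.rel_sasa.items(), key=lambda kv: str(kv[0]))
        ]


def surface_residues(
    crystal: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    threshold: float = 0.30,
    generic_reference: float = GENERIC_REFERENCE_AREA,
) -> SurfaceMask:
    """Flag residues whose relative side-chain accessibility exceeds ``threshold``.

    Computed on heavy atoms of the given (crystal) structure only; the mask is
    then reused unchanged for every other ensemble member.
    """
    heavy = crystal.heavy_atoms()
    sasa = shrake_rupley(heavy.coords, heavy.vdw_radii, probe, n_points)

    sidechain_area: dict = {}
    resnames: dict = {}
    for atom, area in zip(heavy.atoms, sasa):
        rid = atom.residue_id
        resnames[rid] = atom.residue_name
        name = atom.name.strip()
        is_sidechain = name not in BACKBONE_NAMES or (
            atom.residue_name == "GLY" and name == "CA"
        )
        if is_sidechain:
            sidechain_area[rid] = sidechain_area.get(rid, 0.0) + float(area)

    rel = {}
    missing = set()
    for rid, resname in resnames.items():
        ref = SIDECHAIN_REFERENCE_AREA.get(resname)
        if ref is None:
            ref = generic_reference
            missing.add(resname)
        rel[rid] = sidechain_area.get(rid, 0.0) / ref
    if missing:
        warnings.warn(
            "no reference side-chain area for residue type(s) "
            f"{sorted(missing)}; using generic {generic_reference} Å²"
        )
    flagged = {rid for rid, r in rel.items() if r > threshold}
    return SurfaceMask(surface_residues=flagged, rel_sasa=rel, threshold=threshold)


def export_mask_csv(mask: SurfaceMask, path) -> None:
    import pandas as pd

    rows = mask.to_rows()
    pd.DataFrame(rows, columns=["residue_id", "rel_sasa", "surface"]).to_csv(
        path, index=False
    )
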