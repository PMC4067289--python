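"""Optimal rigid-body superposition (Kabsch) and heavy-atom RMSD.

Protocol: structures are aligned on C-alpha atoms (all heavy atoms when no
C-alpha naming exists, e.g. synthetic pseudo-atom systems) and deviations are
then measured over heavy atoms, optionally excluding a residue set such as
surface-exposed residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import Structure, TopologyError


class DegenerateFitError(ValueError):
    """Fewer than 3 atoms, or a (near-)collinear fit set."""


@dataclass(frozen=True)
class Superposition:
    """Proper rigid motion x -> R x + t minimizing RMSD over the fit set."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float  # Å over the fit atom set

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def transform(self, s: Structure) -> Structure:
        return s.transformed(self.rotation, self.translation)


def _fit_mask(s: Structure, fit_selection) -> np.ndarray:
    if fit_selection is not None:
        mask = np.asarray(fit_selection, dtype=bool)
        if mask.shape != (len(s),):
            raise ValueError("fit_selection length must equal atom count")
        return mask
    ca = s.ca_mask()
    if ca.sum() >= 3:
        return ca
    return s.heavy_mask


def superpose(
    mobile: Structure,
    reference: Structure,
    fit_selection: Optional[Iterable[bool]] = None,
) -> Superposition:
    """Least-squares optimal rotation/translation of ``mobile`` onto ``reference``.

    ``fit_selection`` is a boolean mask applied to both structures (they must
    correspond 1:1 over the selection).  Defaults to C-alpha atoms, falling
    back to all heavy atoms.
    """
    mmask = _fit_mask(mobile, fit_selection)
    rmask = _fit_mask(reference, fit_selection)
    P = mobile.coords[mmask]
    Q = reference.coords[rmask]
    if P.shape != Q.shape:
        raise TopologyError(
            f"fit selections differ in size: {P.shape[0]} vs {Q.shape[0]}"
        )
    if P.shape[0] < 3:
        raise DegenerateFitError("need at least 3 fit atoms")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # collinear (rank < 2) sets leave the rotation underdetermined
    if np.linalg.matrix_rank(Qc, tol=1e-8) < 2 or np.linalg.matrix_rank(Pc, tol=1e-8) < 2:
        raise DegenerateFitError("fit atoms are collinear")
    rot, rssd = Rotation.align_vectors(Qc, Pc)
    R = rot.as_matrix()
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    rmsd = float(rssd / np.sqrt(P.shape[0]))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def superpose_ensemble(members, fit_selection=None):
    """Superpose every member onto the first; returns a new member list."""
    members = list(members)
    if not members:
        return []
    ref = members[0]
    out = [ref]
    for m in members[1:]:
        out.append(superpose(m, ref, fit_selection).transform(m))
    return out


def rmsd_heavy(
    a: Structure,
    b: Structure,
    exclude_residues: Optional[set] = None,
) -> float:
    """RMSD over heavy atoms, both structures assumed already superposed.

    ``exclude_residues`` is a set of residue_ids removed identically from both
    sides (e.g. surface-exposed residues).
    """
    ha, hb = a.heavy_atoms(), b.heavy_atoms()
    keys_a, keys_b = ha.atom_keys(), hb.atom_keys()
    if len(keys_a) != len(keys_b):
        raise TopologyError(
            f"heavy-atom counts differ: {len(keys_a)} vs {len(keys_b)}"
        )
    for k, (ka, kb) in enumerate(zip(keys_a, keys_b)):
        if ka != kb:
            raise TopologyError(f"first mismatched atom at index {k}: {kb} != {ka}")
    if exclude_residues:
        mask = np.array(
            [at.residue_id not in exclude_residues for at in ha.atoms], dtype=bool
        )
    else:
        mask = np.ones(len(keys_a), dtype=bool)
    if not mask.any():
        raise ValueError("exclusion mask removed every heavy atom")
    d = ha.coords[mask] - hb.coords[mask]
    return float(np.sqrt((d * d).sum(axis=1).mean()))
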