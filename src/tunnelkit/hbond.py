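"""Hydrogen-bond detection and hydrogen-bond-network ensemble similarity.

A bond position is a (donor, acceptor) atom pair identified by residue id and
atom name, so positions are comparable across ensemble members with matching
topology.  The similarity score between two members is the fraction of
mismatched positions over the union of bonds observed anywhere in the
ensemble: 0 means identical networks, 1 completely dissimilar networks.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .cluster import SimilarityMatrix
from .structures import Structure

#: geometric criteria (g_hbond-style defaults): donor-acceptor distance and
#: hydrogen-donor-acceptor angle
D_CUT_ANGSTROM = 3.5
ANGLE_CUT_DEG = 30.0
#: maximum covalent H-donor bond length used to attach hydrogens to donors
H_BOND_ATTACH = 1.25


def detect_hbonds(
    s: Structure,
    d_cut: float = D_CUT_ANGSTROM,
    angle_cut: float = ANGLE_CUT_DEG,
) -> set:
    """Donor->acceptor pairs satisfying the distance (and angle) criteria.

    Donors and acceptors are protein N/O atoms (waters and ligand excluded);
    when the structure carries hydrogens, a donor must have a covalently
    attached H and the H-donor-acceptor angle must be <= ``angle_cut`` for at
    least one attached hydrogen.  Without hydrogens the distance criterion
    alone applies.  Pairs within one residue are skipped.
    """
    atoms = [a for a in s.atoms if not a.is_water and not a.is_ligand]
    polar = [a for a in atoms if a.element.upper() in ("N", "O")]
    if not polar:
        return set()
    hydrogens = [a for a in atoms if a.element.upper() == "H"]
    have_h = bool(hydrogens)

    attached: dict = {}
    if have_h:
        h_coords = np.array([h.coord for h in hydrogens])
        tree = cKDTree(h_coords)
        for a in polar:
            idx = tree.query_ball_point(a.coord, H_BOND_ATTACH)
            if idx:
                attached[id(a)] = h_coords[idx]

    coords = np.array([a.coord for a in polar])
    ptree = cKDTree(coords)
    pairs = ptree.query_pairs(d_cut)
    cos_cut = np.cos(np.deg2rad(angle_cut))

    def angle_ok(donor, acceptor) -> bool:
        hs = attached.get(id(donor))
        if hs is None:
            return False
        da = acceptor.coord - donor.coord
        da /= np.linalg.norm(da)
        dh = hs - donor.coord
        dh /= np.linalg.norm(dh, axis=1, keepdims=True)
        return bool(np.any(dh @ da >= cos_cut))

    bonds = set()
    for i, j in pairs:
        a, b = polar[i], polar[j]
        if a.residue_id == b.residue_id:
            continue
        for donor, acceptor in ((a, b), (b, a)):
            if have_h:
                if not angle_ok(donor, acceptor):
                    continue
            bonds.add(
                ((donor.residue_id, donor.name), (acceptor.residue_id, acceptor.name))
            )
    return bonds


def hbond_similarity(ensemble, mask=None, d_cut=D_CUT_ANGSTROM, angle_cut=ANGLE_CUT_DEG) -> SimilarityMatrix:
    """Pairwise hydrogen-bond-network mismatch scores over an ensemble.

    Positions are the union of bonds over all members, restricted to buried
    residues when a surface ``mask`` is given.  score(k, n) is the mean of
    per-position mismatches (0 = same pattern at every position).
    """
    members = list(ensemble)
    if len(members) < 2:
        raise ValueError("need at least 2 ensemble members")

    def buried(bond) -> bool:
        if mask is None:
            return True
        (drid, _), (arid, _) = bond
        return not mask.is_surface(drid) and not mask.is_surface(arid)

    bond_sets = []
    for m in members:
        bond_sets.append({b for b in detect_hbonds(m, d_cut, angle_cut) if buried(b)})

    positions = sorted(set().union(*bond_sets), key=repr)
    n = len(members)
    if not positions:
        warnings.warn("no hydrogen-bond positions found; all similarities are 0")
        return SimilarityMatrix(np.zeros((n, n)), [m.label for m in members])

    presence = np.array(
        [[b in bs for b in positions] for bs in bond_sets], dtype=bool
    )
    mismatch = (presence[:, None, :] != presence[None, :, :]).mean(axis=2)
    return SimilarityMatrix(mismatch, [m.label for m in members])
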