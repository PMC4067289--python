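"""Ensemble construction: time-point extraction, structure clustering
(gromos RMSD, pairwise-distance, hydrogen-bond network), mixed apo/holo
concatenation, and pseudo-apo/holo structure building.

Conventions: crystal and minimized structures are prepended to time-point
ensembles but excluded from clustering inputs; cluster representatives are
actual conformations (medoids/centers), never averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cluster import GromosClustering, KMedoids, SimilarityMatrix
from .structures import Ensemble, Structure
from .superpose import rmsd_heavy, superpose, superpose_ensemble


@dataclass
class PairwiseDistanceSimilarity(SimilarityMatrix):
    """Pairwise-distance dissimilarity: RMS difference of intra-structure
    heavy-atom pair distances between two conformations (Å)."""

    pair_universe: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), int))
    subsampled: bool = False


@dataclass
class ClusteringResult:
    assignment: dict  # member index -> cluster id
    representatives: dict  # cluster id -> member index
    cutoff_used: Optional[float] = None  # Å (gromos) ...
    k_used: Optional[int] = None  # ... or k (medoid)
    objective: float = 0.0

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def representative_ensemble(self, members, name: str = "") -> Ensemble:
        members = list(members)
        picks = [members[self.representatives[c]] for c in sorted(self.representatives)]
        return Ensemble(picks, name=name)


def time_point_ensemble(
    traj: Ensemble,
    stride_ps: float,
    crystal: Optional[Structure] = None,
    minimized: Optional[Structure] = None,
    name: str = "",
) -> Ensemble:
    """Frames at t = 0, stride, 2*stride, ... plus crystal and minimized.

    A 10 ns trajectory at 100 ps frames gives 103, 53, 23, 13 or 8 members for
    strides of 100, 200, 500, 1000 or 2000 ps.
    """
    frames = sorted(traj.members, key=lambda s: s.time_ps)
    times = np.array([f.time_ps for f in frames])
    if len(frames) > 1:
        steps = np.diff(times)
        step = steps[0]
        if not np.allclose(steps, step):
            raise ValueError("trajectory frames are not uniformly spaced")
        ratio = stride_ps / step
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"stride {stride_ps} ps is not a multiple of the frame step {step} ps"
            )
    ratios = times / stride_ps
    picked = [
        f for f, r in zip(frames, ratios) if abs(r - round(r)) < 1e-9
    ]
    head = []
    if crystal is None or minimized is None:
        warnings.warn("building time-point ensemble without crystal/minimized")
    if crystal is not None:
        head.append(crystal)
    if minimized is not None:
        head.append(minimized)
    return Ensemble(head + picked, name=name or f"timepoint-{stride_ps:g}ps")


def clustering_input(ensemble: Ensemble) -> Ensemble:
    """Trajectory frames only: crystal and minimized are excluded from
    structure clustering."""
    keep = [m for m in ensemble if m.source_tag == "frame"]
    return Ensemble(keep, name=ensemble.name)


def rmsd_matrix(members, mask=None, fit_selection=None) -> SimilarityMatrix:
    """All-pair heavy-atom RMSD after superposing everything onto member 0."""
    aligned = superpose_ensemble(list(members), fit_selection)
    exclude = mask.surface_residues if mask is not None else None
    n = len(aligned)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = rmsd_heavy(aligned[i], aligned[j], exclude)
    return SimilarityMatrix(M, [m.label for m in aligned])


def gromos_cluster(members, mask=None, target_size: int = 1) -> ClusteringResult:
    """gromos clustering at the smallest cutoff giving <= target_size clusters.

    Dissimilarity is masked heavy-atom RMSD after C-alpha (or all-heavy)
    superposition onto the first member.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    S = members if isinstance(members, SimilarityMatrix) else rmsd_matrix(members, mask)
    est = GromosClustering(target_size=target_size).fit(S.values)
    assignment = {i: int(c) for i, c in enumerate(est.labels_)}
    reps = {c: int(idx) for c, idx in enumerate(est.center_indices_)}
    within = sum(
        S.values[i, reps[c]] for i, c in assignment.items()
    )
    return ClusteringResult(assignment, reps, cutoff_used=est.cutoff_, objective=within)


def pairwise_distance_similarity(
    members,
    mask=None,
    max_pairs: int = 50000,
    seed: int = 0,
) -> PairwiseDistanceSimilarity:
    """S_kn = sqrt(mean over heavy-atom pairs ij of (d_ij^k - d_ij^n)^2).

    Only buried heavy atoms enter; when the number of pairs exceeds
    ``max_pairs`` a deterministic seeded subsample is used (flagged on the
    result).  Internal distances make the measure rigid-motion invariant.
    """
    members = list(members)
    ref = members[0].heavy_atoms()
    if mask is not None:
        buried = [not mask.is_surface(a.residue_id) for a in ref.atoms]
    else:
        buried = [True] * len(ref)
    idx = np.flatnonzero(np.array(buried))
    if len(idx) < 2:
        raise ValueError("need at least 2 buried heavy atoms")
    ii, jj = np.triu_indices(len(idx), k=1)
    pairs = np.column_stack((idx[ii], idx[jj]))
    subsampled = False
    if len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = pairs[np.sort(pick)]
        subsampled = True

    dists = []
    for m in members:
        c = m.heavy_atoms().coords
        d = np.linalg.norm(c[pairs[:, 0]] - c[pairs[:, 1]], axis=1)
        dists.append(d)
    D = np.stack(dists)
    n = len(members)
    S = np.zeros((n, n))
    for i in range(n):
        diff = D[i + 1 :] - D[i]
        S[i, i + 1 :] = S[i + 1 :, i] = np.sqrt((diff * diff).mean(axis=1))
    return PairwiseDistanceSimilarity(
        values=S,
        labels=[m.label for m in members],
        pair_universe=pairs,
        subsampled=subsampled,
    )


def kmedoid(S: SimilarityMatrix, k: int) -> ClusteringResult:
    """PAM k-medoids on a precomputed similarity matrix."""
    est = KMedoids(n_clusters=k).fit(S.values)
    assignment = {i: int(c) for i, c in enumerate(est.labels_)}
    reps = {c: int(m) for c, m in enumerate(est.medoid_indices_)}
    return ClusteringResult(assignment, reps, k_used=k, objective=est.inertia_)


def mixed_ensemble(apo_parent: Ensemble, holo_parent: Ensemble, name: str = "mixed") -> Ensemble:
    """Concatenate apo and holo parent ensembles (state tags preserved)."""
    members = []
    seen = set()
    for m in list(apo_parent) + list(holo_parent):
        label = m.label
        if label in seen:
            label = f"{m.state_tag}:{m.label}"
        seen.add(label)
        members.append(m.with_tags(label=label) if label != m.label else m)
    return Ensemble(members, name=name)


def make_pseudo(
    holo: Optional[Structure] = None,
    apo: Optional[Structure] = None,
    direction: str = "remove_ligand",
) -> Structure:
    """Build a pseudo-apo (ligand removed) or pseudo-holo (ligand grafted).

    ``add_ligand`` superposes the holo protein onto the apo protein, applies
    the same transform to the ligand atoms, and appends them to the apo
    structure.
    """
    if direction == "remove_ligand":
        if holo is None:
            raise ValueError("remove_ligand requires a holo structure")
        if not any(a.is_ligand for a in holo.atoms):
            raise ValueError("holo structure has no ligand atoms")
        out = holo.without_ligand()
        return out.with_tags(state_tag="pseudo_apo", source_tag="pseudo")
    if direction == "add_ligand":
        if holo is None or apo is None:
            raise ValueError("add_ligand requires both apo and holo structures")
        ligand_atoms = [a for a in holo.atoms if a.is_ligand]
        if not ligand_atoms:
            raise ValueError("holo structure has no ligand atoms")
        from dataclasses import replace as _replace

        sup = superpose(holo.without_ligand(), apo)
        max_serial = max(a.serial for a in apo.atoms)
        moved = [
            _replace(
                a,
                serial=max_serial + i + 1,
                coord=sup.apply(a.coord),
                is_hetatm=True,
            )
            for i, a in enumerate(ligand_atoms)
        ]
        return Structure(
            list(apo.atoms) + moved,
            label=f"{apo.label}+ligand",
            time_ps=apo.time_ps,
            source_tag="pseudo",
            state_tag="pseudo_holo",
        )
    raise ValueError(f"unknown direction {direction!r}")
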