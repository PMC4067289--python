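"""Ensemble builders: time-point, similarity matrices, mixed, pseudo."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tunnelkit.ensembles import (
    clustering_input,
    gromos_cluster,
    kmedoid,
    make_pseudo,
    mixed_ensemble,
    pairwise_distance_similarity,
    rmsd_matrix,
    time_point_ensemble,
)
from tunnelkit.cluster import SimilarityMatrix
from tunnelkit.structures import Ensemble, CRYSTAL_TIME_PS, MINIMIZED_TIME_PS

from conftest import build_structure


def make_traj(n_frames, dt=100.0, seed=0, n_atoms=12, drift=0.0):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n_atoms, 3)) * 5
    frames = []
    for i in range(n_frames):
        coords = base + drift * i + rng.normal(scale=0.01, size=base.shape)
        frames.append(
            build_structure(coords, label=f"f{i}", time_ps=i * dt, source_tag="frame")
        )
    return Ensemble(frames, name="traj")


def crystal_and_minimized(seed=0, n_atoms=12):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n_atoms, 3)) * 5
    c = build_structure(base, label="crystal", time_ps=CRYSTAL_TIME_PS, source_tag="crystal")
    m = build_structure(base + 0.01, label="min", time_ps=MINIMIZED_TIME_PS, source_tag="minimized")
    return c, m


class TestTimePointEnsemble:
    @pytest.mark.parametrize(
        "stride,expected",
        [(100.0, 103), (200.0, 53), (500.0, 23), (1000.0, 13), (2000.0, 8)],
    )
    def test_member_counts_for_10ns_trajectory(self, stride, expected):
        traj = make_traj(101)  # 10 ns at 100 ps
        c, m = crystal_and_minimized()
        ens = time_point_ensemble(traj, stride, c, m)
        assert len(ens) == expected

    def test_stride_beyond_trajectory_keeps_frame_zero(self):
        traj = make_traj(101)
        c, m = crystal_and_minimized()
        ens = time_point_ensemble(traj, 20000.0, c, m)
        assert len(ens) == 3

    def test_crystal_and_minimized_order_before_frames(self):
        traj = make_traj(11)
        c, m = crystal_and_minimized()
        ens = time_point_ensemble(traj, 500.0, c, m)
        assert [s.source_tag for s in ens.members[:2]] == ["crystal", "minimized"]
        assert ens.times()[0] < ens.times()[1] < 0 <= ens.times()[2]

    def test_non_multiple_stride_rejected(self):
        traj = make_traj(11)
        c, m = crystal_and_minimized()
        with pytest.raises(ValueError):
            time_point_ensemble(traj, 250.0, c, m)

    def test_missing_crystal_warns(self):
        traj = make_traj(5)
        with pytest.warns(UserWarning):
            ens = time_point_ensemble(traj, 100.0)
        assert len(ens) == 5

    def test_clustering_input_drops_crystal_and_minimized(self):
        traj = make_traj(101)
        c, m = crystal_and_minimized()
        ens = time_point_ensemble(traj, 100.0, c, m)
        assert len(clustering_input(ens)) == 101


class TestPairwiseDistanceSimilarity:
    def test_identical_members_zero(self):
        s = build_structure(np.random.default_rng(0).normal(size=(6, 3)) * 4)
        S = pairwise_distance_similarity([s, s])
        assert np.allclose(S.values, 0.0)

    def test_rigid_motion_invariant(self):
        s = build_structure(np.random.default_rng(1).normal(size=(6, 3)) * 4)
        R = Rotation.from_euler("xyz", [1.0, 0.2, -0.5]).as_matrix()
        moved = s.transformed(R, np.array([4.0, 1.0, -2.0]))
        S = pairwise_distance_similarity([s, moved])
        assert np.allclose(S.values, 0.0, atol=1e-9)

    def test_three_atom_hand_computation(self):
        a = build_structure([(0, 0, 0), (1, 0, 0), (0, 1, 0)])
        b = build_structure([(0, 0, 0), (2, 0, 0), (0, 1, 0)])
        S = pairwise_distance_similarity([a, b])
        # pairs (0,1): 1 vs 2; (0,2): 1 vs 1; (1,2): sqrt2 vs sqrt5
        expected = np.sqrt((1.0**2 + 0.0**2 + (np.sqrt(5) - np.sqrt(2)) ** 2) / 3.0)
        assert np.isclose(S.values[0, 1], expected, atol=1e-12)

    def test_subsampling_is_deterministic(self):
        rng = np.random.default_rng(2)
        members = [
            build_structure(rng.normal(size=(30, 3)) * 5, label=f"m{i}")
            for i in range(3)
        ]
        S1 = pairwise_distance_similarity(members, max_pairs=100, seed=7)
        S2 = pairwise_distance_similarity(members, max_pairs=100, seed=7)
        assert S1.subsampled and np.array_equal(S1.values, S2.values)

    def test_too_few_atoms_rejected(self):
        a = build_structure([(0, 0, 0)])
        with pytest.raises(ValueError):
            pairwise_distance_similarity([a, a])


class TestStructureClusteringWrappers:
    def test_gromos_on_two_conformational_groups(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(12, 3)) * 5
        members = []
        for i in range(6):
            offset = np.zeros(3) if i < 3 else np.array([4.0, 0, 0])
            # non-rigid displacement of half the atoms makes two RMSD groups
            coords = base.copy()
            coords[:6] += offset
            coords += rng.normal(scale=0.05, size=base.shape)
            members.append(build_structure(coords, label=f"m{i}"))
        res = gromos_cluster(Ensemble(members), target_size=2)
        assert res.n_clusters == 2
        groups = {}
        for i, c in res.assignment.items():
            groups.setdefault(c, set()).add(i)
        assert set(map(frozenset, groups.values())) == {
            frozenset({0, 1, 2}),
            frozenset({3, 4, 5}),
        }

    def test_kmedoid_wrapper_returns_member_representatives(self):
        vals = np.abs(np.subtract.outer([0.0, 1.0, 10.0, 11.0], [0.0, 1.0, 10.0, 11.0]))
        res = kmedoid(SimilarityMatrix(vals), 2)
        assert res.n_clusters == 2
        assert set(res.representatives.values()) <= {0, 1, 2, 3}
        assert res.k_used == 2

    def test_rmsd_matrix_symmetric_zero_diagonal(self):
        members = make_traj(4, seed=5).members
        S = rmsd_matrix(members)
        assert np.allclose(S.values, S.values.T)
        assert np.allclose(np.diag(S.values), 0.0)


class TestMixedEnsemble:
    def test_seven_plus_seven(self):
        apo = make_traj(7, seed=1)
        holo = make_traj(7, seed=2)
        for m in holo:
            m.state_tag = "holo"
        mixed = mixed_ensemble(apo, holo)
        assert len(mixed) == 14

    def test_empty_apo_parent(self):
        holo = make_traj(3, seed=2)
        mixed = mixed_ensemble(Ensemble([]), holo)
        assert mixed.labels() == holo.labels()

    def test_labels_unique_after_merge(self):
        apo = make_traj(5, seed=1)
        holo = make_traj(5, seed=1)
        for m in holo:
            m.state_tag = "holo"
        mixed = mixed_ensemble(apo, holo)
        assert len(set(mixed.labels())) == 10


class TestMakePseudo:
    def _holo(self, rotate=None):
        rng = np.random.default_rng(9)
        protein = rng.normal(size=(20, 3)) * 5
        ligand = rng.normal(size=(4, 3)) * 1.5
        coords = np.vstack([protein, ligand])
        if rotate is not None:
            coords = coords @ rotate.T
        return build_structure(
            coords,
            resnames=["ALA"] * 20 + ["LIG"] * 4,
            hetatm=[False] * 20 + [True] * 4,
            resids=[("A", 1 + i // 8, "") for i in range(20)]
            + [("L", 99, "")] * 4,
            label="holo",
            state_tag="holo",
        )

    def test_remove_ligand_strips_ligand_atoms(self):
        holo = self._holo()
        pseudo = make_pseudo(holo=holo, direction="remove_ligand")
        assert len(pseudo) == 20
        assert pseudo.state_tag == "pseudo_apo"

    def test_add_ligand_identity_transform(self):
        holo = self._holo()
        apo = holo.without_ligand().with_tags(state_tag="apo", label="apo")
        pseudo = make_pseudo(holo=holo, apo=apo, direction="add_ligand")
        assert pseudo.state_tag == "pseudo_holo"
        lig = np.array([a.coord for a in pseudo.atoms if a.is_ligand])
        want = np.array([a.coord for a in holo.atoms if a.is_ligand])
        assert np.allclose(lig, want, atol=1e-6)

    def test_add_ligand_through_known_rotation(self):
        theta = np.deg2rad(30.0)
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1.0],
            ]
        )
        holo = self._holo()
        apo = self._holo(rotate=R).without_ligand().with_tags(state_tag="apo")
        pseudo = make_pseudo(holo=holo, apo=apo, direction="add_ligand")
        lig = np.array([a.coord for a in pseudo.atoms if a.is_ligand])
        want = np.array([a.coord for a in holo.atoms if a.is_ligand]) @ R.T
        assert np.allclose(lig, want, atol=1e-6)

    def test_no_ligand_rejected(self):
        apo = self._holo().without_ligand()
        with pytest.raises(ValueError):
            make_pseudo(holo=apo, direction="remove_ligand")
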