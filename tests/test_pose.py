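"""Pose transforms, membrane-topology analytics and QT clustering."""

import numpy as np
import pytest

from palmcensus import (
    Pose,
    ProtomerStructure,
    TopologyParams,
    apply_pose,
    filter_poses,
    pairwise_rmsd,
    plant_pose_clusters,
    qt_cluster,
    read_ca_coordinates,
    rmsd_matrix,
    topology_metrics,
)

from _oracles import greedy_qt_oracle


def rot_z(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_x(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def random_pose(rng, pid=-1, sigma_t=5.0):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    return Pose(rotation=R, translation=rng.normal(0, sigma_t, 3), id=pid)


@pytest.fixture
def structure(rng):
    return ProtomerStructure(ca_coords=rng.normal(0.0, 10.0, size=(40, 3)))


class TestReadCa:
    def test_ca_trace_in_file_order(self, tiny_pdb):
        s = read_ca_coordinates(tiny_pdb, chain="A")
        assert s.ca_coords.shape == (3, 3)
        assert np.allclose(s.ca_coords[1], [2.0, 0.0, 0.0])

    def test_centroid_hand_value(self, tiny_pdb):
        s = read_ca_coordinates(tiny_pdb, chain="A")
        assert np.allclose(s.centroid, [1.0, 1.0, 0.0])

    def test_malformed_atom_line_named(self, tmp_path, tiny_pdb):
        bad = tmp_path / "bad.pdb"
        text = tiny_pdb.read_text().replace("2.000", "xx.xx", 1)
        bad.write_text(text)
        with pytest.raises(ValueError, match="line 4"):
            read_ca_coordinates(bad, chain="A")

    def test_missing_chain_is_error(self, tiny_pdb):
        with pytest.raises(ValueError, match="chain 'B'"):
            read_ca_coordinates(tiny_pdb, chain="B")


class TestPose:
    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            Pose(rotation=np.eye(3) * 2.0, translation=np.zeros(3))

    def test_reflection_rejected(self):
        with pytest.raises(ValueError):
            Pose(rotation=np.diag([1.0, 1.0, -1.0]), translation=np.zeros(3))

    def test_identity_leaves_coordinates(self, structure):
        p = Pose(rotation=np.eye(3), translation=np.zeros(3))
        assert np.allclose(apply_pose(structure, p), structure.ca_coords)

    def test_half_turn_about_z(self):
        s = ProtomerStructure(ca_coords=[[1, 2, 3], [0, 0, 0], [1, 0, 0]])
        p = Pose(rotation=rot_z(np.pi), translation=np.zeros(3))
        assert np.allclose(apply_pose(s, p)[0], [-1.0, -2.0, 3.0])

    def test_composition_matches_composed_transform(self, structure, rng):
        a, b = random_pose(rng), random_pose(rng)
        # apply a then b == single pose (Rb Ra, Rb ta + tb)
        composed = Pose(
            rotation=b.rotation @ a.rotation,
            translation=b.rotation @ a.translation + b.translation,
        )
        two_step = apply_pose(
            ProtomerStructure(ca_coords=apply_pose(structure, a)), b
        )
        assert np.allclose(two_step, apply_pose(structure, composed))


class TestTopology:
    def test_identity_pose_passes(self, structure):
        m = topology_metrics(structure, Pose(np.eye(3), np.zeros(3)))
        assert m.tilt == 0.0 and m.z_offset == 0.0 and m.passes

    def test_in_plane_rotation_tilt_threshold(self, structure):
        """0.5 rad about an in-plane axis exceeds the 0.4 rad cap."""
        m = topology_metrics(structure, Pose(rot_x(0.5), np.zeros(3)))
        assert m.tilt == pytest.approx(0.5, abs=1e-9)
        assert not m.passes

    def test_vertical_translation_zoffset_threshold(self, structure):
        """A 7 A vertical shift exceeds the 6.0 A cap."""
        m = topology_metrics(structure, Pose(np.eye(3), np.array([0, 0, 7.0])))
        assert m.tilt == 0.0 and m.z_offset == pytest.approx(7.0)
        assert not m.passes

    def test_rotation_about_normal_never_tilts(self, structure, rng):
        for _ in range(20):
            theta = rng.uniform(0, 2 * np.pi)
            m = topology_metrics(structure, Pose(rot_z(theta), np.zeros(3)))
            assert m.tilt == pytest.approx(0.0, abs=1e-7)

    def test_filter_monotone_in_thresholds(self, structure, rng):
        poses = [random_pose(rng, pid=k, sigma_t=3.0) for k in range(60)]
        tight = TopologyParams(tilt_max=0.2, zoffset_max=3.0)
        loose = TopologyParams(tilt_max=0.4, zoffset_max=6.0)
        kept_tight = {p.id for p in filter_poses(structure, poses, tight)}
        kept_loose = {p.id for p in filter_poses(structure, poses, loose)}
        assert kept_tight <= kept_loose


class TestFilterPoses:
    def test_empty_input(self, structure):
        assert filter_poses(structure, []) == []

    def test_truncation_to_best_4000(self, structure):
        """Of 5000 passing poses only the 4000 best-scored are considered."""
        poses = [
            Pose(np.eye(3), np.zeros(3), score=float(k), id=k) for k in range(5000)
        ]
        kept = filter_poses(structure, poses)
        assert len(kept) == 4000
        assert {p.id for p in kept} == set(range(1000, 5000))
        scores = [p.score for p in kept]
        assert scores == sorted(scores, reverse=True)

    def test_output_all_pass(self, structure, rng):
        poses = [random_pose(rng, pid=k) for k in range(100)]
        for p in filter_poses(structure, poses):
            assert topology_metrics(structure, p).passes


class TestRMSD:
    def test_identical_poses_zero(self, structure, rng):
        p = random_pose(rng)
        assert pairwise_rmsd(structure, p, p) == 0.0

    def test_uniform_translation_equals_norm(self, structure):
        a = Pose(np.eye(3), np.zeros(3))
        b = Pose(np.eye(3), np.array([0.0, 0.0, 1.0]))
        assert pairwise_rmsd(structure, a, b) == pytest.approx(1.0)

    def test_symmetry(self, structure, rng):
        for _ in range(10):
            a, b = random_pose(rng), random_pose(rng)
            assert pairwise_rmsd(structure, a, b) == pytest.approx(
                pairwise_rmsd(structure, b, a)
            )

    def test_matrix_matches_pairwise(self, structure, rng):
        poses = [random_pose(rng) for _ in range(6)]
        m = rmsd_matrix(structure, poses)
        for i in range(6):
            for j in range(6):
                assert m[i, j] == pytest.approx(
                    pairwise_rmsd(structure, poses[i], poses[j])
                )


class TestQTCluster:
    def test_single_pose_singleton(self, structure, rng):
        p = random_pose(rng, pid=0)
        (c,) = qt_cluster(structure, [p])
        assert c.member_ids == (0,) and c.center_id == 0 and c.population == 1

    def test_three_pose_chain_centered_at_middle(self, structure):
        """Translations at x = 0, 2, 4 A: only B neighbours both, one cluster."""
        poses = [
            Pose(np.eye(3), np.array([2.0 * k, 0, 0]), id=k) for k in range(3)
        ]
        clusters = qt_cluster(structure, poses)
        assert len(clusters) == 1
        assert clusters[0].center_id == 1
        assert clusters[0].member_ids == (0, 1, 2)

    def test_matches_exhaustive_oracle(self, structure, rng):
        params = TopologyParams()
        for _ in range(20):
            n = int(rng.integers(1, 13))
            poses = [random_pose(rng, pid=k, sigma_t=2.0) for k in range(n)]
            got = [
                (c.center_id, frozenset(c.member_ids))
                for c in qt_cluster(structure, poses, params)
            ]
            dmat = rmsd_matrix(structure, poses)
            assert got == greedy_qt_oracle(dmat, range(n), params.rmsd_threshold)

    def test_partition_and_radius_invariants(self, structure, rng):
        poses = [random_pose(rng, pid=k, sigma_t=2.0) for k in range(40)]
        params = TopologyParams()
        clusters = qt_cluster(structure, poses, params)
        seen = sorted(i for c in clusters for i in c.member_ids)
        assert seen == list(range(40))
        by_id = {p.id: p for p in poses}
        for c in clusters:
            for m in c.member_ids:
                assert (
                    pairwise_rmsd(structure, by_id[c.center_id], by_id[m])
                    <= params.rmsd_threshold + 1e-12
                )
        pops = [c.population for c in clusters]
        assert pops == sorted(pops, reverse=True)

    def test_planted_clusters_recovered(self, structure):
        poses, labels = plant_pose_clusters(
            n_clusters=4, members_per_cluster=6, seed=3
        )
        clusters = qt_cluster(structure, poses)
        assert len(clusters) == 4
        got = {frozenset(c.member_ids) for c in clusters}
        want = {
            frozenset(i for i, l in enumerate(labels) if l == c) for c in range(4)
        }
        assert got == want
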