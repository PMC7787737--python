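"""Robust-PCA features, fuzzy c-means clustering and region extraction."""

import numpy as np
import pytest

from cranioface.meshkit import CorrespondedPair, SampleSet, TriMesh
from cranioface import segmentation as seg


def grid_mesh(rows, cols):
    """Open rectangular grid mesh in the z=0 plane."""
    xs, ys = np.meshgrid(np.arange(cols), np.arange(rows))
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(rows * cols)]).astype(float)
    faces = []
    v = lambda i, j: i * cols + j
    for i in range(rows - 1):
        for j in range(cols - 1):
            faces.append([v(i, j), v(i, j + 1), v(i + 1, j + 1)])
            faces.append([v(i, j), v(i + 1, j + 1), v(i + 1, j)])
    return TriMesh(verts, np.asarray(faces))


class TestRPCA:
    def test_exact_low_rank_input(self, rng):
        u = rng.normal(size=(40, 1))
        v = rng.normal(size=(1, 12))
        X = u @ v
        L, S = seg.rpca_decompose(X, tol=1e-10, max_iter=1000)
        assert np.linalg.norm(X - L) / np.linalg.norm(X) < 1e-6
        assert np.abs(S).max() < 1e-6

    def test_zero_matrix(self):
        L, S = seg.rpca_decompose(np.zeros((10, 5)))
        assert not L.any() and not S.any()

    def test_planted_sparse_corruption_recovered(self, rng):
        U = rng.normal(size=(100, 2))
        V = rng.normal(size=(2, 20))
        L0 = U @ V
        S0 = np.zeros_like(L0)
        mask = rng.random(L0.shape) < 0.05
        S0[mask] = rng.normal(0, 10, mask.sum())
        L, S = seg.rpca_decompose(L0 + S0, max_iter=2000, tol=1e-10)
        assert np.linalg.norm(L - L0) / np.linalg.norm(L0) < 1e-4

    def test_reconstruction_identity(self, rng):
        X = rng.normal(size=(30, 10))
        L, S = seg.rpca_decompose(X, tol=1e-8, max_iter=500)
        assert np.linalg.norm(X - L - S) / np.linalg.norm(X) < 1e-7


class TestReduceFeatures:
    def test_preserves_distances_in_subspace(self, rng):
        basis = np.linalg.qr(rng.normal(size=(10, 3)))[0]
        rows = rng.normal(size=(50, 3)) @ basis.T  # rows live in a 3-dim subspace
        red = seg.reduce_features(rows, 3).values
        d_orig = np.linalg.norm(rows[:, None] - rows[None], axis=-1)
        d_red = np.linalg.norm(red[:, None] - red[None], axis=-1)
        np.testing.assert_allclose(d_red, d_orig, atol=1e-9)

    def test_planted_clusters_stay_separated(self, rng):
        a = rng.normal(0, 0.2, (30, 8)) + 4.0
        b = rng.normal(0, 0.2, (30, 8)) - 4.0
        red = seg.reduce_features(np.vstack([a, b]), 2).values
        between = np.linalg.norm(red[:30].mean(0) - red[30:].mean(0))
        within = max(
            np.sqrt(((red[:30] - red[:30].mean(0)) ** 2).sum(1).mean()),
            np.sqrt(((red[30:] - red[30:].mean(0)) ** 2).sum(1).mean()),
        )
        assert between > 5 * within

    def test_d_too_large(self, rng):
        with pytest.raises(ValueError):
            seg.reduce_features(rng.normal(size=(5, 3)), 4)


class TestFCM:
    def test_membership_hand_case_and_zero_distance(self):
        # fixed centers 0 and 1; memberships evaluated without center updates
        X = np.array([[0.0], [1.0], [0.25]])
        U = seg.fcm_cluster(X, C=2, m=2.0, max_iter=0, init_centers=[[0.0], [1.0]])
        np.testing.assert_allclose(U.U[:, 2], [0.9, 0.1], atol=1e-12)
        # coincident points take full membership in their center
        np.testing.assert_allclose(U.U[:, 0], [1.0, 0.0])
        np.testing.assert_allclose(U.U[:, 1], [0.0, 1.0])

    def test_two_blobs_recovered(self, rng):
        a = rng.normal(0, 0.05, (40, 2))
        b = rng.normal(0, 0.05, (40, 2)) + 5.0
        X = np.vstack([a, b])
        U = seg.fcm_cluster(X, C=2, seed=0)
        assert U.U.max(axis=0).min() > 0.99
        labels = seg.assign_labels(U)
        assert len(set(labels[:40])) == 1 and len(set(labels[40:])) == 1
        assert labels[0] != labels[40]

    def test_column_sums_and_objective_monotone(self, rng):
        X = rng.normal(size=(200, 4))
        U = seg.fcm_cluster(X, C=3, seed=1)
        assert U.max_colsum_dev < 1e-12
        J = np.array(U.J_history)
        assert np.all(np.diff(J) <= 1e-9 * J[0])

    def test_duplicated_point_gets_identical_label(self, rng):
        X = rng.normal(size=(60, 3))
        X2 = np.vstack([X, X[-1]])
        U = seg.fcm_cluster(X2, C=3, seed=0)
        labels = seg.assign_labels(U)
        assert labels[-1] == labels[-2]

    def test_parameter_validation(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            seg.fcm_cluster(X, C=1)
        with pytest.raises(ValueError):
            seg.fcm_cluster(X, C=2, m=1.0)


class TestAssignLabels:
    def test_argmax_and_tie_rule(self):
        U = np.array([[0.2, 0.5, 0.5], [0.5, 0.5, 0.2], [0.3, 0.0, 0.3]])
        np.testing.assert_array_equal(seg.assign_labels(U), [1, 0, 0])

    def test_one_hot(self):
        U = np.eye(3)[:, [2, 0, 1]]
        np.testing.assert_array_equal(seg.assign_labels(U), [2, 0, 1])


class TestMerge:
    def _membership(self, centers, X):
        from scipy.spatial.distance import cdist

        U = seg._fcm_memberships(cdist(np.asarray(centers, float), X, "sqeuclidean"), 2.0)
        return seg.MembershipMatrix(U, np.asarray(centers, float), 2.0)

    def test_identical_centers_merge_first(self, rng):
        X = rng.normal(size=(20, 2))
        U = self._membership([[0, 0], [0, 0], [5, 5]], X)
        labels = seg.assign_labels(U)
        merged, new_labels = seg.merge_similar_regions(U, labels, tau=1.0, target_count=2)
        assert merged.n_clusters == 2

    def test_tau_zero_blocks_merging(self, rng):
        X = rng.normal(size=(20, 2))
        U = self._membership([[0, 0], [1, 1], [5, 5]], X)
        labels = seg.assign_labels(U)
        with pytest.raises(ValueError, match="cannot reach"):
            seg.merge_similar_regions(U, labels, tau=0.0, target_count=2)

    def test_duplicated_pairs_merged_to_target(self, rng):
        X = rng.normal(size=(50, 2)) * 10
        centers = [[0, 0], [0.01, 0], [10, 0], [10.01, 0], [0, 10], [20, 20], [-10, -10]]
        U = self._membership(centers, X)
        labels = seg.assign_labels(U)
        merged, _ = seg.merge_similar_regions(U, labels, tau=0.5, target_count=5)
        assert merged.n_clusters == 5


class TestRegionOps:
    def test_submesh_whole_region_is_identity(self):
        mesh = grid_mesh(3, 3)
        labels = np.zeros(mesh.n_vertices, dtype=int)
        sub, idx = seg.region_submesh(mesh, labels, 0)
        np.testing.assert_array_equal(sub.vertices, mesh.vertices)
        assert sub.n_faces == mesh.n_faces

    def test_single_triangle_region(self):
        mesh = grid_mesh(2, 2)
        labels = np.zeros(4, dtype=int)
        labels[[0, 1, 3]] = 1
        sub, idx = seg.region_submesh(mesh, labels, 1)
        assert sub.n_vertices == 3 and sub.n_faces == 1
        np.testing.assert_array_equal(sorted(idx), [0, 1, 3])

    def test_submesh_vertices_carry_region_label(self, rng):
        mesh = grid_mesh(6, 6)
        labels = rng.integers(0, 2, mesh.n_vertices)
        try:
            sub, idx = seg.region_submesh(mesh, labels, 1)
        except ValueError:
            return  # no complete face for this draw
        assert np.all(labels[idx] == 1)

    def test_boundary_of_single_triangle(self):
        mesh = grid_mesh(2, 2)
        labels = np.zeros(4, dtype=int)
        labels[[0, 1, 3]] = 1
        loops = seg.region_boundary(mesh, labels, 1)
        assert len(loops) == 1 and sorted(loops[0]) == [0, 1, 3]

    def test_closed_mesh_has_empty_boundary(self):
        from cranioface.synthetic import GeneratorConfig, make_template

        skull, _, _ = make_template(GeneratorConfig(n_theta=8, n_phi=8))
        labels = np.zeros(skull.n_vertices, dtype=int)
        assert seg.region_boundary(skull, labels, 0) == []

    def test_disc_region_loop_matches_edge_census(self):
        mesh = grid_mesh(7, 7)
        labels = np.zeros(mesh.n_vertices, dtype=int)
        disc = [i * 7 + j for i in range(1, 5) for j in range(1, 5)]
        labels[disc] = 1
        loops = seg.region_boundary(mesh, labels, 1)
        assert len(loops) == 1
        # brute-force census of one-sided edges over region faces
        keep = (labels[mesh.faces] == 1).all(axis=1)
        edges = {}
        for f in mesh.faces[keep]:
            for e in [(f[0], f[1]), (f[1], f[2]), (f[2], f[0])]:
                k = tuple(sorted(e))
                edges[k] = edges.get(k, 0) + 1
        n_boundary_edges = sum(1 for c in edges.values() if c == 1)
        assert len(loops[0]) == n_boundary_edges  # a closed loop: #edges == #vertices


def test_transfer_labels_identity_on_same_shape(rng):
    verts = rng.normal(size=(50, 3)) * 10
    labels = rng.integers(0, 3, 50)
    lab = seg.RegionLabeling(labels, {0: "a", 1: "b", 2: "c"}, "face")
    out = seg.transfer_labels(lab, verts, verts, "skull")
    np.testing.assert_array_equal(out.labels, labels)


class TestFeatureBuild:
    def _samples(self, n, jitter):
        base = grid_mesh(3, 3)
        g = np.random.default_rng(0)
        pairs = []
        for i in range(n):
            off = jitter * g.normal(size=base.vertices.shape) if i else 0.0
            m = base.with_vertices(base.vertices + off)
            pairs.append(CorrespondedPair(f"s{i}", m, m.copy(), 30.0, 22.0))
        return SampleSet(pairs)

    def test_identical_samples_reduce_to_positions(self):
        ss = self._samples(2, jitter=0.0)
        fm = seg.build_vertex_features(ss, "face")
        # trajectory block (all columns after the first 3) is exactly zero
        assert not fm.values[:, 3:].any()

    def test_single_sample_rejected(self):
        ss = self._samples(1, jitter=0.0)
        with pytest.raises(ValueError):
            seg.build_vertex_features(ss, "face")

    def test_displacement_localized_to_sample_columns(self):
        base = grid_mesh(3, 3)
        moved = base.copy()
        moved.vertices[4] += [0, 0, 5.0]
        ss = SampleSet(
            [
                CorrespondedPair("a", base, base.copy(), 30, 22),
                CorrespondedPair("b", base.copy(), moved, 30, 22),
            ]
        )
        fm = seg.build_vertex_features(ss, "face")
        traj = fm.values[:, 3:]
        # the displaced vertex's trajectory row is the outlier; all other
        # rows are identical (column centering leaves them equal)
        mask = np.ones(len(traj), bool)
        mask[4] = False
        assert np.ptp(traj[mask], axis=0).max() == 0.0
        assert np.abs(traj[4] - traj[0]).max() > 0
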