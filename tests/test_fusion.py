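"""Rigid alignment, contour shrinking, TPS splicing and region fusion."""

import numpy as np
import pytest
from scipy.interpolate import RBFInterpolator

from cranioface.meshkit import TriMesh
from cranioface.fusion import (
    RegionPart,
    fit_tps,
    fuse_regions,
    midpoint_targets,
    rigid_align,
    shrink_contour,
)


def grid_mesh(rows, cols, bulge=0.0):
    xs, ys = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    zs = bulge * np.sin(xs / 3.0) * np.cos(ys / 3.0)
    verts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
    faces = []
    v = lambda i, j: i * cols + j
    for i in range(rows - 1):
        for j in range(cols - 1):
            faces.append([v(i, j), v(i, j + 1), v(i + 1, j + 1)])
            faces.append([v(i, j), v(i + 1, j + 1), v(i + 1, j)])
    return TriMesh(verts, np.asarray(faces))


class TestRigidAlign:
    def test_identity_for_equal_sets(self, rng):
        P = rng.normal(size=(10, 3))
        tf = rigid_align(P, P)
        np.testing.assert_allclose(tf.R, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(tf.T, 0, atol=1e-10)

    def test_recovers_planted_rotation_translation(self, rng):
        P0 = rng.normal(size=(10, 3))
        th = np.deg2rad(30)
        Rz = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        t = np.array([1.0, 2.0, 3.0])
        tf = rigid_align(P0, P0 @ Rz.T + t)
        np.testing.assert_allclose(tf.R, Rz, atol=1e-8)
        np.testing.assert_allclose(tf.T, t, atol=1e-8)

    def test_mirrored_target_still_proper_rotation(self, rng):
        P0 = rng.normal(size=(12, 3))
        P1 = P0 * [-1.0, 1.0, 1.0]
        tf = rigid_align(P0, P1)
        assert np.linalg.det(tf.R) == pytest.approx(1.0, abs=1e-9)

    def test_residual_no_worse_than_identity(self, rng):
        P0 = rng.normal(size=(15, 3))
        P1 = P0 + rng.normal(0, 0.3, P0.shape)
        tf = rigid_align(P0, P1)
        assert np.linalg.norm(tf.apply(P0) - P1) <= np.linalg.norm(P0 - P1) + 1e-12

    def test_degenerate_configuration_rejected(self):
        P = np.zeros((5, 3))
        with pytest.raises(ValueError):
            rigid_align(P, P + 1.0)


class TestShrinkContour:
    def test_grid_strip_rings_match_bfs_oracle(self):
        mesh = grid_mesh(6, 20)  # unit edge lengths (plus diagonals)
        boundary = np.arange(20)  # top row
        side = np.ones(mesh.n_vertices, bool)
        side[boundary] = False
        inner, band, k = shrink_contour(mesh, boundary, s0=2.0, side_mask=side)
        assert k == 2
        # ring distance on this grid equals the row index
        np.testing.assert_array_equal(inner, np.arange(2 * 20, 3 * 20))
        np.testing.assert_array_equal(band, np.arange(0, 2 * 20))

    def test_small_s0_gives_boundary_only_band(self):
        mesh = grid_mesh(5, 10)
        boundary = np.arange(10)
        side = np.ones(mesh.n_vertices, bool)
        side[boundary] = False
        inner, band, k = shrink_contour(mesh, boundary, s0=0.5, side_mask=side)
        assert k == 1
        np.testing.assert_array_equal(band, boundary)
        np.testing.assert_array_equal(inner, np.arange(10, 20))

    def test_thin_side_reduces_k_with_warning(self):
        mesh = grid_mesh(3, 10)
        boundary = np.arange(10)
        side = np.ones(mesh.n_vertices, bool)
        side[boundary] = False
        with pytest.warns(UserWarning, match="thinner"):
            inner, band, k = shrink_contour(mesh, boundary, s0=5.0, side_mask=side)
        assert k == 2

    def test_empty_boundary_rejected(self):
        mesh = grid_mesh(4, 4)
        with pytest.raises(ValueError, match="whole mesh"):
            shrink_contour(mesh, np.array([], dtype=int), 1.0, np.ones(16, bool))


class TestMidpoint:
    def test_basic_and_symmetry(self):
        a = np.array([[0.0, 0.0, 0.0]])
        b = np.array([[2.0, 4.0, 6.0]])
        np.testing.assert_array_equal(midpoint_targets(a, b), [[1, 2, 3]])
        np.testing.assert_array_equal(midpoint_targets(a, b), midpoint_targets(b, a))
        np.testing.assert_array_equal(midpoint_targets(a, a), a)

    def test_count_mismatch(self):
        with pytest.raises(ValueError):
            midpoint_targets(np.zeros((2, 3)), np.zeros((3, 3)))


class TestTPS:
    def test_identity_map(self, rng):
        C = rng.normal(size=(8, 3))
        tps = fit_tps(C, C)
        assert np.abs(tps.warp_coef).max() < 1e-8
        np.testing.assert_allclose(tps.affine_coef[1:], np.eye(3), atol=1e-8)
        Q = rng.normal(size=(20, 3))
        np.testing.assert_allclose(tps.apply(Q), Q, atol=1e-7)

    def test_reproduces_affine_maps_exactly(self, rng):
        C = rng.normal(size=(10, 3))
        A = rng.normal(size=(3, 3))
        t = rng.normal(size=3)
        tps = fit_tps(C, C @ A.T + t)
        Q = rng.normal(size=(15, 3))
        np.testing.assert_allclose(tps.apply(Q), Q @ A.T + t, atol=1e-8)

    def test_interpolates_random_targets_and_matches_scipy(self, rng):
        C = rng.normal(size=(6, 3))
        T = rng.normal(size=(6, 3))
        tps = fit_tps(C, T)
        np.testing.assert_allclose(tps.apply(C), T, atol=1e-8)
        oracle = RBFInterpolator(C, T, kernel="cubic", smoothing=0.0)
        Q = rng.normal(size=(10, 3))
        np.testing.assert_allclose(tps.apply(Q), oracle(Q), atol=1e-8)

    def test_too_few_controls_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_tps(rng.normal(size=(3, 3)), rng.normal(size=(3, 3)))

    def test_coplanar_controls_still_interpolate(self, rng):
        # flat mesh patches are legitimate; the least-squares fallback must
        # still be exact at the controls
        C = rng.normal(size=(8, 3))
        C[:, 2] = 0.0
        T = rng.normal(size=(8, 3))
        tps = fit_tps(C, T)
        np.testing.assert_allclose(tps.apply(C), T, atol=1e-7)


def disc_part(mesh, rows=(3, 8), cols=(3, 12), ncols=16):
    idx = np.array([i * ncols + j for i in range(*rows) for j in range(*cols)])
    return idx


class TestFuseRegions:
    def _setup(self, bulge=0.5):
        base = grid_mesh(12, 16, bulge=bulge)
        idx = disc_part(base)
        return base, idx

    def test_identical_part_is_idempotent(self):
        base, idx = self._setup()
        part = RegionPart("disc", idx, base.vertices[idx])
        fused, info = fuse_regions(base, [part], s0=2.0)
        np.testing.assert_allclose(fused.vertices, base.vertices, atol=1e-9)

    def test_translated_part_seam_profile_without_alignment(self):
        base, idx = self._setup(bulge=0.0)
        offset = np.array([0.0, 0.0, 1.0])
        part = RegionPart("disc", idx, base.vertices[idx] + offset)
        fused, info = fuse_regions(base, [part], s0=2.0, align=False)
        disp = fused.vertices - base.vertices
        prov = info["provenance"]
        seam = np.array([p.startswith("seam") for p in prov])
        band = np.array([p.startswith("band") for p in prov])
        outside = np.array([p == "base" for p in prov])
        partv = np.array([p.startswith("part") for p in prov])
        # seam at exactly half the offset (midpoint rule)
        np.testing.assert_allclose(disp[seam], np.tile(0.5 * offset, (seam.sum(), 1)), atol=1e-9)
        # deep part vertices carry the full offset
        np.testing.assert_allclose(disp[partv], np.tile(offset, (partv.sum(), 1)), atol=1e-9)
        # untouched base vertices are bit-identical
        assert np.array_equal(fused.vertices[outside], base.vertices[outside])
        # band displacements interpolate between the two levels
        z = disp[band, 2]
        assert z.min() > -0.2 and z.max() < 1.2

    def test_alignment_undoes_pure_translation(self):
        base, idx = self._setup()
        part = RegionPart("disc", idx, base.vertices[idx] + [0, 0, 1.0])
        fused, _ = fuse_regions(base, [part], s0=2.0, align=True)
        np.testing.assert_allclose(fused.vertices, base.vertices, atol=1e-6)

    def test_seam_functions_agree_at_midpoints(self):
        # the two interpolants of a splice must coincide on the seam
        base, idx = self._setup(bulge=0.3)
        rng = np.random.default_rng(0)
        part = RegionPart("disc", idx, base.vertices[idx] + rng.normal(0, 0.2, (len(idx), 3)))
        fused, info = fuse_regions(base, [part], s0=2.0, align=False)
        prov = info["provenance"]
        seam = np.flatnonzero([p.startswith("seam") for p in prov])
        pos = np.full((base.n_vertices, 3), np.nan)
        pos[part.indices] = part.positions
        P2 = 0.5 * (pos[seam] + base.vertices[seam])
        np.testing.assert_allclose(fused.vertices[seam], P2, atol=1e-9)

    def test_self_fusion_of_feature_regions_recovers_face(self):
        from cranioface.synthetic import GeneratorConfig, make_template

        _, face, labeling = make_template(GeneratorConfig(n_theta=24, n_phi=24))
        parts = [
            RegionPart(name, labeling.vertices_of(name), face.vertices[labeling.vertices_of(name)])
            for name in ("left_eye", "right_eye", "nose", "mouth")
        ]
        fused, _ = fuse_regions(face, parts, s0=3.0 * face.mean_edge_length(), on_overlap="skip")
        assert np.abs(fused.vertices - face.vertices).max() < 1e-6

    def test_part_covering_whole_mesh_rejected(self):
        base = grid_mesh(6, 6)
        part = RegionPart("all", np.arange(36), base.vertices)
        with pytest.raises(ValueError, match="boundary"):
            fuse_regions(base, [part], s0=1.0)

    def test_overlapping_bands_error_vs_skip(self):
        base = grid_mesh(12, 16)
        left = disc_part(base, rows=(3, 8), cols=(2, 7))
        right = disc_part(base, rows=(3, 8), cols=(8, 13))
        parts = [
            RegionPart("l", left, base.vertices[left] + [0, 0, 0.5]),
            RegionPart("r", right, base.vertices[right] - [0, 0, 0.5]),
        ]
        with pytest.raises(ValueError, match="overlaps"):
            fuse_regions(base, parts, s0=2.0, align=False, on_overlap="error")
        fused, _ = fuse_regions(base, parts, s0=2.0, align=False, on_overlap="skip")
        assert np.all(np.isfinite(fused.vertices))

    def test_topology_preserved(self):
        base, idx = self._setup()
        part = RegionPart("disc", idx, base.vertices[idx] + [0.1, 0, 0.3])
        fused, _ = fuse_regions(base, [part], s0=2.0, align=False)
        np.testing.assert_array_equal(fused.faces, base.faces)
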