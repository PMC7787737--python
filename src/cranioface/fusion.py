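"""Fusing regional face reconstructions into one smooth mesh.

Each feature-region reconstruction (eyes, nose, mouth) is spliced onto a
base mesh carrying the frame reconstruction on the shared global topology:

1. optional rigid positioning of the part onto the base (orthogonal
   Procrustes over the region's corresponding vertices, rotation +
   translation only, reflections disallowed);
2. boundary-band construction: the region's interface contour B0 is shrunk
   k rings into the region (B0') and k rings outward into the base side
   (B1'), with k derived from the blending width S0 and the mean edge
   length;
3. smooth splicing with a pair of 3-D thin-plate splines: f0 fixes the
   inner contour and sends the part's boundary positions P0 to the midpoint
   targets P2 = (P0 + P1)/2, f1 fixes the outer contour and sends the base
   boundary positions P1 to the same P2, so both sides meet exactly at the
   seam while vertices beyond the bands are untouched.

Band shrinking uses graph (ring) distance on the global topology scaled by
the mean edge length; S0 is expressed in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .meshkit import TriMesh

__all__ = [
    "RigidTransform",
    "TPSMap",
    "RegionPart",
    "rigid_align",
    "shrink_contour",
    "midpoint_targets",
    "fit_tps",
    "apply_tps",
    "fuse_regions",
]


# ---------------------------------------------------------------------------
# Rigid alignment (orthogonal Procrustes / Kabsch, no scaling)


@dataclass
class RigidTransform:
    """x -> R @ x + T with R a proper rotation."""

    R: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, float).reshape(3, 3)
        self.T = np.asarray(self.T, float).reshape(3)
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-8):
            raise ValueError("R is not orthonormal")
        if np.linalg.det(self.R) < 0:
            raise ValueError("R is a reflection (det < 0)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.R.T + self.T


def rigid_align(P0: np.ndarray, P1: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping point set P0 onto P1.

    Minimizes sum ||R p0 + T - p1||^2 with det(R) = +1 enforced (Kabsch).
    """
    P0 = np.asarray(P0, float).reshape(-1, 3)
    P1 = np.asarray(P1, float).reshape(-1, 3)
    if P0.shape != P1.shape or len(P0) < 3:
        raise ValueError("need >= 3 corresponding 3-D points")
    c0 = P0.mean(axis=0)
    c1 = P1.mean(axis=0)
    A = P0 - c0
    B = P1 - c1
    H = A.T @ B
    if np.linalg.matrix_rank(H) < 2:
        raise ValueError("degenerate (rank-deficient) point configuration")
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    S = np.diag([1.0, 1.0, d])
    R = Vt.T @ S @ U.T
    T = c1 - R @ c0
    return RigidTransform(R, T)


# ---------------------------------------------------------------------------
# Contour shrinking by breadth-first ring distance


def _bfs_rings(adjacency, seeds, allowed: np.ndarray, kmax: int) -> dict[int, int]:
    """Graph distance from the seed set, expanding only through ``allowed``
    vertices, up to kmax rings."""
    seeds_set = set(int(s) for s in seeds)
    dist: dict[int, int] = {}
    frontier = list(seeds_set)
    for level in range(1, kmax + 1):
        nxt = []
        for v in frontier:
            for w in adjacency[v]:
                w = int(w)
                if allowed[w] and w not in dist and w not in seeds_set:
                    dist[w] = level
                    nxt.append(w)
        frontier = nxt
        if not frontier:
            break
    return dist


def shrink_contour(
    mesh: TriMesh,
    boundary: np.ndarray,
    s0: float,
    side_mask: np.ndarray,
    adjacency=None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Shrink a boundary contour k rings into one side of the mesh.

    k = max(1, round(s0 / mean edge length)).  Returns (inner_contour,
    band, k_used): the inner contour holds vertices at ring distance
    exactly k from the boundary within ``side_mask``; the band holds the
    boundary itself plus vertices at distances 1..k-1.  If the side is
    thinner than k rings, k is reduced with a warning.
    """
    boundary = np.asarray(boundary, dtype=np.int64)
    if not len(boundary):
        raise ValueError("empty boundary: region covers the whole mesh")
    side_mask = np.asarray(side_mask, bool)
    if adjacency is None:
        adjacency = mesh.vertex_adjacency()
    k = max(1, int(round(s0 / mesh.mean_edge_length())))
    dist = _bfs_rings(adjacency, boundary, side_mask, k)
    if dist:
        kmax_avail = max(dist.values())
    else:
        kmax_avail = 0
    if kmax_avail < k:
        if kmax_avail == 0:
            warnings.warn("side has no interior beyond the boundary; band is the boundary only")
            return np.empty(0, dtype=np.int64), boundary.copy(), 0
        warnings.warn(f"side thinner than {k} rings; reducing blend width to {kmax_avail}")
        k = kmax_avail
    inner = np.array(sorted(v for v, d in dist.items() if d == k), dtype=np.int64)
    band = np.array(
        sorted(set(boundary.tolist()) | {v for v, d in dist.items() if d < k}), dtype=np.int64
    )
    return inner, band, k


def midpoint_targets(B0_points: np.ndarray, B1_points: np.ndarray) -> np.ndarray:
    """Element-wise midpoints P2 = (P0 + P1)/2 of corresponding contours."""
    P0 = np.asarray(B0_points, float)
    P1 = np.asarray(B1_points, float)
    if P0.shape != P1.shape:
        raise ValueError("contour point counts do not match")
    return 0.5 * (P0 + P1)


# ---------------------------------------------------------------------------
# Thin-plate splines in 3-D (polyharmonic r^3 + affine, pure interpolation)


@dataclass
class TPSMap:
    """A 3-D thin-plate-spline map, exact at its control points."""

    controls: np.ndarray
    targets: np.ndarray
    warp_coef: np.ndarray  # (n, 3)
    affine_coef: np.ndarray  # (4, 3): [1, x, y, z] rows

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        K = cdist(pts, self.controls) ** 3
        P = np.hstack([np.ones((len(pts), 1)), pts])
        out = K @ self.warp_coef + P @ self.affine_coef
        return out if np.asarray(points).ndim == 2 else out[0]


def fit_tps(controls: np.ndarray, targets: np.ndarray) -> TPSMap:
    """Fit the interpolating 3-D TPS sending each control point to its target.

    Solves the standard KKT system with the r^3 radial kernel, an affine
    part and the side conditions P^T w = 0; no bending regularization, so
    the map is exact at every control and reproduces affine maps exactly.
    """
    C = np.asarray(controls, float).reshape(-1, 3)
    T = np.asarray(targets, float).reshape(-1, 3)
    if C.shape != T.shape:
        raise ValueError("controls/targets shape mismatch")
    n = len(C)
    if n < 4:
        raise ValueError("need >= 4 control points for a 3-D TPS")
    K = cdist(C, C) ** 3
    P = np.hstack([np.ones((n, 1)), C])
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = T
    # coplanar controls (flat mesh patches) make the affine block rank
    # deficient; the minimum-norm least-squares solution still interpolates
    degenerate = np.linalg.matrix_rank(P) < 4
    try:
        if degenerate:
            raise np.linalg.LinAlgError("rank-deficient polynomial block")
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(A, rhs, rcond=None)[0]
    tps = TPSMap(C, T, sol[:n], sol[n:])
    resid = np.abs(tps.apply(C) - T).max()
    if resid > 1e-6:
        raise np.linalg.LinAlgError(f"TPS interpolation residual too large: {resid:.3g} mm")
    return tps


def apply_tps(tps: TPSMap, points: np.ndarray) -> np.ndarray:
    """Evaluate the TPS (affine + warp) at query points."""
    return tps.apply(points)


# ---------------------------------------------------------------------------
# Full region fusion


@dataclass
class RegionPart:
    """One regional reconstruction to splice onto the base.

    ``indices`` are global vertex ids of the region; ``positions`` the
    reconstructed coordinates of those vertices (same order).
    """

    name: str
    indices: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        if len(self.indices) != len(self.positions):
            raise ValueError("indices/positions length mismatch")

    @classmethod
    def from_submesh(cls, name: str, submesh: TriMesh, index_map: np.ndarray) -> "RegionPart":
        return cls(name, index_map, submesh.vertices)


def fuse_regions(
    base: TriMesh,
    parts: list[RegionPart],
    s0: float,
    align: bool = True,
    on_overlap: str = "error",
) -> tuple[TriMesh, dict]:
    """Splice regional reconstructions onto the base mesh.

    Returns the fused mesh on the base topology and a provenance dict with,
    per vertex, the source ('base', 'part:<name>', 'seam:<name>' or
    'band:<name>').  Vertices outside all blend bands keep their input
    coordinates exactly.  Parts are processed largest-boundary first.

    ``on_overlap`` controls what happens when two parts' blend bands would
    touch the same base vertex: 'error' raises (the default — with feature
    regions separated by frame, overlap signals misuse), 'skip' gives the
    vertex to the first part processed and keeps later bands out of any
    other part's region, which is the right behaviour when data-driven
    regions tile the surface.
    """
    if on_overlap not in ("error", "skip"):
        raise ValueError("on_overlap must be 'error' or 'skip'")
    out = base.vertices.copy()
    provenance = np.array(["base"] * base.n_vertices, dtype=object)
    adjacency = base.vertex_adjacency()
    claimed = np.zeros(base.n_vertices, dtype=bool)
    any_part = np.zeros(base.n_vertices, dtype=bool)
    for part in parts:
        any_part[part.indices] = True

    def boundary_of(mask: np.ndarray) -> np.ndarray:
        idx = np.flatnonzero(mask)
        return np.array(
            [v for v in idx if any(not mask[w] for w in adjacency[v])], dtype=np.int64
        )

    prepared = []
    for part in parts:
        mask = np.zeros(base.n_vertices, dtype=bool)
        mask[part.indices] = True
        b0 = boundary_of(mask)
        prepared.append((part, mask, b0))
    prepared.sort(key=lambda t: -len(t[2]))

    info = {"parts": {}}
    for part, mask, b0 in prepared:
        pos = np.full((base.n_vertices, 3), np.nan)
        pos[part.indices] = part.positions
        if align:
            tf = rigid_align(pos[part.indices], base.vertices[part.indices])
            pos[part.indices] = tf.apply(pos[part.indices])
        if not len(b0):
            raise ValueError(f"part {part.name!r}: region has no boundary (covers whole mesh?)")
        interior = mask.copy()
        interior[b0] = False
        inner, band_in, k_in = shrink_contour(base, b0, s0, interior, adjacency)
        if on_overlap == "skip":
            out_side = ~mask & ~any_part & ~claimed
        else:
            out_side = ~mask
        outer, band_out, k_out = shrink_contour(base, b0, s0, out_side, adjacency)
        touched = np.concatenate([part.indices, band_out, outer])
        if on_overlap == "error" and claimed[touched].any():
            raise ValueError(
                f"blend band of part {part.name!r} overlaps a previous part "
                f"({int(claimed[touched].sum())} vertices)"
            )
        claimed[touched] = True

        P0 = pos[b0]
        P1 = base.vertices[b0]
        P2 = midpoint_targets(P0, P1)

        # part side: interior beyond the band keeps part positions
        deep = mask.copy()
        deep[b0] = False
        band_in_only = np.setdiff1d(band_in, b0)
        out[np.flatnonzero(deep)] = pos[np.flatnonzero(deep)]
        provenance[np.flatnonzero(deep)] = f"part:{part.name}"
        if len(inner) and len(band_in_only):
            f0 = fit_tps(
                np.vstack([pos[inner], P0]),
                np.vstack([pos[inner], P2]),
            )
            out[band_in_only] = f0.apply(pos[band_in_only])
            provenance[band_in_only] = f"band:{part.name}"
        # base side
        band_out_only = np.setdiff1d(band_out, b0)
        if len(outer) and len(band_out_only):
            f1 = fit_tps(
                np.vstack([base.vertices[outer], P1]),
                np.vstack([base.vertices[outer], P2]),
            )
            out[band_out_only] = f1.apply(base.vertices[band_out_only])
            provenance[band_out_only] = f"band:{part.name}"
        # seam: both splines agree at P2 by construction
        out[b0] = P2
        provenance[b0] = f"seam:{part.name}"
        info["parts"][part.name] = {
            "k_inner": k_in,
            "k_outer": k_out,
            "n_boundary": len(b0),
            "seam_midpoint_shift_mm": float(np.linalg.norm(P2 - P1, axis=1).mean()),
        }
    info["provenance"] = provenance
    return base.with_vertices(out), info
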