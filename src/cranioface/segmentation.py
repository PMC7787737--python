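"""Craniofacial region segmentation.

Per-vertex features are built from the training population (mean position
plus the centered across-sample coordinate trajectory), denoised with robust
PCA (principal component pursuit), reduced with PCA, and clustered with fuzzy
c-means into C regions (default C=5, fuzzifier m=2).  Hard labels come from
the maximum-membership rule; similar clusters can optionally be merged.
Regions are named anatomically (left_eye, right_eye, nose, mouth, frame)
from their centroid positions in the canonical head frame: the largest
cluster is the frame, the two most lateral of the rest are the eyes, and the
higher/lower remaining clusters are nose and mouth.

Segmentation is computed once on the training set; because all corresponded
meshes share a topology, the labeling transfers to any new mesh by vertex
index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

from .meshkit import SampleSet, TriMesh

__all__ = [
    "FeatureMatrix",
    "MembershipMatrix",
    "RegionLabeling",
    "REGION_NAMES",
    "build_vertex_features",
    "rpca_decompose",
    "reduce_features",
    "fcm_cluster",
    "assign_labels",
    "merge_similar_regions",
    "name_regions",
    "transfer_labels",
    "region_submesh",
    "region_boundary",
    "segment_modality",
]

REGION_NAMES = ("left_eye", "right_eye", "nose", "mouth", "frame")


@dataclass
class FeatureMatrix:
    """Per-vertex feature rows (N x d) with a provenance note."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")


@dataclass
class MembershipMatrix:
    """Fuzzy memberships U (C x N), cluster centers (C x d) and fuzzifier m.

    ``J_history`` records the clustering objective at every iteration and
    ``max_colsum_dev`` the largest deviation of any membership column sum
    from 1, for diagnostics.
    """

    U: np.ndarray
    centers: np.ndarray
    m: float
    J_history: list[float] = field(default_factory=list)
    max_colsum_dev: float = 0.0
    n_iter: int = 0
    converged: bool = True

    @property
    def n_clusters(self) -> int:
        return self.U.shape[0]

    @property
    def n_points(self) -> int:
        return self.U.shape[1]


@dataclass
class RegionLabeling:
    """Hard per-vertex region assignment with anatomical names."""

    labels: np.ndarray
    names: dict[int, str]
    modality: str = "face"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.names)

    def vertices_of(self, region: int | str) -> np.ndarray:
        rid = self.id_of(region)
        return np.flatnonzero(self.labels == rid)

    def id_of(self, region: int | str) -> int:
        if isinstance(region, str):
            for rid, name in self.names.items():
                if name == region:
                    return rid
            raise KeyError(f"no region named {region!r}")
        return int(region)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "vertex_index": np.arange(len(self.labels)),
                "label": self.labels,
                "region_name": [self.names[int(l)] for l in self.labels],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, modality: str = "face") -> "RegionLabeling":
        df = pd.read_csv(path)
        names = (
            df.drop_duplicates("label").set_index("label")["region_name"].to_dict()
        )
        return cls(df["label"].to_numpy(), {int(k): str(v) for k, v in names.items()}, modality)


# ---------------------------------------------------------------------------
# Features


def build_vertex_features(
    samples: SampleSet, modality: str, traj_weight: float = 0.25
) -> FeatureMatrix:
    """Row j = [mean position of vertex j | centered across-sample trajectory].

    The trajectory block captures how each vertex co-varies across the
    population; vertices that move together cluster together.  Columns are
    standardized (zero-variance columns are left centered); the trajectory
    block is then rescaled so its total variance is ``traj_weight`` times
    the position block's.  Keeping position dominant anchors the clusters
    spatially — per-vertex shape trajectories vary smoothly over the mesh,
    and a fuzzy clustering driven mostly by them degenerates (centers
    coalesce) instead of partitioning the surface.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to build vertex features")
    mats = samples.skull_matrix() if modality == "skull" else samples.face_matrix()
    M = mats.shape[0]
    pos = mats.reshape(M, -1, 3)  # (M, N, 3)
    mean_pos = pos.mean(axis=0)  # (N, 3)
    traj = np.transpose(pos - mean_pos[None], (1, 0, 2)).reshape(mean_pos.shape[0], 3 * M)

    def standardize(block: np.ndarray) -> np.ndarray:
        mu = block.mean(axis=0)
        sd = block.std(axis=0)
        return (block - mu) / np.where(sd > 1e-12, sd, 1.0)

    pos_std = standardize(mean_pos)
    traj_std = standardize(traj) * np.sqrt(traj_weight * 3.0 / traj.shape[1])
    raw = np.hstack([pos_std, traj_std])
    return FeatureMatrix(
        raw,
        provenance=(
            f"{modality}: mean position + trajectory over {M} samples, "
            f"traj_weight={traj_weight}"
        ),
    )


def rpca_decompose(
    X: np.ndarray,
    lam: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Principal component pursuit via inexact augmented Lagrangian.

    Splits X into a low-rank part L and a sparse part S with X ~ L + S.
    lam defaults to 1/sqrt(max(X.shape)).  Non-convergence returns the best
    iterate with a warning.
    """
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("rpca input must be finite")
    if X.size == 0 or not np.any(X):
        return np.zeros_like(X), np.zeros_like(X)
    if lam is None:
        lam = 1.0 / np.sqrt(max(X.shape))
    norm_2 = np.linalg.norm(X, 2)
    norm_inf = np.abs(X).max() / lam
    Y = X / max(norm_2, norm_inf)
    mu = 1.25 / norm_2
    # slow multiplier growth: aggressive schedules satisfy X = L + S quickly
    # but freeze an inaccurate L/S allocation
    rho = 1.05
    normX = np.linalg.norm(X)
    S = np.zeros_like(X)
    L = np.zeros_like(X)
    for _ in range(max_iter):
        # low-rank update: singular value thresholding
        U, sig, Vt = np.linalg.svd(X - S + Y / mu, full_matrices=False)
        sig_t = np.maximum(sig - 1.0 / mu, 0.0)
        rank = int((sig_t > 0).sum())
        L = (U[:, :rank] * sig_t[:rank]) @ Vt[:rank]
        # sparse update: soft thresholding
        T = X - L + Y / mu
        S = np.sign(T) * np.maximum(np.abs(T) - lam / mu, 0.0)
        Z = X - L - S
        Y = Y + mu * Z
        mu *= rho
        if np.linalg.norm(Z) / normX < tol:
            return L, S
    warnings.warn("rpca_decompose did not converge; returning best iterate")
    return L, S


def reduce_features(L: np.ndarray, d: int) -> FeatureMatrix:
    """PCA projection of feature rows to d dims with a deterministic sign
    convention (largest-magnitude loading of each component is positive)."""
    L = np.asarray(L, dtype=np.float64)
    if d > min(L.shape):
        raise ValueError(f"d={d} exceeds matrix rank bound {min(L.shape)}")
    centered = L - L.mean(axis=0)
    U, sig, Vt = np.linalg.svd(centered, full_matrices=False)
    comps = Vt[:d]
    for k in range(d):
        j = np.argmax(np.abs(comps[k]))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
    return FeatureMatrix(centered @ comps.T, provenance=f"pca d={d}")


# ---------------------------------------------------------------------------
# Fuzzy c-means


def _fcm_memberships(D2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared center-point distances D2 (C x N).

    Coincident points (zero distance to a center) receive full membership in
    the first such center.
    """
    C, N = D2.shape
    expo = 1.0 / (m - 1.0)
    U = np.zeros_like(D2)
    zero_cols = (D2 <= 1e-300).any(axis=0)
    safe = ~zero_cols
    if safe.any():
        inv = D2[:, safe] ** (-expo)
        U[:, safe] = inv / inv.sum(axis=0, keepdims=True)
    for j in np.flatnonzero(zero_cols):
        i = int(np.argmax(D2[:, j] <= 1e-300))
        U[:, j] = 0.0
        U[i, j] = 1.0
    return U


def fcm_cluster(
    features: FeatureMatrix | np.ndarray,
    C: int = 5,
    m: float = 2.0,
    epsilon: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
    init_centers: np.ndarray | None = None,
) -> MembershipMatrix:
    """Fuzzy c-means clustering of per-vertex feature rows.

    Alternates the center update v_i = sum_j u_ij^m x_j / sum_j u_ij^m with
    the membership update u_ij proportional to ||v_i - x_j||^(-2/(m-1)),
    until the sup-norm change of U falls below epsilon.  The objective
    J = sum_ij u_ij^m ||v_i - x_j||^2 is non-increasing across iterations.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if C < 2:
        raise ValueError("C must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if len(X) < C:
        raise ValueError("fewer points than clusters")

    def run(seed_: int) -> MembershipMatrix:
        if init_centers is not None:
            centers = np.asarray(init_centers, dtype=np.float64).copy()
        else:
            centers, _ = kmeans_plusplus(X, n_clusters=C, random_state=seed_)
        D2 = cdist(centers, X, "sqeuclidean")
        U = _fcm_memberships(D2, m)
        J_hist = [float((U**m * D2).sum())]
        max_dev = float(np.abs(U.sum(axis=0) - 1.0).max())
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            Um = U**m
            w = Um.sum(axis=1)
            centers = (Um @ X) / w[:, None]
            D2 = cdist(centers, X, "sqeuclidean")
            U_new = _fcm_memberships(D2, m)
            J_hist.append(float((U_new**m * D2).sum()))
            max_dev = max(max_dev, float(np.abs(U_new.sum(axis=0) - 1.0).max()))
            change = float(np.abs(U_new - U).max())
            U = U_new
            if change < epsilon:
                converged = True
                break
        return MembershipMatrix(U, centers, m, J_hist, max_dev, it, converged)

    result = run(seed)
    hard = result.U.argmax(axis=0)
    if len(np.unique(hard)) < C:
        result = run(seed + 1)
        hard = result.U.argmax(axis=0)
        if len(np.unique(hard)) < C:
            raise RuntimeError("fcm_cluster produced an empty cluster after re-seeding")
    return result


def assign_labels(U: MembershipMatrix | np.ndarray) -> np.ndarray:
    """Hard label per vertex = argmax membership; ties break to the lowest
    cluster index (numpy argmax convention)."""
    mat = U.U if isinstance(U, MembershipMatrix) else np.asarray(U, float)
    return mat.argmax(axis=0).astype(np.int64)


def merge_similar_regions(
    U: MembershipMatrix,
    labels: np.ndarray,
    tau: float,
    target_count: int,
) -> tuple[MembershipMatrix, np.ndarray]:
    """Greedily merge the closest pair of cluster centers until target_count
    regions remain or no pair is closer than tau.

    Memberships of merged clusters are summed; the merged center is the
    membership-mass-weighted mean of the pair.  Raises if target_count
    cannot be reached under tau.
    """
    if target_count > U.n_clusters:
        raise ValueError("target_count exceeds current cluster count")
    Um = U.U.copy()
    centers = U.centers.copy()
    labels = np.asarray(labels).copy()
    groups = [[i] for i in range(U.n_clusters)]
    while len(centers) > target_count:
        D = cdist(centers, centers)
        np.fill_diagonal(D, np.inf)
        i, j = np.unravel_index(np.argmin(D), D.shape)
        if D[i, j] > tau:
            raise ValueError(
                f"cannot reach {target_count} regions under tau={tau}; "
                f"remaining center distances (min {D.min():.4g}): "
                f"{np.sort(D[np.isfinite(D)])[:6]}"
            )
        i, j = min(i, j), max(i, j)
        wi, wj = Um[i].sum(), Um[j].sum()
        centers[i] = (wi * centers[i] + wj * centers[j]) / max(wi + wj, 1e-300)
        Um[i] = Um[i] + Um[j]
        Um = np.delete(Um, j, axis=0)
        centers = np.delete(centers, j, axis=0)
        groups[i].extend(groups[j])
        del groups[j]
    # relabel by new cluster ordering
    old_to_new = {}
    for new, grp in enumerate(groups):
        for old in grp:
            old_to_new[old] = new
    new_labels = np.array([old_to_new[int(l)] for l in labels], dtype=np.int64)
    merged = MembershipMatrix(Um, centers, U.m, list(U.J_history), U.max_colsum_dev, U.n_iter, U.converged)
    return merged, new_labels


# ---------------------------------------------------------------------------
# Region naming and submeshes


def name_regions(labels: np.ndarray, vertices: np.ndarray, modality: str) -> RegionLabeling:
    """Assign anatomical names to clusters from centroid geometry.

    Convention (canonical head frame: x lateral with left = +x, y anterior,
    z vertical): the cluster with the most vertices is the frame; of the
    remaining four, the two with the most extreme centroid x are the eyes
    (left = larger x); of the last two, the higher-z centroid is the nose and
    the lower is the mouth.
    """
    labels = np.asarray(labels, dtype=np.int64)
    ids = np.unique(labels)
    counts = {int(i): int((labels == i).sum()) for i in ids}
    cents = {int(i): vertices[labels == i].mean(axis=0) for i in ids}
    names: dict[int, str] = {}
    remaining = sorted(counts, key=lambda i: -counts[i])
    frame = remaining.pop(0)
    names[frame] = "frame"
    if len(remaining) >= 4:
        by_x = sorted(remaining, key=lambda i: cents[i][0])
        right = by_x[0]
        left = by_x[-1]
        names[left] = "left_eye"
        names[right] = "right_eye"
        rest = [i for i in remaining if i not in (left, right)]
        by_z = sorted(rest, key=lambda i: -cents[i][2])
        names[by_z[0]] = "nose"
        for k, i in enumerate(by_z[1:]):
            names[i] = "mouth" if k == 0 else f"region_{i}"
    else:
        for k, i in enumerate(remaining):
            names[i] = f"region_{i}"
    return RegionLabeling(labels, names, modality)


def transfer_labels(
    labeling: RegionLabeling,
    source_vertices: np.ndarray,
    target_vertices: np.ndarray,
    modality: str,
) -> RegionLabeling:
    """Transfer a labeling to another mesh by angular nearest neighbour.

    Each target vertex takes the label of the source vertex whose direction
    from the source centroid is closest to the target vertex's direction
    from its own centroid.  For head-shaped surfaces this matches skull
    vertices to the overlying face region regardless of topology, which is
    how a face segmentation is carried to the skull (soft tissue lies
    radially outside the bone that supports it).
    """
    from scipy.spatial import cKDTree

    def unit_dirs(v):
        c = v - v.mean(axis=0)
        n = np.linalg.norm(c, axis=1, keepdims=True)
        return c / np.where(n > 1e-12, n, 1.0)

    _, nn = cKDTree(unit_dirs(np.asarray(source_vertices, float))).query(
        unit_dirs(np.asarray(target_vertices, float))
    )
    return RegionLabeling(labeling.labels[nn], dict(labeling.names), modality)


def region_submesh(
    mesh: TriMesh, labeling: RegionLabeling | np.ndarray, region: int | str
) -> tuple[TriMesh, np.ndarray]:
    """Submesh of faces whose three vertices all carry the region label.

    Returns the submesh and the injective index map region-vertex -> global
    vertex index.
    """
    if isinstance(labeling, RegionLabeling):
        rid = labeling.id_of(region)
        labels = labeling.labels
    else:
        labels = np.asarray(labeling)
        rid = int(region)
    in_region = labels == rid
    if not in_region.any():
        raise ValueError(f"region {region!r} is empty")
    keep = in_region[mesh.faces].all(axis=1)
    if not keep.any():
        raise ValueError(f"region {region!r} has no complete face")
    faces = mesh.faces[keep]
    used = np.unique(faces)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub = TriMesh(mesh.vertices[used], remap[faces])
    return sub, used


def region_boundary(
    mesh: TriMesh, labeling: RegionLabeling | np.ndarray, region: int | str
) -> list[list[int]]:
    """Ordered closed boundary loops of a region, as global vertex indices.

    Boundary edges are edges incident to exactly one region face; loops are
    walked along the face winding so all loops share a consistent
    orientation.  Raises on non-manifold boundary connectivity.
    """
    if isinstance(labeling, RegionLabeling):
        rid = labeling.id_of(region)
        labels = labeling.labels
    else:
        labels = np.asarray(labeling)
        rid = int(region)
    in_region = labels == rid
    keep = in_region[mesh.faces].all(axis=1)
    faces = mesh.faces[keep]
    if not len(faces):
        raise ValueError(f"region {region!r} has no complete face")
    # undirected edge census over region faces
    und = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    key = np.sort(und, axis=1)
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    boundary_und = {tuple(e) for e in uniq[counts == 1]}
    if not boundary_und:
        return []
    # directed boundary edges follow the face winding
    nxt: dict[int, int] = {}
    for a, b in und:
        if tuple(sorted((a, b))) in boundary_und:
            if int(a) in nxt:
                raise ValueError("non-manifold region boundary (branching vertex)")
            nxt[int(a)] = int(b)
    loops: list[list[int]] = []
    seen: set[int] = set()
    for start in sorted(nxt):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt[start]
        while cur != start:
            if cur in seen or cur not in nxt:
                raise ValueError("non-manifold or open region boundary")
            loop.append(cur)
            seen.add(cur)
            cur = nxt[cur]
        loops.append(loop)
    return loops


# ---------------------------------------------------------------------------
# One-call segmentation of a modality


def segment_modality(
    samples: SampleSet,
    modality: str,
    C: int = 5,
    m: float = 2.0,
    feature_dim: int = 6,
    rpca: bool = True,
    rpca_max_iter: int = 150,
    epsilon: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
) -> tuple[RegionLabeling, MembershipMatrix]:
    """Features -> (robust PCA) -> PCA(d) -> FCM -> named hard labels."""
    feats = build_vertex_features(samples, modality)
    mat = feats.values
    if rpca:
        L, _ = rpca_decompose(mat, max_iter=rpca_max_iter)
    else:
        L = mat
    d_max = min(feature_dim, min(L.shape))
    # FCM with m=2 can degenerate on smooth mesh features: centers coalesce
    # or a cluster collapses onto a handful of vertices.  A partition is
    # accepted only if every cluster holds at least 1% of the vertices;
    # otherwise walk a deterministic ladder of init seeds, then retry at
    # lower feature dimension (position-dominant features in few dimensions
    # cluster the most stably).
    n_vertices = L.shape[0]
    min_size = max(C, int(0.01 * n_vertices))
    U = None
    for d in range(d_max, 2, -1):
        reduced = reduce_features(L, d)
        for attempt in range(4):
            try:
                cand = fcm_cluster(
                    reduced, C=C, m=m, epsilon=epsilon, max_iter=max_iter,
                    seed=seed + 2 * attempt,
                )
            except RuntimeError:
                continue
            sizes = np.bincount(cand.U.argmax(axis=0), minlength=C)
            if sizes.min() >= min_size:
                U = cand
                break
        if U is not None:
            break
    if U is None:
        raise RuntimeError(
            f"segmentation failed: no stable {C}-cluster FCM partition found"
        )
    labels = assign_labels(U)
    mean_pos = (samples.skull_matrix() if modality == "skull" else samples.face_matrix()).mean(0).reshape(-1, 3)
    labeling = name_regions(labels, mean_pos, modality)
    return labeling, U
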