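"""Triangle-mesh data model, OBJ/PLY I/O, shape-vector flattening and the
reconstruction-error metric.

All meshes live in millimetres.  Vertex indices are 0-based internally; the
Wavefront OBJ format on disk is 1-based, converted at the I/O boundary.  A
population of corresponded meshes shares one topology per modality, so a mesh
is fully described by its vertex coordinates once the reference topology is
fixed — this is what makes the flat :class:`ShapeVector` representation and
the vertex-wise :func:`average_error` metric meaningful.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TriMesh",
    "ShapeVector",
    "CorrespondedPair",
    "SampleSet",
    "MeshFormatError",
    "read_mesh",
    "write_mesh",
    "flatten",
    "unflatten",
    "normalize_pose",
    "SimilarityTransform",
    "average_error",
]


class MeshFormatError(ValueError):
    """Raised for malformed mesh files or invariant violations."""


@dataclass
class TriMesh:
    """A triangle mesh: ``vertices`` (n, 3) float64 mm, ``faces`` (m, 3) int.

    Invariants enforced at construction: all face indices in range, no face
    with a repeated vertex, all coordinates finite.  Faces may be empty
    (point cloud).
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise MeshFormatError("mesh vertices contain non-finite coordinates")
        n = len(self.vertices)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= n:
                raise MeshFormatError(
                    f"face index out of range [0, {n}): "
                    f"min={self.faces.min()}, max={self.faces.max()}"
                )
            degenerate = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if degenerate.any():
                raise MeshFormatError(
                    f"face {int(np.flatnonzero(degenerate)[0])} repeats a vertex index"
                )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy())

    def with_vertices(self, vertices: np.ndarray) -> "TriMesh":
        """Same topology, new coordinates."""
        return TriMesh(np.asarray(vertices, dtype=np.float64), self.faces.copy())

    def edges_unique(self) -> np.ndarray:
        """Undirected edges as a sorted (e, 2) array of vertex index pairs."""
        if not self.faces.size:
            return np.empty((0, 2), dtype=np.int64)
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def mean_edge_length(self) -> float:
        e = self.edges_unique()
        if not len(e):
            raise MeshFormatError("mesh has no edges")
        d = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        return float(d.mean())

    def vertex_adjacency(self) -> list[np.ndarray]:
        """Neighbour index array per vertex (graph of mesh edges)."""
        e = self.edges_unique()
        nbr: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for a, b in e:
            nbr[a].append(b)
            nbr[b].append(a)
        return [np.asarray(v, dtype=np.int64) for v in nbr]


@dataclass
class ShapeVector:
    """Flat (x1,y1,z1,...,xN,yN,zN) view of mesh vertices, in mm.

    ``modality`` tags skull vs face, ``region`` optionally names the region
    the vector was cut from.
    """

    values: np.ndarray
    modality: str = "face"
    region: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size % 3:
            raise ValueError("shape vector length must be divisible by 3")

    @property
    def n_points(self) -> int:
        return self.values.size // 3

    def points(self) -> np.ndarray:
        return self.values.reshape(-1, 3)


def flatten(mesh: TriMesh, vertex_subset: np.ndarray | None = None) -> np.ndarray:
    """Flatten mesh vertices (optionally a subset) to a 1-D shape vector."""
    v = mesh.vertices
    if vertex_subset is not None:
        idx = np.asarray(vertex_subset, dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= len(v)):
            raise IndexError("vertex_subset index out of range")
        v = v[idx]
    return v.reshape(-1).copy()


def unflatten(values: np.ndarray, faces: np.ndarray | None = None) -> TriMesh:
    """Rebuild a TriMesh from a flat shape vector and (optional) topology."""
    pts = np.asarray(values, dtype=np.float64).reshape(-1, 3)
    if faces is None:
        faces = np.empty((0, 3), dtype=np.int64)
    return TriMesh(pts, faces)


# ---------------------------------------------------------------------------
# File I/O.
#
# OBJ is parsed directly: the contract requires exact vertex-order
# preservation, refusal to triangulate non-triangle faces and parse errors
# naming the offending line, none of which a generic loader guarantees.
# ASCII PLY goes through trimesh.


def _read_obj(path: Path) -> TriMesh:
    verts: list[tuple[float, float, float]] = []
    faces: list[tuple[int, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if tok[0] == "v":
                if len(tok) < 4:
                    raise MeshFormatError(f"{path}:{lineno}: malformed vertex record")
                try:
                    verts.append((float(tok[1]), float(tok[2]), float(tok[3])))
                except ValueError as exc:
                    raise MeshFormatError(f"{path}:{lineno}: {exc}") from exc
            elif tok[0] == "f":
                refs = tok[1:]
                if len(refs) != 3:
                    raise MeshFormatError(
                        f"{path}:{lineno}: non-triangle face with {len(refs)} "
                        "vertices (triangulation is refused to keep dense "
                        "correspondence unambiguous)"
                    )
                idx = []
                for r in refs:
                    s = r.split("/")[0]
                    try:
                        i = int(s)
                    except ValueError as exc:
                        raise MeshFormatError(f"{path}:{lineno}: bad face index {r!r}") from exc
                    if i == 0:
                        raise MeshFormatError(f"{path}:{lineno}: OBJ face index 0 is invalid")
                    idx.append(i - 1 if i > 0 else len(verts) + i)
                faces.append(tuple(idx))
            # other records (vn, vt, usemtl, ...) are ignored
    return TriMesh(np.asarray(verts, dtype=np.float64).reshape(-1, 3),
                   np.asarray(faces, dtype=np.int64).reshape(-1, 3))


def _write_obj(mesh: TriMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cranioface OBJ: {mesh.n_vertices} vertices, {mesh.n_faces} faces\n")
        for x, y, z in mesh.vertices:
            fh.write(f"v {x:.9g} {y:.9g} {z:.9g}\n")
        for a, b, c in mesh.faces:
            fh.write(f"f {a + 1} {b + 1} {c + 1}\n")


def _read_ply(path: Path) -> TriMesh:
    import trimesh as _tm

    loaded = _tm.load(str(path), file_type="ply", process=False, maintain_order=True)
    faces = np.asarray(loaded.faces, dtype=np.int64) if hasattr(loaded, "faces") else np.empty((0, 3))
    if faces.size and faces.shape[1] != 3:
        raise MeshFormatError(f"{path}: non-triangle faces in PLY")
    return TriMesh(np.asarray(loaded.vertices, dtype=np.float64), faces)


def _write_ply(mesh: TriMesh, path: Path) -> None:
    import trimesh as _tm

    tm = _tm.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    data = tm.export(file_type="ply", encoding="ascii")
    if isinstance(data, str):
        data = data.encode()
    with open(path, "wb") as fh:
        fh.write(data)


def read_mesh(path: str | os.PathLike, fmt: str | None = None) -> TriMesh:
    """Read an OBJ or PLY triangle mesh; format inferred from suffix if omitted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "obj":
        return _read_obj(path)
    if fmt == "ply":
        return _read_ply(path)
    raise ValueError(f"unsupported mesh format {fmt!r} (use 'obj' or 'ply')")


def write_mesh(mesh: TriMesh, path: str | os.PathLike, fmt: str | None = None) -> None:
    """Write a mesh as OBJ (1-based faces) or ascii PLY."""
    path = Path(path)
    if not np.all(np.isfinite(mesh.vertices)):
        raise MeshFormatError("refusing to write mesh with non-finite vertices")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "obj":
        _write_obj(mesh, path)
    elif fmt == "ply":
        _write_ply(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format {fmt!r} (use 'obj' or 'ply')")


# ---------------------------------------------------------------------------
# Pose normalization.


@dataclass
class SimilarityTransform:
    """x_norm = R @ (x - center) / scale, with R orthonormal (det +1)."""

    rotation: np.ndarray
    center: np.ndarray
    scale: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.center) @ self.rotation.T / self.scale

    def invert(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation * self.scale + self.center


def normalize_pose(mesh: TriMesh, anchor_indices) -> tuple[TriMesh, SimilarityTransform]:
    """Canonical-frame normalization from >=3 non-collinear anchor vertices.

    The anchor centroid moves to the origin, the mean anchor distance is
    scaled to 1 and the rotation is fixed by an orthonormal frame built from
    the first two non-degenerate anchor directions.  The output is invariant
    under any similarity transform (rotation + translation + uniform scale)
    of the input.  This is deliberately landmark-free plumbing: anatomical
    Frankfurt-plane alignment is out of scope and synthetic data is generated
    already canonical.
    """
    idx = np.asarray(anchor_indices, dtype=np.int64)
    if idx.size < 3:
        raise ValueError("need at least 3 anchor indices")
    anchors = mesh.vertices[idx]
    center = anchors.mean(axis=0)
    centered = anchors - center
    norms = np.linalg.norm(centered, axis=1)
    scale = float(norms.mean())
    if scale <= 0:
        raise ValueError("anchors are coincident")
    u = centered / scale
    # first frame axis: first anchor with non-negligible offset from centroid
    first = next((i for i in range(len(u)) if np.linalg.norm(u[i]) > 1e-9), None)
    if first is None:
        raise ValueError("anchors are coincident")
    e1 = u[first] / np.linalg.norm(u[first])
    e3 = None
    for j in range(len(u)):
        if j == first:
            continue
        c = np.cross(e1, u[j])
        if np.linalg.norm(c) > 1e-9:
            e3 = c / np.linalg.norm(c)
            break
    if e3 is None:
        raise ValueError("anchors are collinear; cannot fix a rotation")
    e2 = np.cross(e3, e1)
    rotation = np.vstack([e1, e2, e3])
    tf = SimilarityTransform(rotation=rotation, center=center, scale=scale)
    return mesh.with_vertices(tf.apply(mesh.vertices)), tf


# ---------------------------------------------------------------------------
# Error metric.


def average_error(recon: TriMesh | np.ndarray, truth: TriMesh | np.ndarray) -> float:
    """Mean Euclidean vertex-to-corresponding-vertex distance in mm.

    Both meshes must be in dense correspondence (identical vertex counts);
    this is the averageError metric used throughout evaluation.
    """
    a = recon.vertices if isinstance(recon, TriMesh) else np.asarray(recon, float).reshape(-1, 3)
    b = truth.vertices if isinstance(truth, TriMesh) else np.asarray(truth, float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError(f"vertex count mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b, axis=1).mean())


# ---------------------------------------------------------------------------
# Corresponded sample sets.


@dataclass
class CorrespondedPair:
    """One training sample: a skull and face mesh pair plus attributes."""

    sample_id: str
    skull: TriMesh
    face: TriMesh
    age: float
    bmi: float
    sex: str | None = None


@dataclass
class SampleSet:
    """Corresponded skull/face pairs sharing reference topologies."""

    pairs: list[CorrespondedPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.sample_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids are not unique")
        if self.pairs:
            s0, f0 = self.pairs[0].skull, self.pairs[0].face
            for p in self.pairs[1:]:
                if p.skull.n_vertices != s0.n_vertices or not np.array_equal(p.skull.faces, s0.faces):
                    raise ValueError(f"sample {p.sample_id}: skull topology mismatch")
                if p.face.n_vertices != f0.n_vertices or not np.array_equal(p.face.faces, f0.faces):
                    raise ValueError(f"sample {p.sample_id}: face topology mismatch")

    def __len__(self) -> int:
        return len(self.pairs)

    def __getitem__(self, i: int) -> CorrespondedPair:
        return self.pairs[i]

    @property
    def skull_faces(self) -> np.ndarray:
        return self.pairs[0].skull.faces

    @property
    def face_faces(self) -> np.ndarray:
        return self.pairs[0].face.faces

    def skull_matrix(self) -> np.ndarray:
        """(n_samples, 3N_skull) stacked flattened skulls."""
        return np.stack([flatten(p.skull) for p in self.pairs])

    def face_matrix(self) -> np.ndarray:
        return np.stack([flatten(p.face) for p in self.pairs])

    def attributes(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [p.sample_id for p in self.pairs],
                "age": [p.age for p in self.pairs],
                "bmi": [p.bmi for p in self.pairs],
            }
        ).set_index("id")

    def subset(self, indices) -> "SampleSet":
        return SampleSet([self.pairs[i] for i in indices])

    # -- directory persistence: <id>_skull.obj, <id>_face.obj, attributes.csv

    def save(self, directory: str | os.PathLike) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for p in self.pairs:
            write_mesh(p.skull, d / f"{p.sample_id}_skull.obj")
            write_mesh(p.face, d / f"{p.sample_id}_face.obj")
        self.attributes().reset_index().to_csv(d / "attributes.csv", index=False)

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "SampleSet":
        d = Path(directory)
        attrs = pd.read_csv(d / "attributes.csv").set_index("id")
        pairs = []
        for sid, row in attrs.iterrows():
            pairs.append(
                CorrespondedPair(
                    sample_id=str(sid),
                    skull=read_mesh(d / f"{sid}_skull.obj"),
                    face=read_mesh(d / f"{sid}_face.obj"),
                    age=float(row["age"]),
                    bmi=float(row["bmi"]),
                )
            )
        return cls(pairs)


def random_split(samples: SampleSet, n_test: int, seed: int) -> tuple[SampleSet, SampleSet]:
    """Seeded random train/test split (test drawn without replacement)."""
    if not 0 < n_test < len(samples):
        raise ValueError("n_test must be in (0, n_samples)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(samples))
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return samples.subset(train_idx), samples.subset(test_idx)
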