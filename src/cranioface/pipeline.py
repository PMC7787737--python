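"""End-to-end training, reconstruction and evaluation.

Training: segment the corresponded training population into five regions
per modality, fit one GP-LVM per modality x region, and train a
multi-output LSSVR from skull latent coordinates (optionally augmented with
z-scored age/BMI) to face latent coordinates.  Reconstruction: encode each
skull region into its latent space, regress to the face latent, decode the
regional face shape, and fuse the feature regions onto the frame
reconstruction with TPS seam blending.  A global (single-region) variant of
the same pipeline serves as the baseline: skull and face are used whole and
no fusion is needed.

Evaluation reports the averageError metric (mean vertex-wise Euclidean
distance, mm) per test sample and per region.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gplvm, lssvr
from .fusion import RegionPart, _bfs_rings, fuse_regions
from .meshkit import SampleSet, TriMesh, average_error, flatten
from .segmentation import RegionLabeling, segment_modality, transfer_labels

log = logging.getLogger("cranioface")

__all__ = [
    "PipelineConfig",
    "RegionModels",
    "ModelBundle",
    "EvaluationReport",
    "train",
    "train_global",
    "reconstruct",
    "reconstruct_global",
    "mean_face_baseline",
    "evaluate",
]

FEATURE_REGIONS = ("left_eye", "right_eye", "nose", "mouth")


@dataclass
class PipelineConfig:
    """All tunables of the training/reconstruction pipeline.

    ``q=None`` selects the latent dimension per region as the smallest
    number of PCA components explaining 99% variance, capped at 8.
    ``clusters=1`` degenerates to the global (non-regional) pipeline.
    ``s0=None`` sets the blending width to 3x the mean edge length.
    """

    q: int | None = None
    clusters: int = 5
    m: float = 2.0
    feature_dim: int = 6
    rpca: bool = True
    rpca_max_iter: int = 150
    fcm_epsilon: float = 1e-5
    fcm_max_iter: int = 300
    C_reg: float = 1000.0
    sigma2: float = 100.0
    tune: bool = True
    s0: float | None = None
    use_attributes: bool = False
    gplvm_max_iter: int = 300
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class RegionModels:
    """The trained models of one region.

    ``skull_idx``/``face_idx`` are the model SUPPORT vertex sets: the region
    itself plus a blend-depth collar into the neighbouring regions, so that
    at every region boundary two models hold a genuine opinion and fusion
    can average them.  ``face_own_idx`` is the region proper (the vertices
    this region contributes to the assembled face).
    """

    name: str
    skull_idx: np.ndarray
    face_idx: np.ndarray
    face_own_idx: np.ndarray
    skull_model: gplvm.LatentModel
    face_model: gplvm.LatentModel
    regressor: lssvr.MultiOutputLSSVR


@dataclass
class ModelBundle:
    """A trained region-fusion reconstructor."""

    skull_labeling: RegionLabeling
    face_labeling: RegionLabeling
    regions: dict  # name -> RegionModels
    mean_face: np.ndarray  # (N_face, 3)
    face_faces: np.ndarray
    skull_n_vertices: int
    s0: float
    attribute_scaler: lssvr.AttributeScaler | None
    config: PipelineConfig
    training_ids: list

    @property
    def uses_attributes(self) -> bool:
        return self.attribute_scaler is not None

    @property
    def is_global(self) -> bool:
        return set(self.regions) == {"global"}

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.skull_labeling.to_csv(d / "skull_labels.csv")
        self.face_labeling.to_csv(d / "face_labels.csv")
        np.savez(d / "topology.npz", mean_face=self.mean_face, face_faces=self.face_faces)
        self.config.to_yaml(d / "config.yaml")
        meta = {
            "s0": self.s0,
            "skull_n_vertices": self.skull_n_vertices,
            "training_ids": list(self.training_ids),
            "regions": sorted(self.regions),
            "config_hash": self.config.hash(),
            "attribute_columns": self.attribute_scaler.columns if self.attribute_scaler else None,
        }
        (d / "bundle.json").write_text(json.dumps(meta, indent=2))
        if self.attribute_scaler is not None:
            np.savez(
                d / "attribute_scaler.npz",
                mean=self.attribute_scaler.mean,
                scale=self.attribute_scaler.scale,
            )
        for name, rm in self.regions.items():
            rd = d / f"region_{name}"
            rd.mkdir(exist_ok=True)
            np.savez(
                rd / "indices.npz",
                skull_idx=rm.skull_idx,
                face_idx=rm.face_idx,
                face_own_idx=rm.face_own_idx,
            )
            rm.skull_model.save(rd / "skull_gplvm")
            rm.face_model.save(rd / "face_gplvm")
            reg = rm.regressor
            np.savez(
                rd / "lssvr.npz",
                support_X=reg.models[0].support_X,
                alpha=np.column_stack([m.alpha for m in reg.models]),
                b=np.array([m.b for m in reg.models]),
                sigma2=reg.models[0].sigma2,
                C_reg=reg.models[0].C_reg,
                input_mean=reg.input_mean,
                input_scale=reg.input_scale,
            )

    @classmethod
    def load(cls, directory) -> "ModelBundle":
        d = Path(directory)
        meta = json.loads((d / "bundle.json").read_text())
        topo = np.load(d / "topology.npz")
        scaler = None
        if meta["attribute_columns"]:
            sc = np.load(d / "attribute_scaler.npz")
            scaler = lssvr.AttributeScaler(meta["attribute_columns"], sc["mean"], sc["scale"])
        regions = {}
        for name in meta["regions"]:
            rd = d / f"region_{name}"
            idx = np.load(rd / "indices.npz")
            lz = np.load(rd / "lssvr.npz")
            models = [
                lssvr.LSSVRModel(
                    lz["support_X"], lz["alpha"][:, j], float(lz["b"][j]),
                    float(lz["sigma2"]), float(lz["C_reg"]),
                )
                for j in range(lz["alpha"].shape[1])
            ]
            regions[name] = RegionModels(
                name,
                idx["skull_idx"],
                idx["face_idx"],
                idx["face_own_idx"],
                gplvm.LatentModel.load(rd / "skull_gplvm"),
                gplvm.LatentModel.load(rd / "face_gplvm"),
                lssvr.MultiOutputLSSVR(models, lz["input_mean"], lz["input_scale"]),
            )
        return cls(
            RegionLabeling.from_csv(d / "skull_labels.csv", "skull"),
            RegionLabeling.from_csv(d / "face_labels.csv", "face"),
            regions,
            topo["mean_face"],
            topo["face_faces"],
            int(meta["skull_n_vertices"]),
            float(meta["s0"]),
            scaler,
            PipelineConfig.from_yaml(d / "config.yaml"),
            meta["training_ids"],
        )


def _region_matrix(mats: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Columns of the (M, 3N) shape matrix belonging to a vertex subset."""
    M = mats.shape[0]
    return mats.reshape(M, -1, 3)[:, idx, :].reshape(M, -1)


def _global_labeling(n_vertices: int, modality: str) -> RegionLabeling:
    return RegionLabeling(np.zeros(n_vertices, dtype=np.int64), {0: "global"}, modality)


def _collar_support(
    mesh: TriMesh, labeling: RegionLabeling, region: str, k: int
) -> np.ndarray:
    """Region vertices plus a k-ring collar reaching into the other regions."""
    own = labeling.vertices_of(region)
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    mask[own] = True
    adjacency = mesh.vertex_adjacency()
    boundary = [v for v in own if any(not mask[w] for w in adjacency[v])]
    dist = _bfs_rings(adjacency, boundary, ~mask, k)
    return np.array(sorted(set(own.tolist()) | set(dist)), dtype=np.int64)


def train(samples: SampleSet, config: PipelineConfig | None = None) -> ModelBundle:
    """Train the full region-fusion reconstructor from a corresponded set."""
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    if len(samples) < 4:
        raise ValueError("need at least 4 training samples")
    skull_mat = samples.skull_matrix()
    face_mat = samples.face_matrix()
    n_skull = skull_mat.shape[1] // 3
    n_face = face_mat.shape[1] // 3

    mean_skull = skull_mat.mean(axis=0).reshape(-1, 3)
    mean_face = face_mat.mean(axis=0).reshape(-1, 3)
    if config.clusters <= 1:
        skull_lab = _global_labeling(n_skull, "skull")
        face_lab = _global_labeling(n_face, "face")
    else:
        seg_kwargs = dict(
            C=config.clusters, m=config.m, feature_dim=config.feature_dim,
            rpca=config.rpca, rpca_max_iter=config.rpca_max_iter,
            epsilon=config.fcm_epsilon, max_iter=config.fcm_max_iter, seed=config.seed,
        )
        # regions are defined on the face and carried to the skull by angular
        # correspondence, so a region's skull model sees the bone that lies
        # under exactly the soft tissue its face model predicts
        face_lab, _ = segment_modality(samples, "face", **seg_kwargs)
        skull_lab = transfer_labels(face_lab, mean_face, mean_skull, "skull")
        log.info("segmentation done in %.1fs", time.perf_counter() - t0)

    scaler = None
    attrs = samples.attributes()
    if config.use_attributes:
        scaler = lssvr.AttributeScaler.fit(attrs)

    face_mesh = TriMesh(mean_face, samples.face_faces)
    skull_mesh = TriMesh(mean_skull, samples.skull_faces)
    s0 = config.s0 if config.s0 is not None else 3.0 * face_mesh.mean_edge_length()

    common = sorted(
        set(skull_lab.names.values()) & set(face_lab.names.values())
    )
    # every region model's support is its region plus a collar reaching one
    # blend band into the neighbouring regions, so at each boundary two
    # models hold a genuine opinion and fusion can average them
    regional = len(common) > 1
    if regional:
        k_blend = max(1, int(round(s0 / face_mesh.mean_edge_length())))
        k_s = max(1, int(round(s0 / skull_mesh.mean_edge_length())))

    regions: dict[str, RegionModels] = {}
    for name in common:
        f_own = face_lab.vertices_of(name)
        if regional:
            s_idx = _collar_support(skull_mesh, skull_lab, name, k_s)
            f_idx = _collar_support(face_mesh, face_lab, name, k_blend)
        else:
            s_idx = skull_lab.vertices_of(name)
            f_idx = f_own
        if len(s_idx) < 4 or len(f_idx) < 4:
            raise ValueError(f"region {name!r} has fewer than 4 vertices")
        t1 = time.perf_counter()
        Ys = _region_matrix(skull_mat, s_idx)
        Yf = _region_matrix(face_mat, f_idx)
        sm = gplvm.fit_gplvm(
            Ys, q=config.q, seed=config.seed, max_iter=config.gplvm_max_iter,
            modality="skull", region=name,
        )
        fm = gplvm.fit_gplvm(
            Yf, q=config.q, seed=config.seed, max_iter=config.gplvm_max_iter,
            modality="face", region=name,
        )
        X_in = sm.X
        if scaler is not None:
            X_in, _ = lssvr.augment_with_attributes(X_in, attrs, scaler=scaler)
        C_reg, sigma2 = config.C_reg, config.sigma2
        if config.tune:
            C_reg, sigma2, _ = lssvr.tune_hyperparams(X_in, fm.X, seed=config.seed)
        reg = lssvr.train_multi(X_in, fm.X, C_reg, sigma2)
        regions[name] = RegionModels(name, s_idx, f_idx, f_own, sm, fm, reg)
        log.info(
            "region %-9s q_s=%d q_f=%d trained in %.1fs",
            name, sm.q, fm.q, time.perf_counter() - t1,
        )

    return ModelBundle(
        skull_lab, face_lab, regions, mean_face, samples.face_faces,
        n_skull, float(s0), scaler, config,
        [p.sample_id for p in samples.pairs],
    )


def train_global(samples: SampleSet, config: PipelineConfig | None = None) -> ModelBundle:
    """Baseline: identical pipeline with skull and face used whole."""
    config = config or PipelineConfig()
    cfg = PipelineConfig(**{**asdict(config), "clusters": 1})
    return train(samples, cfg)


def _attr_row(bundle: ModelBundle, attrs) -> np.ndarray:
    if attrs is None:
        raise ValueError("this bundle was trained with attributes; pass age and bmi")
    if isinstance(attrs, dict):
        vals = [[float(attrs[c]) for c in bundle.attribute_scaler.columns]]
    else:
        vals = np.atleast_2d(np.asarray(attrs, float))
    return bundle.attribute_scaler.transform(np.asarray(vals, float))


def reconstruct(bundle: ModelBundle, skull: TriMesh, attrs=None) -> TriMesh:
    """Reconstruct the face of an unknown skull in training correspondence.

    Per region: encode the skull region into its latent space, map through
    the trained LSSVR to the face latent, decode the regional face shape;
    then fuse the feature regions onto the frame reconstruction (the base is
    the mean training face with frame vertices replaced by the frame
    prediction).
    """
    if skull.n_vertices != bundle.skull_n_vertices:
        raise ValueError(
            f"skull has {skull.n_vertices} vertices; bundle expects {bundle.skull_n_vertices} "
            "(dense correspondence with the training topology is required)"
        )
    positions: dict[str, np.ndarray] = {}
    for name, rm in bundle.regions.items():
        y = flatten(skull, rm.skull_idx)
        x_s = gplvm.encode(rm.skull_model, y)
        x_in = x_s[None, :]
        if bundle.uses_attributes:
            x_in = np.hstack([x_in, _attr_row(bundle, attrs)])
        z_f = rm.regressor.predict(x_in)[0]
        mean, _ = gplvm.decode(rm.face_model, z_f)
        positions[name] = mean.reshape(-1, 3)

    if bundle.is_global:
        return TriMesh(positions["global"], bundle.face_faces)

    # scatter every model's prediction over its support
    n = len(bundle.mean_face)
    pred_full = {}
    for name, rm in bundle.regions.items():
        arr = np.full((n, 3), np.nan)
        arr[rm.face_idx] = positions[name]
        pred_full[name] = arr

    # base: mean face, frame vertices from the frame model; at every feature
    # -region boundary vertex the base carries the averaged opinion of the
    # OTHER models whose collar support covers it, so the seam midpoint
    # averages two genuine predictions rather than falling back to the mean
    base_v = bundle.mean_face.copy()
    if "frame" in bundle.regions:
        rm = bundle.regions["frame"]
        base_v[rm.face_own_idx] = pred_full["frame"][rm.face_own_idx]
    base = TriMesh(base_v, bundle.face_faces)
    adjacency = base.vertex_adjacency()
    labels = bundle.face_labeling.labels
    parts = []
    for name in FEATURE_REGIONS:
        if name not in bundle.regions:
            warnings.warn(f"region {name!r} missing from bundle; skipped in fusion")
            continue
        rm = bundle.regions[name]
        own = rm.face_own_idx
        rid = bundle.face_labeling.id_of(name)
        own_mask = np.zeros(n, dtype=bool)
        own_mask[own] = True
        boundary = [v for v in own if any(not own_mask[w] for w in adjacency[v])]
        for v in boundary:
            others = [
                pred_full[o][v]
                for o in bundle.regions
                if o != name and np.isfinite(pred_full[o][v, 0])
            ]
            if others:
                base_v[v] = np.mean(others, axis=0)
        parts.append(RegionPart(name, own, pred_full[name][own]))
    base = TriMesh(base_v, bundle.face_faces)
    # decoded regions share the training canonical frame, so no rigid
    # repositioning is applied before splicing
    fused, _ = fuse_regions(base, parts, bundle.s0, align=False, on_overlap="skip")
    return fused


def reconstruct_global(bundle: ModelBundle, skull: TriMesh, attrs=None) -> TriMesh:
    """Reconstruction with a global (single-region) bundle; no fusion step."""
    if not bundle.is_global:
        raise ValueError("bundle is regional; use reconstruct()")
    return reconstruct(bundle, skull, attrs)


def mean_face_baseline(bundle: ModelBundle) -> TriMesh:
    """The population-mean face predictor (ignores the skull entirely)."""
    return TriMesh(bundle.mean_face, bundle.face_faces)


@dataclass
class EvaluationReport:
    """Per-sample and per-region reconstruction errors (mm)."""

    per_sample: pd.DataFrame
    summary: pd.DataFrame

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.per_sample.to_csv(d / "per_sample_errors.csv", index=False, float_format="%.6f")
        self.summary.to_csv(d / "summary_errors.csv", index=False, float_format="%.6f")

    def __str__(self) -> str:
        lines = ["Reconstruction errors (averageError, mm)", str(self.summary.to_string(index=False))]
        return "\n".join(lines)


def evaluate(
    bundle: ModelBundle,
    test: SampleSet,
    baseline: ModelBundle | None = None,
) -> EvaluationReport:
    """Evaluate a bundle on held-out corresponded pairs.

    Per sample: the fused-face averageError and the mean vertex error inside
    each face region.  The summary table gives min/max/mean/SD over samples
    for each region and the fused face; an optional baseline bundle adds a
    comparison column.
    """
    if not len(test):
        raise ValueError("empty test set")
    region_names = sorted(set(bundle.face_labeling.names.values()))
    rows = []
    for pair in test.pairs:
        attrs = {"age": pair.age, "bmi": pair.bmi} if bundle.uses_attributes else None
        recon = reconstruct(bundle, pair.skull, attrs)
        dist = np.linalg.norm(recon.vertices - pair.face.vertices, axis=1)
        row = {"id": pair.sample_id, "averageError": float(dist.mean())}
        for name in region_names:
            idx = bundle.face_labeling.vertices_of(name)
            row[f"err_{name}"] = float(dist[idx].mean())
        if baseline is not None:
            battrs = {"age": pair.age, "bmi": pair.bmi} if baseline.uses_attributes else None
            brecon = reconstruct(baseline, pair.skull, battrs)
            row["averageError_baseline"] = average_error(brecon, pair.face)
        rows.append(row)
    per_sample = pd.DataFrame(rows)
    summary_rows = []
    for name in region_names:
        col = per_sample[f"err_{name}"]
        summary_rows.append(
            {
                "region": name,
                "min_mm": col.min(),
                "max_mm": col.max(),
                "mean_mm": col.mean(),
                "sd_mm": col.std(ddof=1) if len(col) > 1 else 0.0,
            }
        )
    col = per_sample["averageError"]
    summary_rows.append(
        {
            "region": "fused_face",
            "min_mm": col.min(),
            "max_mm": col.max(),
            "mean_mm": col.mean(),
            "sd_mm": col.std(ddof=1) if len(col) > 1 else 0.0,
        }
    )
    if baseline is not None:
        colb = per_sample["averageError_baseline"]
        summary_rows.append(
            {
                "region": "fused_face_baseline",
                "min_mm": colb.min(),
                "max_mm": colb.max(),
                "mean_mm": colb.mean(),
                "sd_mm": colb.std(ddof=1) if len(colb) > 1 else 0.0,
            }
        )
    return EvaluationReport(per_sample, pd.DataFrame(summary_rows))
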