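"""End-to-end orchestration: configuration, stage dispatch, run manifest.

A scene directory is processed through pose filtering, mask fusion,
density-grid export, cloud semantics + calibration, and trait extraction.
Stages whose outputs are already present in the directory are skipped, so
the pipeline can be entered at any point (e.g. a scene containing only
``sem.ply`` and ``calib.json`` runs just the trait stage). Each run writes
``traits.json`` plus a manifest recording the config snapshot, input
hashes, stage timings and warnings; identical config and inputs reproduce
byte-identical trait output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cloud as cloud_mod
from . import io as pio
from . import masks as masks_mod
from . import traits as traits_mod
from .field import marching_cubes, mesh_to_cloud
from .poses import estimate_scene_center, filter_images, load_poses, save_poses

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "stage_seed", "run_pipeline"]

VERSION = "0.1.0"


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters with their module defaults."""

    seed: int = 0
    max_angle: float = 20.0
    min_area: int = 10_000
    min_stability: float = 0.8
    erosion_radius: int = 5
    iso: float | None = None           # None = midpoint of value range
    eps: float | None = None           # None = adaptive median-NN radius
    min_pts: int = 10
    min_cluster_size: int = 100
    label_cm: float = 7.5
    lbc_k: int = 16
    lbc_contraction_weight: float = 1.0
    lbc_attraction_weight: float = 1.0
    lbc_growth: float = 2.0
    lbc_max_iterations: int = 10
    lbc_tol: float = 1e-4
    angle_limit: float = 45.0
    leaf: float | None = None          # None = bbox diagonal / 100
    voxel: float = 0.01                # label units
    spline_smoothing: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.max_angle <= 180:
            raise ValueError("max_angle must be in [0, 180] degrees")
        if self.min_area < 0 or not 0 <= self.min_stability <= 1:
            raise ValueError("invalid candidate-filter thresholds")
        if self.min_pts < 1 or self.min_cluster_size < 1:
            raise ValueError("min_pts and min_cluster_size must be >= 1")
        if self.label_cm <= 0 or self.voxel <= 0:
            raise ValueError("label_cm and voxel must be positive")
        if self.eps is not None and self.eps <= 0:
            raise ValueError("eps must be positive when given")
        if self.leaf is not None and self.leaf <= 0:
            raise ValueError("leaf must be positive when given")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def lbc_params(self) -> traits_mod.LBCParams:
        return traits_mod.LBCParams(
            k_neighbors=self.lbc_k,
            contraction_weight=self.lbc_contraction_weight,
            attraction_weight=self.lbc_attraction_weight,
            growth=self.lbc_growth,
            max_iterations=self.lbc_max_iterations,
            tol=self.lbc_tol,
        )


@dataclass
class RunManifest:
    config: dict
    input_hashes: dict = field(default_factory=dict)
    stage_timings: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    version: str = VERSION


def stage_seed(global_seed: int, stage: str) -> int:
    """Fan a global seed out to a per-stage seed by stable hashing, so
    adding a stage never perturbs the randomness of the others."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _atomic_json(path: Path, payload: dict) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(payload, indent=1, sort_keys=True))
    os.replace(tmp, path)


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.records: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.records.append(record.getMessage())


def _stage_filter_poses(scene: Path, cfg: PipelineConfig,
                        manifest: RunManifest) -> None:
    src = scene / "poses.json"
    out = scene / "kept_poses.json"
    if not src.exists() or out.exists():
        return
    t0 = time.perf_counter()
    poses = load_poses(src)
    manifest.input_hashes["poses.json"] = _sha256(src)
    center = estimate_scene_center(poses)
    kept = filter_images(poses, center.point, max_angle=cfg.max_angle)
    save_poses(kept, out)
    manifest.stage_timings["filter_poses"] = time.perf_counter() - t0
    manifest.outputs["kept_poses"] = str(out)
    logger.info("filter_poses: %d/%d kept, center residual %.4g",
                len(kept), len(poses), center.residual)


def _load_candidates(cand_dir: Path) -> list[masks_mod.MaskCandidate]:
    sidecar = cand_dir / "stability.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"{sidecar} missing")
    entries = json.loads(sidecar.read_text())
    out = []
    for e in entries:
        mask = pio.read_rgba(cand_dir / e["file"])
        if mask.ndim == 3:
            mask = mask[..., 0]
        out.append(masks_mod.MaskCandidate(mask=mask > 0,
                                           stability=float(e["stability"])))
    return out


def _load_rough(rough_dir: Path) -> list[masks_mod.RoughInstance]:
    sidecar = rough_dir / "labels.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"{sidecar} missing")
    entries = json.loads(sidecar.read_text())
    out = []
    for e in entries:
        mask = pio.read_rgba(rough_dir / e["file"])
        if mask.ndim == 3:
            mask = mask[..., 0]
        out.append(masks_mod.RoughInstance(mask=mask > 0, label=e["label"]))
    return out


def _stage_fuse_masks(scene: Path, cfg: PipelineConfig,
                      manifest: RunManifest) -> None:
    frames = scene / "frames"
    cands = scene / "candidates"
    rough = scene / "rough"
    fused_dir = scene / "fused"
    if not (frames.is_dir() and cands.is_dir() and rough.is_dir()):
        return
    if fused_dir.is_dir():
        return
    t0 = time.perf_counter()
    fused_dir.mkdir()
    seed = stage_seed(cfg.seed, "fuse_masks")
    n = 0
    for img_path in sorted(frames.glob("*.png")):
        stem = img_path.stem
        cdir, rdir = cands / stem, rough / stem
        if not (cdir.is_dir() and rdir.is_dir()):
            logger.warning("frame %s: missing candidates or rough masks; "
                           "skipped", stem)
            continue
        image = pio.read_rgba(img_path)[..., :3]
        fused = masks_mod.fuse_frame(
            _load_rough(rdir), _load_candidates(cdir),
            rng_seed=seed + n,
            min_area=cfg.min_area, min_stability=cfg.min_stability,
            erosion_radius=cfg.erosion_radius)
        pio.write_rgba(fused_dir / f"{stem}.png",
                       masks_mod.compose_rgba(image, fused))
        n += 1
    manifest.stage_timings["fuse_masks"] = time.perf_counter() - t0
    manifest.outputs["fused"] = str(fused_dir)
    logger.info("fuse_masks: %d frames fused", n)


def _stage_extract_cloud(scene: Path, cfg: PipelineConfig,
                         manifest: RunManifest) -> None:
    src = scene / "field.npz"
    out = scene / "cloud.ply"
    if not src.exists() or out.exists():
        return
    t0 = time.perf_counter()
    fld = pio.read_field(src)
    manifest.input_hashes["field.npz"] = _sha256(src)
    if cfg.iso is not None:
        fld.iso = cfg.iso
    points = mesh_to_cloud(marching_cubes(fld))
    pio.write_ply(out, points)
    manifest.stage_timings["extract_cloud"] = time.perf_counter() - t0
    manifest.outputs["cloud"] = str(out)
    logger.info("extract_cloud: %d points", len(points))


def _stage_segment(scene: Path, cfg: PipelineConfig,
                   manifest: RunManifest) -> None:
    src = scene / "cloud.ply"
    sem_out = scene / "sem.ply"
    calib_out = scene / "calib.json"
    if not src.exists() or (sem_out.exists() and calib_out.exists()):
        return
    t0 = time.perf_counter()
    points, _ = pio.read_ply(src)
    manifest.input_hashes["cloud.ply"] = _sha256(src)
    clustered = cloud_mod.dbscan(points, eps=cfg.eps, min_pts=cfg.min_pts)
    clustered = cloud_mod.drop_small_clusters(
        clustered, min_size=cfg.min_cluster_size)
    sem = cloud_mod.assign_semantics(clustered)
    x1 = cloud_mod.label_length(sem.tag_label)
    calib = cloud_mod.calibrate(x1, x_cm=cfg.label_cm)
    pio.write_ply(sem_out, sem.points, attrs={"semantic": sem.semantic},
                  force=True)
    _atomic_json(calib_out, {"X1": calib.x1, "X_cm": calib.x_cm,
                             "scale_cm_per_unit": calib.scale})
    manifest.stage_timings["segment"] = time.perf_counter() - t0
    manifest.outputs["sem"] = str(sem_out)
    manifest.outputs["calib"] = str(calib_out)
    logger.info("segment: %d clusters, X1=%.5g, scale=%.5g cm/unit",
                clustered.n_clusters, calib.x1, calib.scale)


def _stage_traits(scene: Path, cfg: PipelineConfig,
                  manifest: RunManifest) -> traits_mod.TraitReport:
    sem_path = scene / "sem.ply"
    calib_path = scene / "calib.json"
    if not (sem_path.exists() and calib_path.exists()):
        raise FileNotFoundError(
            f"{scene}: no entry point found (need sem.ply + calib.json, "
            "cloud.ply, or field.npz)")
    t0 = time.perf_counter()
    points, attrs = pio.read_ply(sem_path)
    manifest.input_hashes["sem.ply"] = _sha256(sem_path)
    if "semantic" not in attrs:
        raise ValueError(f"{sem_path}: missing 'semantic' vertex property")
    sem = cloud_mod.SemanticCloud(points=points, semantic=attrs["semantic"])
    calib_data = json.loads(calib_path.read_text())
    calib = cloud_mod.calibrate(calib_data["X1"],
                                x_cm=calib_data.get("X_cm", cfg.label_cm))
    report = traits_mod.extract_traits(
        sem.panicle, calib,
        lbc=cfg.lbc_params(),
        angle_limit=cfg.angle_limit,
        leaf=cfg.leaf,
        spline_smoothing=cfg.spline_smoothing,
    )
    manifest.stage_timings["traits"] = time.perf_counter() - t0
    return report


def run_pipeline(config: PipelineConfig, scene_dir: str | Path,
                 ) -> tuple[traits_mod.TraitReport, RunManifest]:
    """Run every stage whose inputs are present in ``scene_dir``.

    Stage order: pose filtering, mask fusion, density-grid export, cloud
    semantics + calibration, traits. A stage is skipped when its inputs are
    absent or its outputs already exist, so supplying intermediate products
    enters the pipeline mid-way. Returns the trait report and the run
    manifest; both are also written into the scene directory.
    """
    scene = Path(scene_dir)
    if not scene.is_dir():
        raise NotADirectoryError(f"{scene} is not a directory")
    manifest = RunManifest(config=config.to_dict())
    collector = _WarningCollector()
    root = logging.getLogger("paniclekit")
    root.addHandler(collector)
    try:
        for stage_fn, name in [
            (_stage_filter_poses, "filter_poses"),
            (_stage_fuse_masks, "fuse_masks"),
            (_stage_extract_cloud, "extract_cloud"),
            (_stage_segment, "segment"),
        ]:
            try:
                stage_fn(scene, config, manifest)
            except Exception as exc:
                raise RuntimeError(f"stage {name} failed: {exc}") from exc
        try:
            report = _stage_traits(scene, config, manifest)
        except Exception as exc:
            raise RuntimeError(f"stage traits failed: {exc}") from exc
    finally:
        root.removeHandler(collector)
    manifest.warnings = collector.records
    traits_path = scene / "traits.json"
    _atomic_json(traits_path, {
        "L1": report.l1,
        "X1": report.x1,
        "X_cm": report.x_cm,
        "L_cm": report.length_cm,
        "Num": report.num_voxels,
        "V_cm3": report.volume_cm3,
    })
    manifest.outputs["traits"] = str(traits_path)
    _atomic_json(scene / "manifest.json", dataclasses.asdict(manifest))
    return report, manifest
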