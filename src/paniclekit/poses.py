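"""Camera-pose handling: scene-center estimation and angular image filtering.

Hand-held orbit videos of a single panicle produce many frames whose camera
does not actually point at the target (the operator drifts, the phone tilts).
Reconstructing from those frames wastes compute and degrades the radiance
field, so the pipeline estimates a common "look-at" point from all camera
rays (the pose-derived viewing direction, PDVD) and then discards every
image whose viewing direction deviates from the camera-to-center line by
more than a threshold angle (image alignment filtering, IAF; 20° by
default).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CameraPose",
    "SceneCenter",
    "DegenerateGeometryError",
    "load_poses",
    "save_poses",
    "estimate_scene_center",
    "view_angle",
    "filter_images",
    "subsample_frames",
]


class DegenerateGeometryError(ValueError):
    """Raised when the viewing rays carry no triangulation information."""


@dataclass(frozen=True)
class CameraPose:
    """A camera position and unit viewing direction in scene coordinates."""

    image_id: str
    position: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError(
                f"pose {self.image_id!r}: direction has zero length"
            )
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "direction", d / n)


@dataclass(frozen=True)
class SceneCenter:
    """Least-squares intersection point of all viewing rays.

    ``residual`` is the RMS perpendicular distance from the point to the
    rays; it is zero (to rounding) when the rays meet exactly.
    """

    point: np.ndarray
    residual: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "point", np.asarray(self.point, dtype=float).reshape(3)
        )
        if self.residual < 0:
            raise ValueError("residual must be non-negative")


def _pose_from_entry(entry: dict, index: int) -> CameraPose:
    try:
        image_id = str(entry["image_id"])
        position = entry["position"]
        direction = entry["direction"]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"pose entry {index}: missing field {exc}") from exc
    return CameraPose(image_id=image_id, position=np.asarray(position),
                      direction=np.asarray(direction))


def _pose_from_frame(frame: dict, index: int) -> CameraPose:
    # transforms.json dialect: 4x4 camera-to-world; the camera looks along -z.
    try:
        m = np.asarray(frame["transform_matrix"], dtype=float)
        image_id = str(frame.get("file_path", f"frame_{index:04d}"))
    except (KeyError, TypeError) as exc:
        raise ValueError(f"frame {index}: missing field {exc}") from exc
    if m.shape != (4, 4):
        raise ValueError(f"frame {index}: transform_matrix is not 4x4")
    return CameraPose(image_id=image_id, position=m[:3, 3],
                      direction=-m[:3, 2])


def load_poses(path: str | Path) -> list[CameraPose]:
    """Load camera poses from JSON.

    Two dialects are accepted: a plain array of
    ``{"image_id", "position", "direction"}`` objects, or the
    transforms-matrix layout emitted by radiance-field toolchains
    (``{"frames": [{"file_path", "transform_matrix"}]}``, viewing
    direction taken as the negative z column). Directions are normalized
    on load.
    """
    path = Path(path)
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: not valid JSON: {exc}") from exc
    if isinstance(data, dict) and "frames" in data:
        poses = [_pose_from_frame(f, i) for i, f in enumerate(data["frames"])]
    elif isinstance(data, list):
        poses = [_pose_from_entry(e, i) for i, e in enumerate(data)]
    else:
        raise ValueError(f"{path}: unrecognized pose file layout")
    ids = [p.image_id for p in poses]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate image_id(s) {dup}")
    return poses


def save_poses(poses: list[CameraPose], path: str | Path) -> None:
    """Write poses in the plain-array JSON dialect."""
    payload = [
        {
            "image_id": p.image_id,
            "position": [float(x) for x in p.position],
            "direction": [float(x) for x in p.direction],
        }
        for p in poses
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def estimate_scene_center(poses: list[CameraPose]) -> SceneCenter:
    """Least-squares closest point to all viewing rays.

    Minimizes ``sum_i || (I - d_i d_i^T)(x - p_i) ||^2`` over ``x`` via the
    normal equations ``A x = b`` with ``A = sum_i (I - d_i d_i^T)``. This is
    the canonical common look-at estimator: closed form, deterministic, and
    exact when the rays genuinely intersect.
    """
    if len(poses) < 2:
        raise ValueError("need at least 2 poses to triangulate a center")
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for p in poses:
        proj = np.eye(3) - np.outer(p.direction, p.direction)
        A += proj
        b += proj @ p.position
    if np.linalg.cond(A) > 1e12:
        raise DegenerateGeometryError(
            "viewing rays are (near-)parallel; scene center is unconstrained"
        )
    x = np.linalg.solve(A, b)
    sq = [
        float(np.sum(((np.eye(3) - np.outer(p.direction, p.direction))
                      @ (x - p.position)) ** 2))
        for p in poses
    ]
    return SceneCenter(point=x, residual=float(np.sqrt(np.mean(sq))))


def view_angle(pose: CameraPose, center: np.ndarray) -> float:
    """Angle in degrees between the viewing direction and the line from the
    camera to ``center``; 0° means the camera points exactly at the center."""
    center = np.asarray(center, dtype=float).reshape(3)
    to_center = center - pose.position
    dist = np.linalg.norm(to_center)
    if dist < 1e-12:
        raise ValueError(
            f"pose {pose.image_id!r}: camera sits on the center point; "
            "view angle undefined"
        )
    cosang = float(np.clip(np.dot(pose.direction, to_center / dist), -1, 1))
    return float(np.degrees(np.arccos(cosang)))


def filter_images(
    poses: list[CameraPose],
    center: np.ndarray,
    max_angle: float = 20.0,
) -> list[CameraPose]:
    """Retain the poses whose view angle is at most ``max_angle`` degrees.

    The exclusion rule is strict-greater ("angle greater than 20°" is
    dropped), so an angle exactly at the threshold is kept. Order is
    preserved.
    """
    if not poses:
        raise ValueError("pose list is empty")
    kept = [p for p in poses if view_angle(p, center) <= max_angle]
    logger.info("image alignment filter: retained %d/%d poses (max %.3g°)",
                len(kept), len(poses), max_angle)
    if not kept:
        logger.warning("image alignment filter retained no poses")
    return kept


def subsample_frames(frames: list, source_fps: float = 30.0,
                     target_fps: float = 15.0) -> list:
    """Temporal subsampling of an extracted frame sequence.

    Keeps one frame per ``source_fps / target_fps`` stride starting at the
    first frame (a 15-s, 30-fps clip subsampled at 15 fps gives 225 frames).
    Video decoding itself is out of scope; inputs are already-ordered frame
    identifiers or paths.
    """
    if target_fps <= 0 or source_fps <= 0:
        raise ValueError("frame rates must be positive")
    if target_fps > source_fps:
        raise ValueError("target frame rate exceeds source frame rate")
    stride = int(round(source_fps / target_fps))
    return list(frames[::stride])
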