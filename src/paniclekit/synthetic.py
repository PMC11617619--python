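"""Seedable synthetic fixtures with analytic ground truth.

Every input the pipeline consumes has a generator here: an orbiting camera
rig with known view angles, an over-segmented mask fixture derived from a
known ground-truth silhouette, density grids of analytic solids, and a 3D
scene made of a curved panicle-surrogate tube (known arc length and solid
volume) plus a planar calibration tag of known physical length. The
generators emulate the *geometry* the field pipeline sees — not photometry,
lighting, or real segmentation-model failure modes — so tests built on them
validate the geometric processing, not image understanding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import splev, splprep
from scipy.spatial import cKDTree
from skimage.draw import disk as draw_disk
from skimage.morphology import dilation, disk

from .cloud import SEMANTIC_PANICLE, SEMANTIC_TAG_LABEL
from .field import DensityField
from .masks import InstanceLabel, MaskCandidate, RoughInstance
from .poses import CameraPose

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "make_camera_rig",
    "make_mask_fixture",
    "make_density_field",
    "make_scene_cloud",
]

# Control polygon of the default panicle-surrogate curve (cm): a drooping
# arc about 22 cm long, the length of a mature rice panicle.
DEFAULT_SPLINE_CM = np.array([
    [0.0, 0.0, 0.0],
    [2.0, 0.3, 6.0],
    [5.0, -0.3, 11.0],
    [9.0, 0.2, 15.0],
    [14.0, 0.0, 18.0],
])


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic panicle + tag scene.

    ``scene_scale`` is in scene units per cm (the reconstruction's
    arbitrary metric); the tag's printed length is ``label_length`` cm.
    Point counts default to radiance-field-export densities (mesh vertices
    at grid resolution are dense), which is what makes voxel volume
    counting meaningful.
    """

    rng_seed: int = 0
    scene_scale: float = 0.4
    panicle_spline: np.ndarray = field(
        default_factory=lambda: DEFAULT_SPLINE_CM.copy())
    tube_radius: float = 0.75          # cm
    label_length: float = 7.5          # cm
    label_width: float = 2.5           # cm
    noise_sd: float = 0.02             # cm
    n_panicle: int = 400_000
    n_label: int = 20_000
    n_spurs: int = 0
    spur_length: float = 6.0           # cm
    spur_radius: float = 0.35          # cm
    spur_angle: float = 55.0           # degrees off the local tangent

    def __post_init__(self) -> None:
        if self.scene_scale <= 0:
            raise ValueError("scene_scale must be positive")
        if self.label_length <= 0:
            raise ValueError("label_length must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth for a generated scene."""

    arc_length: float          # cm, main curve
    solid_volume: float        # cm^3, tube(s)
    label_scene_length: float  # scene units
    semantic: np.ndarray       # per-point codes (cloud.SEMANTIC_*)


def _perp(v: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
    """A unit vector perpendicular to v (deterministic unless rng given)."""
    ref = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(ref, v)) > 0.9 * np.linalg.norm(v):
        ref = np.array([1.0, 0.0, 0.0])
    u = ref - np.dot(ref, v) / np.dot(v, v) * v
    u = u / np.linalg.norm(u)
    if rng is not None:
        phi = rng.uniform(0, 2 * np.pi)
        w = np.cross(v / np.linalg.norm(v), u)
        u = np.cos(phi) * u + np.sin(phi) * w
    return u


def make_camera_rig(
    n: int,
    radius: float,
    center: np.ndarray,
    jitter_deg: float | np.ndarray = 0.0,
    rng_seed: int = 0,
) -> tuple[list[CameraPose], np.ndarray]:
    """Cameras equally spaced on a circle around ``center``, aimed at it.

    ``jitter_deg`` is either a scalar (each camera's aim is tilted by a
    uniform random angle in [0, jitter]) or a per-camera array of exact
    tilt angles. Because each direction starts exactly on target and is
    then rotated by the tilt about a perpendicular axis, the returned
    angles ARE the view angles — an analytic oracle for the filter.
    """
    if n < 2:
        raise ValueError("need at least 2 cameras")
    center = np.asarray(center, dtype=float).reshape(3)
    rng = np.random.default_rng(rng_seed)
    if np.isscalar(jitter_deg):
        angles = rng.uniform(0.0, float(jitter_deg), size=n)
    else:
        angles = np.asarray(jitter_deg, dtype=float)
        if angles.shape != (n,):
            raise ValueError("per-camera angle array must have length n")
    poses = []
    for i in range(n):
        phi = 2 * np.pi * i / n
        pos = center + radius * np.array([np.cos(phi), np.sin(phi), 0.0])
        d = center - pos
        d = d / np.linalg.norm(d)
        u = _perp(d, rng)
        theta = np.radians(angles[i])
        direction = np.cos(theta) * d + np.sin(theta) * u
        poses.append(CameraPose(image_id=f"frame_{i:04d}", position=pos,
                                direction=direction))
    return poses, angles


def _blob_mask(shape: tuple[int, int], center: tuple[float, float],
               r0: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth star-convex blob: radius modulated by low-order harmonics."""
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    dy, dx = rows - center[0], cols - center[1]
    phi = np.arctan2(dy, dx)
    r = np.hypot(dy, dx)
    boundary = np.full(phi.shape, r0)
    for k in range(2, 6):
        amp = rng.uniform(0.0, 0.06) * r0
        boundary += amp * np.cos(k * phi + rng.uniform(0, 2 * np.pi))
    return r <= boundary


def _add_protrusions(mask: np.ndarray, center: tuple[float, float],
                     r0: float, rng: np.random.Generator,
                     n: int = 3) -> np.ndarray:
    """Thin radial protrusions (branch surrogates) grafted onto the blob."""
    out = mask.copy()
    h, w = mask.shape
    for _ in range(n):
        phi = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(40, 70)
        for t in np.linspace(0.7 * r0, r0 + length, 60):
            rr = center[0] + t * np.sin(phi)
            cc = center[1] + t * np.cos(phi)
            if 3 <= rr < h - 3 and 3 <= cc < w - 3:
                ridx, cidx = draw_disk((rr, cc), 3, shape=mask.shape)
                out[ridx, cidx] = True
    return out


def _jagged(mask: np.ndarray, rng: np.random.Generator,
            n_bites: int = 40, max_r: int = 4) -> np.ndarray:
    """Degrade a mask boundary with small random bites and bumps."""
    out = mask.copy()
    boundary = mask & ~np.pad(mask, 1)[2:, 1:-1]  # cheap proxy: shifted edge
    coords = np.argwhere(boundary if boundary.any() else mask)
    for _ in range(n_bites):
        r, c = coords[rng.integers(len(coords))]
        rad = int(rng.integers(1, max_r + 1))
        ridx, cidx = draw_disk((r, c), rad, shape=mask.shape)
        if rng.random() < 0.5:
            out[ridx, cidx] = False
        else:
            out[ridx, cidx] = True
    return out


def make_mask_fixture(
    shape: tuple[int, int] = (512, 512),
    rng_seed: int = 0,
) -> dict:
    """Ground-truth silhouette plus emulated segmentation-model outputs.

    The ground truth is a smooth blob with thin protrusions. Candidates are
    the ground truth split by peripheral cuts into a dominant part plus
    small slices (over-segmentation), together with off-target distractor
    blobs and deliberately weak candidates that exercise the area/stability
    filters. The rough instance mask is the ground truth dilated and given
    a jagged boundary, emulating a coarse detector outline.
    """
    if shape[0] < 256 or shape[1] < 256:
        raise ValueError("fixture image must be at least 256 x 256")
    rng = np.random.default_rng(rng_seed)
    h, w = shape
    center = (h / 2.0 + rng.uniform(-10, 10), w / 2.0 + rng.uniform(-10, 10))
    r0 = 0.27 * min(h, w)
    gt = _blob_mask(shape, center, r0, rng)
    gt = _add_protrusions(gt, center, r0, rng)
    gt_area = int(gt.sum())

    # Peripheral cuts: slice off small lobes (each a separate candidate),
    # capped at 4% of the area in total so the dominant part stays dominant.
    rows, cols = np.mgrid[0:h, 0:w]
    main = gt.copy()
    slices = []
    sliced_area = 0
    for _ in range(rng.integers(1, 5)):
        psi = rng.uniform(0, 2 * np.pi)
        t = rng.uniform(0.78, 0.92) * r0
        proj = (rows - center[0]) * np.sin(psi) + (cols - center[1]) * np.cos(psi)
        piece = main & (proj > t)
        a = int(piece.sum())
        if 0 < a and sliced_area + a <= 0.04 * gt_area:
            slices.append(piece)
            main = main & ~piece
            sliced_area += a

    candidates = [MaskCandidate(mask=main, stability=float(rng.uniform(0.85, 0.98)))]
    for piece in slices:
        candidates.append(
            MaskCandidate(mask=piece, stability=float(rng.uniform(0.85, 0.98))))
    # Distractors: blobs far from the target, plus filter-fodder candidates.
    for corner in [(40, 40), (h - 40, w - 40)]:
        ridx, cidx = draw_disk(corner, 60, shape=shape)
        dm = np.zeros(shape, dtype=bool)
        dm[ridx, cidx] = True
        candidates.append(MaskCandidate(mask=dm, stability=float(rng.uniform(0.85, 0.98))))
    low_stab = np.zeros(shape, dtype=bool)
    low_stab[:150, :150] = True
    candidates.append(MaskCandidate(mask=low_stab, stability=0.5))
    tiny = np.zeros(shape, dtype=bool)
    tiny[0:30, 0:30] = True
    candidates.append(MaskCandidate(mask=tiny, stability=0.95))

    rough_mask = _jagged(dilation(gt, disk(12)), rng)
    rough = RoughInstance(mask=rough_mask, label=InstanceLabel.PANICLE)
    return {"gt": gt, "candidates": candidates, "rough": rough}


def make_density_field(
    solid: str,
    grid_n: int = 64,
    radius: float = 1.0,
    tube_radius: float = 0.3,
    margin: float = 0.3,
) -> DensityField:
    """Signed-distance density of an analytic solid (positive inside).

    ``sphere``: radius ``radius`` centered at the origin. ``tube``: a tube
    of radius ``tube_radius`` around one turn of a helix of radius
    ``radius``. The zero level set is the analytic surface, so marching
    cubes at iso 0 can be checked in closed form.
    """
    if grid_n < 32:
        raise ValueError("grid_n must be at least 32")
    if solid == "sphere":
        half = radius + margin
        lin = np.linspace(-half, half, grid_n)
        spacing = lin[1] - lin[0]
        gx, gy, gz = np.meshgrid(lin, lin, lin, indexing="ij")
        values = radius - np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)
        return DensityField(values=values, origin=[-half] * 3,
                            spacing=spacing, iso=0.0)
    if solid == "tube":
        t = np.linspace(0, 2 * np.pi, 800)
        pitch = 0.5
        curve = np.column_stack([radius * np.cos(t), radius * np.sin(t),
                                 pitch * t / (2 * np.pi)])
        half = radius + tube_radius + margin
        lin = np.linspace(-half, half, grid_n)  # cube covers the full turn
        spacing = lin[1] - lin[0]
        gx, gy, gz = np.meshgrid(lin, lin, lin, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        d, _ = cKDTree(curve).query(pts)
        values = (tube_radius - d).reshape(gx.shape)
        return DensityField(values=values, origin=[-half] * 3,
                            spacing=spacing, iso=0.0)
    raise ValueError(f"unknown solid {solid!r}")


def _spline_model(control_cm: np.ndarray):
    ctrl = np.asarray(control_cm, dtype=float)
    tck, _ = splprep(ctrl.T, s=0, k=min(3, len(ctrl) - 1))

    def pos(u):
        return np.column_stack(splev(u, tck))

    def der(u):
        return np.column_stack(splev(u, tck, der=1))

    def speed(u: float) -> float:
        return float(np.linalg.norm(np.asarray(splev(u, tck, der=1))))

    return pos, der, speed


def _arc_length(speed, a: float = 0.0, b: float = 1.0) -> float:
    length, _ = quad(speed, a, b, epsrel=1e-9, limit=400)
    return float(length)


def make_scene_cloud(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Point cloud of a panicle-surrogate tube plus a flat calibration tag.

    Panicle points fill a solid tube of ``tube_radius`` around the panicle
    spline, sampled uniformly in arc length; tag points cover a
    ``label_length`` x ``label_width`` rectangle placed clear of the tube.
    Everything is generated in cm, scaled by ``scene_scale`` into scene
    units, then perturbed by isotropic Gaussian noise. Ground-truth arc
    length comes from adaptive quadrature of the spline speed; the solid
    volume is pi r^2 per unit arc length (exact for a normal-disk sweep),
    plus the clear part of each branch spur.
    """
    rng = np.random.default_rng(spec.rng_seed)
    pos, der, speed = _spline_model(spec.panicle_spline)
    arc = _arc_length(speed)

    # invert arc length -> parameter for uniform sampling along the curve
    ugrid = np.linspace(0, 1, 2001)
    cum = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(pos(ugrid), axis=0), axis=1))])
    cum /= cum[-1]

    n_main = spec.n_panicle if spec.n_spurs == 0 else int(spec.n_panicle * 0.85)
    s = rng.uniform(0, 1, n_main)
    u = np.interp(s, cum, ugrid)
    centers = pos(u)
    tangents = der(u)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    ref = np.array([0.0, 1.0, 0.0])
    normals = ref - tangents * (tangents @ ref)[:, None]
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    binormals = np.cross(tangents, normals)
    rho = spec.tube_radius * np.sqrt(rng.uniform(0, 1, n_main))
    theta = rng.uniform(0, 2 * np.pi, n_main)
    panicle_cm = centers + rho[:, None] * (
        np.cos(theta)[:, None] * normals + np.sin(theta)[:, None] * binormals)

    spur_volume = 0.0
    spur_parts = []
    if spec.n_spurs > 0:
        n_per = (spec.n_panicle - n_main) // spec.n_spurs
        alpha = np.radians(spec.spur_angle)
        # spur tube starts where its axis clears the main tube surface
        s0 = spec.tube_radius / np.sin(alpha)
        # spurs attach along the middle half of the stem: lateral branches
        # are interior structure, and a spur grafted right at a stem end
        # would model a forked tip rather than a branch
        for j in range(spec.n_spurs):
            uj = 0.3 + 0.4 * j / max(spec.n_spurs - 1, 1)
            base = pos([uj])[0]
            tj = der([uj])[0]
            tj /= np.linalg.norm(tj)
            side = _perp(tj, rng)
            axis = np.cos(alpha) * tj + np.sin(alpha) * side
            seg = rng.uniform(s0, spec.spur_length, n_per)
            nj = _perp(axis)
            bj = np.cross(axis, nj)
            rr = spec.spur_radius * np.sqrt(rng.uniform(0, 1, n_per))
            th = rng.uniform(0, 2 * np.pi, n_per)
            spur_parts.append(base + seg[:, None] * axis
                              + rr[:, None] * (np.cos(th)[:, None] * nj
                                               + np.sin(th)[:, None] * bj))
            spur_volume += np.pi * spec.spur_radius ** 2 * (spec.spur_length - s0)
        panicle_cm = np.vstack([panicle_cm] + spur_parts)

    # tag: rectangle in a plane, offset to the side of the tube, tilted
    bbox_mid = 0.5 * (spec.panicle_spline.min(0) + spec.panicle_spline.max(0))
    offset = bbox_mid + np.array([0.0, 8.0, 0.0])
    n_lab = spec.n_label
    uu = rng.uniform(-0.5, 0.5, n_lab) * spec.label_length
    vv = rng.uniform(-0.5, 0.5, n_lab) * spec.label_width
    tilt = rng.uniform(0, 2 * np.pi)
    e1 = np.array([np.cos(tilt), 0.1, np.sin(tilt)])
    e1 /= np.linalg.norm(e1)
    e2 = _perp(e1, rng)
    label_cm = offset + uu[:, None] * e1 + vv[:, None] * e2

    cloud_cm = np.vstack([panicle_cm, label_cm])
    semantic = np.concatenate([
        np.full(len(panicle_cm), SEMANTIC_PANICLE, dtype=np.uint8),
        np.full(n_lab, SEMANTIC_TAG_LABEL, dtype=np.uint8),
    ])
    points = cloud_cm * spec.scene_scale
    if spec.noise_sd > 0:
        points = points + rng.normal(
            0.0, spec.noise_sd * spec.scene_scale, points.shape)

    truth = GroundTruth(
        arc_length=arc,
        solid_volume=np.pi * spec.tube_radius ** 2 * arc + spur_volume,
        label_scene_length=spec.label_length * spec.scene_scale,
        semantic=semantic,
    )
    return points, truth
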