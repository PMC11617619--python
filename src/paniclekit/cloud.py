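"""Point-cloud semantics and metric calibration.

The exported cloud mixes the panicle, the printed reference tag and stray
reconstruction noise. DBSCAN isolates dense components and discards small
ones; covariance-eigenvalue planarity separates the flat tag from the
tubular panicle; the tag's oriented bounding box and a 2D minimum-area
rectangle fit on its median-area face give its in-scene length X1, from
which the cm-per-scene-unit scale is X / X1 with X = 7.5 cm (the tag's
printed length).

For the volume trait the cloud is additionally rescaled by 1/X1 so the tag
has unit length ("label units"); voxel counting then happens on that
normalized cloud.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import LineString, MultiPoint, Polygon
from sklearn.cluster import DBSCAN as _SKDBSCAN

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteredCloud",
    "SemanticCloud",
    "OrientedBox",
    "Calibration",
    "SEMANTIC_NOISE",
    "SEMANTIC_PANICLE",
    "SEMANTIC_TAG_LABEL",
    "LABEL_LENGTH_CM",
    "adaptive_eps",
    "dbscan",
    "drop_small_clusters",
    "planarity_score",
    "assign_semantics",
    "oriented_bounding_box",
    "label_length",
    "calibrate",
]

SEMANTIC_NOISE = 0
SEMANTIC_PANICLE = 1
SEMANTIC_TAG_LABEL = 2

LABEL_LENGTH_CM = 7.5  # printed length of the calibration tag


@dataclass
class ClusteredCloud:
    points: np.ndarray
    cluster_id: np.ndarray  # -1 = noise; clusters are 0..k-1 contiguous

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.cluster_id = np.asarray(self.cluster_id, dtype=int).ravel()
        if len(self.points) != len(self.cluster_id):
            raise ValueError("points and cluster ids disagree in length")
        ids = np.unique(self.cluster_id[self.cluster_id >= 0])
        if len(ids) and not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("cluster ids must be contiguous from 0")

    def cluster_points(self, cid: int) -> np.ndarray:
        return self.points[self.cluster_id == cid]

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_id.max() + 1) if (self.cluster_id >= 0).any() else 0


@dataclass
class SemanticCloud:
    """Points tagged noise / panicle / tag_label (uint8 codes)."""

    points: np.ndarray
    semantic: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.semantic = np.asarray(self.semantic, dtype=np.uint8).ravel()
        if len(self.points) != len(self.semantic):
            raise ValueError("points and semantics disagree in length")

    def of(self, code: int) -> np.ndarray:
        return self.points[self.semantic == code]

    @property
    def panicle(self) -> np.ndarray:
        return self.of(SEMANTIC_PANICLE)

    @property
    def tag_label(self) -> np.ndarray:
        return self.of(SEMANTIC_TAG_LABEL)


@dataclass
class OrientedBox:
    """PCA-aligned bounding box: axes are covariance eigenvectors, extents
    the full side lengths (max - min of projections), sorted descending."""

    center: np.ndarray
    axes: np.ndarray     # rows are unit vectors
    extents: np.ndarray  # full side lengths, descending

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.extents = np.asarray(self.extents, dtype=float).reshape(3)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8):
            raise ValueError("box axes are not orthonormal")

    @property
    def face_areas(self) -> np.ndarray:
        """Areas of the three distinct faces, one per axis pair, descending."""
        e = self.extents
        return np.sort([e[0] * e[1], e[0] * e[2], e[1] * e[2]])[::-1]


@dataclass(frozen=True)
class Calibration:
    """Metric scale from the reference tag: scale = X / X1 cm per scene unit.

    ``normalization`` (= 1/X1) rescales the scene so the tag has unit
    length, the frame in which voxel volume counting is defined.
    """

    x1: float
    x_cm: float = LABEL_LENGTH_CM

    def __post_init__(self) -> None:
        if self.x1 <= 0:
            raise ValueError("tag scene length X1 must be positive")
        if self.x_cm <= 0:
            raise ValueError("tag physical length must be positive")

    @property
    def scale(self) -> float:
        return self.x_cm / self.x1

    @property
    def normalization(self) -> float:
        return 1.0 / self.x1


def adaptive_eps(points: np.ndarray, factor: float = 4.0) -> float:
    """DBSCAN radius as ``factor`` times the median nearest-neighbor
    distance — robust to the cloud's sampling density.

    For a Poisson-distributed cloud the expected neighbor count inside
    ``factor`` median-NN radii is roughly ``(4/3)*pi*(0.554*factor)^3`` in
    a volume and ``pi*(0.47*factor)^2`` on a surface, independent of the
    density itself; factor 4 puts both comfortably above the default
    ``min_pts`` of 10, while factor 2 would sit below it and fragment
    every cluster.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < 2:
        raise ValueError("need at least 2 points for an adaptive radius")
    d, _ = cKDTree(points).query(points, k=2)
    eps = factor * float(np.median(d[:, 1]))
    if eps <= 0:
        raise ValueError("degenerate cloud: median neighbor distance is 0")
    return eps


def dbscan(points: np.ndarray, eps: float | None = None,
           min_pts: int = 10) -> ClusteredCloud:
    """Density-based clustering of the cloud.

    Core points have at least ``min_pts`` neighbors (self included) within
    ``eps``; clusters are maximal density-connected sets and border points
    join the cluster of the first core point reaching them in index order.
    ``eps=None`` uses the adaptive median-neighbor radius.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < 1:
        raise ValueError("empty point cloud")
    if not np.isfinite(points).all():
        raise ValueError("non-finite coordinates in point cloud")
    if eps is None:
        eps = adaptive_eps(points)
    if eps <= 0 or min_pts < 1:
        raise ValueError("eps must be > 0 and min_pts >= 1")
    labels = _SKDBSCAN(eps=eps, min_samples=min_pts).fit_predict(points)
    return ClusteredCloud(points=points, cluster_id=labels)


def drop_small_clusters(clustered: ClusteredCloud,
                        min_size: int = 100) -> ClusteredCloud:
    """Relabel clusters smaller than ``min_size`` points (inclusive keep at
    >=) as noise and re-compact the surviving ids."""
    ids = clustered.cluster_id.copy()
    new_ids = np.full_like(ids, -1)
    next_id = 0
    for cid in range(clustered.n_clusters):
        sel = ids == cid
        if int(sel.sum()) >= min_size:
            new_ids[sel] = next_id
            next_id += 1
    if next_id == 0 and clustered.n_clusters > 0:
        raise ValueError(
            "all clusters fell below the size threshold; review eps/min_size")
    return ClusteredCloud(points=clustered.points, cluster_id=new_ids)


def _sorted_eigh(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    cov = np.cov(pts.T)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]  # descending
    return w[order], v[:, order]


def planarity_score(cluster_points: np.ndarray) -> float:
    """Planarity of a cluster from its covariance eigenvalues.

    With eigenvalues l1 >= l2 >= l3 the score is 1 - l3/l2: a perfect plane
    (l3 = 0) scores 1, an isotropic blob (l3 ~ l2) scores ~0. A printed tag
    is far more planar than a panicle, so this one scalar separates them.
    """
    pts = np.asarray(cluster_points, dtype=float).reshape(-1, 3)
    if len(pts) < 10:
        raise ValueError("need at least 10 points for a planarity score")
    w, _ = _sorted_eigh(pts)
    if w[1] <= 0:
        raise ValueError("cluster is collinear; planarity undefined")
    return float(1.0 - w[2] / w[1])


def assign_semantics(clustered: ClusteredCloud) -> SemanticCloud:
    """Mark the most planar cluster as the tag label, the rest as panicle.

    Ties on planarity break toward the cluster with the smaller extent
    along its thinnest principal axis (the physically thinner object).
    """
    if clustered.n_clusters < 2:
        raise ValueError(
            "need at least 2 clusters to separate the tag from the panicle")
    scores = []
    for cid in range(clustered.n_clusters):
        pts = clustered.cluster_points(cid)
        thickness = oriented_bounding_box(pts).extents[2]
        scores.append((planarity_score(pts), -thickness, cid))
    best_cid = max(scores)[2]
    semantic = np.zeros(len(clustered.points), dtype=np.uint8)
    semantic[clustered.cluster_id >= 0] = SEMANTIC_PANICLE
    semantic[clustered.cluster_id == best_cid] = SEMANTIC_TAG_LABEL
    return SemanticCloud(points=clustered.points, semantic=semantic)


def oriented_bounding_box(points: np.ndarray) -> OrientedBox:
    """PCA-aligned bounding box of a point set.

    Axes are the covariance eigenvectors and extents the max - min of the
    projections, reported in descending order. For a planar tag the third
    extent is its (near-zero) thickness.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 4:
        raise ValueError("need at least 4 points for an oriented box")
    _, v = _sorted_eigh(pts)
    proj = (pts - pts.mean(axis=0)) @ v
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    extents = hi - lo
    order = np.argsort(extents)[::-1]
    axes = v[:, order].T
    center = pts.mean(axis=0) + v @ ((lo + hi) / 2.0)
    return OrientedBox(center=center, axes=axes, extents=extents[order])


def _plane_refined_box(pts: np.ndarray) -> OrientedBox:
    """PCA box with in-plane axes realigned to the minimum-area rectangle.

    For a nearly square tag the two in-plane covariance eigenvalues are
    close and the PCA axes are arbitrarily rotated within the plane, which
    would distort every face of the box; re-deriving the two dominant axes
    from the minimum-area enclosing rectangle of the in-plane projection
    pins them to the tag's actual sides.
    """
    box = oriented_bounding_box(pts)
    plane_axes = box.axes[:2]
    uv = (pts - box.center) @ plane_axes.T
    geom = MultiPoint(uv).minimum_rotated_rectangle
    if not isinstance(geom, Polygon):
        return box
    corners = np.asarray(geom.exterior.coords[:-1])
    side_a = corners[1] - corners[0]
    side_b = corners[2] - corners[1]
    if np.linalg.norm(side_a) < np.linalg.norm(side_b):
        side_a, side_b = side_b, side_a
    a1 = side_a @ plane_axes
    a1 /= np.linalg.norm(a1)
    a3 = np.cross(plane_axes[0], plane_axes[1])
    a2 = np.cross(a3, a1)
    axes = np.vstack([a1, a2, a3])
    proj = (pts - pts.mean(axis=0)) @ axes.T
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    extents = hi - lo
    order = np.argsort(extents)[::-1]
    center = pts.mean(axis=0) + axes.T @ ((lo + hi) / 2.0)
    return OrientedBox(center=center, axes=axes[order], extents=extents[order])


def label_length(label_points: np.ndarray, box: OrientedBox | None = None) -> float:
    """Length of the tag in scene units (X1).

    The tag's points are projected onto the plane of the box face with the
    median area and a minimum-area enclosing rectangle is fitted to the
    projection; X1 is the rectangle's longer side. The median-area face of
    a thin slab is spanned by its longest and thinnest axes, so the
    projection views the tag side-on and the long rectangle side is its
    length. Degenerate (collinear) projections fall back to the maximum
    spread, which is the same length.
    """
    pts = np.asarray(label_points, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise ValueError("need at least 3 tag points")
    if box is None:
        box = _plane_refined_box(pts)
    # Face areas per axis pair: (0,1), (0,2), (1,2); median by construction
    # is the (longest, thinnest) = (0, 2) pair for descending extents.
    e = box.extents
    pair_areas = {(0, 1): e[0] * e[1], (0, 2): e[0] * e[2],
                  (1, 2): e[1] * e[2]}
    median_area = float(np.median(list(pair_areas.values())))
    pair = min(pair_areas, key=lambda k: abs(pair_areas[k] - median_area))
    plane_axes = box.axes[list(pair)]
    uv = (pts - box.center) @ plane_axes.T
    geom = MultiPoint(uv).minimum_rotated_rectangle
    if isinstance(geom, Polygon):
        corners = np.asarray(geom.exterior.coords[:-1])
        sides = np.linalg.norm(np.diff(corners, axis=0, append=corners[:1]),
                               axis=1)
        x1 = float(sides.max())
    elif isinstance(geom, LineString):  # collinear projection
        x1 = float(geom.length)
    else:  # single point
        raise ValueError("tag projection is degenerate (single point)")
    if x1 <= 0:
        raise ValueError("fitted tag length is not positive")
    return x1


def calibrate(x1: float, x_cm: float = LABEL_LENGTH_CM) -> Calibration:
    """Metric calibration from the tag's scene length X1 and its known
    printed length X (cm): scale = X / X1 cm per scene unit."""
    return Calibration(x1=float(x1), x_cm=float(x_cm))
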