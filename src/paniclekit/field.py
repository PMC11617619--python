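"""Density-grid to point-cloud conversion.

A trained radiance field is queried on a regular grid to give an explicit
scalar density volume; marching cubes extracts the iso-density surface as a
triangle mesh and the deduplicated mesh vertices become the working point
cloud. Only the exported grid is consumed here — field training and
rendering happen upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import marching_cubes as _skimage_marching_cubes

logger = logging.getLogger(__name__)

__all__ = ["DensityField", "TriangleMesh", "marching_cubes", "mesh_to_cloud"]


@dataclass
class DensityField:
    """A scalar density volume on a regular grid.

    Grid index (i, j, k) maps to scene point ``origin + spacing * (i, j, k)``.
    ``iso`` defaults to the midpoint of the value range, the usual choice
    when exporting radiance-field density without a calibrated threshold.
    """

    values: np.ndarray
    origin: np.ndarray
    spacing: float
    iso: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("values must be a 3D grid with every axis >= 2")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = float(self.spacing)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.iso is None:
            self.iso = float(self.values.min() + self.values.max()) / 2.0
        else:
            self.iso = float(self.iso)


@dataclass
class TriangleMesh:
    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces):
            if self.faces.max() >= len(self.vertices) or self.faces.min() < 0:
                raise ValueError("face index out of range")
            a, b, c = self.faces.T
            if np.any((a == b) | (b == c) | (a == c)):
                raise ValueError("degenerate face with repeated vertices")

    @property
    def is_empty(self) -> bool:
        return len(self.vertices) == 0


_EMPTY_MESH = lambda: TriangleMesh(np.empty((0, 3)), np.empty((0, 3), int))


def marching_cubes(fld: DensityField) -> TriangleMesh:
    """Extract the iso-density surface as a triangle mesh.

    Standard lookup-table marching cubes with linear edge interpolation;
    vertices are mapped to scene coordinates via origin and spacing. An iso
    level outside the value range (no surface crossing anywhere) yields an
    empty mesh with a warning rather than an error, so sweeping iso levels
    is cheap.
    """
    vmin, vmax = float(fld.values.min()), float(fld.values.max())
    if not vmin < fld.iso < vmax:
        logger.warning(
            "iso level %.6g outside open value range (%.6g, %.6g); "
            "returning empty mesh", fld.iso, vmin, vmax)
        return _EMPTY_MESH()
    verts, faces, _, _ = _skimage_marching_cubes(
        fld.values, level=fld.iso, spacing=(fld.spacing,) * 3)
    return TriangleMesh(vertices=verts + fld.origin, faces=faces)


def mesh_to_cloud(mesh: TriangleMesh) -> np.ndarray:
    """Deduplicated mesh vertices as an N x 3 point cloud (scene units)."""
    if mesh.is_empty:
        logger.warning("empty mesh; returning empty cloud")
        return np.empty((0, 3))
    return np.unique(mesh.vertices, axis=0)
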