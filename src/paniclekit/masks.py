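"""Ensemble 2D mask post-processing.

A generic segmenter proposes many candidate masks per frame with a
per-mask stability score but no semantics; a detector provides rough
instance masks (panicle, tag label) that carry the semantics but have poor
boundaries. The fusion procedure keeps the sharp candidate boundaries and
the rough semantics: candidates are filtered by area and stability, each
rough instance is eroded into an inner region (positive prompts) and an
edge ring (negative prompts), prompts select candidates by containment,
and the selected candidates are merged by pixelwise union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from skimage.morphology import dilation, disk, erosion

logger = logging.getLogger(__name__)

__all__ = [
    "InstanceLabel",
    "MaskCandidate",
    "RoughInstance",
    "PromptSet",
    "filter_candidates",
    "erode_instance",
    "sample_prompts",
    "match_and_merge",
    "compose_rgba",
    "fuse_instance",
    "fuse_frame",
]

DEFAULT_MIN_AREA = 10_000          # px; candidates smaller than this are noise
DEFAULT_MIN_STABILITY = 0.8


class InstanceLabel(str, Enum):
    PANICLE = "panicle"
    TAG_LABEL = "tag_label"


def _as_mask(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid)
    if grid.ndim != 2 or grid.shape[0] < 1 or grid.shape[1] < 1:
        raise ValueError("mask must be a non-empty 2D raster")
    return grid.astype(bool)


@dataclass
class MaskCandidate:
    """A candidate foreground mask with its stability score.

    ``area`` is always recomputed from the raster; a stale sidecar value
    cannot leak through.
    """

    mask: np.ndarray
    stability: float
    area: int = field(init=False)

    def __post_init__(self) -> None:
        self.mask = _as_mask(self.mask)
        if not 0.0 <= self.stability <= 1.0:
            raise ValueError(f"stability {self.stability} outside [0, 1]")
        self.area = int(self.mask.sum())


@dataclass
class RoughInstance:
    """A rough instance mask with its semantic label."""

    mask: np.ndarray
    label: InstanceLabel

    def __post_init__(self) -> None:
        self.mask = _as_mask(self.mask)
        self.label = InstanceLabel(self.label)
        if not self.mask.any():
            raise ValueError("rough instance mask is empty")


@dataclass(frozen=True)
class PromptSet:
    """Positive/negative point prompts in (row, col) pixel coordinates."""

    positives: tuple
    negatives: tuple


def filter_candidates(
    candidates: list[MaskCandidate],
    min_area: int = DEFAULT_MIN_AREA,
    min_stability: float = DEFAULT_MIN_STABILITY,
) -> list[MaskCandidate]:
    """Drop candidates with area *smaller than* ``min_area`` or stability
    *below* ``min_stability``; boundary equality is retained."""
    kept = [c for c in candidates
            if c.area >= min_area and c.stability >= min_stability]
    logger.info("candidate filter: retained %d/%d", len(kept), len(candidates))
    return kept


def erode_instance(
    instance: RoughInstance, radius: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Split a rough mask into an inner region and an edge ring.

    ``inner`` is the morphological erosion by a disk of ``radius`` pixels,
    ``ring`` the removed boundary band; together they partition the mask.
    If erosion would empty a thin mask the radius is halved until the inner
    region survives; at radius 0 the ring is empty (warned).
    """
    mask = instance.mask
    r = int(radius)
    while r > 0:
        inner = erosion(mask, disk(r))
        if inner.any():
            return inner, mask & ~inner
        r //= 2
    logger.warning("erosion emptied the mask at every radius; returning the "
                   "mask unshrunk with an empty ring")
    return mask.copy(), np.zeros_like(mask)


def _positive_count(inner_area: int) -> int:
    # Monotone area-to-count rule spanning the 3..5 prompt range.
    if inner_area < 20_000:
        return 3
    if inner_area < 50_000:
        return 4
    return 5


def _sample_region(region: np.ndarray, k: int,
                   rng: np.random.Generator) -> tuple:
    coords = np.argwhere(region)
    if len(coords) < k:
        logger.warning("prompt region has %d px, fewer than the requested "
                       "%d samples; using all", len(coords), k)
        k = len(coords)
    idx = rng.choice(len(coords), size=k, replace=False)
    return tuple(map(tuple, coords[np.sort(idx)]))


def sample_prompts(
    inner: np.ndarray,
    ring: np.ndarray,
    rng_seed: int,
) -> PromptSet:
    """Sample positive prompts from the inner region and 3 negatives from
    the edge ring, uniformly without replacement.

    The positive count follows the inner area (3 below 20k px, 4 below
    50k px, 5 otherwise). If the ring is empty, negatives are drawn from a
    5-px dilation band just outside the mask instead.
    """
    inner = _as_mask(inner)
    ring = _as_mask(ring)
    if not inner.any():
        raise ValueError("inner region is empty; cannot place positives")
    if not ring.any():
        mask = inner
        ring = dilation(mask, disk(5)) & ~mask
        if not ring.any():
            raise ValueError("no pixels available for negative prompts")
    rng = np.random.default_rng(rng_seed)
    positives = _sample_region(inner, _positive_count(int(inner.sum())), rng)
    negatives = _sample_region(ring, 3, rng)
    return PromptSet(positives=positives, negatives=negatives)


def match_and_merge(
    prompts: PromptSet, candidates: list[MaskCandidate]
) -> np.ndarray:
    """Union of the candidates selected by the prompts.

    A candidate is selected iff it contains at least one positive point and
    no negative point (negatives veto). An empty selection returns an empty
    mask with a warning so batch processing can drop the frame.
    """
    if not candidates:
        logger.warning("no candidates to match; returning empty mask")
        return np.zeros((1, 1), dtype=bool)
    shape = candidates[0].mask.shape
    out = np.zeros(shape, dtype=bool)
    n_sel = 0
    for cand in candidates:
        if cand.mask.shape != shape:
            raise ValueError("candidate masks disagree in shape")
        if any(cand.mask[r, c] for r, c in prompts.negatives):
            continue
        if any(cand.mask[r, c] for r, c in prompts.positives):
            out |= cand.mask
            n_sel += 1
    if n_sel == 0:
        logger.warning("no candidate matched the prompts; frame treated as "
                       "segmentation-failed")
    return out


def compose_rgba(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Attach the mask as an alpha channel (255 inside, 0 outside)."""
    image = np.asarray(image)
    mask = _as_mask(mask)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be H x W x 3")
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"image {image.shape[:2]} and mask {mask.shape} shapes disagree")
    rgba = np.zeros(image.shape[:2] + (4,), dtype=np.uint8)
    rgba[..., :3] = image
    rgba[..., 3] = np.where(mask, 255, 0).astype(np.uint8)
    return rgba


def fuse_instance(
    instance: RoughInstance,
    candidates: list[MaskCandidate],
    rng_seed: int,
    erosion_radius: int = 5,
) -> np.ndarray:
    """Refine one rough instance: erode, prompt, match, merge."""
    inner, ring = erode_instance(instance, radius=erosion_radius)
    prompts = sample_prompts(inner, ring, rng_seed=rng_seed)
    return match_and_merge(prompts, candidates)


def fuse_frame(
    instances: list[RoughInstance],
    candidates: list[MaskCandidate],
    rng_seed: int,
    min_area: int = DEFAULT_MIN_AREA,
    min_stability: float = DEFAULT_MIN_STABILITY,
    erosion_radius: int = 5,
) -> np.ndarray:
    """Full per-frame fusion over all instances.

    Candidates are filtered once; each instance (panicle, tag label) is
    fused independently with its own derived seed and the refined masks are
    OR-ed into the frame foreground — both the panicle and the calibration
    label must survive into the 3D scene.
    """
    kept = filter_candidates(candidates, min_area=min_area,
                             min_stability=min_stability)
    if not instances:
        raise ValueError("no rough instances supplied")
    shape = instances[0].mask.shape
    out = np.zeros(shape, dtype=bool)
    for i, inst in enumerate(instances):
        fused = fuse_instance(inst, kept, rng_seed=rng_seed + i,
                              erosion_radius=erosion_radius)
        if fused.shape == out.shape:
            out |= fused
    return out
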