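"""Lung delineation: bounding ROI, seeded region growing at a fixed HU
threshold, leak detection, and automatic ROI-retry.

The lung is the maximal connected set of voxels with HU at or below the
threshold (default -160 HU) that contains the seed, restricted to a
bounding ROI whose superior face sits 2 mm above the carina.  The ROI
intentionally admits the proximal airways, and no airway stripping is
performed (documented limitation).  If the grown region escapes into
outside-body air ("leak"), the offending ROI faces are stepped inward and
the growth repeated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .image import Box, VolumeImage

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD_HU = -160.0
SUPERIOR_MARGIN_MM = 2.0


def superior_offset_planes(spacing_z_mm: float, margin_mm: float = SUPERIOR_MARGIN_MM) -> int:
    """Number of voxel planes corresponding to the superior ROI margin."""
    return int(round(margin_mm / spacing_z_mm))


@dataclass(frozen=True)
class BoundingROI:
    """Axis-aligned segmentation ROI anchored to the carina landmark.

    The superior (high-z) face lies ``superior_offset_planes`` above the
    carina, rounded to the nearest voxel plane; lateral and inferior faces
    default to the full grid.
    """

    box: Box
    carina_voxel: tuple[int, int, int]

    @property
    def n_voxels(self) -> int:
        return self.box.n_voxels


@dataclass
class LungMask:
    """Boolean lung mask plus the provenance of its segmentation."""

    mask: np.ndarray
    seed_voxel: tuple[int, int, int]
    threshold_hu: float
    roi: BoundingROI
    connectivity: int
    leak_flag: bool = False
    retries: int = 0

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def define_lung_roi(
    image: VolumeImage,
    carina_voxel: tuple[int, int, int],
    lateral_box: Box | None = None,
    margin_mm: float = SUPERIOR_MARGIN_MM,
) -> BoundingROI:
    """Bounding ROI with its superior face ``margin_mm`` above the carina.

    ``lateral_box`` optionally restricts the in-plane and inferior extent
    (e.g. to the body); by default the ROI spans the full grid below the
    superior face.  A superior face beyond the grid is clamped with a
    warning.
    """
    shape = image.shape
    carina_voxel = tuple(int(v) for v in carina_voxel)
    if not all(0 <= c < s for c, s in zip(carina_voxel, shape)):
        raise ValueError(f"carina voxel {carina_voxel} outside grid {shape}")
    offset = superior_offset_planes(image.spacing_mm[0], margin_mm)
    hi_z = carina_voxel[0] + offset
    if hi_z > shape[0]:
        log.warning(
            "superior ROI face (plane %d) beyond grid top (%d); clamping", hi_z, shape[0]
        )
        hi_z = shape[0]
    if hi_z <= 0:
        raise ValueError("carina placement leaves an empty ROI")
    if lateral_box is None:
        lo = (0, 0, 0)
        hi = (hi_z, shape[1], shape[2])
    else:
        lo = (lateral_box.lo[0], lateral_box.lo[1], lateral_box.lo[2])
        hi = (min(hi_z, lateral_box.hi[0]), lateral_box.hi[1], lateral_box.hi[2])
    box = Box(lo, hi).clipped(shape)
    return BoundingROI(box=box, carina_voxel=carina_voxel)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def choose_seed(
    image: VolumeImage, roi: BoundingROI, hu_max: float = -400.0
) -> tuple[int, int, int]:
    """Automatic seed: centroid of the clearly-air voxels (HU < hu_max)
    inside the ROI, snapped to the nearest such voxel if the centroid
    itself is not air (e.g. it falls in the mediastinum between lobes)."""
    sl = roi.box.slices()
    air = image.values[sl] < hu_max
    idx = np.argwhere(air)
    if idx.size == 0:
        raise ValueError(f"no voxels below {hu_max} HU inside the ROI")
    centroid = idx.mean(axis=0)
    c = tuple(int(round(v)) for v in centroid)
    if not air[c]:
        d2 = ((idx - centroid) ** 2).sum(axis=1)
        c = tuple(int(v) for v in idx[int(np.argmin(d2))])
    return tuple(int(c[i] + roi.box.lo[i]) for i in range(3))


def grow_lung(
    image: VolumeImage,
    seed_voxel: tuple[int, int, int],
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    roi: BoundingROI | None = None,
    connectivity: int = 26,
) -> LungMask:
    """Seeded region growing: maximal connected HU <= threshold component
    containing the seed, restricted to the ROI.  Deterministic."""
    if image.scale != "HU":
        raise ValueError("segmentation requires a calibrated (HU-scale) image")
    if roi is None:
        roi = BoundingROI(
            box=Box((0, 0, 0), image.shape), carina_voxel=(image.shape[0] - 1, 0, 0)
        )
    seed_voxel = tuple(int(v) for v in seed_voxel)
    if not roi.box.contains(seed_voxel):
        raise ValueError(f"seed {seed_voxel} outside the bounding ROI {roi.box}")
    seed_hu = float(image.values[seed_voxel])
    if seed_hu > threshold_hu:
        raise ValueError(
            f"seed not in lung-density range: HU={seed_hu:.1f} > threshold {threshold_hu}"
        )
    sl = roi.box.slices()
    below = image.values[sl] <= threshold_hu
    labels, _ = ndimage.label(below, structure=_structure(connectivity))
    seed_local = tuple(s - l for s, l in zip(seed_voxel, roi.box.lo))
    lab = labels[seed_local]
    mask = np.zeros(image.shape, bool)
    mask[sl] = labels == lab
    return LungMask(
        mask=mask,
        seed_voxel=seed_voxel,
        threshold_hu=threshold_hu,
        roi=roi,
        connectivity=connectivity,
    )


def touched_faces(mask: np.ndarray, box: Box) -> list[tuple[int, int]]:
    """ROI faces the mask touches, as (axis, side) with side 0=lo, 1=hi."""
    sl = box.slices()
    sub = mask[sl]
    faces = []
    for axis in range(3):
        lo_face = np.take(sub, 0, axis=axis)
        hi_face = np.take(sub, sub.shape[axis] - 1, axis=axis)
        if lo_face.any():
            faces.append((axis, 0))
        if hi_face.any():
            faces.append((axis, 1))
    return faces


def detect_leak(
    lung: LungMask,
    max_faces: int = 2,
    max_volume_fraction: float = 0.9,
) -> bool:
    """Flag probable segmentation escape into trachea/outside-body air.

    True if the mask touches more than ``max_faces`` ROI faces or fills
    more than ``max_volume_fraction`` of the ROI volume.
    """
    if lung.voxel_count == 0:
        return False
    faces = touched_faces(lung.mask, lung.roi.box)
    if len(faces) > max_faces:
        return True
    return lung.voxel_count > max_volume_fraction * lung.roi.n_voxels


def segment_with_retry(
    image: VolumeImage,
    seed_voxel: tuple[int, int, int],
    roi: BoundingROI,
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    connectivity: int = 26,
    max_retries: int = 3,
    step_mm: float = 0.5,
    max_faces: int = 2,
    max_volume_fraction: float = 0.9,
) -> LungMask:
    """Grow; on leak, shrink the touched ROI faces by ``step_mm`` and
    re-grow, up to ``max_retries``.  A still-leaking final mask is
    returned with ``leak_flag=True`` for manual review (not an error)."""
    lung = grow_lung(image, seed_voxel, threshold_hu, roi, connectivity)
    retries = 0
    while detect_leak(lung, max_faces, max_volume_fraction) and retries < max_retries:
        steps = [max(1, int(round(step_mm / s))) for s in image.spacing_mm]
        lo = list(roi.box.lo)
        hi = list(roi.box.hi)
        for axis, side in touched_faces(lung.mask, roi.box):
            if side == 0:
                lo[axis] += steps[axis]
            else:
                hi[axis] -= steps[axis]
        if any(h - l < 2 for l, h in zip(lo, hi)):
            log.warning("ROI collapsed during retry; returning flagged mask")
            break
        new_box = Box(tuple(lo), tuple(hi))
        if not new_box.contains(seed_voxel):
            log.warning("seed left the ROI during retry; returning flagged mask")
            break
        roi = replace(roi, box=new_box)
        retries += 1
        log.info("segmentation leak: retry %d with ROI %s", retries, new_box)
        lung = grow_lung(image, seed_voxel, threshold_hu, roi, connectivity)
    lung.retries = retries
    lung.leak_flag = detect_leak(lung, max_faces, max_volume_fraction)
    return lung


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
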