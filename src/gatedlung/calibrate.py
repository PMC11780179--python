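"""Hounsfield-unit calibration from in-image air/water references, and
edge-preserving bilateral pre-filtering.

Calibration follows the standard two-anchor convention: the mean raw grey
value over a tracheal-air ROI is mapped to -1000 HU and the mean over a
water-equivalent ROI to 0 HU; the map is affine, so it is applied per
image pair with the references measured on that pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .image import Box, VolumeImage

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationRefs:
    """Raw grey values measured over trachea-air and water reference ROIs."""

    raw_air: float
    raw_water: float

    def __post_init__(self) -> None:
        if self.raw_air == self.raw_water:
            raise ValueError("degenerate calibration: raw_air == raw_water")


def measure_reference(image: VolumeImage, roi: Box) -> float:
    """Arithmetic mean of the raw values inside an axis-aligned box ROI."""
    if not roi.inside(image.shape):
        raise ValueError(f"reference ROI {roi} extends outside the grid {image.shape}")
    if roi.n_voxels < 8:
        raise ValueError(f"reference ROI must contain at least 8 voxels, got {roi.n_voxels}")
    return float(image.values[roi.slices()].mean())


def refs_from_image(image: VolumeImage) -> CalibrationRefs:
    """Measure calibration references from the ROIs carried in image metadata."""
    try:
        trachea = image.meta["trachea_roi"]
        water = image.meta["water_roi"]
    except KeyError as exc:
        raise ValueError(
            "image metadata carries no calibration ROIs; supply them explicitly"
        ) from exc
    if not isinstance(trachea, Box):
        trachea = Box.from_json(trachea)
    if not isinstance(water, Box):
        water = Box.from_json(water)
    return CalibrationRefs(
        raw_air=measure_reference(image, trachea),
        raw_water=measure_reference(image, water),
    )


def rescale_to_hu(image: VolumeImage, refs: CalibrationRefs) -> VolumeImage:
    """Affine rescale of raw grey values to HU through the two anchors.

    ``HU(v) = 1000 * (v - raw_water) / (raw_water - raw_air)`` so that the
    measured water reference maps to 0 and the air reference to -1000.
    Spacing, phase and metadata are preserved; output scale is ``HU``.
    """
    if image.scale == "HU":
        raise ValueError("image is already on the HU scale")
    hu = 1000.0 * (image.values - refs.raw_water) / (refs.raw_water - refs.raw_air)
    log.debug(
        "calibrated with raw_air=%.4f raw_water=%.4f (slope %.6f HU/raw)",
        refs.raw_air, refs.raw_water, 1000.0 / (refs.raw_water - refs.raw_air),
    )
    return image.with_values(hu, scale="HU")


# ---------------------------------------------------------------------------
# Bilateral filtering

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @njit(cache=False, fastmath=True)
    def _bilateral_core(padded, out, offsets, sw, inv2sr2, rz, ry, rx):
        nz, ny, nx = out.shape
        K = offsets.shape[0]
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    c = padded[z + rz, y + ry, x + rx]
                    num = 0.0
                    den = 0.0
                    for k in range(K):
                        v = padded[
                            z + rz + offsets[k, 0],
                            y + ry + offsets[k, 1],
                            x + rx + offsets[k, 2],
                        ]
                        d = v - c
                        w = sw[k] * np.exp(-d * d * inv2sr2)
                        num += w * v
                        den += w
                    out[z, y, x] = num / den
        return out


def _bilateral_numpy(padded, shape, offsets, sw, inv2sr2, rz, ry, rx):
    nz, ny, nx = shape
    center = padded[rz : rz + nz, ry : ry + ny, rx : rx + nx]
    num = np.zeros(shape)
    den = np.zeros(shape)
    for (dz, dy, dx), w_s in zip(offsets, sw):
        v = padded[
            rz + dz : rz + dz + nz, ry + dy : ry + dy + ny, rx + dx : rx + dx + nx
        ]
        w = w_s * np.exp(-((v - center) ** 2) * inv2sr2)
        num += w * v
        den += w
    return num / den


def bilateral_filter(
    image: VolumeImage,
    sigma_spatial_mm: float = 0.075,
    sigma_range: float = 100.0,
) -> VolumeImage:
    """Edge-preserving bilateral filter.

    Each voxel is replaced by the normalized Gaussian-weighted mean of its
    neighborhood, with weights the product of a spatial Gaussian (sigma in
    mm, converted per axis through the voxel spacing, neighborhood
    truncated at 3 spatial sigmas) and a range Gaussian on the intensity
    difference (``sigma_range`` in the image's intensity units).  Constant
    regions are unchanged and the output is bounded by the input extrema.
    """
    if sigma_spatial_mm <= 0 or sigma_range <= 0:
        raise ValueError("bilateral filter sigmas must be positive")
    sig_vox = [sigma_spatial_mm / s for s in image.spacing_mm]
    radii = [max(1, int(np.ceil(3.0 * sv))) for sv in sig_vox]
    grids = np.meshgrid(
        *[np.arange(-r, r + 1) for r in radii], indexing="ij"
    )
    offsets = np.stack([g.ravel() for g in grids], axis=1).astype(np.int64)
    sw = np.exp(
        -0.5 * sum((grids[i].ravel() / sig_vox[i]) ** 2 for i in range(3))
    )
    inv2sr2 = 1.0 / (2.0 * sigma_range**2)
    # 'symmetric' matches scipy.ndimage's 'reflect' boundary convention
    padded = np.pad(
        np.asarray(image.values, float),
        [(r, r) for r in radii],
        mode="symmetric",
    )
    rz, ry, rx = radii
    if _HAVE_NUMBA:
        out = np.empty(image.shape)
        _bilateral_core(padded, out, offsets, sw, inv2sr2, rz, ry, rx)
    else:  # pragma: no cover
        out = _bilateral_numpy(padded, image.shape, offsets, sw, inv2sr2, rz, ry, rx)
    return image.with_values(out)
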