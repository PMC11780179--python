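"""Volumetric image container and file IO.

Arrays are indexed ``(z, y, x)`` with ``z`` the axial direction (index
increases toward the superior / head end).  ``spacing_mm`` is stored per
array axis in the same ``(z, y, x)`` order.  Physical positions are voxel-
center based; boxes are half-open ``[lo, hi)`` in 0-based voxel indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

PHASES = ("inspiration", "expiration", "unknown")
SCALES = ("raw", "HU")


@dataclass(frozen=True)
class Box:
    """Axis-aligned half-open voxel box ``[lo, hi)`` in (z, y, x) order."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.lo) != 3 or len(self.hi) != 3:
            raise ValueError("Box corners must be 3-tuples")
        if any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"empty Box: lo={self.lo} hi={self.hi}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    def contains(self, voxel: Sequence[int]) -> bool:
        return all(l <= v < h for v, l, h in zip(voxel, self.lo, self.hi))

    def clipped(self, shape: Sequence[int]) -> "Box":
        lo = tuple(int(np.clip(l, 0, s)) for l, s in zip(self.lo, shape))
        hi = tuple(int(np.clip(h, 0, s)) for h, s in zip(self.hi, shape))
        return Box(lo, hi)

    def inside(self, shape: Sequence[int]) -> bool:
        return all(l >= 0 and h <= s for l, h, s in zip(self.lo, self.hi, shape))

    def to_json(self) -> list[list[int]]:
        return [list(self.lo), list(self.hi)]

    @classmethod
    def from_json(cls, obj: Sequence[Sequence[int]]) -> "Box":
        return cls(tuple(int(v) for v in obj[0]), tuple(int(v) for v in obj[1]))


@dataclass
class VolumeImage:
    """A 3D scalar grid with spacing, respiratory phase and intensity scale.

    ``scale`` records whether voxel values are raw reconstructed grey
    values or calibrated Hounsfield units; it is never implicit.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    phase: str = "unknown"
    scale: str = "raw"
    subject: str | None = None
    timepoint: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("values must be a non-empty 3D array")
        if np.isscalar(self.spacing_mm):
            self.spacing_mm = (float(self.spacing_mm),) * 3
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def with_values(self, values: np.ndarray, **changes) -> "VolumeImage":
        """Copy of this image with new voxel data (and optional field changes)."""
        out = replace(self, values=values, **changes)
        out.meta = dict(self.meta)
        return out


def save_volume(image: VolumeImage, path: str | Path) -> Path:
    """Write a volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        # NIfTI stores (x, y, z); our arrays are (z, y, x).
        data = np.ascontiguousarray(image.values.transpose(2, 1, 0))
        affine = np.diag(list(image.spacing_mm[::-1]) + [1.0])
        nib.save(nib.Nifti1Image(data, affine), str(path))
    elif path.suffix in (".mha", ".mhd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(image.values)
        img.SetSpacing(tuple(image.spacing_mm[::-1]))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    return path


def load_volume(
    path: str | Path,
    phase: str = "unknown",
    scale: str = "raw",
    subject: str | None = None,
    timepoint: float | None = None,
    meta: Mapping | None = None,
) -> VolumeImage:
    """Read a NIfTI or MetaImage volume into a :class:`VolumeImage`."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        values = np.asarray(img.dataobj).transpose(2, 1, 0)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])[::-1]
    elif path.suffix in (".mha", ".mhd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        values = sitk.GetArrayFromImage(img)
        spacing = tuple(float(s) for s in img.GetSpacing())[::-1]
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    return VolumeImage(
        values=values,
        spacing_mm=spacing,
        phase=phase,
        scale=scale,
        subject=subject,
        timepoint=timepoint,
        meta=dict(meta or {}),
    )
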