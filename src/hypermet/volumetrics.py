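"""Plane-averaged tumor volumetry from per-plane segmentation masks.

Volume per imaging plane is voxel count × in-plane pixel area × slice
spacing; the final tumor volume is the arithmetic mean over the coronal,
sagittal and axial T2-weighted segmentations.  For gapped acquisitions the
default slice spacing is thickness + gap (center-to-center, the
conventional choice for volumetrizing gapped 2-D stacks); ``"thickness"``
mode multiplies by slice thickness alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = ["PlaneMask", "mask_volume", "plane_averaged_volume",
           "read_mask_nifti", "PLANE_LABELS"]

PLANE_LABELS = ("coronal", "sagittal", "axial")


@dataclass
class PlaneMask:
    """Binary voxel mask of one imaging plane stack plus its geometry.

    ``mask`` is (slices, rows, cols); spacings in mm.  Defaults mirror a
    RARE T2-weighted protocol: 0.75 mm slices with a 0.25 mm gap.
    """

    mask: np.ndarray
    in_plane_spacing_mm: tuple[float, float]
    slice_thickness_mm: float = 0.75
    slice_gap_mm: float = 0.25
    plane_label: str = "axial"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D (slices, rows, cols)")
        dr, dc = self.in_plane_spacing_mm
        if dr <= 0 or dc <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("spacings must be > 0")
        if self.slice_gap_mm < 0:
            raise ValueError("slice gap must be >= 0")
        if self.plane_label not in PLANE_LABELS:
            raise ValueError(f"plane_label must be one of {PLANE_LABELS}")


def mask_volume(mask: PlaneMask, slice_mode: str = "center_to_center") -> float:
    """Tumor volume (mm³) of one plane stack.

    ``slice_mode='center_to_center'`` (default) uses thickness + gap as the
    per-slice extent; ``'thickness'`` uses the excited slab alone.
    """
    if slice_mode == "center_to_center":
        dz = mask.slice_thickness_mm + mask.slice_gap_mm
    elif slice_mode == "thickness":
        dz = mask.slice_thickness_mm
    else:
        raise ValueError("slice_mode must be 'center_to_center' or 'thickness'")
    dr, dc = mask.in_plane_spacing_mm
    return float(mask.mask.sum()) * dr * dc * dz


def plane_averaged_volume(masks: Iterable[PlaneMask],
                          slice_mode: str = "center_to_center") -> float:
    """Mean of the three per-plane volumes (coronal, sagittal, axial).

    Exactly one mask per plane label is required.
    """
    masks = list(masks)
    labels = sorted(m.plane_label for m in masks)
    if labels != sorted(PLANE_LABELS):
        raise ValueError(
            f"need exactly one mask per plane {PLANE_LABELS}, got {labels}")
    return float(np.mean([mask_volume(m, slice_mode) for m in masks]))


def read_mask_nifti(path, plane_label: str,
                    slice_thickness_mm: float | None = None,
                    slice_gap_mm: float = 0.0,
                    slice_axis: int = 2) -> PlaneMask:
    """Load a binary segmentation mask from NIfTI, geometry from the header.

    The header voxel size along ``slice_axis`` is taken as the slice
    thickness unless overridden; NIfTI stores center-to-center spacing, so
    pass an explicit thickness + gap split if the acquisition was gapped.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj) > 0
    zooms = img.header.get_zooms()[:3]
    in_plane = tuple(z for i, z in enumerate(zooms) if i != slice_axis)
    data = np.moveaxis(data, slice_axis, 0)
    thickness = zooms[slice_axis] if slice_thickness_mm is None \
        else slice_thickness_mm
    return PlaneMask(data, (float(in_plane[0]), float(in_plane[1])),
                     float(thickness), float(slice_gap_mm), plane_label)
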