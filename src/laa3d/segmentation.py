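"""Threshold-based extraction of the contrast-enhanced blood-pool mask.

The left atrium and its appendage appear bright on contrast-enhanced CT; a
global intensity threshold separates the blood pool from the myocardium and
background, and a seeded connected-component pass isolates the left-atrial
pool from other enhancing structures.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import BinaryMask, ImageVolume

__all__ = [
    "auto_threshold",
    "apply_threshold",
    "select_component",
    "mask_voxel_volume",
]

# 26-neighbour connectivity: the blood pool is a thick structure, so the
# fullest 3D connectivity minimises spurious splits at thin necks.
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def auto_threshold(volume: ImageVolume) -> float:
    """Initial segmentation threshold via Otsu's method (256-bin histogram).

    Maximises the between-class intensity variance; the returned value lies
    strictly between the volume's minimum and maximum intensity.  Operators
    may override it downstream (see :func:`apply_threshold`).
    """
    data = np.asarray(volume.data)
    if data.max() == data.min():
        raise ValueError("no contrast: volume is constant, cannot derive a threshold")
    return float(threshold_otsu(data, nbins=256))


def apply_threshold(volume: ImageVolume, threshold: float, override: float | None = None) -> BinaryMask:
    """Binary mask of voxels with intensity >= threshold.

    ``override`` models the operator's interactive adjustment and replaces
    ``threshold`` when given.  An empty mask is allowed at this stage.
    """
    t = float(threshold if override is None else override)
    if not np.isfinite(t):
        raise ValueError(f"threshold must be finite, got {t}")
    return BinaryMask(np.asarray(volume.data) >= t, volume.spacing, volume.origin)


def select_component(mask: BinaryMask, seed_mm) -> BinaryMask:
    """Keep only the 26-connected component containing the seed point (mm)."""
    idx = mask.world_to_index(seed_mm)
    if np.any(idx < 0) or np.any(idx >= np.asarray(mask.data.shape)):
        raise ValueError(f"seed {np.asarray(seed_mm).tolist()} lies outside the volume bounds")
    if not mask.data[tuple(idx)]:
        raise ValueError("seed outside segmented blood pool")
    labels, _ = ndimage.label(mask.data, structure=_STRUCT_26)
    keep = labels == labels[tuple(idx)]
    return BinaryMask(keep, mask.spacing, mask.origin)


def mask_voxel_volume(mask: BinaryMask) -> float:
    """Mask volume in cm^3: true-voxel count times the voxel volume."""
    n = mask.count
    if n == 0:
        raise ValueError("cannot compute the volume of an empty mask")
    voxel_mm3 = float(np.prod(mask.spacing))
    return n * voxel_mm3 / 1000.0
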