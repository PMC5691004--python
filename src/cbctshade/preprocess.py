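"""Per-slice preprocessing: centering and structure masking with water fill.

Bone, gas and fiducial-like structures are mostly high-frequency and would
leak into the low-frequency fit, so they are located by fixed HU thresholds,
cleaned up with binary opening, padded by dilation, and replaced with water
(0 HU).  The filled slice is used only for bias estimation, never as the
image being corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

__all__ = ["StructureMask", "EmptySliceError", "estimate_center",
           "mask_structures", "fill_with_water", "body_mask"]

WATER_HU = 0.0


class EmptySliceError(ValueError):
    """Signals a slice with no body support (skipped by the pipeline)."""


@dataclass(frozen=True)
class StructureMask:
    """Boolean masks of high-frequency structures on one slice."""

    bone: np.ndarray
    gas: np.ndarray
    combined: np.ndarray


def body_mask(slice_hu: np.ndarray, body_threshold: float = -300.0) -> np.ndarray:
    return np.asarray(slice_hu) > body_threshold


def estimate_center(slice_hu: np.ndarray, body_threshold: float = -300.0
                    ) -> tuple[float, float]:
    """Centroid ``(x, y)`` of the largest connected component above threshold."""
    mask = body_mask(slice_hu, body_threshold)
    if not mask.any():
        raise EmptySliceError("no voxel above the body threshold")
    labeled, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
        largest = int(np.argmax(sizes)) + 1
        mask = labeled == largest
    cy, cx = ndimage.center_of_mass(mask)
    return float(cx), float(cy)


def mask_structures(slice_hu: np.ndarray, bone_threshold: float = 100.0,
                    gas_range: tuple[float, float] = (-750.0, -500.0),
                    opening_radius: int = 1, margin_radius: int = 2
                    ) -> StructureMask:
    """Threshold bone (HU > bone_threshold) and gas (HU in gas_range), open to
    remove speckle, then dilate by a safety margin.

    Fiducial inserts are captured by the bone threshold.
    """
    gas_lo, gas_hi = gas_range
    if not gas_lo < gas_hi < bone_threshold:
        raise ValueError("thresholds must satisfy gas_lo < gas_hi < bone_threshold")
    slice_hu = np.asarray(slice_hu)
    bone = slice_hu > bone_threshold
    gas = (slice_hu >= gas_lo) & (slice_hu <= gas_hi)
    bone = _open_and_pad(bone, opening_radius, margin_radius)
    gas = _open_and_pad(gas, opening_radius, margin_radius)
    return StructureMask(bone=bone, gas=gas, combined=bone | gas)


def _open_and_pad(mask: np.ndarray, opening_radius: int, margin_radius: int
                  ) -> np.ndarray:
    if opening_radius > 0 and mask.any():
        mask = ndimage.binary_opening(mask, structure=disk(opening_radius))
    if margin_radius > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, structure=disk(margin_radius))
    return mask


def fill_with_water(slice_hu: np.ndarray, mask: StructureMask) -> np.ndarray:
    """Replace masked voxels with water (0 HU); idempotent."""
    return np.where(mask.combined, WATER_HU, np.asarray(slice_hu, dtype=np.float64))
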