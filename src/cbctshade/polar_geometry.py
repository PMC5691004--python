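"""Cartesian <-> polar resampling of transverse slices and air flagging.

A slice is resampled onto an ``(r, theta)`` grid about a per-slice center
with cubic spline interpolation.  Angles are periodic: bin 0 adjoins bin
``n_angular - 1`` in every angular operation.  The patient boundary is found
per angle at the maximum radial gradient; bins beyond it are flagged invalid
so air never enters the bias fit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = ["PolarSlice", "to_polar", "from_polar", "detect_air_boundary"]

HU_AIR = -1000.0


@dataclass
class PolarSlice:
    """A slice on an ``(r, theta)`` grid.

    ``values`` is indexed ``(radial bin, angular bin)``.  Radial bin ``k``
    samples radius ``k * radial_step`` (in voxels); angular bin ``j`` samples
    ``(j + 0.5) * angular_step_deg`` degrees, counter-clockwise from +x.
    """

    values: np.ndarray
    radial_step: float
    center_xy: tuple[float, float]
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("polar values must be 2D (radial, angular)")
        if self.valid.shape != self.values.shape:
            raise ValueError("valid mask must match polar shape")
        if self.radial_step <= 0:
            raise ValueError("radial_step must be positive")

    @property
    def n_radial(self) -> int:
        return self.values.shape[0]

    @property
    def n_angular(self) -> int:
        return self.values.shape[1]

    @property
    def angular_step_deg(self) -> float:
        return 360.0 / self.n_angular

    def with_values(self, values: np.ndarray) -> "PolarSlice":
        return replace(self, values=values, valid=self.valid.copy())


def _angles_rad(n_angular: int) -> np.ndarray:
    # bin centers at half-bin offsets, CCW from +x
    return np.deg2rad((np.arange(n_angular) + 0.5) * (360.0 / n_angular))


def to_polar(slice2d: np.ndarray, center_xy: tuple[float, float],
             n_radial: int = 600, n_angular: int = 360,
             order: int = 3, fill_value: float = HU_AIR) -> PolarSlice:
    """Resample a Cartesian slice onto a polar grid about ``center_xy``.

    ``radial_step`` is chosen so the ``n_radial`` bins cover the largest
    distance from the center to a slice corner.  Samples falling outside the
    Cartesian grid take ``fill_value`` and are flagged invalid.
    """
    slice2d = np.asarray(slice2d, dtype=np.float64)
    ny, nx = slice2d.shape
    cx, cy = center_xy
    if not (0 <= cx <= nx - 1 and 0 <= cy <= ny - 1):
        raise ValueError(f"center {center_xy} outside slice of shape {slice2d.shape}")

    corners = np.array([[0, 0], [0, nx - 1], [ny - 1, 0], [ny - 1, nx - 1]], float)
    half_diag = np.hypot(corners[:, 0] - cy, corners[:, 1] - cx).max()
    radial_step = half_diag / (n_radial - 1)

    r = np.arange(n_radial)[:, None] * radial_step
    theta = _angles_rad(n_angular)[None, :]
    rows = cy + r * np.sin(theta)
    cols = cx + r * np.cos(theta)

    values = ndimage.map_coordinates(slice2d, [rows, cols], order=order,
                                     mode="constant", cval=fill_value)
    inside = (rows >= 0) & (rows <= ny - 1) & (cols >= 0) & (cols <= nx - 1)
    values[~inside] = fill_value
    return PolarSlice(values=values, radial_step=radial_step,
                      center_xy=(float(cx), float(cy)), valid=inside)


def from_polar(polar: PolarSlice, out_shape: tuple[int, int],
               order: int = 3) -> np.ndarray:
    """Resample a polar grid back onto a Cartesian slice.

    Uses the polar slice's own center and steps.  Cartesian points beyond the
    outermost radial bin receive the outermost value of their angle (constant
    radial extrapolation); the angular axis is treated periodically.
    """
    ny, nx = out_shape
    cx, cy = polar.center_xy
    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)

    rbin = np.clip(r / polar.radial_step, 0.0, polar.n_radial - 1.0)
    tbin = theta / np.deg2rad(polar.angular_step_deg) - 0.5

    pad = order + 1
    padded = np.concatenate(
        [polar.values[:, -pad:], polar.values, polar.values[:, :pad]], axis=1)
    return ndimage.map_coordinates(padded, [rbin, tbin + pad], order=order,
                                   mode="nearest")


def detect_air_boundary(polar: PolarSlice, min_radius: int = 5,
                        gradient_floor: float = 100.0) -> np.ndarray:
    """Locate the patient boundary per angle at the maximum radial gradient.

    Works on an HU-domain polar slice.  Returns the per-angle boundary radial
    index and updates ``polar.valid`` in place: bins strictly beyond the
    boundary are invalid.  Angles whose peak |gradient| stays below
    ``gradient_floor`` (all air) get boundary 0 and are wholly invalidated.
    """
    diff = np.abs(np.diff(polar.values, axis=0))  # diff[k] = |v[k+1] - v[k]|
    diff[:min_radius, :] = 0.0
    boundary = np.argmax(diff, axis=0)
    peak = diff[boundary, np.arange(polar.n_angular)]
    dead = peak < gradient_floor
    boundary[dead] = 0

    radial_idx = np.arange(polar.n_radial)[:, None]
    polar.valid &= radial_idx <= boundary[None, :]
    polar.valid[:, dead] = False
    return boundary
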