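"""Low-frequency bias-field estimation in polar space.

The estimator runs per slice on the water-filled, air-flagged polar image in
the relative-attenuation domain.  First pass: a wide circular median along
the angular direction, then a per-angle polynomial fit of order
``order_angular`` along the radius.  Second pass: a (usually width-1) median
along the radius followed by a per-angle polynomial fit of order
``order_radial``.  The per-slice fields are stacked and 3D-median filtered.

A separate precorrection round removes globally radial, largely uniform
shading (bowtie/half-fan ring patterns): a single full-circle radial median
profile is segmented at its sharpest drop into inner ring / transition /
outer ring, and the bias is the region means with the profile kept unchanged
across the transition.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .polar_geometry import PolarSlice, from_polar, to_polar, detect_air_boundary
from .preprocess import (EmptySliceError, estimate_center, fill_with_water,
                         mask_structures)
from .volume_io import CTVolume, Unit

__all__ = [
    "BiasProvenance",
    "BiasField",
    "CorrectionConfig",
    "FitDegenerateError",
    "angular_median",
    "radial_median",
    "fit_polynomial_1d",
    "estimate_slice_bias",
    "precorrect_global_radial",
    "smooth_bias_3d",
]

_POSITIVE_FLOOR = 1e-6


class BiasProvenance(enum.Enum):
    PRECORRECTION = "PRECORRECTION"
    MAIN = "MAIN"
    COMBINED = "COMBINED"


@dataclass
class BiasField:
    """Strictly positive, dimensionless multiplicative 3D field."""

    values: np.ndarray
    provenance: BiasProvenance

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("bias field must be 3D")
        if self.values.min() <= 0:
            raise ValueError("bias field must be strictly positive")

    def as_volume(self, like: CTVolume) -> CTVolume:
        """Export the field as a REL_MU volume sharing ``like``'s geometry."""
        return CTVolume(values=self.values, unit=Unit.REL_MU, spacing=like.spacing)


@dataclass
class CorrectionConfig:
    """Every tunable of the correction, with the published defaults.

    ``angular_width_deg`` defaults to the pelvis-style 80 degrees; use 40 for
    head-like sites.  ``second_pass_axis`` keeps the default reading of the
    radial pass (order-``order_radial`` fit along r per angle);
    ``angular_fit_axis`` switches the first-pass order-8 fit from along-r
    (default) to along-theta per radius.
    """

    bone_threshold: float = 100.0
    gas_range: tuple[float, float] = (-750.0, -500.0)
    body_threshold: float = -300.0
    n_radial: int = 600
    n_angular: int = 360
    angular_width_deg: float = 80.0
    radial_width_bins: int = 1
    order_angular: int = 8
    order_radial: int = 3
    median3d_kernel: tuple[int, int, int] = (3, 3, 3)
    precorrection: bool = False
    clamp_lo: float = 0.2
    clamp_hi: float = 5.0
    opening_radius: int = 1
    margin_radius: int = 2
    downsample_factor: int = 2
    interp_order: int = 3
    angular_fit_axis: str = "radial"
    center_offset_xy: tuple[float, float] = (0.0, 0.0)
    min_boundary_radius: int = 5
    gradient_floor_hu: float = 100.0
    transition_snr: float = 5.0
    profile_smooth_bins: int = 5
    min_transition_drop: float = 0.02

    def __post_init__(self) -> None:
        self.gas_range = tuple(float(v) for v in self.gas_range)
        self.median3d_kernel = tuple(int(k) for k in self.median3d_kernel)
        self.center_offset_xy = tuple(float(v) for v in self.center_offset_xy)
        self.validate()

    def validate(self) -> None:
        lo, hi = self.gas_range
        if not lo < hi < self.bone_threshold:
            raise ValueError("need gas_lo < gas_hi < bone_threshold")
        if self.order_angular < 0 or self.order_radial < 0:
            raise ValueError("polynomial orders must be >= 0")
        if not 1 <= self.angular_width_deg <= 360:
            raise ValueError("angular_width_deg must be in [1, 360]")
        if self.radial_width_bins < 1:
            raise ValueError("radial_width_bins must be >= 1")
        if any(k < 1 or k % 2 == 0 for k in self.median3d_kernel):
            raise ValueError("median3d_kernel sizes must be odd and positive")
        if not 0 < self.clamp_lo < self.clamp_hi:
            raise ValueError("need 0 < clamp_lo < clamp_hi")
        if self.n_radial < 2 or self.n_angular < 2:
            raise ValueError("polar grid must have >= 2 bins per axis")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.angular_fit_axis not in ("radial", "angular"):
            raise ValueError("angular_fit_axis must be 'radial' or 'angular'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CorrectionConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "CorrectionConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        for k, v in data.items():
            if isinstance(v, tuple):
                data[k] = list(v)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


class FitDegenerateError(ValueError):
    """Too few valid points to fit the requested polynomial order."""


# ---------------------------------------------------------------------------
# median filters
# ---------------------------------------------------------------------------

def angular_median(polar: PolarSlice, width_deg: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Circular median along the angular axis, per radial bin.

    For each ``(r, theta)`` the output is the median of the valid values in
    the window of ``width_deg`` centered (circularly) on ``theta``.  Invalid
    input bins are excluded; windows with no valid bin come back invalid.

    Returns ``(median_values, median_valid)``.
    """
    if not 1 <= width_deg <= 360:
        raise ValueError("width_deg must be in [1, 360]")
    n_ang = polar.n_angular
    w = max(1, int(round(width_deg / polar.angular_step_deg)))
    w = min(w, n_ang)
    offsets = np.arange(w) - w // 2
    idx = (np.arange(n_ang)[:, None] + offsets[None, :]) % n_ang  # (n_ang, w)

    # sort-based masked median: invalid bins sort to +inf and are skipped by
    # indexing at the per-window valid count (much faster than nanmedian)
    vals = np.where(polar.valid, polar.values, np.inf)
    windowed = np.sort(vals[:, idx], axis=-1)  # (n_radial, n_ang, w)
    counts = polar.valid[:, idx].sum(axis=-1)  # (n_radial, n_ang)
    k_lo = np.maximum((counts - 1) // 2, 0)[..., None]
    k_hi = np.minimum(counts // 2, w - 1)[..., None]
    med = 0.5 * (np.take_along_axis(windowed, k_lo, axis=-1)[..., 0]
                 + np.take_along_axis(windowed, k_hi, axis=-1)[..., 0])
    out_valid = counts > 0
    return np.where(out_valid, med, 0.0), out_valid


def radial_median(values: np.ndarray, valid: np.ndarray, width_bins: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Running median along the radial axis (non-circular, window clipped at
    the ends).  ``width_bins = 1`` is the identity."""
    if width_bins < 1:
        raise ValueError("width_bins must be >= 1")
    if width_bins == 1:
        return values.copy(), valid.copy()
    n_rad = values.shape[0]
    vals = np.where(valid, values, np.nan)
    out = np.empty_like(values)
    half = width_bins // 2
    for k in range(n_rad):
        lo, hi = max(0, k - half), min(n_rad, k - half + width_bins)
        with np.errstate(all="ignore"):
            out[k] = np.nanmedian(vals[lo:hi], axis=0)
    out_valid = ~np.isnan(out)
    return np.nan_to_num(out), out_valid


# ---------------------------------------------------------------------------
# polynomial fitting
# ---------------------------------------------------------------------------

def fit_polynomial_1d(profile: np.ndarray, valid: np.ndarray, order: int
                      ) -> np.ndarray:
    """Least-squares polynomial fit over the valid points of a 1D profile.

    The abscissa is the sample index rescaled to [-1, 1] over the *full*
    profile; the fitted polynomial is evaluated at every position, including
    invalid ones (extrapolation).
    """
    profile = np.asarray(profile, dtype=np.float64)
    valid = np.asarray(valid, dtype=bool)
    n = profile.shape[0]
    n_valid = int(valid.sum())
    if n_valid <= order:
        raise FitDegenerateError(
            f"{n_valid} valid points cannot constrain an order-{order} fit")
    x = np.linspace(-1.0, 1.0, n)
    coeffs = np.polynomial.polynomial.polyfit(x[valid], profile[valid], order)
    return np.polynomial.polynomial.polyval(x, coeffs)


def _fit_columns(values: np.ndarray, valid: np.ndarray, order: int
                 ) -> np.ndarray:
    """Fit each column (angle) along the radial axis; fall back to the
    column's median when degenerate, to 1.0 when empty."""
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col_valid = valid[:, j]
        try:
            out[:, j] = fit_polynomial_1d(values[:, j], col_valid, order)
        except FitDegenerateError:
            out[:, j] = (np.median(values[col_valid, j])
                         if col_valid.any() else 1.0)
    return out


def _fit_rows(values: np.ndarray, valid: np.ndarray, order: int) -> np.ndarray:
    """Fit each row (radius) along the angular axis (non-periodic abscissa)."""
    out = np.empty_like(values)
    for i in range(values.shape[0]):
        row_valid = valid[i]
        try:
            out[i] = fit_polynomial_1d(values[i], row_valid, order)
        except FitDegenerateError:
            out[i] = (np.median(values[i, row_valid])
                      if row_valid.any() else 1.0)
    return out


# ---------------------------------------------------------------------------
# per-slice estimation
# ---------------------------------------------------------------------------

def estimate_slice_bias(polar: PolarSlice, cfg: CorrectionConfig
                        ) -> np.ndarray:
    """Estimate the low-frequency bias of one polar slice (REL_MU, filled).

    Pass 1: angular median of width ``cfg.angular_width_deg``, then per angle
    an order-``cfg.order_angular`` fit along the radius (or along the angle
    per radius when ``cfg.angular_fit_axis == 'angular'``).  Pass 2: radial
    median of width ``cfg.radial_width_bins``, then per angle an
    order-``cfg.order_radial`` fit along the radius.  The result is defined
    on the full polar grid (extrapolated beyond the body) and floored at a
    tiny positive value.

    A slice with no valid bins yields the identity bias (all ones).
    """
    if not polar.valid.any():
        return np.ones_like(polar.values)

    med, med_valid = angular_median(polar, cfg.angular_width_deg)
    if cfg.angular_fit_axis == "radial":
        initial = _fit_columns(med, med_valid, cfg.order_angular)
    else:
        initial = _fit_rows(med, med_valid, cfg.order_angular)

    med2, med2_valid = radial_median(initial, med_valid, cfg.radial_width_bins)
    bias = _fit_columns(med2, med2_valid, cfg.order_radial)
    return np.maximum(bias, _POSITIVE_FLOOR)


# ---------------------------------------------------------------------------
# precorrection round (global radial / ring shading)
# ---------------------------------------------------------------------------

def _ring_profile_bias(profile: np.ndarray, defined: np.ndarray,
                       cfg: CorrectionConfig) -> np.ndarray | None:
    """Turn a full-circle radial median profile into a ring bias profile.

    The transition band is the contiguous interval, around the
    maximum-magnitude radial derivative, where |derivative| exceeds
    ``cfg.transition_snr`` times its median magnitude.  The bias equals the
    inner-region mean before the band, the outer-region mean after it, and
    the profile itself inside the band; it is normalized so the inner level
    is 1.  Returns None when no transition is found (identity precorrection).
    """
    idx = np.flatnonzero(defined)
    if idx.size < 10:
        return None
    lo, hi = idx.min(), idx.max()
    if not defined[lo:hi + 1].all():  # holes: keep it simple, bail out
        return None
    p = profile[lo:hi + 1]
    # differentiate a lightly smoothed profile so bin-level jitter does not
    # drown the wide, shallow ramp of a real ring transition
    d = np.diff(ndimage.uniform_filter1d(p, size=cfg.profile_smooth_bins,
                                         mode="nearest"))
    # ignore the center bins and the partial-volume rim at the body edge
    search = np.abs(d).copy()
    guard_lo = max(0, cfg.min_boundary_radius - lo)
    search[:guard_lo] = 0.0
    # exclude the partial-volume rolloff at the body rim from the search
    rim = max(3, search.size // 10)
    if search.size > rim:
        search[-rim:] = 0.0
    if not search.any():
        return None
    floor = cfg.transition_snr * np.median(np.abs(d))
    imax = int(np.argmax(search))
    if search[imax] <= floor or search[imax] < 1e-12:
        return None
    band_lo = imax
    while band_lo > 0 and search[band_lo - 1] > floor:
        band_lo -= 1
    band_hi = imax
    while band_hi < search.size - 1 and search[band_hi + 1] > floor:
        band_hi += 1
    start, end = band_lo, band_hi + 1  # profile indices bracketing the band
    if start < 1 or end > p.size - 2:
        return None
    if abs(p[end] - p[start]) < cfg.min_transition_drop:
        return None
    inner = float(np.mean(p[:start]))
    outer = float(np.mean(p[end + 1:]))
    if inner <= 0 or outer <= 0:
        return None

    bias = np.full(profile.shape[0], outer)
    bias[:lo + start] = inner
    bias[lo + start:lo + end + 1] = p[start:end + 1]
    return bias / inner


def precorrect_global_radial(volume: CTVolume, cfg: CorrectionConfig
                             ) -> tuple[CTVolume, BiasField]:
    """Remove globally radial, largely uniform (ring) shading slice by slice.

    Operates on a REL_MU volume.  Per slice: preprocess (center, mask, water
    fill), go polar, flag air, take the single full-circle radial median
    profile shared by all angles, split it at its sharpest drop into inner
    ring / transition / outer ring, and divide out the region-mean bias
    (normalized so the inner level is 1 -- precorrection fixes relative
    shading only).  Slices with no detectable transition pass through
    unchanged.
    """
    if volume.unit is not Unit.REL_MU:
        raise ValueError("precorrect_global_radial expects a REL_MU volume")
    out = volume.values.copy()
    bias3d = np.ones_like(out)
    for i in range(volume.n_slices):
        slice_rel = volume.values[i]
        slice_hu = 1000.0 * (slice_rel - 1.0)
        try:
            cx, cy = estimate_center(slice_hu, cfg.body_threshold)
        except EmptySliceError:
            continue
        cx += cfg.center_offset_xy[0]
        cy += cfg.center_offset_xy[1]
        mask = mask_structures(slice_hu, cfg.bone_threshold, cfg.gas_range,
                               cfg.opening_radius, cfg.margin_radius)
        filled_hu = fill_with_water(slice_hu, mask)
        polar = to_polar(filled_hu, (cx, cy), cfg.n_radial, cfg.n_angular,
                         order=cfg.interp_order)
        detect_air_boundary(polar, cfg.min_boundary_radius, cfg.gradient_floor_hu)
        rel_vals = np.clip(polar.values / 1000.0 + 1.0, 0.0, None)

        vals = np.where(polar.valid, rel_vals, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows = air
            profile = np.nanmedian(vals, axis=1)
        frac_valid = polar.valid.mean(axis=1)
        defined = ~np.isnan(profile) & (frac_valid >= 0.999)

        prof_bias = _ring_profile_bias(np.nan_to_num(profile, nan=1.0),
                                       defined, cfg)
        if prof_bias is None:
            continue
        polar_bias = polar.with_values(
            np.repeat(prof_bias[:, None], cfg.n_angular, axis=1))
        cart_bias = from_polar(polar_bias, slice_rel.shape, order=1)
        cart_bias = np.clip(cart_bias, cfg.clamp_lo, cfg.clamp_hi)
        bias3d[i] = cart_bias
        out[i] = slice_rel / cart_bias
    return (volume.with_values(out),
            BiasField(values=bias3d, provenance=BiasProvenance.PRECORRECTION))


# ---------------------------------------------------------------------------
# 3D smoothing
# ---------------------------------------------------------------------------

def smooth_bias_3d(bias_stack: np.ndarray,
                   kernel: tuple[int, int, int] = (3, 3, 3),
                   clamp: tuple[float, float] = (0.2, 5.0)) -> np.ndarray:
    """3D median filter (edge replication) followed by clamping."""
    if any(k < 1 or k % 2 == 0 for k in kernel):
        raise ValueError("kernel sizes must be odd and positive")
    smoothed = ndimage.median_filter(np.asarray(bias_stack, dtype=np.float64),
                                     size=kernel, mode="nearest")
    return np.clip(smoothed, clamp[0], clamp[1])
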