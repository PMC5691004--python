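"""End-to-end shading correction: preprocess, polar bias estimation, 3D
smoothing, division, and HU recalibration."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .bias_estimation import (BiasField, BiasProvenance, CorrectionConfig,
                              estimate_slice_bias, precorrect_global_radial,
                              smooth_bias_3d)
from .polar_geometry import detect_air_boundary, from_polar, to_polar
from .preprocess import (EmptySliceError, body_mask, estimate_center,
                         fill_with_water, mask_structures)
from .volume_io import CTVolume, Unit, hu_to_rel_mu, rel_mu_to_hu

__all__ = ["SliceLogEntry", "CorrectionResult", "PipelineError", "correct_volume"]


class PipelineError(RuntimeError):
    """The whole volume cannot be corrected (empty / all air)."""


@dataclass
class SliceLogEntry:
    index: int
    center_xy: tuple[float, float] | None
    boundary_min: int
    boundary_max: int
    fallback: str | None = None


@dataclass
class CorrectionResult:
    corrected: CTVolume
    bias: BiasField
    per_slice_log: list[SliceLogEntry] = field(default_factory=list)
    precorrection_bias: BiasField | None = None
    main_bias: BiasField | None = None


def correct_volume(volume: CTVolume, cfg: CorrectionConfig | None = None
                   ) -> CorrectionResult:
    """Correct a HU volume and return it with the combined bias field.

    Fully deterministic.  Slices that cannot be processed (no body, masks
    covering nearly all of the body) fall back to an identity bias and are
    flagged in the per-slice log; an entirely unprocessable volume raises
    :class:`PipelineError`.
    """
    if cfg is None:
        cfg = CorrectionConfig()
    if volume.unit is not Unit.HU:
        raise ValueError("correct_volume expects a volume in HU")
    if volume.values.size == 0:
        raise PipelineError("empty volume")
    if not (volume.values > cfg.body_threshold).any():
        raise PipelineError("volume contains no voxels above the body threshold")

    rel = hu_to_rel_mu(volume)
    pre_bias = None
    if cfg.precorrection:
        rel, pre_bias = precorrect_global_radial(rel, cfg)

    nz, ny, nx = volume.shape
    bias_stack = np.ones((nz, ny, nx))
    filled_rel = np.ones((nz, ny, nx))
    soft_mask = np.zeros((nz, ny, nx), dtype=bool)
    log: list[SliceLogEntry] = []
    centers = np.full((nz, 2), np.nan)

    f = cfg.downsample_factor
    for i in range(nz):
        slice_rel = rel.values[i]
        slice_hu = 1000.0 * (slice_rel - 1.0)
        try:
            cx, cy = estimate_center(slice_hu, cfg.body_threshold)
        except EmptySliceError:
            log.append(SliceLogEntry(i, None, 0, 0, fallback="empty-slice"))
            continue
        cx += cfg.center_offset_xy[0]
        cy += cfg.center_offset_xy[1]
        centers[i] = (cx, cy)

        mask = mask_structures(slice_hu, cfg.bone_threshold, cfg.gas_range,
                               cfg.opening_radius, cfg.margin_radius)
        body = body_mask(slice_hu, cfg.body_threshold)
        if body.any() and mask.combined[body].mean() > 0.9:
            log.append(SliceLogEntry(i, (cx, cy), 0, 0, fallback="masked-out"))
            continue
        filled_hu = fill_with_water(slice_hu, mask)
        filled_rel[i] = np.clip(filled_hu / 1000.0 + 1.0, 0.0, None)
        soft_mask[i] = body & ~mask.combined

        if f > 1:
            work_hu = ndimage.zoom(filled_hu, 1.0 / f, order=1, grid_mode=True,
                                   mode="nearest")
            work_center = (cx / f, cy / f)
        else:
            work_hu, work_center = filled_hu, (cx, cy)

        polar = to_polar(work_hu, work_center, cfg.n_radial, cfg.n_angular,
                         order=cfg.interp_order)
        boundary = detect_air_boundary(polar, cfg.min_boundary_radius,
                                       cfg.gradient_floor_hu)
        polar.values = np.clip(polar.values / 1000.0 + 1.0, 0.0, None)

        polar_bias = estimate_slice_bias(polar, cfg)
        slice_bias = from_polar(polar.with_values(polar_bias), work_hu.shape,
                                order=cfg.interp_order)
        if f > 1:
            slice_bias = ndimage.zoom(
                slice_bias, (ny / slice_bias.shape[0], nx / slice_bias.shape[1]),
                order=1, grid_mode=True, mode="nearest")
        bias_stack[i] = slice_bias
        log.append(SliceLogEntry(i, (cx, cy), int(boundary.min()),
                                 int(boundary.max())))

    if all(e.fallback is not None for e in log) or not log:
        raise PipelineError("no slice could be processed")

    main = smooth_bias_3d(bias_stack, cfg.median3d_kernel,
                          (cfg.clamp_lo, cfg.clamp_hi))

    # water calibration: pin the bias scale so the filled image and the bias
    # agree (in median) over unmasked soft tissue -- Eq-fixes B's free scale
    if soft_mask.any():
        scale = (np.median(filled_rel[soft_mask])
                 / np.median(main[soft_mask]))
        main = np.clip(main * scale, cfg.clamp_lo, cfg.clamp_hi)

    corrected_rel = rel.with_values(rel.values / main)
    corrected = rel_mu_to_hu(corrected_rel)
    corrected.center_xy = centers

    main_field = BiasField(values=main, provenance=BiasProvenance.MAIN)
    if pre_bias is not None:
        combined = BiasField(values=pre_bias.values * main,
                             provenance=BiasProvenance.COMBINED)
    else:
        combined = BiasField(values=main.copy(),
                             provenance=BiasProvenance.COMBINED)
    return CorrectionResult(corrected=corrected, bias=combined,
                            per_slice_log=log, precorrection_bias=pre_bias,
                            main_bias=main_field)
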