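"""ROI statistics, mean CT-number error, and spatial nonuniformity (SNU).

SNU over a set of ROIs is ``(max ROI mean - min ROI mean) / 1000 x 100%``;
the SNU error is ``SNU(test) - SNU(reference)`` and may be negative.  The
mean CT-number error is ``reference ROI mean - test ROI mean`` with the
propagated standard deviation ``sqrt(std_test^2 + std_ref^2)``.  Standard
deviations are population (ddof = 0) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .volume_io import CTVolume, ROIBox

__all__ = ["ROIRecord", "MetricsReport", "roi_stats", "ct_error", "snu",
           "snu_error", "evaluate_volumes"]


def _check_geometry(test: CTVolume, ref: CTVolume) -> None:
    if test.shape != ref.shape:
        raise ValueError(f"volume shapes differ: {test.shape} vs {ref.shape}")
    if not np.allclose(test.spacing, ref.spacing):
        raise ValueError(f"volume spacings differ: {test.spacing} vs {ref.spacing}")


def roi_stats(volume: CTVolume, roi: ROIBox) -> tuple[float, float]:
    """Arithmetic mean and population std of the voxels in a half-open box."""
    roi.check_inside(volume.shape)
    vals = volume.values[roi.slices()]
    if vals.size == 0:
        raise ValueError(f"ROI {roi.label!r} is empty")
    return float(vals.mean()), float(vals.std(ddof=0))


def ct_error(test: CTVolume, ref: CTVolume, roi: ROIBox) -> tuple[float, float]:
    """Mean CT-number error (ref mean - test mean) and propagated std."""
    _check_geometry(test, ref)
    mean_t, std_t = roi_stats(test, roi)
    mean_r, std_r = roi_stats(ref, roi)
    return mean_r - mean_t, float(np.hypot(std_t, std_r))


def snu(volume: CTVolume, rois: Sequence[ROIBox]) -> float:
    """Spatial nonuniformity in percent over >= 2 ROIs."""
    if len(rois) < 2:
        raise ValueError("SNU needs at least 2 ROIs")
    means = [roi_stats(volume, r)[0] for r in rois]
    return (max(means) - min(means)) / 1000.0 * 100.0


def snu_error(test: CTVolume, ref: CTVolume, rois: Sequence[ROIBox]) -> float:
    """Signed difference of SNUs, test minus reference, in percent."""
    _check_geometry(test, ref)
    return snu(test, rois) - snu(ref, rois)


@dataclass(frozen=True)
class ROIRecord:
    label: str
    test_mean: float
    test_std: float
    ref_mean: float
    ref_std: float
    error_mean: float
    error_std: float


@dataclass
class MetricsReport:
    rois: list[ROIRecord] = field(default_factory=list)
    snu_test: float = 0.0
    snu_ref: float = 0.0

    @property
    def snu_error(self) -> float:
        return self.snu_test - self.snu_ref

    def to_text(self) -> str:
        lines = ["# label test_mean test_std ref_mean ref_std error_mean error_std"]
        for r in self.rois:
            lines.append(f"{r.label} {r.test_mean:.3f} {r.test_std:.3f} "
                         f"{r.ref_mean:.3f} {r.ref_std:.3f} "
                         f"{r.error_mean:.3f} {r.error_std:.3f}")
        lines.append(f"snu_test_pct {self.snu_test:.4f}")
        lines.append(f"snu_ref_pct {self.snu_ref:.4f}")
        lines.append(f"snu_error_pct {self.snu_error:.4f}")
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())


def evaluate_volumes(test: CTVolume, ref: CTVolume,
                     rois: Sequence[ROIBox]) -> MetricsReport:
    """Full report: per-ROI stats and errors plus volume-level SNUs."""
    _check_geometry(test, ref)
    report = MetricsReport()
    for roi in rois:
        mt, st = roi_stats(test, roi)
        mr, sr = roi_stats(ref, roi)
        err, std = ct_error(test, ref, roi)
        report.rois.append(ROIRecord(roi.label, mt, st, mr, sr, err, std))
    if len(rois) >= 2:
        report.snu_test = snu(test, rois)
        report.snu_ref = snu(ref, rois)
    return report
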