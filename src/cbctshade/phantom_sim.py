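"""Synthetic patient volumes and multiplicative shading fields with ground truth.

The generated phantoms carry exactly the structure the correction assumes:
an elliptical soft-tissue body surrounded by air, bone-like inserts above
100 HU, gas pockets in [-750, -500] HU, and optional low-contrast inserts.
Shading fields are strictly positive, low-frequency, and retained as ground
truth so every downstream stage can be verified end to end.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .volume_io import CTVolume, Unit, hu_to_rel_mu, rel_mu_to_hu

__all__ = [
    "Insert",
    "PhantomSpec",
    "ShadingKind",
    "ShadingModel",
    "Labels",
    "SpecError",
    "make_phantom",
    "make_bias_field",
    "apply_shading",
    "max_inplane_gradient",
]


class SpecError(ValueError):
    """Raised for an invalid phantom or shading specification."""


class Labels:
    """Integer codes of the structure label map."""

    AIR = 0
    BODY = 1
    BONE = 2
    GAS = 3
    INSERT = 4


@dataclass(frozen=True)
class Insert:
    """A 2.5D insert (same footprint on every slice).

    ``center_mm`` / ``size_mm`` are in-plane ``(x, y)`` offsets from the grid
    center; for ellipses ``size_mm`` are semi-axes, for boxes half-widths.
    """

    shape: str  # "ellipse" | "box"
    hu: float
    center_mm: tuple[float, float]
    size_mm: tuple[float, float]

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "box"):
            raise SpecError(f"unknown insert shape {self.shape!r}")
        if not (self.hu > 100 or -750 <= self.hu <= -500 or -100 < self.hu < 100):
            raise SpecError(
                f"insert HU {self.hu} outside the allowed classes "
                "(bone > 100, gas in [-750, -500], soft contrast in (-100, 100))")
        if min(self.size_mm) <= 0:
            raise SpecError("insert size must be positive")

    @property
    def label(self) -> int:
        if self.hu > 100:
            return Labels.BONE
        if self.hu <= -500:
            return Labels.GAS
        return Labels.INSERT


@dataclass
class PhantomSpec:
    """Declarative description of a synthetic patient."""

    grid_shape: tuple[int, int, int] = (32, 256, 256)
    spacing: tuple[float, float, float] = (1.4, 1.4, 1.4)
    body_semi_axes_mm: tuple[float, float] = (150.0, 110.0)  # (x, y)
    body_hu: float = 0.0
    inserts: tuple[Insert, ...] = ()
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        self.spacing = tuple(float(v) for v in self.spacing)
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 1:
            raise SpecError(f"bad grid_shape {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise SpecError(f"bad spacing {self.spacing}")
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be >= 0")
        half_x = self.grid_shape[2] * self.spacing[2] / 2.0
        half_y = self.grid_shape[1] * self.spacing[1] / 2.0
        ax, ay = self.body_semi_axes_mm
        if ax >= half_x or ay >= half_y:
            raise SpecError("body ellipse does not fit inside the grid")
        self.inserts = tuple(
            i if isinstance(i, Insert) else Insert(**i) for i in self.inserts)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PhantomSpec":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise SpecError(f"unknown phantom keys: {sorted(unknown)}")
        data = dict(data)
        if "inserts" in data:
            data["inserts"] = tuple(Insert(**i) for i in data["inserts"])
        return cls(**data)


class ShadingKind(enum.Enum):
    GLOBAL_RING = "GLOBAL_RING"
    LOCAL_RADIAL = "LOCAL_RADIAL"
    SMOOTH_POLY = "SMOOTH_POLY"


@dataclass
class ShadingModel:
    """Multiplicative low-frequency shading field description.

    ``amplitude`` is the peak fractional deviation of the field from 1.
    GLOBAL_RING: radially symmetric field equal to ``inner_level`` inside
    ``ring_inner_mm``, ``outer_level`` outside ``ring_outer_mm``, with a
    smooth monotone (cubic smoothstep) ramp in between.
    LOCAL_RADIAL: broad Gaussian dip ``1 - amplitude*exp(-d^2/2*sigma^2)``
    centered at ``offset_mm`` from the slice center.
    SMOOTH_POLY: 2D polynomial in normalized in-plane coordinates; if
    ``coefficients`` (a 2D array for numpy polyval2d) is omitted, a gentle
    default tilted-bowl polynomial scaled by ``amplitude`` is used.
    """

    kind: ShadingKind = ShadingKind.GLOBAL_RING
    amplitude: float = 0.25
    ring_inner_mm: float = 60.0
    ring_outer_mm: float = 100.0
    inner_level: float | None = None
    outer_level: float = 1.0
    sigma_mm: float = 110.0
    offset_mm: tuple[float, float] = (25.0, -15.0)
    coefficients: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.kind, ShadingKind):
            self.kind = ShadingKind(self.kind)
        if not 0 <= self.amplitude < 1:
            raise SpecError("amplitude must be in [0, 1): the field must stay positive")
        if self.kind is ShadingKind.GLOBAL_RING:
            if self.inner_level is None:
                self.inner_level = 1.0 - self.amplitude
            if self.inner_level <= 0 or self.outer_level <= 0:
                raise SpecError("ring levels must be positive")
            if not 0 <= self.ring_inner_mm < self.ring_outer_mm:
                raise SpecError("need 0 <= ring_inner_mm < ring_outer_mm")
        if self.coefficients is not None:
            self.coefficients = np.asarray(self.coefficients, dtype=np.float64)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ShadingModel":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def from_dict(cls, data: dict) -> "ShadingModel":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise SpecError(f"unknown shading keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _inplane_coords_mm(shape: tuple[int, int, int],
                       spacing: tuple[float, float, float]):
    """(x, y) coordinate grids in mm about the in-plane grid center."""
    _, ny, nx = shape
    _, sy, sx = spacing
    y = (np.arange(ny) - (ny - 1) / 2.0) * sy
    x = (np.arange(nx) - (nx - 1) / 2.0) * sx
    return np.meshgrid(x, y)  # each (ny, nx)


def make_phantom(spec: PhantomSpec) -> tuple[CTVolume, np.ndarray]:
    """Build the noise-free ground-truth HU volume and its structure label map.

    Returns ``(truth, labels)`` where ``labels`` uses the :class:`Labels`
    codes.  Deterministic: the construction involves no randomness (the
    spec's seed drives only the noise added by :func:`apply_shading`).
    """
    xx, yy = _inplane_coords_mm(spec.grid_shape, spec.spacing)
    ax, ay = spec.body_semi_axes_mm
    body2d = (xx / ax) ** 2 + (yy / ay) ** 2 <= 1.0

    slice_hu = np.where(body2d, spec.body_hu, -1000.0)
    labels2d = np.where(body2d, Labels.BODY, Labels.AIR).astype(np.int8)

    for ins in spec.inserts:
        cx, cy = ins.center_mm
        wx, wy = ins.size_mm
        if ins.shape == "ellipse":
            m = ((xx - cx) / wx) ** 2 + ((yy - cy) / wy) ** 2 <= 1.0
        else:
            m = (np.abs(xx - cx) <= wx) & (np.abs(yy - cy) <= wy)
        if np.any(m & ~body2d):
            raise SpecError(f"insert at {ins.center_mm} extends outside the body")
        slice_hu = np.where(m, ins.hu, slice_hu)
        labels2d = np.where(m, ins.label, labels2d).astype(np.int8)

    nz = spec.grid_shape[0]
    truth = CTVolume(values=np.broadcast_to(slice_hu, spec.grid_shape).copy(),
                     unit=Unit.HU, spacing=spec.spacing)
    labels = np.broadcast_to(labels2d, spec.grid_shape).copy()
    return truth, labels


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def make_bias_field(model: ShadingModel, grid: CTVolume) -> np.ndarray:
    """Evaluate the model's strictly positive multiplicative field on a grid.

    The returned array has the grid's shape and is dimensionless (REL_MU
    scale: 1 = no shading).
    """
    shape, spacing = grid.shape, grid.spacing
    xx, yy = _inplane_coords_mm(shape, spacing)

    if model.kind is ShadingKind.GLOBAL_RING:
        r = np.hypot(xx, yy)
        t = _smoothstep((r - model.ring_inner_mm)
                        / (model.ring_outer_mm - model.ring_inner_mm))
        field2d = model.inner_level + (model.outer_level - model.inner_level) * t
    elif model.kind is ShadingKind.LOCAL_RADIAL:
        ox, oy = model.offset_mm
        d2 = (xx - ox) ** 2 + (yy - oy) ** 2
        field2d = 1.0 - model.amplitude * np.exp(-d2 / (2.0 * model.sigma_mm ** 2))
    else:  # SMOOTH_POLY
        coeffs = model.coefficients
        if coeffs is None:
            a = model.amplitude
            # tilted bowl: 1 - a/2*(x^2+y^2) + a/4*(x + y/2), bounded by a
            coeffs = np.array([
                [1.0, a / 8.0, -a / 2.0],
                [a / 4.0, 0.0, 0.0],
                [-a / 2.0, 0.0, 0.0],
            ])
        half_x = shape[2] * spacing[2] / 2.0
        half_y = shape[1] * spacing[1] / 2.0
        field2d = np.polynomial.polynomial.polyval2d(xx / half_x, yy / half_y, coeffs)

    field = np.broadcast_to(field2d, shape).copy()
    if field.min() <= 0:
        raise SpecError("shading field must be strictly positive everywhere")
    return field


def apply_shading(truth: CTVolume, bias: np.ndarray, noise_sigma: float = 0.0,
                  seed: int = 0) -> CTVolume:
    """Forward model: shaded = truth (in REL_MU) x bias, plus HU-domain noise.

    Inverse of the correction's division; with ``noise_sigma = 0`` dividing
    the output by ``bias`` in REL_MU recovers ``truth`` exactly.
    """
    if truth.unit is not Unit.HU:
        raise ValueError("apply_shading expects the truth volume in HU")
    bias = np.asarray(bias, dtype=np.float64)
    if bias.shape != truth.shape:
        raise ValueError(f"bias shape {bias.shape} != volume shape {truth.shape}")
    rel = hu_to_rel_mu(truth)
    shaded = rel_mu_to_hu(rel.with_values(rel.values * bias))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        shaded = shaded.with_values(
            shaded.values + rng.normal(0.0, noise_sigma, size=shaded.shape))
    return shaded


def max_inplane_gradient(field: np.ndarray,
                         exclude: np.ndarray | None = None) -> float:
    """Largest in-plane per-voxel finite-difference magnitude of a 3D field.

    ``exclude`` masks voxels (e.g. a declared ring transition band) whose
    differences are ignored; used to assert the low-frequency invariant.
    """
    gmax = 0.0
    for axis in (1, 2):
        d = np.abs(np.diff(field, axis=axis))
        if exclude is not None:
            keep = ~(np.take(exclude, range(d.shape[axis]), axis=axis)
                     | np.take(exclude, range(1, d.shape[axis] + 1), axis=axis))
            d = d[keep]
        if d.size:
            gmax = max(gmax, float(d.max()))
    return gmax
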