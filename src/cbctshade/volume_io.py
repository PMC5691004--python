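"""Volume containers, file I/O, and HU <-> relative-attenuation conversion.

Volumes are stored as ``(slice, row, col)`` arrays; transverse slices are the
2D ``(row, col)`` planes.  All multiplicative bias arithmetic happens in the
relative-attenuation domain (``REL_MU``, water = 1, air = 0); Hounsfield units
are the external interface.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Unit",
    "CTVolume",
    "ROIBox",
    "FormatError",
    "read_volume",
    "write_volume",
    "hu_to_rel_mu",
    "rel_mu_to_hu",
    "read_roi_file",
    "write_roi_file",
]

HU_AIR = -1000.0


class Unit(enum.Enum):
    """Value domain of a :class:`CTVolume`."""

    HU = "HU"
    REL_MU = "REL_MU"


class FormatError(ValueError):
    """Raised when a volume file cannot be read unambiguously."""


@dataclass
class CTVolume:
    """A 3D voxel grid with spacing and a declared value domain.

    Parameters
    ----------
    values
        3D float array ordered ``(slice, row, col)``.
    unit
        ``Unit.HU`` or ``Unit.REL_MU``.
    spacing
        Per-axis voxel size in mm, same ordering as ``values``.
    center_xy
        Optional per-slice in-plane processing center, shape ``(n_slices, 2)``
        as continuous ``(x, y)`` voxel coordinates (x = column, y = row).
    """

    values: np.ndarray
    unit: Unit
    spacing: tuple[float, float, float]
    center_xy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.values.ndim}")
        if min(self.values.shape[1], self.values.shape[2]) < 8:
            raise ValueError("in-plane grid dimensions must be >= 8")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not isinstance(self.unit, Unit):
            self.unit = Unit(self.unit)
        if self.center_xy is not None:
            self.center_xy = np.asarray(self.center_xy, dtype=np.float64)
            if self.center_xy.shape != (self.values.shape[0], 2):
                raise ValueError("center_xy must have shape (n_slices, 2)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: np.ndarray, unit: Unit | None = None) -> "CTVolume":
        """Return a copy sharing geometry but holding new voxel values."""
        return replace(self, values=values, unit=self.unit if unit is None else unit)


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned voxel box, 0-based, half-open ``[lo, hi)``."""

    label: str
    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lo", tuple(int(v) for v in self.lo))
        object.__setattr__(self, "hi", tuple(int(v) for v in self.hi))
        if not all(l < h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"ROI {self.label!r}: lo must be < hi component-wise")

    def check_inside(self, shape: Sequence[int]) -> None:
        if any(l < 0 for l in self.lo) or any(h > s for h, s in zip(self.hi, shape)):
            raise ValueError(f"ROI {self.label!r} lies outside volume of shape {tuple(shape)}")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

def hu_to_rel_mu(volume: CTVolume) -> CTVolume:
    """Convert HU to relative attenuation: ``mu_rel = HU/1000 + 1``, clamped at 0.

    Water (0 HU) maps to exactly 1, air (-1000 HU) to 0.
    """
    if volume.unit is not Unit.HU:
        raise ValueError("hu_to_rel_mu requires a volume in HU")
    rel = np.clip(volume.values / 1000.0 + 1.0, 0.0, None)
    return volume.with_values(rel, Unit.REL_MU)


def rel_mu_to_hu(volume: CTVolume) -> CTVolume:
    """Convert relative attenuation back to HU: ``HU = 1000 * (mu_rel - 1)``."""
    if volume.unit is not Unit.REL_MU:
        raise ValueError("rel_mu_to_hu requires a volume in REL_MU")
    hu = 1000.0 * (volume.values - 1.0)
    return volume.with_values(hu, Unit.HU)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_MET_TYPES = {
    "MET_CHAR": np.int8,
    "MET_UCHAR": np.uint8,
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_INT": np.int32,
    "MET_UINT": np.uint32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_MET_TYPES_INV = {np.dtype(v): k for k, v in _MET_TYPES.items()}


def read_volume(path: str | Path, format_hint: str | None = None,
                unit: Unit | str = Unit.HU) -> CTVolume:
    """Read a volume from NIfTI, MetaImage, or raw-binary-with-sidecar.

    The format is chosen from ``format_hint`` (``"nifti"``, ``"metaimage"``,
    ``"raw"``) or else from the file suffix.  NIfTI and MetaImage files are
    assumed to hold HU unless ``unit`` says otherwise; the raw sidecar states
    its unit explicitly and overrides ``unit``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format_hint or _guess_format(path)
    if fmt == "nifti":
        return _read_nifti(path, Unit(unit))
    if fmt == "metaimage":
        return _read_metaimage(path, Unit(unit))
    if fmt == "raw":
        return _read_raw(path)
    raise FormatError(f"cannot determine volume format of {path}")


def write_volume(volume: CTVolume, path: str | Path, format_hint: str | None = None) -> None:
    """Write a volume; the format is chosen as in :func:`read_volume`."""
    path = Path(path)
    fmt = format_hint or _guess_format(path)
    if fmt == "nifti":
        _write_nifti(volume, path)
    elif fmt == "metaimage":
        _write_metaimage(volume, path)
    elif fmt == "raw":
        _write_raw(volume, path)
    else:
        raise FormatError(f"cannot determine volume format of {path}")


def _guess_format(path: Path) -> str | None:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mha", ".mhd")):
        return "metaimage"
    if name.endswith(".raw"):
        return "raw"
    return None


def _read_nifti(path: Path, unit: Unit) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    # nibabel axis order is (x, y, z); ours is (slice, row, col) = (z, y, x)
    data = np.asanyarray(img.dataobj).astype(np.float64).T
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return CTVolume(values=data, unit=unit, spacing=spacing)


def _write_nifti(volume: CTVolume, path: Path) -> None:
    import nibabel as nib

    sz, sy, sx = volume.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(volume.values.T, affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))


def _read_metaimage(path: Path, unit: Unit) -> CTVolume:
    header: dict[str, str] = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                raise FormatError(f"{path}: truncated MetaImage header")
            key, _, value = line.decode("ascii", errors="replace").partition("=")
            key, value = key.strip(), value.strip()
            header[key] = value
            if key == "ElementDataFile":
                break
        for req in ("NDims", "DimSize", "ElementType", "ElementSpacing"):
            if req not in header:
                raise FormatError(f"{path}: MetaImage header missing field {req!r}")
        if header["NDims"] != "3":
            raise FormatError(f"{path}: only 3D MetaImage supported (NDims={header['NDims']})")
        if header.get("CompressedData", "False").lower() == "true":
            raise FormatError(f"{path}: compressed MetaImage not supported")
        if header["ElementType"] not in _MET_TYPES:
            raise FormatError(f"{path}: unsupported ElementType {header['ElementType']}")
        dtype = np.dtype(_MET_TYPES[header["ElementType"]])
        if header.get("ElementByteOrderMSB", "False").lower() == "true" or \
                header.get("BinaryDataByteOrderMSB", "False").lower() == "true":
            dtype = dtype.newbyteorder(">")
        nx, ny, nz = (int(v) for v in header["DimSize"].split())
        sx, sy, sz = (float(v) for v in header["ElementSpacing"].split())
        datafile = header["ElementDataFile"]
        if datafile == "LOCAL":
            raw = fh.read(nx * ny * nz * dtype.itemsize)
        else:
            raw = (path.parent / datafile).read_bytes()
    data = np.frombuffer(raw, dtype=dtype, count=nx * ny * nz)
    # MetaImage raster order: x fastest, z slowest -> reshape to (z, y, x)
    values = data.reshape(nz, ny, nx).astype(np.float64)
    return CTVolume(values=values, unit=unit, spacing=(sz, sy, sx))


def _write_metaimage(volume: CTVolume, path: Path) -> None:
    nz, ny, nx = volume.shape
    sz, sy, sx = volume.spacing
    data = np.ascontiguousarray(volume.values, dtype=np.float64)
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        "CompressedData = False\n"
        f"DimSize = {nx} {ny} {nz}\n"
        f"ElementSpacing = {sx:.10g} {sy:.10g} {sz:.10g}\n"
        f"ElementType = {_MET_TYPES_INV[data.dtype]}\n"
    )
    if path.suffix.lower() == ".mhd":
        rawname = path.with_suffix(".raw").name
        path.write_text(header + f"ElementDataFile = {rawname}\n")
        (path.parent / rawname).write_bytes(data.tobytes())
    else:
        with open(path, "wb") as fh:
            fh.write((header + "ElementDataFile = LOCAL\n").encode("ascii"))
            fh.write(data.tobytes())


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_raw(path: Path) -> CTVolume:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"{path}: raw volume requires sidecar {sidecar.name} "
                          "(fields: shape, dtype, spacing, unit)")
    meta = json.loads(sidecar.read_text())
    for req in ("shape", "dtype", "spacing", "unit"):
        if req not in meta:
            raise FormatError(f"{sidecar}: sidecar missing field {req!r}")
    shape = tuple(int(v) for v in meta["shape"])
    if len(shape) != 3:
        raise FormatError(f"{sidecar}: shape must be 3 integers (slice, row, col)")
    dtype = np.dtype(meta["dtype"])
    data = np.fromfile(path, dtype=dtype)
    if data.size != int(np.prod(shape)):
        raise FormatError(f"{path}: raw size {data.size} does not match shape {shape}")
    return CTVolume(values=data.reshape(shape).astype(np.float64),
                    unit=Unit(meta["unit"]),
                    spacing=tuple(float(v) for v in meta["spacing"]))


def _write_raw(volume: CTVolume, path: Path) -> None:
    data = np.ascontiguousarray(volume.values, dtype=np.float64)
    data.tofile(path)
    meta = {
        "shape": list(volume.shape),
        "dtype": str(data.dtype),
        "spacing": list(volume.spacing),
        "unit": volume.unit.value,
        "axis_order": "slice,row,col",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")


# ---------------------------------------------------------------------------
# ROI specification files
# ---------------------------------------------------------------------------

def read_roi_file(path: str | Path) -> list[ROIBox]:
    """Parse an ROI file: one box per line,
    ``label lo_slice lo_row lo_col hi_slice hi_row hi_col`` (0-based, half-open).
    Blank lines and ``#`` comments are ignored.
    """
    rois: list[ROIBox] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise FormatError(f"{path}:{lineno}: expected 'label lo_z lo_y lo_x hi_z hi_y hi_x'")
        try:
            nums = [int(p) for p in parts[1:]]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer ROI bound") from exc
        rois.append(ROIBox(label=parts[0], lo=tuple(nums[:3]), hi=tuple(nums[3:])))
    if not rois:
        raise FormatError(f"{path}: no ROIs found")
    return rois


def write_roi_file(rois: Sequence[ROIBox], path: str | Path) -> None:
    lines = ["# label lo_slice lo_row lo_col hi_slice hi_row hi_col"]
    for r in rois:
        lines.append(f"{r.label} {' '.join(map(str, r.lo))} {' '.join(map(str, r.hi))}")
    Path(path).write_text("\n".join(lines) + "\n")
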