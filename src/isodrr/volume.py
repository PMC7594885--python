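"""Voxel volumes: the in-memory model, MetaImage I/O and 8-bit cube packing.

A :class:`VoxelVolume` stores scalar *attenuation codes* — unsigned integer
intensities that are mapped to linear attenuation coefficients only at render
time.  Volumes carry per-axis spacing (mm), the world position of the centre
of voxel ``(0, 0, 0)`` and a mapping of array axes onto patient anatomical
axes.  The shared patient frame used throughout the package is right handed,
with +X toward the patient's left, +Y anterior and +Z superior ("LAS"), and
its origin at the isocentre confluence of the median-sagittal, auricular
(coronal) and anthropological (axial) planes.

CT-style acquisitions (e.g. 184 slices of 512 x 512 16-bit pixels) are
down-packed with :func:`pack_to_cube` into the 256-cube 8-bit layout the
renderer consumes; the physical extent of the volume is preserved.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

logger = logging.getLogger(__name__)

CUBE_SIZE = 256

# unit vectors of anatomical directions in the LAS patient frame
_ANATOMICAL_DIRECTIONS = {
    "L": np.array([1.0, 0.0, 0.0]),
    "R": np.array([-1.0, 0.0, 0.0]),
    "A": np.array([0.0, 1.0, 0.0]),
    "P": np.array([0.0, -1.0, 0.0]),
    "S": np.array([0.0, 0.0, 1.0]),
    "I": np.array([0.0, 0.0, -1.0]),
}


class VolumeFormatError(ValueError):
    """Base class for volume file-format problems."""


class MalformedHeaderError(VolumeFormatError):
    """The MetaImage header is unreadable or inconsistent."""


class TruncatedVolumeError(VolumeFormatError):
    """The raw payload is shorter than the header's DimSize promises."""


class UnsupportedElementTypeError(VolumeFormatError):
    """The element type is not 8- or 16-bit unsigned integer."""


def _validate_axes(axes: str) -> None:
    if len(axes) != 3 or any(c not in _ANATOMICAL_DIRECTIONS for c in axes):
        raise ValueError(f"axes must be three of L/R/A/P/S/I, got {axes!r}")
    basis = np.array([_ANATOMICAL_DIRECTIONS[c] for c in axes])
    if np.abs(basis.sum(axis=0)).sum() != 3:
        raise ValueError(f"axes {axes!r} do not span three distinct anatomical axes")
    if np.linalg.det(basis) <= 0:
        raise ValueError(f"axes {axes!r} are not a right-handed frame")


@dataclass
class VoxelVolume:
    """3-D scalar attenuation-code array with spacing and patient-frame pose.

    Parameters
    ----------
    intensities
        Array of shape ``(nx, ny, nz)``; unsigned integer codes (8- or
        16-bit) or non-negative floats.
    spacing
        Per-axis voxel size in mm, all components > 0.
    origin
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    axes
        Three letters mapping array axes to anatomical directions
        (default ``"LAS"``); must form a right-handed frame.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: str = "LAS"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3-D array")
        kind = self.intensities.dtype.kind
        if kind not in "uif":
            raise ValueError(f"unsupported intensity dtype {self.intensities.dtype}")
        if kind == "f" and not np.isfinite(self.intensities).all():
            raise ValueError("intensities contain non-finite values")
        if kind != "u" and (self.intensities < 0).any():
            raise ValueError("intensities must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        _validate_axes(self.axes)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical extent per axis: voxel count x spacing."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def corner_mm(self) -> np.ndarray:
        """World position of the low corner of the physical bounding box."""
        return np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world coordinates (…, 3) to fractional voxel indices."""
        p = np.asarray(points_mm, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)


_ELEMENT_TYPES = {"MET_UCHAR": np.uint8, "MET_USHORT": np.uint16}
_DTYPE_TO_ELEMENT = {np.dtype(np.uint8): "MET_UCHAR", np.dtype(np.uint16): "MET_USHORT"}


def _parse_mhd_header(path: Path) -> dict[str, str]:
    try:
        text = path.read_text()
    except UnicodeDecodeError as exc:
        raise MalformedHeaderError(f"{path}: header is not ASCII text") from exc
    header: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if "=" not in line:
            raise MalformedHeaderError(f"{path}: malformed header line {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        header[key] = value
        if key == "ElementDataFile":
            break
    return header


def read_volume(path: str | Path) -> VoxelVolume:
    """Read an uncompressed MetaImage (.mhd + .raw) volume.

    The header is validated before the payload is loaded so that malformed
    headers, truncated raw files and unsupported element types each produce
    a distinct diagnostic.
    """
    path = Path(path)
    header = _parse_mhd_header(path)

    for key in ("NDims", "DimSize", "ElementType", "ElementDataFile"):
        if key not in header:
            raise MalformedHeaderError(f"{path}: missing header key {key}")
    if header.get("ObjectType", "Image") != "Image":
        raise MalformedHeaderError(f"{path}: ObjectType is not Image")
    if header["NDims"] != "3":
        raise MalformedHeaderError(f"{path}: expected NDims = 3, got {header['NDims']}")
    if header.get("CompressedData", "False").lower() == "true":
        raise MalformedHeaderError(f"{path}: compressed MetaImage payloads are not supported")
    try:
        dims = tuple(int(d) for d in header["DimSize"].split())
    except ValueError as exc:
        raise MalformedHeaderError(f"{path}: unparseable DimSize {header['DimSize']!r}") from exc
    if len(dims) != 3 or any(d <= 0 for d in dims):
        raise MalformedHeaderError(f"{path}: DimSize must be three positive integers, got {dims}")
    element_type = header["ElementType"]
    if element_type not in _ELEMENT_TYPES:
        raise UnsupportedElementTypeError(
            f"{path}: unsupported ElementType {element_type} "
            f"(supported: {sorted(_ELEMENT_TYPES)})"
        )
    raw_name = header["ElementDataFile"]
    if raw_name == "LOCAL":
        raise MalformedHeaderError(f"{path}: embedded (LOCAL) payloads are not supported")
    raw_path = path.parent / raw_name
    if not raw_path.exists():
        raise TruncatedVolumeError(f"{path}: raw payload {raw_name} not found")
    expected = int(np.prod(dims)) * np.dtype(_ELEMENT_TYPES[element_type]).itemsize
    actual = raw_path.stat().st_size
    if actual < expected:
        raise TruncatedVolumeError(
            f"{raw_path}: raw payload is {actual} bytes, header promises {expected}"
        )
    if actual > expected:
        raise MalformedHeaderError(
            f"{raw_path}: raw payload is {actual} bytes, larger than the {expected} "
            "bytes declared in the header"
        )

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # (z,y,x) -> (x,y,z)
    return VoxelVolume(
        intensities=arr,
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )


def write_volume(vol: VoxelVolume, path: str | Path) -> Path:
    """Write ``vol`` as an uncompressed MetaImage pair (.mhd + .raw).

    Round-trips bit-exactly with :func:`read_volume` for uint8/uint16 data.
    """
    path = Path(path)
    if path.suffix != ".mhd":
        raise ValueError(f"volume path must end in .mhd, got {path}")
    if vol.intensities.dtype not in _DTYPE_TO_ELEMENT:
        raise ValueError(
            f"only uint8/uint16 volumes can be written, got {vol.intensities.dtype}"
        )
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.intensities.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, str(path), useCompression=False)
    return path


def pack_to_cube(vol: VoxelVolume, size: int = CUBE_SIZE) -> VoxelVolume:
    """Resample a volume into the renderer's ``size``-cube 8-bit layout.

    The volume is trilinearly resampled onto an isotropic-in-count grid whose
    per-axis spacing is ``physical extent / size`` (the extent is preserved),
    then min–max rescaled to the full 8-bit range.  A constant-valued input
    has no dynamic range and maps to an all-zero cube.
    """
    data = np.asarray(vol.intensities, dtype=np.float64)
    if not np.isfinite(data).all():
        raise ValueError("cannot pack a volume with non-finite intensities")

    extent = np.asarray(vol.extent_mm)
    new_spacing = extent / size
    corner = vol.corner_mm()
    new_origin = corner + 0.5 * new_spacing

    # fractional source indices of the new voxel centres, per axis
    axes_idx = [
        (new_origin[a] + np.arange(size) * new_spacing[a] - vol.origin[a]) / vol.spacing[a]
        for a in range(3)
    ]
    coords = np.meshgrid(*axes_idx, indexing="ij")
    resampled = ndimage.map_coordinates(
        data, np.stack([c.ravel() for c in coords]), order=1, mode="nearest"
    ).reshape(size, size, size)

    lo, hi = resampled.min(), resampled.max()
    if hi == lo:
        logger.info("pack_to_cube: zero dynamic range; output is all zeros")
        packed = np.zeros((size, size, size), dtype=np.uint8)
    else:
        scaled = (resampled - lo) * (255.0 / (hi - lo))
        packed = np.floor(scaled + 0.5).astype(np.uint8)

    return VoxelVolume(
        intensities=packed,
        spacing=tuple(new_spacing),
        origin=tuple(new_origin),
        axes=vol.axes,
    )
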