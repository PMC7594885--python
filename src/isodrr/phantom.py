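"""Synthetic digital head phantom and landmark catalogues.

The phantom stands in for an anthropomorphic skull: a lower-attenuation
"soft-tissue" ellipsoid enclosing a high-attenuation ellipsoidal "skull"
shell, with small high-intensity marker spheres at named cephalometric
landmark positions.  Markers are what the measurement pipeline detects on
rendered projections; their exact analytic centres form the geometric
oracle.

Coordinates live in the shared patient frame: origin at the isocentre
(confluence of the median-sagittal, auricular and anthropological planes),
+X toward the patient's left, +Y anterior, +Z superior.  Midline landmarks
sit on the median sagittal plane (x = 0); paired landmarks are mirror
images about it.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume import VoxelVolume

#: landmark positions (mm, patient frame) of the default synthetic head.
#: Chosen to be anatomically plausible for an adult skull while keeping the
#: projected marker blobs of each measured triplet well separated on the
#: study projections.
DEFAULT_LANDMARKS_MM: dict[str, tuple[float, float, float]] = {
    "Rt EAM": (-65.0, 0.0, -2.0),
    "Lt EAM": (65.0, 0.0, -2.0),
    "Porion": (-65.0, -10.0, 2.0),
    "Rt TMJ": (-60.0, 15.0, -5.0),
    "Lt TMJ": (60.0, 15.0, -5.0),
    "Rt Mastoid": (-60.0, -15.0, -30.0),
    "Sella": (0.0, 12.0, 18.0),
    "ANS": (0.0, 85.0, -45.0),
    "Nasion": (0.0, 95.0, 25.0),
    "Glabella": (0.0, 96.0, 35.0),
    "Bregma": (0.0, 18.0, 95.0),
    "Petrous": (0.0, -10.0, 10.0),
    "Rt Outer Canthus": (-42.0, 80.0, 20.0),
    "Lt Outer Canthus": (42.0, 80.0, 20.0),
    "External Occipital Protuberance": (0.0, -90.0, 5.0),
}

REQUIRED_LANDMARKS = tuple(DEFAULT_LANDMARKS_MM)


@dataclass(frozen=True)
class Landmark:
    name: str
    position_mm: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position_mm, dtype=float)
        if pos.shape != (3,) or not np.isfinite(pos).all():
            raise ValueError(f"landmark {self.name!r}: position must be a finite 3-vector")
        object.__setattr__(self, "position_mm", pos)


class LandmarkCatalogue:
    """Ordered, uniquely named collection of 3-D landmarks."""

    def __init__(self, entries: dict[str, tuple[float, float, float]] | list[Landmark]):
        if isinstance(entries, dict):
            entries = [Landmark(n, np.asarray(p, float)) for n, p in entries.items()]
        names = [lm.name for lm in entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate landmark names: {dupes}")
        self._entries: dict[str, Landmark] = {lm.name: lm for lm in entries}

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    @property
    def names(self) -> list[str]:
        return list(self._entries)

    def get(self, name: str) -> np.ndarray:
        try:
            return self._entries[name].position_mm
        except KeyError:
            raise KeyError(f"unknown landmark {name!r}; known: {self.names}") from None

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "x_mm", "y_mm", "z_mm"])
            for lm in self:
                writer.writerow([lm.name, *(f"{c:.6g}" for c in lm.position_mm)])
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "LandmarkCatalogue":
        entries = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries.append(
                    Landmark(row["name"], np.array([row["x_mm"], row["y_mm"], row["z_mm"]], float))
                )
        return cls(entries)


def default_catalogue() -> LandmarkCatalogue:
    return LandmarkCatalogue(dict(DEFAULT_LANDMARKS_MM))


@dataclass(frozen=True)
class HeadPhantomParams:
    """Geometry and attenuation codes of the synthetic head.

    All lengths in mm; codes on the 8-bit scale with
    air < soft tissue < bone < marker.  ``marker_code`` is *added* to the
    underlying tissue code (clipped to 255) so markers stay detectable on
    any projection.  ``texture_sigma`` adds optional seeded noise to
    soft-tissue voxels; geometry itself is deterministic.
    ``render_markers`` is a diagnostic switch: when False the catalogue is
    still returned but no spheres are voxelized, so downstream marker
    detection must fail.
    """

    size: int = 256
    spacing_mm: float = 1.0
    ellipsoid_centre_mm: tuple[float, float, float] = (0.0, 8.0, 20.0)
    soft_semiaxes_mm: tuple[float, float, float] = (80.0, 105.0, 100.0)
    skull_outer_semiaxes_mm: tuple[float, float, float] = (74.0, 99.0, 94.0)
    shell_thickness_mm: float = 6.0
    marker_radius_mm: float = 2.0
    air_code: int = 0
    soft_code: int = 30
    bone_code: int = 160
    marker_code: int = 255
    texture_sigma: float = 0.0
    render_markers: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.air_code < self.soft_code < self.bone_code < self.marker_code <= 255:
            raise ValueError("require air < soft < bone < marker codes within 8 bits")
        if self.marker_radius_mm <= 0 or self.shell_thickness_mm <= 0:
            raise ValueError("marker radius and shell thickness must be positive")

    @property
    def skull_inner_semiaxes_mm(self) -> tuple[float, float, float]:
        return tuple(a - self.shell_thickness_mm for a in self.skull_outer_semiaxes_mm)


def _ellipsoid_q(points: np.ndarray, centre, semiaxes) -> np.ndarray:
    """Quadratic form value; <= 1 inside the ellipsoid."""
    d = (points - np.asarray(centre)) / np.asarray(semiaxes)
    return np.einsum("...i,...i->...", d, d)


def phantom_code_at(points_mm: np.ndarray, params: HeadPhantomParams,
                    catalogue: LandmarkCatalogue) -> np.ndarray:
    """Analytic attenuation code of the phantom at arbitrary world points.

    This is the continuous model the voxel grid discretises, and serves as
    the independent oracle for voxelization tests.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    codes = np.full(pts.shape[0], params.air_code, dtype=np.int64)
    soft = _ellipsoid_q(pts, params.ellipsoid_centre_mm, params.soft_semiaxes_mm) <= 1.0
    codes[soft] = params.soft_code
    outer = _ellipsoid_q(pts, params.ellipsoid_centre_mm, params.skull_outer_semiaxes_mm) <= 1.0
    inner = _ellipsoid_q(pts, params.ellipsoid_centre_mm, params.skull_inner_semiaxes_mm) <= 1.0
    codes[outer & ~inner] = params.bone_code
    r2 = params.marker_radius_mm ** 2
    for lm in catalogue:
        in_marker = ((pts - lm.position_mm) ** 2).sum(axis=1) <= r2
        codes[in_marker] = np.minimum(codes[in_marker] + params.marker_code, 255)
    return codes


def generate_head_phantom(
    params: HeadPhantomParams | None = None,
    seed: int = 0,
    catalogue: LandmarkCatalogue | None = None,
) -> tuple[VoxelVolume, LandmarkCatalogue]:
    """Voxelize the analytic head model onto a ``size``-cube 8-bit grid.

    Returns the volume (centred on the isocentre) and the catalogue of
    exact marker-centre coordinates.  Raises if any marker sphere would
    poke outside the volume or overlap another marker, naming the
    offending landmark.
    """
    params = params or HeadPhantomParams()
    catalogue = catalogue or default_catalogue()

    n, sp = params.size, params.spacing_mm
    half_extent = n * sp / 2.0
    origin = -half_extent + 0.5 * sp  # centre of voxel (0,0,0); grid centred on isocentre

    r = params.marker_radius_mm
    marks = list(catalogue)
    for lm in marks:
        if (np.abs(lm.position_mm) + r > half_extent).any():
            raise ValueError(f"marker sphere for {lm.name!r} extends outside the volume")
    for i, a in enumerate(marks):
        for b in marks[i + 1:]:
            if np.linalg.norm(a.position_mm - b.position_mm) < 2 * r:
                raise ValueError(
                    f"marker spheres for {a.name!r} and {b.name!r} overlap"
                )

    coords = origin + sp * np.arange(n)
    gx, gy, gz = np.meshgrid(coords, coords, coords, indexing="ij", sparse=True)

    arr = np.full((n, n, n), params.air_code, dtype=np.int16)
    soft = (
        ((gx - params.ellipsoid_centre_mm[0]) / params.soft_semiaxes_mm[0]) ** 2
        + ((gy - params.ellipsoid_centre_mm[1]) / params.soft_semiaxes_mm[1]) ** 2
        + ((gz - params.ellipsoid_centre_mm[2]) / params.soft_semiaxes_mm[2]) ** 2
    ) <= 1.0
    arr[soft] = params.soft_code
    if params.texture_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, params.texture_sigma, size=arr.shape)
        arr[soft] = np.clip(arr[soft] + np.round(noise[soft]), 0, 255).astype(np.int16)

    def shell_mask(semiaxes):
        return (
            ((gx - params.ellipsoid_centre_mm[0]) / semiaxes[0]) ** 2
            + ((gy - params.ellipsoid_centre_mm[1]) / semiaxes[1]) ** 2
            + ((gz - params.ellipsoid_centre_mm[2]) / semiaxes[2]) ** 2
        ) <= 1.0

    outer = shell_mask(params.skull_outer_semiaxes_mm)
    inner = shell_mask(params.skull_inner_semiaxes_mm)
    arr[outer & ~inner] = params.bone_code

    # markers: additive within a local bounding box around each centre
    for lm in marks if params.render_markers else []:
        idx_c = (lm.position_mm - origin) / sp
        lo = np.maximum(np.floor(idx_c - r / sp - 1).astype(int), 0)
        hi = np.minimum(np.ceil(idx_c + r / sp + 1).astype(int) + 1, n)
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        bx, by, bz = np.meshgrid(
            coords[sl[0]], coords[sl[1]], coords[sl[2]], indexing="ij", sparse=True
        )
        sphere = (
            (bx - lm.position_mm[0]) ** 2
            + (by - lm.position_mm[1]) ** 2
            + (bz - lm.position_mm[2]) ** 2
        ) <= r ** 2
        region = arr[sl]
        region[sphere] = np.minimum(region[sphere] + params.marker_code, 255)

    vol = VoxelVolume(
        intensities=arr.astype(np.uint8),
        spacing=(sp, sp, sp),
        origin=(origin, origin, origin),
    )
    return vol, catalogue
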