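"""Landmark projection and point-to-point distance measurement.

Two routes to the same quantity, compared by the validation pipeline:

* the **analytic oracle** — perspective projection of exact 3-D landmark
  coordinates through the pose's focal point onto the detector plane;
* the **image route** — sub-pixel localisation of the rendered marker
  blobs (intensity-weighted centroid after background subtraction and
  Otsu thresholding), emulating a human observer reading the radiograph.

Distances between projected points inherit the magnification
``SID / (source–object distance)`` of a divergent beam: an object in the
plane through the isocentre perpendicular to the central ray at SID 1000 /
OID 250 is magnified by 1000/750 = 4/3.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .geometry import DetectorSpec, ProjectionPose
from .images import DRRImage
from .phantom import LandmarkCatalogue

PLANES = ("sagittal", "coronal", "axial")
SOURCES = ("analytic", "image", "observer")


class MarkerNotFoundError(RuntimeError):
    """No above-threshold marker blob in the region of interest."""


class MultipleMarkersError(RuntimeError):
    """More than one candidate blob in the region of interest."""


@dataclass(frozen=True)
class MeasurementRecord:
    """One point-to-point distance with provenance."""

    projection_name: str
    landmark_a: str
    landmark_b: str
    distance_mm: float
    source: str
    plane_tested: str

    def __post_init__(self) -> None:
        if self.distance_mm < 0:
            raise ValueError("distance_mm must be non-negative")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")
        if self.plane_tested not in PLANES:
            raise ValueError(f"plane_tested must be one of {PLANES}, got {self.plane_tested!r}")


@dataclass(frozen=True)
class MeasurementDefinition:
    """A named distance to measure on a given projection."""

    name: str
    projection: str
    landmark_a: str
    landmark_b: str
    plane: str


def load_measurement_definitions(path: str | Path | None = None) -> list[MeasurementDefinition]:
    """Load measurement definitions; default is the packaged six-distance set

    (two distances per anatomical plane, each measured on the projection
    whose receptor is roughly perpendicular to that plane).
    """
    if path is None:
        ref = resources.files("isodrr.data") / "measurements_default.csv"
        with resources.as_file(ref) as p:
            return load_measurement_definitions(p)
    defs = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            defs.append(
                MeasurementDefinition(
                    name=row["measurement"],
                    projection=row["projection"],
                    landmark_a=row["landmark_a"],
                    landmark_b=row["landmark_b"],
                    plane=row["plane"],
                )
            )
    return defs


@dataclass(frozen=True)
class ProjectedPoint:
    """A 3-D point's image on the detector, in mm and fractional pixels."""

    u_mm: float
    v_mm: float
    col: float
    row: float


def project_point(p: np.ndarray, pose: ProjectionPose,
                  det: DetectorSpec | None = None) -> ProjectedPoint:
    """Perspective-project a world point through the source onto the detector.

    Intersects the line source→p with the detector plane (normal = central
    ray, through ``det_centre``).  Raises for points at/behind the source
    or rays parallel to the detector plane.
    """
    det = det or DetectorSpec()
    p = np.asarray(p, dtype=float)
    d = p - pose.source
    denom = d @ pose.cr
    if abs(denom) < 1e-12:
        raise ValueError("ray through point is parallel to the detector plane")
    if denom < 0:
        raise ValueError("point lies behind the source")
    t = ((pose.det_centre - pose.source) @ pose.cr) / denom
    hit = pose.source + t * d
    rel = hit - pose.det_centre
    u_mm = float(rel @ pose.u_hat)
    v_mm = float(rel @ pose.v_hat)
    return ProjectedPoint(
        u_mm=u_mm,
        v_mm=v_mm,
        col=u_mm / det.pitch_mm + (det.n_u - 1) / 2.0,
        row=v_mm / det.pitch_mm + (det.n_v - 1) / 2.0,
    )


def projected_distance(a: str, b: str, cat: LandmarkCatalogue, pose: ProjectionPose,
                       det: DetectorSpec | None = None) -> float:
    """Euclidean distance (mm) between two landmarks' detector images."""
    pa = project_point(cat.get(a), pose, det)
    pb = project_point(cat.get(b), pose, det)
    return float(np.hypot(pa.u_mm - pb.u_mm, pa.v_mm - pb.v_mm))


@dataclass(frozen=True)
class MarkerDetection:
    u_mm: float
    v_mm: float
    col: float
    row: float
    n_pixels: int


def _fit_background_plane(patch: np.ndarray) -> np.ndarray:
    """Least-squares plane through the patch's one-pixel border ring."""
    h, w = patch.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    ring = np.zeros((h, w), dtype=bool)
    ring[0, :] = ring[-1, :] = ring[:, 0] = ring[:, -1] = True
    A = np.stack([np.ones(ring.sum()), rr[ring], cc[ring]], axis=1)
    coef, *_ = np.linalg.lstsq(A, patch[ring].astype(float), rcond=None)
    return coef[0] + coef[1] * rr + coef[2] * cc


def detect_marker(img: DRRImage, roi: tuple[int, int, int, int],
                  min_contrast: float = 3.0) -> MarkerDetection:
    """Locate a single marker blob inside ``roi = (row0, row1, col0, col1)``.

    A background plane fitted to the ROI border is subtracted, the residual
    is thresholded (Otsu, floored at ``min_contrast`` grey levels) and the
    intensity-weighted centroid of the single above-threshold component is
    returned in detector mm and fractional pixels.
    """
    row0, row1, col0, col1 = roi
    n_v, n_u = img.pixels.shape
    if not (0 <= row0 < row1 <= n_v and 0 <= col0 < col1 <= n_u):
        raise ValueError(f"ROI {roi} not inside image of shape {img.pixels.shape}")
    patch = img.pixels[row0:row1, col0:col1].astype(float)

    residual = patch - _fit_background_plane(patch)
    if residual.max() < min_contrast:
        raise MarkerNotFoundError(
            f"landmark not found: no pixel exceeds {min_contrast} grey levels "
            f"above background in ROI {roi}"
        )
    thr = max(float(threshold_otsu(residual)), min_contrast)
    mask = residual > thr
    if not mask.any():
        raise MarkerNotFoundError(f"landmark not found in ROI {roi}")
    labels, n_comp = ndimage.label(mask)
    if n_comp > 1:
        raise MultipleMarkersError(
            f"{n_comp} connected components above threshold in ROI {roi}"
        )

    weights = residual[mask] - thr
    if weights.sum() <= 0:
        weights = residual[mask]
    rr, cc = np.nonzero(mask)
    row = row0 + float((rr * weights).sum() / weights.sum())
    col = col0 + float((cc * weights).sum() / weights.sum())
    u_mm, v_mm = img.pixel_to_mm(col, row)
    return MarkerDetection(u_mm=u_mm, v_mm=v_mm, col=col, row=row, n_pixels=int(mask.sum()))


def roi_around(point: ProjectedPoint, img: DRRImage,
               half_width_mm: float = 5.0) -> tuple[int, int, int, int]:
    """Square ROI of ±``half_width_mm`` centred on a predicted projection."""
    half_px = max(2, int(round(half_width_mm / img.pitch_mm)))
    n_v, n_u = img.pixels.shape
    row, col = int(round(point.row)), int(round(point.col))
    return (
        max(row - half_px, 0), min(row + half_px + 1, n_v),
        max(col - half_px, 0), min(col + half_px + 1, n_u),
    )


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the rule used for reported millimetres)."""
    factor = 10.0 ** decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def measure_image_distance(img: DRRImage, roi_a: tuple[int, int, int, int],
                           roi_b: tuple[int, int, int, int],
                           round_to_mm: bool = False) -> float:
    """Distance (mm) between the marker centroids found in two ROIs.

    With ``round_to_mm`` the result is rounded to whole millimetres,
    emulating observers reading a ruler.
    """
    a = detect_marker(img, roi_a)
    b = detect_marker(img, roi_b)
    d = float(np.hypot(a.u_mm - b.u_mm, a.v_mm - b.v_mm))
    return round_half_away(d) if round_to_mm else d


def records_to_csv(records: list[MeasurementRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["projection", "landmark_a", "landmark_b",
                        "distance_mm", "source", "plane"])
        for r in records:
            writer.writerow([r.projection_name, r.landmark_a, r.landmark_b,
                             f"{r.distance_mm:.6f}", r.source, r.plane_tested])
    return path


def records_from_csv(path: str | Path) -> list[MeasurementRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                MeasurementRecord(
                    projection_name=row["projection"],
                    landmark_a=row["landmark_a"],
                    landmark_b=row["landmark_b"],
                    distance_mm=float(row["distance_mm"]),
                    source=row["source"],
                    plane_tested=row["plane"],
                )
            )
    return records
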