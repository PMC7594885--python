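"""Dulac isocentric projection geometry.

The Dulac system describes any skull projection relative to a *base setup*
by two axis angles and two table displacements.  In the base setup the
central ray (CR) enters the posterior aspect of the head perpendicular to
the coronal plane and passes through the isocentre — the confluence of the
median-sagittal, auricular and anthropological planes, which is the origin
of the patient frame (+X left, +Y anterior, +Z superior).

Angle convention (pinned by two anchor configurations):

* ``alpha`` ("L" angle) rotates the CR about the patient transverse (X)
  axis, moving it within the sagittal plane;
* ``beta`` ("M" angle) then rotates the result about the anteroposterior
  (Y) axis, moving an L-rotated CR within the coronal plane;
* at ``alpha = beta = 0`` the CR is +Y (posterior entry); at
  ``alpha = beta = 90`` it is +X (entering at the right external auditory
  meatus and travelling right to left).

Both rotations are right handed about the +X / +Y axes; that sign choice is
what makes the two anchors above hold and is asserted by the test suite.
The receptor is always perpendicular to the CR.  The source sits
``sid - oid`` behind the (displaced) isocentre along the CR and the detector
centre ``oid`` beyond it, so the CR pierces the detector at its principal
point.
"""
from __future__ import annotations

import logging
import math
import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])

#: directions the displacement parameters move the isocentre along.
#: Raise/lower acts along the patient AP axis (the table vertical for a
#: supine patient) and cranial/caudal along the longitudinal axis; the
#: negative "cranial" sign convention means long_mm = -40 displaces the
#: isocentre 40 mm superiorly.
_RAISE_AXIS = -_Y
_LONG_AXIS = -_Z


@dataclass(frozen=True)
class DetectorSpec:
    """Receptor grid: ``n_u x n_v`` square pixels of ``pitch_mm`` mm.

    The default 1024 x 1024 at 0.3 mm pitch spans about 30.7 cm, on the
    scale of a 24 x 30 cm film.
    """

    n_u: int = 1024
    n_v: int = 1024
    pitch_mm: float = 0.3

    def __post_init__(self) -> None:
        if self.n_u <= 0 or self.n_v <= 0:
            raise ValueError("detector pixel counts must be positive")
        if self.pitch_mm <= 0:
            raise ValueError("detector pitch must be positive")


@dataclass(frozen=True)
class IsocentricSetup:
    """One Dulac projection: two angles, two displacements, SID/OID."""

    alpha_deg: float
    beta_deg: float
    raise_mm: float = 0.0
    long_mm: float = 0.0
    sid_mm: float = 1000.0
    oid_mm: float = 250.0
    detector: DetectorSpec = field(default_factory=DetectorSpec)
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha_deg", float(self.alpha_deg) % 360.0)
        object.__setattr__(self, "beta_deg", float(self.beta_deg) % 360.0)
        if not self.sid_mm > self.oid_mm > 0:
            raise ValueError(
                f"require sid_mm > oid_mm > 0, got sid={self.sid_mm}, oid={self.oid_mm}"
            )


@dataclass(frozen=True)
class ProjectionPose:
    """Explicit source/detector geometry derived from an IsocentricSetup."""

    source: np.ndarray
    iso: np.ndarray
    cr: np.ndarray
    det_centre: np.ndarray
    u_hat: np.ndarray
    v_hat: np.ndarray
    sid_mm: float
    oid_mm: float

    def __post_init__(self) -> None:
        for name in ("source", "iso", "cr", "det_centre", "u_hat", "v_hat"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        basis = np.stack([self.cr, self.u_hat, self.v_hat])
        if not np.allclose(basis @ basis.T, np.eye(3), atol=1e-9):
            raise ValueError("cr, u_hat, v_hat must be mutually orthonormal")


def _rot_x(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_y(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def displaced_isocentre(setup: IsocentricSetup) -> np.ndarray:
    """Isocentre after the raise/lower and cranial/caudal displacements."""
    return setup.raise_mm * _RAISE_AXIS + setup.long_mm * _LONG_AXIS


def central_ray(alpha_deg: float, beta_deg: float) -> np.ndarray:
    """Unit CR direction for the given L (alpha) and M (beta) angles."""
    return _rot_y(beta_deg) @ (_rot_x(alpha_deg) @ _Y)


def detector_axes(cr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane detector axes for a CR-perpendicular receptor.

    ``u_hat`` is the normalised projection of the patient transverse axis
    onto the detector plane; when the CR is itself transverse (lateral
    projections) the longitudinal axis is projected instead.  ``v_hat``
    completes the right-handed triad as ``cr x u_hat``.
    """
    u = _X - (_X @ cr) * cr
    norm = np.linalg.norm(u)
    if norm < 1e-8:
        logger.debug("CR parallel to transverse axis; deriving u_hat from longitudinal axis")
        u = _Z - (_Z @ cr) * cr
        norm = np.linalg.norm(u)
    u = u / norm
    v = np.cross(cr, u)
    return u, v / np.linalg.norm(v)


def pose_from_isocentric(setup: IsocentricSetup) -> ProjectionPose:
    """Convert Dulac parameters into an explicit source/detector pose."""
    cr = central_ray(setup.alpha_deg, setup.beta_deg)
    iso = displaced_isocentre(setup)
    source = iso - (setup.sid_mm - setup.oid_mm) * cr
    det_centre = iso + setup.oid_mm * cr
    u_hat, v_hat = detector_axes(cr)
    return ProjectionPose(
        source=source,
        iso=iso,
        cr=cr,
        det_centre=det_centre,
        u_hat=u_hat,
        v_hat=v_hat,
        sid_mm=setup.sid_mm,
        oid_mm=setup.oid_mm,
    )


_REQUIRED_KEYS = ("L_deg", "M_deg")
_OPTIONAL_KEYS = {"raise_mm": 0.0, "long_mm": 0.0, "SID_mm": 1000.0, "OID_mm": 250.0}


def projection_config_load(path: str | Path) -> list[IsocentricSetup]:
    """Load projection definitions from a flat TOML config.

    One table per projection with keys ``L_deg``, ``M_deg`` (required) and
    ``raise_mm``, ``long_mm``, ``SID_mm``, ``OID_mm``, ``det_n``,
    ``det_pitch_mm`` (optional).  Angles outside [0, 360) are normalised
    with a logged note.  An empty file yields an empty list.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    setups = []
    for name, section in cfg.items():
        if not isinstance(section, dict):
            raise ValueError(f"{path}: top-level key {name!r} is not a projection table")
        missing = [k for k in _REQUIRED_KEYS if k not in section]
        if missing:
            raise ValueError(f"{path}: projection {name!r} missing keys {missing}")
        for angle_key in _REQUIRED_KEYS:
            raw = float(section[angle_key])
            if not 0 <= raw < 360:
                logger.info(
                    "projection %s: %s=%g normalised to %g",
                    name, angle_key, raw, raw % 360.0,
                )
        det_kwargs = {}
        if "det_n" in section:
            det_kwargs["n_u"] = det_kwargs["n_v"] = int(section["det_n"])
        if "det_pitch_mm" in section:
            det_kwargs["pitch_mm"] = float(section["det_pitch_mm"])
        opts = {k: float(section.get(k, default)) for k, default in _OPTIONAL_KEYS.items()}
        setups.append(
            IsocentricSetup(
                alpha_deg=float(section["L_deg"]),
                beta_deg=float(section["M_deg"]),
                raise_mm=opts["raise_mm"],
                long_mm=opts["long_mm"],
                sid_mm=opts["SID_mm"],
                oid_mm=opts["OID_mm"],
                detector=DetectorSpec(**det_kwargs),
                name=name,
            )
        )
    return setups


def default_projections() -> list[IsocentricSetup]:
    """The packaged three-projection study set (Lat, OF15, FO)."""
    with resources.as_file(
        resources.files("isodrr.data") / "projections_default.toml"
    ) as p:
        return projection_config_load(p)


def with_detector(setup: IsocentricSetup, det: DetectorSpec) -> IsocentricSetup:
    """Return a copy of ``setup`` using detector spec ``det``."""
    return replace(setup, detector=det)
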