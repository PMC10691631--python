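"""Coordinate frames and transforms for isocentric arc delivery.

Convention (IEC 61217 style, fixed patient/room frame with the isocenter at
the origin):

* ``+X`` patient left, ``+Y`` superior, ``+Z`` up (anterior for a supine
  patient).
* Gantry angle 0 places the source at ``+Z``; the gantry rotates about ``+Y``
  so gantry 90 places the source at ``+X``.
* Couch rotation turns the patient about ``+Z``; it is implemented as a
  rotation of the beam by the negative couch angle in patient coordinates, so
  the dose grid never moves.
* Collimator rotation turns the beam's-eye-view (BEV) axes about the central
  axis; at collimator 0 the BEV x-axis (MLC leaf-travel direction) is the
  image of ``+X`` under the gantry/couch rotation.

All lengths are millimetres, all angles degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateProjectionError, NoIntersectionError, ValidationError

__all__ = ["BeamGeometry", "Phantom", "source_position", "beam_basis",
           "to_beam_frame", "from_beam_frame", "ray_depth"]


def _wrap_360(a: float) -> float:
    return float(np.mod(a, 360.0))


def _wrap_couch(a: float) -> float:
    # Couch angles live in [-90, 90]; values outside are wrapped by 180
    # (a couch at c+180 with gantry g matches a couch at c with gantry -g).
    a = float(np.mod(a + 180.0, 360.0) - 180.0)
    if a > 90.0:
        a -= 180.0
    elif a < -90.0:
        a += 180.0
    return a


@dataclass(frozen=True)
class BeamGeometry:
    """A single beam direction at fixed source-axis distance.

    Angles are normalised on construction: gantry and collimator to
    ``[0, 360)``, couch to ``[-90, 90)``.
    """

    gantry_angle: float = 0.0
    collimator_angle: float = 0.0
    couch_angle: float = 0.0
    sad: float = 1000.0

    def __post_init__(self) -> None:
        if not self.sad > 0:
            raise ValidationError(f"sad must be positive, got {self.sad}")
        object.__setattr__(self, "gantry_angle", _wrap_360(self.gantry_angle))
        object.__setattr__(self, "collimator_angle", _wrap_360(self.collimator_angle))
        object.__setattr__(self, "couch_angle", _wrap_couch(self.couch_angle))


@dataclass(frozen=True)
class Phantom:
    """Water phantom: an infinite slab below ``z = size`` or a sphere of
    radius ``size`` centred at the isocenter."""

    shape: str = "sphere"
    size: float = 80.0

    def __post_init__(self) -> None:
        if self.shape not in ("slab", "sphere"):
            raise ValidationError(f"unknown phantom shape {self.shape!r}")
        if not self.size > 0:
            raise ValidationError("phantom size must be positive")


def _rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def beam_basis(geom: BeamGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Source position and the 3x3 beam rotation matrix.

    The columns of the matrix are the BEV x-axis, BEV y-axis and the unit
    vector from isocenter to source (so ``R @ [0, 0, 1]`` points at the
    source). Collimator rotation is applied to the two transverse columns.
    """
    r = _rot_z(-geom.couch_angle) @ _rot_y(geom.gantry_angle)
    phi = np.radians(geom.collimator_angle)
    c, s = np.cos(phi), np.sin(phi)
    coll = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
    return geom.sad * r[:, 2], r @ coll.T


def source_position(geom: BeamGeometry) -> np.ndarray:
    """Source location in the patient frame; ``|result| == sad``."""
    return beam_basis(geom)[0]


def to_beam_frame(point: np.ndarray, geom: BeamGeometry) -> tuple[float, float, float]:
    """Express a patient-frame point in BEV coordinates.

    Returns ``(x_bev, y_bev, z_along)`` where ``z_along`` is the distance
    from the source along the central axis (``sad`` at the isocenter) and the
    transverse offsets are measured in the plane at that distance.
    """
    src, basis = beam_basis(geom)
    d = np.asarray(point, dtype=float) - src
    x = float(d @ basis[:, 0])
    y = float(d @ basis[:, 1])
    z = float(d @ (-basis[:, 2]))
    if abs(z) < 1e-12 and abs(x) < 1e-12 and abs(y) < 1e-12:
        raise DegenerateProjectionError("point coincides with the source")
    return x, y, z


def from_beam_frame(bev: tuple[float, float, float], geom: BeamGeometry) -> np.ndarray:
    """Inverse of :func:`to_beam_frame`."""
    src, basis = beam_basis(geom)
    x, y, z = bev
    return src + x * basis[:, 0] + y * basis[:, 1] - z * basis[:, 2]


def ray_depth(point: np.ndarray, geom: BeamGeometry, phantom: Phantom) -> tuple[float, float]:
    """Water-equivalent depth and SSD along the source-to-point ray.

    ``depth`` is the path length from the phantom entry to the point and
    ``ssd`` the source-to-surface distance, so ``ssd + depth`` equals the
    source-to-point distance.
    """
    src, _ = beam_basis(geom)
    p = np.asarray(point, dtype=float)
    d = p - src
    dist = float(np.linalg.norm(d))
    if dist == 0.0:
        raise DegenerateProjectionError("point coincides with the source")
    u = d / dist

    if phantom.shape == "slab":
        if p[2] > phantom.size + 1e-9:
            raise NoIntersectionError("point above the slab surface")
        if u[2] >= 0:
            raise NoIntersectionError("ray never enters the slab")
        t_entry = (phantom.size - src[2]) / u[2]
    else:  # sphere
        b = float(src @ u)
        disc = b * b - float(src @ src) + phantom.size ** 2
        if disc <= 0:
            raise NoIntersectionError("ray misses the sphere phantom")
        t_entry = -b - np.sqrt(disc)
        if float(np.linalg.norm(p)) > phantom.size + 1e-9:
            raise NoIntersectionError("point outside the sphere phantom")
    if t_entry < 0 or t_entry > dist + 1e-9:
        raise NoIntersectionError("phantom entry not between source and point")
    return dist - t_entry, t_entry
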