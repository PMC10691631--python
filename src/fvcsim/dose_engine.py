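"""Voxelized dose superposition for fVC arc plans in a water phantom.

The point-dose model is the standard SAD-geometry factorisation used for
small-field hand calculations:

``D = MU * k_cal * OF(field) * TMR(depth) * fluence(x', y') * (SAD/z)**2``

where ``(x', y')`` are the beam's-eye-view coordinates back-projected to the
isocenter plane, ``z`` the source distance along the central axis, and
``k_cal`` a per-preset constant fixed so that the nominal fVC field delivers
exactly the preset's calibration dose per MU at 95 cm SSD / 5 cm depth
(100 cm SAD). Primary fluence only: for the near-axis, sub-centimetre
observables of interest, phantom scatter is folded into the OF/TMR/penumbra
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beam_model import (BeamPreset, MLCField, dose_sigma, field_output_factor,
                         fluence, make_fvc_field, tmr)
from .exceptions import DegenerateProjectionError, ValidationError
from .geometry import BeamGeometry, Phantom, beam_basis
from .planning import ControlPoint, PlanSpec, DEFAULT_DELTA_GANTRY

__all__ = ["DoseGrid", "PlanarDose", "make_grid", "point_dose", "compute_dose",
           "compute_planar_dose", "static_field_plane", "extract_plane"]

_CAL_DEPTH = 50.0  # mm: calibration reference, 95 cm SSD / 5 cm depth at 100 cm SAD

_PLANE_AXES = {"coronal": (0, 1, 2), "axial": (0, 2, 1), "sagittal": (1, 2, 0)}


@dataclass
class DoseGrid:
    """Regular voxel grid of dose values (cGy), axes aligned with the patient
    frame. ``values[i, j, k]`` sits at ``origin + (i, j, k) * spacing``."""

    origin: np.ndarray
    spacing: np.ndarray
    dims: tuple[int, int, int]
    values: np.ndarray
    total_mu: float = 0.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValidationError("grid spacing must be positive")
        if self.values.shape != tuple(self.dims):
            raise ValidationError("values shape does not match dims")

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def points(self) -> np.ndarray:
        """All voxel centres, shape (n_voxels, 3), in ij-k order."""
        ax = [self.axis_coords(i) for i in range(3)]
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack([a.ravel() for a in g], axis=1)


@dataclass
class PlanarDose:
    """A 2D dose map with physical coordinates: ``values[i, j]`` at
    ``(x[i], y[j])`` (mm) in the plane's own right-handed axes."""

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.values.shape != (self.x.size, self.y.size):
            raise ValidationError("planar values shape must be (len(x), len(y))")

    @property
    def max(self) -> float:
        return float(self.values.max())


def make_grid(half_extent: float = 30.0, spacing: float = 1.0,
              center=(0.0, 0.0, 0.0)) -> DoseGrid:
    """Isotropic grid centred on ``center`` spanning ``+-half_extent`` mm."""
    n = int(round(2 * half_extent / spacing)) + 1
    origin = np.asarray(center, dtype=float) - half_extent
    return DoseGrid(origin=origin, spacing=np.full(3, float(spacing)),
                    dims=(n, n, n), values=np.zeros((n, n, n)))


def _calibration_constant(preset: BeamPreset) -> float:
    """k_cal such that the nominal field gives dmu_cal per MU at 95/5."""
    nominal = make_fvc_field()
    of = field_output_factor(nominal, preset)
    f0 = float(fluence(nominal, preset, 0.0, 0.0, sigma=dose_sigma(preset)))
    t = float(tmr(preset, _CAL_DEPTH))
    return preset.dmu_cal / (of * t * f0)


def _dose_from_cp(cp: ControlPoint, field_: MLCField, preset: BeamPreset,
                  points: np.ndarray, phantom: Phantom,
                  k_cal: float, of: float) -> np.ndarray:
    """Vectorised point dose for one control point at many points (cGy)."""
    geom = cp.geometry
    src, basis = beam_basis(geom)
    d = points - src
    x = d @ basis[:, 0]
    y = d @ basis[:, 1]
    z = d @ (-basis[:, 2])
    if np.any(z <= 1e-9):
        raise DegenerateProjectionError("point at or behind the source")
    dist = np.sqrt(np.einsum("ij,ij->i", d, d))
    u = d / dist[:, None]
    if phantom.shape == "slab":
        uz = u[:, 2]
        if np.any(uz >= 0):
            raise ValidationError("slab phantom requires a descending beam at every point")
        t_entry = (phantom.size - src[2]) / uz
    else:
        b = u @ src
        disc = b * b - float(src @ src) + phantom.size ** 2
        if np.any(disc <= 0):
            raise ValidationError("some rays miss the sphere phantom")
        t_entry = -b - np.sqrt(disc)
    depth = dist - t_entry
    scale = geom.sad / z
    f = fluence(field_, preset, x * scale, y * scale, sigma=dose_sigma(preset))
    return cp.mu * k_cal * of * np.asarray(tmr(preset, depth)) * f * scale ** 2


def point_dose(cp: ControlPoint, field_: MLCField, preset: BeamPreset,
               point, phantom: Phantom) -> float:
    """Dose (cGy) at a single patient-frame point from one control point."""
    pts = np.asarray(point, dtype=float).reshape(1, 3)
    k_cal = _calibration_constant(preset)
    of = field_output_factor(field_, preset)
    return float(_dose_from_cp(cp, field_, preset, pts, phantom, k_cal, of)[0])


def _accumulate(plan: PlanSpec, preset: BeamPreset, points: np.ndarray,
                phantom: Phantom, delta_gantry: float,
                per_arc: bool = False):
    k_cal = _calibration_constant(preset)
    of = field_output_factor(plan.field, preset)
    per_arc_doses = []
    total = np.zeros(points.shape[0])
    for arc in plan.arcs:
        from .planning import sine_weights
        arc_dose = np.zeros(points.shape[0])
        for cp in sine_weights(arc, delta_gantry, arc_mu=arc.weight * plan.total_mu):
            arc_dose += _dose_from_cp(cp, plan.field, preset, points, phantom, k_cal, of)
        total += arc_dose
        if per_arc:
            per_arc_doses.append(arc_dose)
    return total, per_arc_doses


def compute_dose(plan: PlanSpec, phantom: Phantom, grid: DoseGrid,
                 preset: BeamPreset,
                 delta_gantry: float = DEFAULT_DELTA_GANTRY) -> DoseGrid:
    """Superpose all control points on the grid.

    With ``normalization_mode == 'max_dose'`` the result is rescaled so the
    maximum voxel dose equals the prescription; with ``'fixed_mu'`` the plan's
    total MU is delivered as-is.
    """
    if len(plan.arcs) == 0:
        raise ValidationError("plan has no arcs")
    pts = grid.points()
    total, _ = _accumulate(plan, preset, pts, phantom, delta_gantry)
    values = total.reshape(grid.dims)
    total_mu = plan.total_mu
    if plan.normalization_mode == "max_dose":
        peak = values.max()
        if peak <= 0:
            raise ValidationError("zero dose everywhere; cannot normalise to max")
        factor = plan.prescription / peak
        values = values * factor
        total_mu *= factor
    return DoseGrid(origin=grid.origin.copy(), spacing=grid.spacing.copy(),
                    dims=grid.dims, values=values, total_mu=total_mu)


def compute_planar_dose(plan: PlanSpec, phantom: Phantom, preset: BeamPreset,
                        orientation: str = "coronal", offset: float = 0.0,
                        half_extent: float = 40.0, spacing: float = 1.0,
                        delta_gantry: float = DEFAULT_DELTA_GANTRY,
                        per_arc: bool = False,
                        normalize: bool = True):
    """Planar dose through the isocenter computed directly (no 3D grid).

    The plane's max stands in for the plan max under ``max_dose``
    normalisation, which is exact for planes through the dose maximum.
    Returns a :class:`PlanarDose`, or ``(cumulative, [per-arc planes])`` when
    ``per_arc`` is set.
    """
    if orientation not in _PLANE_AXES:
        raise ValidationError(f"unknown orientation {orientation!r}")
    a0, a1, anorm = _PLANE_AXES[orientation]
    n = int(round(2 * half_extent / spacing)) + 1
    c = -half_extent + spacing * np.arange(n)
    uu, vv = np.meshgrid(c, c, indexing="ij")
    pts = np.zeros((n * n, 3))
    pts[:, a0] = uu.ravel()
    pts[:, a1] = vv.ravel()
    pts[:, anorm] = offset
    total, arcs = _accumulate(plan, preset, pts, phantom, delta_gantry, per_arc=per_arc)
    factor = 1.0
    if normalize and plan.normalization_mode == "max_dose":
        factor = plan.prescription / total.max()
    plane = PlanarDose(x=c, y=c.copy(), values=(total * factor).reshape(n, n))
    if per_arc:
        return plane, [PlanarDose(x=c, y=c.copy(), values=(a * factor).reshape(n, n))
                       for a in arcs]
    return plane


def static_field_plane(field_: MLCField, preset: BeamPreset,
                       depth: float = 50.0, half_extent: float = 20.0,
                       spacing: float = 0.5, mu: float = 100.0) -> PlanarDose:
    """Transverse dose map of a single static vertical beam at the isocenter
    plane (slab phantom with the surface ``depth`` mm above the isocenter).

    This is the profile from which the clinical field size S_clin is
    measured: FWHMs are taken at the depth of dose measurement.
    """
    phantom = Phantom(shape="slab", size=float(depth))
    cp = ControlPoint(BeamGeometry(gantry_angle=0.0, collimator_angle=0.0), mu=mu)
    n = int(round(2 * half_extent / spacing)) + 1
    c = -half_extent + spacing * np.arange(n)
    xx, yy = np.meshgrid(c, c, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)], axis=1)
    k_cal = _calibration_constant(preset)
    of = field_output_factor(field_, preset)
    vals = _dose_from_cp(cp, field_, preset, pts, phantom, k_cal, of)
    return PlanarDose(x=c, y=c.copy(), values=vals.reshape(n, n))


def extract_plane(grid: DoseGrid, orientation: str = "coronal",
                  offset: float = 0.0) -> PlanarDose:
    """Resample a plane from a 3D grid (linear interpolation along the
    plane normal; in-plane samples are the grid's own)."""
    if orientation not in _PLANE_AXES:
        raise ValidationError(f"unknown orientation {orientation!r}")
    a0, a1, anorm = _PLANE_AXES[orientation]
    coords = grid.axis_coords(anorm)
    if offset < coords[0] or offset > coords[-1]:
        raise ValidationError(f"offset {offset} mm outside grid along axis {anorm}")
    f = (offset - coords[0]) / grid.spacing[anorm]
    i0 = min(int(np.floor(f)), len(coords) - 2)
    w = f - i0
    sl = [slice(None)] * 3
    sl[anorm] = i0
    lower = grid.values[tuple(sl)]
    sl[anorm] = i0 + 1
    upper = grid.values[tuple(sl)]
    vals = (1 - w) * lower + w * upper
    # After removing anorm the remaining axes appear in ascending order,
    # which matches (a0, a1) for every supported orientation.
    return PlanarDose(x=grid.axis_coords(a0), y=grid.axis_coords(a1), values=vals)
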