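"""Scalar dosimetric statistics: FWHM, equivalent square field size (S_clin),
isodose contour geometry, percent differences and the leaf-shift sensitivity
study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .beam_model import BeamPreset, field_output_factor, make_fvc_field
from .dose_engine import PlanarDose, point_dose
from .exceptions import NoIntersectionError, ValidationError
from .geometry import BeamGeometry, Phantom
from .planning import ControlPoint

__all__ = ["IsodoseGeometry", "fwhm", "s_clin", "isodose_geometry",
           "percent_difference", "oar_max_dose", "leaf_shift_study"]


@dataclass(frozen=True)
class IsodoseGeometry:
    """Caliper geometry of one isodose contour: the major/minor diameters and
    the equivalent circle diameter ``sqrt(d_major * d_minor)``."""

    level: float
    d_major: float
    d_minor: float

    def __post_init__(self) -> None:
        if not self.d_major >= self.d_minor > 0:
            raise ValidationError("diameters must satisfy d_major >= d_minor > 0")

    @property
    def d_equiv(self) -> float:
        return float(np.sqrt(self.d_major * self.d_minor))


def fwhm(positions, values) -> float:
    """Full width at half maximum of a sampled 1D profile (mm).

    The two 50%-of-max crossings are located by linear interpolation between
    the samples that bracket them.
    """
    p = np.asarray(positions, dtype=float)
    v = np.asarray(values, dtype=float)
    if p.size < 5:
        raise ValidationError("profile needs at least 5 samples")
    half = v.max() / 2.0
    imax = int(np.argmax(v))
    above = v >= half

    def crossing(side: str) -> float:
        if side == "left":
            idx = np.where(~above[:imax + 1])[0]
            if idx.size == 0:
                raise ValidationError("profile does not fall below 50% on the left")
            i = idx[-1]
            j = i + 1
        else:
            idx = np.where(~above[imax:])[0]
            if idx.size == 0:
                raise ValidationError("profile does not fall below 50% on the right")
            j = imax + idx[0]
            i = j - 1
        return float(p[i] + (half - v[i]) / (v[j] - v[i]) * (p[j] - p[i]))

    return crossing("right") - crossing("left")


def _axis_profile(plane: PlanarDose, axis: str) -> tuple[np.ndarray, np.ndarray]:
    """Central-axis profile of a planar map (interpolated at the other
    coordinate's zero)."""
    if axis == "x":
        j = np.interp(0.0, plane.y, np.arange(plane.y.size))
        j0 = min(int(np.floor(j)), plane.y.size - 2)
        w = j - j0
        return plane.x, (1 - w) * plane.values[:, j0] + w * plane.values[:, j0 + 1]
    i = np.interp(0.0, plane.x, np.arange(plane.x.size))
    i0 = min(int(np.floor(i)), plane.x.size - 2)
    w = i - i0
    return plane.y, (1 - w) * plane.values[i0, :] + w * plane.values[i0 + 1, :]


def s_clin(plane: PlanarDose) -> float:
    """Equivalent square small-field size sqrt(FWHM_X * FWHM_Y) in mm from
    the two central-axis profiles of a planar dose map."""
    fx = fwhm(*_axis_profile(plane, "x"))
    fy = fwhm(*_axis_profile(plane, "y"))
    return float(np.sqrt(fx * fy))


def _caliper_widths(contour_xy: np.ndarray, n_dirs: int = 72) -> tuple[float, float]:
    ang = np.radians(np.arange(n_dirs) * (180.0 / n_dirs))
    dirs = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    proj = contour_xy @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.max()), float(widths.min())


def isodose_geometry(plane: PlanarDose, level: float) -> IsodoseGeometry:
    """Extract the ``level * max`` contour (marching squares) and measure its
    rotating-caliper major/minor diameters.

    The level is referenced to the planar maximum. Raises if no closed
    contour around the maximum exists at that level.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError("isodose level must lie in (0, 1)")
    threshold = level * plane.max
    contours = measure.find_contours(plane.values, threshold)
    imax, jmax = np.unravel_index(np.argmax(plane.values), plane.values.shape)
    dx = plane.x[1] - plane.x[0]
    dy = plane.y[1] - plane.y[0]
    for c in contours:
        closed = np.allclose(c[0], c[-1])
        if not closed:
            continue
        xy = np.stack([plane.x[0] + c[:, 0] * dx, plane.y[0] + c[:, 1] * dy], axis=1)
        # keep the contour that encloses the maximum
        inside = measure.points_in_poly(
            np.array([[plane.x[imax], plane.y[jmax]]]), xy)[0]
        if inside:
            d_major, d_minor = _caliper_widths(xy)
            return IsodoseGeometry(level=level, d_major=d_major, d_minor=d_minor)
    raise ValidationError(f"no closed contour at level {level:.2f} encloses the maximum")


def percent_difference(calculated: float, measured: float) -> float:
    """Symmetric percent difference, 100*(measured - calculated)/mean.

    The relative-to-mean convention is used for all calculated-vs-measured
    comparisons; it is antisymmetric under argument swap.
    """
    if calculated <= 0 or measured <= 0:
        raise ValidationError("percent_difference requires positive inputs")
    return 100.0 * (measured - calculated) / ((measured + calculated) / 2.0)


def oar_max_dose(grid, center, radius: float,
                 tolerance: float = 0.05) -> tuple[float, float]:
    """Maximum dose (cGy) inside a spherical organ-at-risk and the volume
    (cm^3) of its voxels within ``tolerance`` of that maximum."""
    pts = grid.points()
    r2 = np.sum((pts - np.asarray(center, dtype=float)) ** 2, axis=1)
    mask = r2 <= radius ** 2
    if not mask.any():
        raise NoIntersectionError("OAR sphere does not intersect the grid")
    doses = grid.values.ravel()[mask]
    dmax = float(doses.max())
    voxel_cm3 = float(np.prod(grid.spacing)) / 1000.0
    vol = float(np.count_nonzero(doses >= dmax * (1.0 - tolerance))) * voxel_cm3
    return dmax, vol


_DEFAULT_SETTINGS = ((950.0, 50.0), (900.0, 100.0))  # (SSD mm, depth mm)


def leaf_shift_study(preset: BeamPreset,
                     shifts=(0.0, 0.5, -0.5, 1.0, -1.0),
                     settings=_DEFAULT_SETTINGS) -> pd.DataFrame:
    """Output-factor and central-axis dose/MU sensitivity to leaf shifts.

    For each shifted field and each (SSD, depth) slab setting, evaluates the
    field output factor and the dose per MU on the central axis, plus the
    percent change relative to the unshifted field. Returns a tidy table; the
    per-setting standard deviation of the percent dose changes is in the
    ``pct_dose_change`` column groupings.
    """
    shifts = tuple(shifts)
    if 0.0 not in shifts:
        raise ValidationError("shifts must include 0 as the reference")
    rows = []
    for ssd, depth in settings:
        phantom = Phantom(shape="slab", size=float(depth))
        if abs(ssd + depth - 1000.0) > 1e-6:
            raise ValidationError("settings must be isocentric (ssd + depth = SAD)")
        ref_of = ref_dose = None
        for shift in shifts:
            f = make_fvc_field(shift)
            of = field_output_factor(f, preset)
            cp = ControlPoint(BeamGeometry(gantry_angle=0.0, collimator_angle=90.0), mu=1.0)
            dose = point_dose(cp, f, preset, (0.0, 0.0, 0.0), phantom)
            if shift == 0.0:
                ref_of, ref_dose = of, dose
            rows.append(dict(energy=preset.energy_label, ssd_mm=ssd, depth_mm=depth,
                             shift_mm=shift, output_factor=of, dose_per_mu=dose))
    df = pd.DataFrame(rows)
    out = []
    for (_, _), grp in df.groupby(["ssd_mm", "depth_mm"], sort=False):
        ref = grp[grp.shift_mm == 0.0].iloc[0]
        grp = grp.copy()
        grp["pct_of_change"] = 100.0 * (grp.output_factor - ref.output_factor) / ref.output_factor
        grp["pct_dose_change"] = 100.0 * (grp.dose_per_mu - ref.dose_per_mu) / ref.dose_per_mu
        grp["sigma_pct_dose"] = grp.loc[grp.shift_mm != 0.0, "pct_dose_change"].std()
        out.append(grp)
    return pd.concat(out, ignore_index=True)
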