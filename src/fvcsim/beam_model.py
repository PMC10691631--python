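"""Analytic beam model for the fixed-virtual-cone (fVC) field.

The fVC aperture is a 5.0 mm x 5.0 mm opening formed by the two central
high-definition MLC leaf pairs, with backup jaws at 15.0 mm x 15.0 mm
(all at the isocenter plane, 1000 mm SAD). The model replaces a commissioned
treatment-planning beam with four ingredients:

* a separable error-function fluence: an erf-smoothed top-hat between the
  *effective* field edges, with transmission floors inside the jaw opening
  (MLC transmission) and outside it (jaw transmission). Rounded leaf tips
  push the radiation edge beyond the light-field edge on the leaf-travel (X)
  axis (``leaf_end_offset``); a smaller side-penumbra widening acts on the
  leaf-side (Y) axis (``leaf_side_offset``), so the X profile is strictly
  wider than the Y profile — the asymmetry seen in measured small-field
  profiles.
* a tissue-maximum-ratio (TMR) table for depth dependence at fixed SAD,
* a field-output-factor table indexed by the equivalent square small-field
  size ``sqrt(wx_eff * wy_eff)`` of the effective aperture,
* a calibration dose per MU at the 95 cm SSD / 5 cm depth reference.

Leaf-shift perturbations displace both X-bank edges symmetrically: a shift of
``+s`` widens the aperture to ``(5 + 2s) x 5`` mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .exceptions import ExtrapolationWarning, ValidationError

__all__ = ["MLCField", "BeamPreset", "make_fvc_field", "fluence", "dose_sigma",
           "equivalent_square", "field_output_factor", "tmr"]

NOMINAL_HALF_APERTURE = 2.5   # mm at isocenter
NOMINAL_HALF_JAW = 7.5        # mm at isocenter


@dataclass(frozen=True)
class MLCField:
    """MLC-defined aperture with backup jaws (all edges in mm at 1000 mm SAD)."""

    x1: float = -NOMINAL_HALF_APERTURE
    x2: float = NOMINAL_HALF_APERTURE
    y1: float = -NOMINAL_HALF_APERTURE
    y2: float = NOMINAL_HALF_APERTURE
    jaw_x: float = NOMINAL_HALF_JAW
    jaw_y: float = NOMINAL_HALF_JAW
    leaf_shift: float = 0.0

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValidationError("aperture edges must satisfy x1 < x2 and y1 < y2")
        if self.jaw_x <= 0 or self.jaw_y <= 0:
            raise ValidationError("jaw half-openings must be positive")
        if max(abs(self.x1), abs(self.x2)) > self.jaw_x + 1e-9 or \
           max(abs(self.y1), abs(self.y2)) > self.jaw_y + 1e-9:
            raise ValidationError("aperture must lie inside the jaw opening")

    @property
    def width_x(self) -> float:
        return self.x2 - self.x1

    @property
    def width_y(self) -> float:
        return self.y2 - self.y1


@dataclass(frozen=True)
class BeamPreset:
    """Parameterised analytic beam standing in for a commissioned linac model.

    ``tmr_depths``/``tmr_values`` tabulate the tissue-maximum ratio (depth in
    mm); ``of_sizes``/``of_values`` tabulate the field output factor against
    the equivalent square field size (mm). ``dmu_cal`` is the dose per MU
    (cGy) delivered by the nominal fVC field at 95 cm SSD / 5 cm depth
    (100 cm SAD).
    """

    energy_label: str
    sigma_penumbra: float
    mlc_transmission: float
    jaw_transmission: float
    leaf_end_offset: float
    leaf_side_offset: float
    sigma_lcpe: float
    tmr_depths: np.ndarray
    tmr_values: np.ndarray
    of_sizes: np.ndarray
    of_values: np.ndarray
    dmu_cal: float
    max_dose_rate: float = 2400.0

    def __post_init__(self) -> None:
        for name in ("tmr_depths", "tmr_values", "of_sizes", "of_values"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.sigma_penumbra <= 0 or self.sigma_lcpe < 0:
            raise ValidationError("sigma_penumbra must be positive and sigma_lcpe non-negative")
        if not (0 <= self.mlc_transmission < 0.05 and 0 <= self.jaw_transmission < 0.05):
            raise ValidationError("transmissions must lie in [0, 0.05)")
        if self.jaw_transmission > self.mlc_transmission:
            raise ValidationError("jaw transmission must not exceed MLC transmission")
        imax = int(np.argmax(self.tmr_values))
        beyond = self.tmr_values[imax:]
        if not np.all(np.diff(beyond) <= 0):
            raise ValidationError("TMR must decrease monotonically beyond d_max")
        if not np.all(np.diff(self.of_values) >= 0):
            raise ValidationError("output-factor table must be non-decreasing")
        if np.any(self.of_values <= 0) or np.any(self.of_values > 1.2):
            raise ValidationError("output factors must lie in (0, 1.2]")
        if self.dmu_cal <= 0:
            raise ValidationError("dmu_cal must be positive")

    @property
    def d_max(self) -> float:
        """Depth of maximum dose (mm) per the TMR table."""
        return float(self.tmr_depths[int(np.argmax(self.tmr_values))])


def make_fvc_field(leaf_shift: float = 0.0) -> MLCField:
    """Nominal fVC aperture with both X-bank edges displaced by ``leaf_shift``.

    Positive shifts open the field (width ``5 + 2*leaf_shift`` mm), negative
    shifts close it; the Y aperture and the jaws are unchanged.
    """
    if abs(leaf_shift) > 2.0:
        raise ValidationError(f"|leaf_shift| must be <= 2 mm, got {leaf_shift}")
    if NOMINAL_HALF_APERTURE + leaf_shift <= 0:
        raise ValidationError("leaf shift closes the aperture")
    a = NOMINAL_HALF_APERTURE + leaf_shift
    return MLCField(x1=-a, x2=a, leaf_shift=leaf_shift)


def _edge_profile(u, e1: float, e2: float, sigma: float):
    """erf-smoothed top-hat: 1 between e1 and e2, 0 outside."""
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((np.asarray(u, dtype=float) - e1) / s)
                  - (erf((np.asarray(u, dtype=float) - e2) / s)))


def fluence(field_: MLCField, preset: BeamPreset, x_bev, y_bev,
            sigma: float | None = None):
    """Relative photon fluence at the isocenter plane.

    Separable product of erf-blurred top-hats between the effective edges
    (leaf edges pushed out by the rounded-tip / side offsets), with the MLC
    transmission floor inside the jaw window and the jaw transmission floor
    outside it. Accepts scalars or arrays.

    ``sigma`` overrides the edge blur; the dose engine passes
    ``sqrt(sigma_penumbra**2 + sigma_lcpe**2)`` to model the lateral
    electron-transport spread of the dose at depth (an extra Gaussian blur of
    an erf top-hat is again an erf top-hat with enlarged sigma, so the
    convolution is exact).
    """
    if sigma is None:
        sigma = preset.sigma_penumbra
    ax = _edge_profile(x_bev, field_.x1 - preset.leaf_end_offset,
                       field_.x2 + preset.leaf_end_offset, sigma)
    ay = _edge_profile(y_bev, field_.y1 - preset.leaf_side_offset,
                       field_.y2 + preset.leaf_side_offset, sigma)
    jx = _edge_profile(x_bev, -field_.jaw_x, field_.jaw_x, sigma)
    jy = _edge_profile(y_bev, -field_.jaw_y, field_.jaw_y, sigma)
    t_mlc, t_jaw = preset.mlc_transmission, preset.jaw_transmission
    open_field = t_mlc + (1.0 - t_mlc) * ax * ay
    return t_jaw + jx * jy * (open_field - t_jaw)


def dose_sigma(preset: BeamPreset) -> float:
    """Effective transverse blur of the dose profile at depth (mm):
    collimation penumbra and lateral electron transport in quadrature."""
    return float(np.hypot(preset.sigma_penumbra, preset.sigma_lcpe))


def equivalent_square(field_: MLCField, preset: BeamPreset) -> float:
    """Equivalent square small-field size of the effective aperture (mm)."""
    wx = field_.width_x + 2.0 * preset.leaf_end_offset
    wy = field_.width_y + 2.0 * preset.leaf_side_offset
    return float(np.sqrt(wx * wy))


def field_output_factor(field_: MLCField, preset: BeamPreset) -> float:
    """Field output factor from the equivalent-square lookup table."""
    s = equivalent_square(field_, preset)
    lo, hi = preset.of_sizes[0], preset.of_sizes[-1]
    if s < lo or s > hi:
        warnings.warn(
            f"equivalent square {s:.2f} mm outside OF table range "
            f"[{lo:.1f}, {hi:.1f}] mm; clamped", ExtrapolationWarning, stacklevel=2)
        s = min(max(s, lo), hi)
    return float(np.interp(s, preset.of_sizes, preset.of_values))


def tmr(preset: BeamPreset, depth) -> np.ndarray | float:
    """Tissue-maximum ratio at the given depth(s) in mm (clamped to the table)."""
    return np.interp(depth, preset.tmr_depths, preset.tmr_values)
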