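"""Synthetic diode-array measurements for hardware-free QA.

Emulates a planar SRS diode array: 2.47 mm detector pitch over a
77 mm x 77 mm board. The measurement pipeline applies, in order,

1. an extra Gaussian blur (``widening_sigma``) — measured small-field
   profiles are systematically slightly wider than calculated ones,
2. an optional sub-millimetre registration offset,
3. resampling at the detector lattice (lattice centred on the map origin so
   a detector sits on the central axis),
4. multiplicative Gaussian noise (seeded, deterministic).

None of the angular or field-size dependences of real diode response are
modelled; the generator reproduces the statistical regime of planar QA, not
detector physics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.interpolate import RegularGridInterpolator

from .beam_model import BeamPreset
from .dose_engine import PlanarDose, compute_planar_dose
from .exceptions import ValidationError
from .geometry import Phantom
from .planning import PlanSpec, DEFAULT_DELTA_GANTRY

__all__ = ["DetectorArraySpec", "QASession", "sample_measurement", "simulate_qa_session"]


@dataclass(frozen=True)
class DetectorArraySpec:
    """Planar detector array: pitch/extent in mm, relative noise level,
    registration offset (mm) and extra profile widening (mm)."""

    pitch: float = 2.47
    extent: float = 77.0
    noise_sd: float = 0.01
    registration_offset: tuple[float, float] = (0.0, 0.0)
    widening_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pitch <= 0 or self.extent <= 0:
            raise ValidationError("pitch and extent must be positive")
        if not 0.0 <= self.noise_sd <= 0.1:
            raise ValidationError("noise_sd must lie in [0, 0.1]")

    def lattice(self) -> np.ndarray:
        """Detector coordinates along one axis, centred with a detector at 0."""
        half = int(np.floor((self.extent / 2.0) / self.pitch))
        return self.pitch * np.arange(-half, half + 1)


def sample_measurement(plane: PlanarDose, spec: DetectorArraySpec) -> PlanarDose:
    """Synthetic measurement of a calculated planar dose map.

    Deterministic for a fixed ``spec.seed``. Raises if the detector extent
    is not covered by the map.
    """
    coords = spec.lattice()
    ox, oy = spec.registration_offset
    if (coords[0] + ox < plane.x[0] or coords[-1] + ox > plane.x[-1]
            or coords[0] + oy < plane.y[0] or coords[-1] + oy > plane.y[-1]):
        raise ValidationError("detector extent exceeds the calculated map")
    vals = plane.values
    if spec.widening_sigma > 0:
        sig = (spec.widening_sigma / (plane.x[1] - plane.x[0]),
               spec.widening_sigma / (plane.y[1] - plane.y[0]))
        vals = gaussian_filter(vals, sigma=sig, mode="nearest")
    interp = RegularGridInterpolator((plane.x, plane.y), vals, method="linear")
    xx, yy = np.meshgrid(coords + ox, coords + oy, indexing="ij")
    sampled = interp(np.stack([xx.ravel(), yy.ravel()], axis=1)).reshape(xx.shape)
    rng = np.random.default_rng(spec.seed)
    noisy = sampled * (1.0 + spec.noise_sd * rng.standard_normal(sampled.shape))
    return PlanarDose(x=coords.copy(), y=coords.copy(), values=noisy)


@dataclass
class QASession:
    """Everything a patient-specific QA comparison needs: the cumulative
    calculated/measured coronal planes, the per-arc (field-by-field) pairs
    and a per-arc central-axis dose/MU table."""

    calculated: PlanarDose
    measured: PlanarDose
    field_pairs: list[tuple[PlanarDose, PlanarDose]]
    dose_per_mu: pd.DataFrame


def simulate_qa_session(plan: PlanSpec, phantom: Phantom, preset: BeamPreset,
                        spec: DetectorArraySpec,
                        half_extent: float = 45.0, spacing: float = 1.0,
                        delta_gantry: float = DEFAULT_DELTA_GANTRY) -> QASession:
    """Cumulative and field-by-field planar QA with synthetic measurements.

    The coronal plane through the isocenter is the measurement plane. Each
    per-arc measurement uses a seed derived from ``spec.seed`` so the session
    is reproducible as a whole.
    """
    calc, per_arc = compute_planar_dose(
        plan, phantom, preset, orientation="coronal", half_extent=half_extent,
        spacing=spacing, delta_gantry=delta_gantry, per_arc=True, normalize=False)
    factor = 1.0
    if plan.normalization_mode == "max_dose":
        factor = plan.prescription / calc.max
        calc.values *= factor
        for p in per_arc:
            p.values *= factor
    measured = sample_measurement(calc, spec)
    pairs = []
    rows = []
    for i, (arc, arc_plane) in enumerate(zip(plan.arcs, per_arc)):
        arc_spec = DetectorArraySpec(
            pitch=spec.pitch, extent=spec.extent, noise_sd=spec.noise_sd,
            registration_offset=spec.registration_offset,
            widening_sigma=spec.widening_sigma, seed=spec.seed + 1000 * (i + 1))
        arc_meas = sample_measurement(arc_plane, arc_spec)
        pairs.append((arc_plane, arc_meas))
        # central-axis dose per MU for the arc (calculated and measured)
        i0 = int(np.argmin(np.abs(arc_plane.x)))
        j0 = int(np.argmin(np.abs(arc_plane.y)))
        im = int(np.argmin(np.abs(arc_meas.x)))
        jm = int(np.argmin(np.abs(arc_meas.y)))
        arc_mu = arc.weight * plan.total_mu * factor
        rows.append(dict(arc=i, couch=arc.couch_angle, collimator=arc.collimator_angle,
                         mu=arc_mu,
                         calc_dose_per_mu=float(arc_plane.values[i0, j0]) / arc_mu,
                         meas_dose_per_mu=float(arc_meas.values[im, jm]) / arc_mu))
    return QASession(calculated=calc, measured=measured, field_pairs=pairs,
                     dose_per_mu=pd.DataFrame(rows))
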