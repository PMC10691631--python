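"""Point-dose anchors, superposition properties, plane extraction and
discretisation convergence of the dose engine."""

import numpy as np
import pytest

from fvcsim import (BeamGeometry, ControlPoint, Phantom, PlanSpec, compute_dose,
                    compute_planar_dose, extract_plane, make_fvc_field,
                    make_grid, point_dose)
from fvcsim.dose_engine import DoseGrid
from fvcsim.exceptions import ValidationError
from fvcsim.planning import ArcSpec, sine_weights


@pytest.fixture
def cal_cp():
    return ControlPoint(BeamGeometry(gantry_angle=0.0, collimator_angle=90.0), mu=1.0)


@pytest.mark.parametrize("energy,depth,expected", [
    ("10FFF", 50.0, 0.547), ("10FFF", 100.0, 0.432),
    ("6FFF", 50.0, 0.558), ("6FFF", 100.0, 0.424),
])
def test_point_dose_reference_settings(cal_cp, preset10, preset6, energy, depth, expected):
    """Dose per MU of the nominal field at the two isocentric clinical
    settings matches the calculated values the beam model is anchored to."""
    preset = preset10 if energy == "10FFF" else preset6
    dose = point_dose(cal_cp, make_fvc_field(), preset, (0, 0, 0),
                      Phantom("slab", depth))
    assert dose == pytest.approx(expected, abs=1e-3)


def test_point_dose_linear_in_mu(cal_cp, preset10):
    ph = Phantom("slab", 50.0)
    d1 = point_dose(cal_cp, make_fvc_field(), preset10, (0, 0, 0), ph)
    cp2 = ControlPoint(cal_cp.geometry, mu=2.0)
    d2 = point_dose(cp2, make_fvc_field(), preset10, (0, 0, 0), ph)
    assert d2 == pytest.approx(2.0 * d1, rel=1e-15)


def test_normalisation_to_prescription(default_plan, sphere, preset10):
    grid = make_grid(half_extent=8.0, spacing=2.0)
    dose = compute_dose(default_plan, sphere, grid, preset10)
    assert dose.values.max() == pytest.approx(default_plan.prescription, rel=1e-12)


def test_superposition_linearity(sphere, preset10):
    """The dose of a two-arc plan is the voxelwise sum of its single-arc
    parts delivered with the same MUs."""
    a = ArcSpec(10, 0, 20, 60, "CW")
    b = ArcSpec(-30, 45, -60, -20, "CCW")
    grid = make_grid(half_extent=6.0, spacing=3.0)
    pa = PlanSpec(arcs=(a,), normalization_mode="fixed_mu", total_mu=100.0)
    pb = PlanSpec(arcs=(b,), normalization_mode="fixed_mu", total_mu=200.0)
    pab = PlanSpec(arcs=(ArcSpec(10, 0, 20, 60, "CW", weight=1.0),
                         ArcSpec(-30, 45, -60, -20, "CCW", weight=2.0)),
                   normalization_mode="fixed_mu", total_mu=300.0)
    da = compute_dose(pa, sphere, grid, preset10).values
    db = compute_dose(pb, sphere, grid, preset10).values
    dab = compute_dose(pab, sphere, grid, preset10).values
    assert np.allclose(dab, da + db, rtol=1e-12)


def test_empty_plan_rejected(sphere, preset10):
    with pytest.raises(ValidationError):
        PlanSpec(arcs=())


def test_discretisation_convergence(default_plan, sphere, preset10):
    """Halving the gantry step changes voxel doses by under 1% of the plan
    maximum (global dose-difference convention)."""
    plan = PlanSpec(arcs=default_plan.arcs, total_mu=default_plan.total_mu,
                    normalization_mode="fixed_mu")
    grid = make_grid(half_extent=10.0, spacing=2.0)
    d2 = compute_dose(plan, sphere, grid, preset10, delta_gantry=2.0).values
    d1 = compute_dose(plan, sphere, grid, preset10, delta_gantry=1.0).values
    assert np.abs(d2 - d1).max() / d1.max() < 0.01


def test_full_arc_rotational_symmetry(sphere, preset10):
    """A uniformly weighted full arc gives rotationally symmetric dose about
    the gantry rotation axis: CV < 1% on a 2 mm circle around the isocenter."""
    cps = sine_weights(ArcSpec(0.0, 0.0, 0.0, 360.0, "CW"), 2.0, arc_mu=1000.0)
    flat = [ControlPoint(cp.geometry, 1000.0 / len(cps)) for cp in cps]
    plan = PlanSpec(arcs=(ArcSpec(0.0, 0.0, 0.0, 360.0, "CW"),),
                    normalization_mode="fixed_mu", total_mu=1000.0)
    theta = np.radians(np.arange(0, 360, 10))
    circle = np.stack([2 * np.cos(theta), np.zeros_like(theta),
                       2 * np.sin(theta)], axis=1)
    from fvcsim.dose_engine import _calibration_constant, _dose_from_cp
    from fvcsim.beam_model import field_output_factor
    k = _calibration_constant(preset10)
    of = field_output_factor(plan.field, preset10)
    dose = np.zeros(len(theta))
    for cp in flat:
        dose += _dose_from_cp(cp, plan.field, preset10, circle, sphere, k, of)
    assert dose.std() / dose.mean() < 0.01


def test_planar_dose_matches_grid_plane(default_plan, sphere, preset10, coronal_plane):
    """The directly computed coronal plane agrees with the plane extracted
    from a 3D grid computation."""
    grid = make_grid(half_extent=10.0, spacing=1.0)
    dose = compute_dose(default_plan, sphere, grid, preset10)
    plane3d = extract_plane(dose, "coronal", 0.0)
    # compare on the common 21x21 window (same normalisation: plan max at iso)
    i0 = np.searchsorted(coronal_plane.x, plane3d.x[0])
    sub = coronal_plane.values[i0:i0 + 21, i0:i0 + 21]
    assert np.allclose(sub, plane3d.values, rtol=0.02, atol=0.01 * plane3d.values.max())


def test_extract_plane_symmetry_and_max():
    n = 21
    c = np.arange(n) - 10.0
    xx, yy, zz = np.meshgrid(c, c, c, indexing="ij")
    vals = np.exp(-(xx ** 2 + yy ** 2 + zz ** 2) / 30.0)
    grid = DoseGrid(origin=np.array([-10.0, -10.0, -10.0]),
                    spacing=np.ones(3), dims=(n, n, n), values=vals)
    plane = extract_plane(grid, "coronal", 0.0)
    assert np.allclose(plane.values, plane.values[::-1, :], atol=1e-12)
    assert plane.max == pytest.approx(vals.max(), rel=0.01)
    # interpolated plane lies between the bracketing slices
    half = extract_plane(grid, "coronal", 0.5)
    lo = np.minimum(vals[:, :, 10], vals[:, :, 11])
    hi = np.maximum(vals[:, :, 10], vals[:, :, 11])
    assert np.all(half.values >= lo - 1e-12)
    assert np.all(half.values <= hi + 1e-12)


def test_extract_plane_errors():
    grid = make_grid(half_extent=5.0, spacing=1.0)
    grid.values[...] = 1.0
    with pytest.raises(ValidationError):
        extract_plane(grid, "coronal", 20.0)
    with pytest.raises(ValidationError):
        extract_plane(grid, "oblique", 0.0)


def test_per_arc_planes_sum_to_cumulative(default_plan, sphere, preset10):
    cum, per_arc = compute_planar_dose(default_plan, sphere, preset10,
                                       half_extent=10.0, per_arc=True)
    total = np.sum([p.values for p in per_arc], axis=0)
    assert np.allclose(total, cum.values, rtol=1e-10)
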