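"""Dosimetric statistics: FWHM, S_clin, isodose caliper geometry, percent
differences, organ-at-risk dose and the leaf-shift sensitivity study."""

import numpy as np
import pytest

from fvcsim import (IsodoseGeometry, PlanarDose, compute_dose,
                    default_tgn_plan, fwhm, isodose_geometry, leaf_shift_study,
                    make_grid, oar_max_dose, percent_difference, s_clin)
from fvcsim.exceptions import NoIntersectionError, ValidationError
from scipy.special import erf


# ------------------------------------------------------------------ fwhm

def test_fwhm_top_hat():
    x = np.arange(-10.0, 10.01, 0.1)
    v = np.where(np.abs(x) <= 2.5, 1.0, 0.0)
    assert fwhm(x, v) == pytest.approx(5.0, abs=0.1)


def test_fwhm_gaussian_closed_form():
    x = np.arange(-15.0, 15.001, 0.05)
    v = np.exp(-x ** 2 / (2 * 2.0 ** 2))
    assert fwhm(x, v) == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 2.0, abs=0.02)


@pytest.mark.parametrize("sigma", [0.3, 0.6, 1.0])
def test_fwhm_erf_top_hat_sigma_independent(sigma):
    """With zero floor, the 50% crossings of an erf-smoothed 5 mm top-hat sit
    at the edges while the profile top stays flat (blur narrow relative to
    the half-width; for wider blurs the eroding peak moves the 50% level)."""
    x = np.arange(-15.0, 15.001, 0.02)
    s = sigma * np.sqrt(2)
    v = 0.5 * (erf((x + 2.5) / s) - erf((x - 2.5) / s))
    assert fwhm(x, v) == pytest.approx(5.0, abs=0.05)


def test_fwhm_unbounded_profile_raises():
    x = np.linspace(-5, 5, 50)
    with pytest.raises(ValidationError):
        fwhm(x, np.exp(x))  # never falls below half max on the right
    with pytest.raises(ValidationError):
        fwhm(x[:4], np.ones(4))


# ------------------------------------------------------------------ s_clin

def _separable_map(fx, fy, spacing=0.2):
    c = np.arange(-15.0, 15.001, spacing)
    x_prof = np.where(np.abs(c) <= fx / 2, 1.0, 0.0)
    y_prof = np.where(np.abs(c) <= fy / 2, 1.0, 0.0)
    return PlanarDose(x=c, y=c.copy(), values=np.outer(x_prof, y_prof))


def test_s_clin_square_field():
    assert s_clin(_separable_map(6.0, 6.0)) == pytest.approx(6.0, abs=0.2)


def test_s_clin_geometric_mean():
    got = s_clin(_separable_map(5.7, 6.0, spacing=0.05))
    assert got == pytest.approx(np.sqrt(5.7 * 6.0), abs=0.05)


def test_s_clin_of_single_fields_in_printed_ranges(single_field_planes):
    """Single static fVC field at 5 cm depth: S_clin in the printed clinical
    ranges, 6.0-6.4 mm (10FFF) and 5.7-6.0 mm (6FFF)."""
    assert 6.0 <= s_clin(single_field_planes["10FFF"]) <= 6.4
    assert 5.7 <= s_clin(single_field_planes["6FFF"]) <= 6.0


# ------------------------------------------------------- isodose geometry

def _ellipse_map(a, b, spacing=0.05):
    c = np.arange(-10.0, 10.001, spacing)
    xx, yy = np.meshgrid(c, c, indexing="ij")
    vals = np.clip(1.0 - (xx / a) ** 2 - (yy / b) ** 2, 0.0, None)
    return PlanarDose(x=c, y=c.copy(), values=vals)


def test_isodose_geometry_circle():
    g = isodose_geometry(_ellipse_map(2.5 * np.sqrt(2), 2.5 * np.sqrt(2)), 0.5)
    assert g.d_major == pytest.approx(5.0, abs=0.1)
    assert g.d_minor == pytest.approx(5.0, abs=0.1)
    assert g.d_equiv == pytest.approx(5.0, abs=0.1)


@pytest.mark.parametrize("level,dmaj,dmin,dequiv,tol", [
    (0.5, 7.0, 5.7, 6.32, 0.05),
    (0.9, 2.1, 1.82, 1.96, 0.02),
])
def test_isodose_geometry_printed_ellipses(level, dmaj, dmin, dequiv, tol):
    """Equivalent diameters of the printed 50% and 90% ellipse dimensions."""
    scale = np.sqrt(1.0 - level)
    g = isodose_geometry(_ellipse_map(dmaj / 2 / scale, dmin / 2 / scale), level)
    assert g.d_major == pytest.approx(dmaj, abs=tol)
    assert g.d_minor == pytest.approx(dmin, abs=tol)
    assert g.d_equiv == pytest.approx(dequiv, abs=tol)


def test_isodose_scale_equivariance():
    m = _ellipse_map(4.0, 3.0)
    g1 = isodose_geometry(m, 0.5)
    m2 = PlanarDose(x=2.0 * m.x, y=2.0 * m.y, values=m.values)
    g2 = isodose_geometry(m2, 0.5)
    assert g2.d_major == pytest.approx(2 * g1.d_major, rel=1e-6)
    assert g2.d_minor == pytest.approx(2 * g1.d_minor, rel=1e-6)


def test_isodose_geometry_invalid_level():
    m = _ellipse_map(3.0, 2.0)
    with pytest.raises(ValidationError):
        isodose_geometry(m, 1.5)
    wide = _ellipse_map(20.0, 20.0)  # 50% contour leaves the map: not closed
    with pytest.raises(ValidationError):
        isodose_geometry(wide, 0.5)


def test_isodose_geometry_identity():
    g = IsodoseGeometry(level=0.5, d_major=7.0, d_minor=5.7)
    assert g.d_equiv == pytest.approx(np.sqrt(7.0 * 5.7), abs=1e-9)
    with pytest.raises(ValidationError):
        IsodoseGeometry(level=0.5, d_major=5.0, d_minor=6.0)


# ---------------------------------------------------- percent difference

@pytest.mark.parametrize("calc,meas,expected", [
    (0.605, 0.620, 2.45), (0.558, 0.577, 3.35), (0.560, 0.568, 1.42),
    (0.510, 0.515, 0.98), (0.424, 0.435, 2.56),
])
def test_percent_difference_reproduces_printed_cells(calc, meas, expected):
    assert percent_difference(calc, meas) == pytest.approx(expected, abs=0.01)


def test_percent_difference_properties():
    assert percent_difference(0.5, 0.5) == 0.0
    a = percent_difference(0.4, 0.5)
    assert percent_difference(0.5, 0.4) == pytest.approx(-a, rel=1e-12)
    with pytest.raises(ValidationError):
        percent_difference(-1.0, 0.5)


# ------------------------------------------------------------------- OAR

@pytest.fixture(scope="module")
def small_dose_grid(sphere, preset10):
    plan = default_tgn_plan(12, seed=1)
    grid = make_grid(half_extent=30.0, spacing=2.0)
    return compute_dose(plan, sphere, grid, preset10)


def test_oar_far_sphere_low_dose(small_dose_grid):
    dmax, _ = oar_max_dose(small_dose_grid, (0.0, -20.0, 0.0), 8.0)
    assert dmax < 0.05 * small_dose_grid.values.max()


def test_oar_containing_isocenter(small_dose_grid):
    dmax, vol = oar_max_dose(small_dose_grid, (0.0, 0.0, 0.0), 10.0)
    assert dmax == pytest.approx(small_dose_grid.values.max())
    assert vol > 0


def test_oar_monotone_falloff_with_gap(small_dose_grid):
    radius = 10.0
    maxes = [oar_max_dose(small_dose_grid, (0.0, -(radius + gap), 0.0), radius)[0]
             for gap in (3.0, 5.0, 8.0)]
    assert maxes[0] > maxes[1] > maxes[2]


def test_oar_no_intersection(small_dose_grid):
    with pytest.raises(NoIntersectionError):
        oar_max_dose(small_dose_grid, (200.0, 0.0, 0.0), 5.0)


# ------------------------------------------------------ leaf-shift study

@pytest.fixture(scope="module")
def shift_tables(preset10, preset6):
    return {p.energy_label: leaf_shift_study(p) for p in (preset10, preset6)}


def test_leaf_shift_reference_rows_zero(shift_tables):
    for df in shift_tables.values():
        ref = df[df.shift_mm == 0.0]
        assert np.allclose(ref.pct_of_change, 0.0)
        assert np.allclose(ref.pct_dose_change, 0.0)


def test_leaf_shift_larger_shift_larger_change(shift_tables):
    """A 1.0 mm leaf error always perturbs dose more than a 0.5 mm error."""
    for df in shift_tables.values():
        for (_, _), grp in df.groupby(["ssd_mm", "depth_mm"]):
            g = grp.set_index("shift_mm")
            for col in ("pct_of_change", "pct_dose_change"):
                assert abs(g[col][1.0]) > abs(g[col][0.5])
                assert abs(g[col][-1.0]) > abs(g[col][-0.5])


def test_leaf_shift_10fff_more_stable_than_6fff(shift_tables):
    """The 10 MV FFF beam delivers more stable outputs under leaf errors."""
    m = shift_tables["6FFF"].merge(shift_tables["10FFF"],
                                   on=["ssd_mm", "depth_mm", "shift_mm"],
                                   suffixes=("_6", "_10"))
    m = m[m.shift_mm != 0.0]
    assert (m.pct_of_change_6.abs() > m.pct_of_change_10.abs()).all()
    assert (m.pct_dose_change_6.abs() > m.pct_dose_change_10.abs()).all()


def test_leaf_shift_requires_reference(preset10):
    with pytest.raises(ValidationError):
        leaf_shift_study(preset10, shifts=(0.5, 1.0))


from hypothesis import given, settings, strategies as st

positives = st.floats(1e-3, 1e3, allow_nan=False)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(a=positives, b=positives)
def test_percent_difference_antisymmetric_property(a, b):
    assert percent_difference(a, b) == pytest.approx(-percent_difference(b, a),
                                                     rel=1e-12, abs=1e-12)
    assert abs(percent_difference(a, b)) < 200.0  # bounded by the mean convention
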