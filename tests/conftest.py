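"""Shared fixtures: presets, the default plan and its coronal plane,
single-field dose maps, and the seeded gamma map-pair ensemble with its
brute-force oracle comparison (expensive, computed once per session)."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from fvcsim import (GammaCriteria, Phantom, PlanarDose, compute_planar_dose,
                    default_tgn_plan, gamma_map, gamma_oracle, make_fvc_field,
                    static_field_plane)
from fvcsim.io import get_preset


@pytest.fixture(scope="session")
def preset10():
    return get_preset("10FFF")


@pytest.fixture(scope="session")
def preset6():
    return get_preset("6FFF")


@pytest.fixture(scope="session")
def sphere():
    return Phantom(shape="sphere", size=80.0)


@pytest.fixture(scope="session")
def default_plan():
    return default_tgn_plan(12, preset_ref="10FFF", prescription=7500.0, seed=1)


@pytest.fixture(scope="session")
def coronal_plane(default_plan, sphere, preset10):
    """Calculated coronal plane through the isocenter of the default plan,
    1 mm sampling, normalised to the prescription."""
    return compute_planar_dose(default_plan, sphere, preset10,
                               orientation="coronal", half_extent=45.0)


@pytest.fixture(scope="session")
def single_field_planes(preset10, preset6):
    """Single static fVC field transverse dose maps at 5 cm depth."""
    f = make_fvc_field()
    return {"10FFF": static_field_plane(f, preset10),
            "6FFF": static_field_plane(f, preset6)}


def qa_map_pair(seed: int) -> tuple[PlanarDose, PlanarDose]:
    """One seeded reference/evaluated planar pair: a dose dome with a smooth
    2% multiplicative perturbation and a sub-millimetre registration shift —
    the regime of planar patient-QA comparisons."""
    rng = np.random.default_rng(seed)
    c = np.arange(21, dtype=float) - 10.0
    xx, yy = np.meshgrid(c, c, indexing="ij")
    cx, cy = rng.uniform(-2.0, 2.0, 2)
    sig = 9.0
    ref = 100.0 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sig ** 2))
    pert = gaussian_filter(rng.standard_normal((21, 21)), 2.0, mode="nearest")
    sx, sy = rng.uniform(-0.2, 0.2, 2)
    ev = 100.0 * np.exp(-((xx - cx - sx) ** 2 + (yy - cy - sy) ** 2) / (2 * sig ** 2))
    ev = ev * (1.0 + 0.02 * pert)
    return (PlanarDose(x=c, y=c.copy(), values=ref),
            PlanarDose(x=c, y=c.copy(), values=ev))


N_QA_PAIRS = 50


@pytest.fixture(scope="session")
def qa_pairs():
    return [qa_map_pair(seed) for seed in range(N_QA_PAIRS)]


@pytest.fixture(scope="session")
def oracle_comparison(qa_pairs):
    """gamma_map and gamma_oracle results for every seeded pair at 3%/1 mm,
    10% threshold."""
    crit = GammaCriteria(dose_percent=3.0, dta=1.0, threshold_percent=10.0)
    out = []
    for ref, ev in qa_pairs:
        out.append((gamma_map(ref, ev, crit), gamma_oracle(ref, ev, crit)))
    return out
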