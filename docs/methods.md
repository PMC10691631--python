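# Methods

This note records the models behind `fvcsim`, the calibration choices, and
what the simulator can and cannot say about real deliveries.

## Coordinate conventions

Fixed patient frame with the isocenter at the origin: +X patient left,
+Y superior, +Z up (anterior for a supine patient). Gantry 0 places the
source at +Z and the gantry rotates about +Y (IEC 61217 style); couch
rotation turns the patient about +Z and is implemented as rotating the beam
by the negative couch angle so the dose grid never moves; collimator
rotation turns the beam's-eye-view axes about the central axis. Gantry
rotation handedness follows the right-hand rule about +Y (gantry 90 = source
at +X); no convention is implied by the clinical observables, so this is
fixed once and used everywhere. Angles are stored in degrees, lengths in mm.
Couch angles are normalised to [−90, 90]; values outside are wrapped by
180° (couch c+180 with gantry g is the same beam as couch c with gantry −g).
Planes: coronal = constant Z (in-plane axes X, Y), axial = constant Y,
sagittal = constant X.

## Beam model

The fixed virtual cone is a 5.0 mm × 5.0 mm aperture of the two central
2.5 mm leaf pairs with jaws at 15 mm × 15 mm, all at the isocenter plane.
A preset (one per energy, shipped as YAML) parameterises:

* **Fluence** — separable product of erf-smoothed top-hats between the
  *effective* edges: the physical edges pushed out by `leaf_end_offset` on
  the leaf-travel (X) axis (rounded leaf tips) and by the smaller
  `leaf_side_offset` on the leaf-side (Y) axis, with the MLC transmission
  floor (1.2%) inside the jaw window and the jaw transmission (0.2%)
  outside. The X profile is therefore strictly wider than the Y profile,
  the asymmetry seen in measured small-field profiles. `sigma_penumbra`
  (0.8 mm 6FFF / 0.9 mm 10FFF) is the collimation penumbra at the isocenter
  plane; it is kept small enough that the open-field centre fluence stays
  ≥ 0.99.
* **Lateral electron transport** — sub-centimetre fields lack lateral
  charged-particle equilibrium; the dose profile at depth is the fluence
  convolved with an electron-transport kernel. Because an erf top-hat is
  already a top-hat convolved with a Gaussian, this convolution is exact and
  free: the dose engine evaluates the same profile with
  `sigma_eff = hypot(sigma_penumbra, sigma_lcpe)`, with `sigma_lcpe` =
  1.4 mm (6FFF) / 1.5 mm (10FFF). This is what makes the at-depth profile
  peaked rather than flat-topped — without it the composite 90% isodose of
  an arc plan comes out ~4 mm instead of the observed ~2 mm, and the 50%
  isodose ~1.5 mm too wide.
* **Edge-offset calibration** — the offsets are solved (by
  `scripts/generate_presets.py`) so that the single-field at-depth FWHMs are
  6.25/6.00 mm (10FFF) and 6.00/5.72 mm (6FFF), placing the clinical field
  size S_clin = √(FWHM_X·FWHM_Y) mid-way in the clinically reported ranges
  (6.0–6.4 mm and 5.7–6.0 mm). The resulting offsets are ≈0.38/0.20 mm
  (10FFF) and ≈0.31/0.12 mm (6FFF).
* **TMR** — exponential fall-off beyond d_max (14 mm / 22 mm), tabulated at
  1 mm steps, with the attenuation coefficient solved so the dose-per-MU
  ratio between the 95 cm SSD / 5 cm depth and 90 cm SSD / 10 cm depth
  settings reproduces the calculated reference pairs (0.558→0.424 cGy/MU
  for 6FFF, 0.547→0.432 for 10FFF). The buildup region is a quadratic ramp;
  no observable of this package samples it.
* **Output factors** — a saturating exponential `1 − B·exp(−k·s)` in the
  equivalent square size `s = √(wx_eff · wy_eff)` of the effective aperture,
  tabulated densely over 1–12 mm. Each table is anchored so the nominal
  field returns the reference output factor (0.605 6FFF / 0.550 10FFF) with
  a per-energy relative slope at the anchor (0.10/mm for 6FFF vs 0.07/mm
  for 10FFF): the lower-energy beam's output is the more sensitive to
  field-size errors, which reproduces the observed ordering of leaf-shift
  perturbations between the energies.
* **Calibration** — `dmu_cal` is the dose per MU of the nominal field at
  95 cm SSD / 5 cm depth; the engine's global constant is fixed so this
  value is returned exactly.

## Dose engine

For each control point,
`D = MU · k_cal · OF(field) · TMR(depth) · Φ(x·SAD/z, y·SAD/z; sigma_eff) · (SAD/z)²`
with depth and SSD from exact ray–phantom intersections (slab or sphere
water phantom) and the inverse square computed from the distance along the
central axis (both clinical settings are isocentric, so TMR with SAD
geometry is the natural factorisation). There is no 3D scatter-kernel
superposition: head scatter, phantom scatter and electron transport are
folded into OF, TMR and sigma_eff respectively, which is adequate for the
near-axis, sub-centimetre observables this package reports. Doses are linear
in MU by construction; arcs are discretised at 2° by default (halving the
step changes voxel doses by <1% of the plan maximum, the global
dose-difference convention also used by the gamma criteria).

Plans are normalised so the maximum voxel (or in-plane maximum, for planar
calculations through the isocenter — the plane contains the dose maximum)
equals the prescription; `fixed_mu` mode is available for absolute-dose
work.

## Arc weighting and the default plan

Within an arc the MU per degree is proportional to |sin θ| with θ the gantry
angle from the vertical; control points sit on a Δ-spaced lattice including
both arc endpoints, each the centre of its Δ-wide sector, and are
renormalised so the arc MU is conserved exactly. With couch positions spread
over the half-turn and full gantry arcs this yields uniform direction
density on the sphere (coefficient of variation < 0.10 over equal-area bins
for a 72-arc ensemble); a uniformly weighted arc, by contrast, is the case
in which the superposition integral is rotationally symmetric about the
gantry axis — the sine-weighted arc is deliberately not.

The default 12-arc TGN plan spreads couch angles over [−85°, 85°] (with a
seeded ≤2° jitter), cycles collimator angles over [0°, 90°], alternates
CW/CCW, and places 30–45° gantry spans just off the vertex on alternating
sides (5–10° from gantry zero). Beams therefore cluster around the
vertical: the composite dose is compact in the coronal plane and elongated
anterior–posteriorly, the character of clinical TGN plans, and the coronal
50% isodose equivalent diameter lands at ≈6.6 mm on a 1 mm grid. The span
placement is a calibration of the generator against the reported plan
geometry — clinical couch/collimator sets are not published, so the
generator exposes all of it as configuration. Leaf-shift perturbations move
both X-bank edges symmetrically (aperture width 5 + 2·shift mm); which banks
physically drift during rotation is not observable here, so the symmetric
convention is documented rather than argued.

## Gamma QA

Global gamma with normalisation to the reference (calculated) map maximum,
reference points below the low-dose threshold excluded. `gamma_map`
minimises over a 3·dta search disc sampled at 0.1·dta with a 0.01·dta local
refinement around the coarse minimum (the coarse lattice quantises the dose
term; near-zero gammas on steep gradients need the fine pass).
`gamma_oracle` is an exhaustive minimisation over a 0.02 mm lattice spanning
the whole evaluated map: the zero-offset gamma bounds the useful search
radius exactly, so the unrestricted minimum is recovered without
approximation; the two agree within 0.02 γ on the seeded map-pair ensemble
used in the tests. Criteria default to the clinical pairs 3%/1 mm
(field-by-field) and 2%/1 mm (cumulative), both with 10% threshold.

## Synthetic measurement

The diode-array emulator samples the calculated plane at a 2.47 mm lattice
(centred so a detector sits on the central axis, extent 77 mm), after an
extra Gaussian blur (`widening_sigma`, 0.3 mm default) that reproduces the
systematic widening of measured small-field profiles (measured S_clin
≈0.2 mm above calculated on the composite plane), an optional sub-millimetre
registration offset, and multiplicative Gaussian noise (1% default, seeded).
The 1% noise level is a calibration choice — no measurement-noise figure is
published for this setting — selected as typical for solid-state array
dosimetry; under it the cumulative 2%/1 mm gamma passes at ≥97% (median over
seeds), the clinically reported regime. Diode volume averaging (0.48 mm
detectors) is an order of magnitude below both pitch and penumbra and is
neglected, as are angular and field-size dependences of diode response.

What passing synthetic-QA tests shows: that the pipeline — dose model,
resampling, gamma implementation, statistics — reproduces the reported QA
regime under a plausible noise model. What it does not show: anything about
a real linac's MLC calibration, output stability or detector behaviour.

## Numerical choices and degenerate inputs

* Isodose contours via marching squares at the level × planar max, measured
  with rotating calipers over 72 directions (2.5° steps, sub-0.05 mm
  accuracy for mm-scale contours); open or absent contours raise. The
  equivalent-diameter identity d = √(d₁·d₂) is enforced by construction.
* FWHM via linear interpolation of the two half-maximum crossings; profiles
  that never fall below half maximum raise. Note the 50% crossings of an
  erf-blurred top-hat sit at the effective edges only while the blur is
  narrow relative to the half-width (σ ≲ 1 mm for a 5 mm field); for wider
  blurs the eroding peak moves the half-max level outward — this is real
  behaviour, not an artefact, and is exactly why sub-centimetre measured
  field sizes exceed the collimator setting.
* Percent differences use the symmetric (relative-to-mean) convention,
  which reproduces the consistent cells of the reference comparison table;
  three cells of that table are internally inconsistent under any single
  convention and are not modelled.
* Rays through the source, points outside the phantom, detector boards
  larger than the calculated map, empty plans and out-of-range isodose
  levels all raise typed exceptions (`fvcsim.exceptions`).
* Lookup tables (TMR, OF) are clamped outside their range with an
  `ExtrapolationWarning`.

## Problem sizes

Default grids are 1 mm isotropic over a 60 mm cube (3D) or a 90 mm square
(planar); arcs are discretised at 2°. The full viability report runs in
tens of seconds on one CPU; the acceptance recomputation (61³ voxel grid
plus ten QA seeds) in under a minute.

## Known limitations

Water phantom only (no heterogeneity), primary-only factorised dose (no
explicit scatter kernel), no interleaf leakage or tongue-and-groove, no
depth dependence of the lateral-transport blur beyond buildup, no DICOM-RT
import/export, no couch/gantry collision model, and no inverse optimisation
of arc weights. The beam presets are analytic stand-ins calibrated to a
handful of published anchors, not commissioned beam data; absolute doses
outside the two reference settings inherit the simple TMR/OF forms.
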