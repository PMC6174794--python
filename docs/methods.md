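# Methods

This note documents the models behind `ctdosim`: what is simulated, which
parameters matter, what the synthetic data do and do not emulate, and the
numerical choices a user should know before trusting (or extending) the
results.

## Phantoms and materials

Transport phantoms are rectilinear voxel grids of mass density (g/cm³) and
material index, indexed `[ix, iy, iz]` with all coordinates in mm, voxel
values referring to voxel centers, and z along the scanner (table) axis.

CT volumes are converted with a piecewise calibration table: density is
linear between (HU, density) breakpoints and clamped at the extremes;
material is constant per HU segment. The default table has four segments —
air (< −850 HU), lung (−850…−200), soft tissue (−200…120), bone (≥ 120) —
with the sub-zero anchors on the air–water line (−1000 HU → 0.0012 g/cm³,
0 HU → 1.000 g/cm³), so e.g. −500 HU maps to 0.5006 g/cm³. Scanner-specific
curves can be supplied as a custom `MaterialTable`.

Organ contours (per-slice closed polygons, e.g. from an RT Structure Set)
are rasterized by the voxel-center-in-polygon rule with boundary points
excluded — a fixed half-open convention that makes ties deterministic.
Polygons must be simple; slices without a polygon stay empty.

Effective diameter is `2·sqrt(A/π)` with `A` the polygon area (shoelace, via
shapely): the diameter of the equal-area circle, consistent with standard
size-specific dose-estimate practice. It is invariant under rigid motions of
the contour and reduces to `2·sqrt(ab)` for an ellipse with semi-axes a, b.

The calibration phantom is a homogeneous *water* cylinder, 16 cm diameter
(water rather than PMMA, matching a water-referenced calibration chain),
with a central coaxial cylinder mask emulating a farmer-type chamber active
volume (default 3.05 mm radius × 24.4 mm, ≈0.71 cm³). Voxels coarser than
diameter/8 are rejected as unable to resolve the chamber; at 0.5 mm voxels
the discretized chamber volume is within ~1% of nominal, at 1 mm within ~8%
(use ≤0.5 mm when the chamber volume itself matters).

## Source model and trajectories

The beam is an extended circular focal spot (default radius 1 mm) at
source-to-axis distance 645 mm, emitting a fan beam with 28° half-angle and
longitudinal width `W = n_slices × slice_width` at the isocenter. These are
plausible wide-bore CT values and are configuration, not claims about any
specific scanner. No bowtie filter is modelled.

The packaged 120 kVp spectrum is computed from a filtered-Kramers
tungsten-anode model: photon fluence ∝ (kVp − E)/E attenuated by 7 mm
aluminium-equivalent total filtration (CT beams are far more heavily
filtered than radiographic ones), plus tungsten K lines at 58/59/67/69 keV
carrying 9% of the fluence. Its mean energy is 59.1 keV. The spectrum ships
as a two-column text table; `tungsten_spectrum()` regenerates it or produces
other tube potentials, and user-measured tables load from the same format.

Acquisitions are discretized as 12 coplanar fields per 360° rotation at 30°
intervals, each weighted mAs/12:

* **axial** — all 12 fields of a rotation share one isocenter z; rotation
  centers step by `W` (contiguous coverage) until the scan range is covered
  (`ceil(range/W)` rotations, so coverage quantizes up to a whole `W`);
* **helical** — consecutive fields advance 30° and `Δz = pitch·W/12`,
  interpolating the per-rotation table feed down to field granularity. By
  default the trajectory over-ranges half a beam width at each end so edge
  slices are fully irradiated; the switch matters when comparing dose
  efficiency between protocols (below).

Fluence per unit scan length therefore scales exactly as 1/pitch at fixed
per-rotation mAs — the physics behind the 4DCT dose penalty.

## Photon transport and scoring

Photons are tracked with Woodcock (delta) tracking against a per-energy
majorant attenuation, with three interactions on packaged 1 keV-resolution
cross sections:

* photoelectric: full local absorption;
* Compton: scattered energy/angle sampled from Klein–Nishina by the
  standard composition–rejection method; the transferred share is deposited
  at the interaction site;
* Rayleigh: direction resampled from the Thomson law `p(cosθ) ∝ 1+cos²θ`
  (form factors omitted — a 1–2% dose-shaping effect at these energies),
  no deposit.

Dose uses the **kerma approximation**: at ≤120 keV the secondary-electron
ranges are well below voxel size, so depositing transferred energy locally
is accurate and electron transport (ECUT-type settings) is metadata, not
physics. The photon cutoff is PCUT = 10 keV (local deposit and
termination). Per-batch energy conservation (emitted = deposited + escaped)
holds to accumulator precision and is asserted in the tests.

Cross sections are an anchored analytic model built at import: the
incoherent component is the exact Klein–Nishina cross section scaled by the
material's Z/A; photoelectric and coherent components are non-negative
power-law terms (`c₂/E² + c₃/E³ + c₄/E⁴`, non-negative least squares)
fitted to standard tabulated total mass-attenuation anchors for water, air
and cortical bone; a final log-log correction makes totals pass exactly
through the anchors (water at 60 keV is 0.2059 cm²/g by construction, and
the measured first-interaction free paths match Beer–Lambert by KS test).
Lung and generic soft tissue use the water composition at their own
densities — the standard water-equivalence assumption at kV energies. The
partial split between photoelectric and coherent terms is approximate at
the few-percent level; every absolute statement in the package rests on the
anchored totals, and relative (protocol-ratio) results are insensitive to
the split.

Two transport routes exist on purpose: the production path is a compiled
(numba) Woodcock kernel; `trace()` is a pure-Python exact voxel-traversal
transport with the same interaction physics. The test suite requires their
mean deposited energy per history to agree within combined statistical
error on a two-material slab — a dual-route check on the tracking logic.

Histories are allocated to fields proportional to field weight; results are
bit-reproducible given the seed (per-batch seeds derive from one
`SeedSequence`). Variance comes from history batches (default 10; the
1/√n-scaling test uses 100 because the standard-error estimator itself has
~1/√(2(B−1)) relative spread). Uncertainty of a region mean is the 1σ
standard error of the per-batch region means; a region with zero mean dose
reports NaN ("undefined"), never zero.

## Absolute calibration

Monte Carlo dose is per-history and arbitrary; absolute scale comes from the
CTDI procedure: simulate the protocol on the water cylinder, average the
per-history dose over the chamber mask, and form
`factor = measured / (simulated × scan_weight)` where `scan_weight` is the
summed field weight (mAs per rotation × rotations). Absolute dose is then
`per-history dose × factor × scan_weight`, linear in mAs and independent of
history count up to statistics. Records store the protocol identity;
applying a factor across protocols requires an explicit override (the
factor is a tube-output property, so a single axial reference rotation —
`reference_calibration()` — legitimately scales other protocols of the same
beam quality). No physical chamber exists here: the packaged "measured"
value (1.80 cGy per 100 mAs axial rotation at the center of the 16 cm
cylinder) is a synthetic but plausible fixture that sets only the absolute
scale; users with real audit data supply their own value.

## Regression and risk

Organ dose is the arithmetic mean of absolute dose over the organ mask,
with batch-propagated 1σ. The size model `dose = intercept + slope·d_eff`
is ordinary least squares (scipy); negative predictions clamp to zero with
a warning (extrapolation guard). The intercept/slope naming avoids the
collision between the size-model symbols and the risk model's dose and
attained age.

The risk model is the BEIR VII preferred ERR form for lung-cancer incidence
(parameters in the README). Organ equivalent dose uses radiation weighting
factor 1 for photons (1 cGy = 0.01 Sv). Confidence intervals substitute the
β bounds with γ and η fixed. Attained age defaults to exposure age + 10 y
(a fixed latency lag; it cancels in protocol ratios). Because ERR is linear
in dose, a patient's 4DCT:3DCT ERR ratio equals their lung-dose ratio
exactly; the cohort summary reports both the mean of per-patient ratios and
the ratio of arm means, which differ under heterogeneity.

## Synthetic data: what it emulates, what it does not

`make_thorax_phantom` builds an elliptical soft-tissue body cylinder
(AP/LAT ratio 0.75) sized to the requested effective diameter (recomputed
within 2%), with two ellipsoidal lungs (0.26 g/cm³), an ellipsoidal heart,
a vertebral bone annulus around the spinal cord, a trachea with air lumen
and soft-tissue wall (a pure air lumen would make kerma scoring sparse), a
posterior esophagus tube, and a skin shell (outermost lateral layer,
default 4 mm). Masks are carved in priority order, so they are pairwise
disjoint and inside the body by construction. Default voxels are 4 mm —
adequate for organ-mean doses, not for surface gradients.

Cohorts default to 102 patients, 51/51 by sex, ages uniform on [6, 93],
effective diameters on [184.5, 465.1] mm drawn *stratified* (evenly spaced
quantiles, order shuffled by seed): uniform density plus deterministic
coverage of the range extremes. `make_dose_table` generates organ-dose
fixtures from packaged cohort-level linear dose–size coefficients plus
Gaussian noise (floored at zero), so regression and risk code is testable
in milliseconds without transport.

None of this is anatomy: passing tests show the pipeline's bookkeeping,
physics scaling and statistics are right on a thorax-like geometry, not
that organ doses for a real patient would be reproduced. Respiratory
motion, 4D phase binning and image texture are not modelled; the only nod
to intensity-projection sensitivity is that lung density is a parameter
(raise it toward tissue to mimic a maximum-intensity-projection volume).

## Study configurations and expected values

* **Pitch scaling**: helical pitch 0.1 vs 1.0 on the water cylinder over a
  100 mm range, equal per-rotation mAs. The discrete field counts make the
  expected ratio (⌊span/Δz⌋+1 ratio) ≈ 9.86 rather than exactly 10;
  200 000 histories per arm give ~0.8% statistics.
* **Protocol ratio**: pitch-0.059 helical vs contiguous axial on a 300 mm
  thorax of 220 mm length, both scanning (0, 200) mm with 8×3 mm
  collimation and helical over-ranging disabled (an efficiency comparison
  over a fixed anatomical range; with over-ranging the helical arm simply
  irradiates a longer range). Axial coverage quantizes to 216 mm, so the
  expected ratio is (1/0.059)·(200/216) ≈ 15.7; measured 16.0 ± 0.13 at
  80 000 histories per arm.
* **Precision**: 500 000 histories, 10 batches, low-pitch helical on the
  default thorax give ~1% 1σ on the lung mean dose (comfortably below 2%).
* **Peripheral vs central dose**: on a fully scanned body-size object the
  skin shell receives *more* than the interior mean (peripheral-to-central
  ratio > 1 at 120 kVp) — surface voxels see unattenuated entrance fluence
  from every gantry angle. Cohort studies that contour skin over the whole
  body while scanning only the thorax will instead report low skin means
  by dilution; both observations are consistent.

Problem sizes (voxel 4 mm, 10⁴–5×10⁵ histories) were chosen so the full
test suite and the acceptance script each run in minutes on one CPU while
keeping every asserted quantity's statistical error far from its tolerance.

## Known limitations

* Kerma scoring in very low-density voxels (air lumina) converges slowly;
  organ masks should include tissue walls, as the synthetic trachea does.
* No electron transport, bremsstrahlung, bowtie filter, tube-current
  modulation or heel effect; Rayleigh form factors omitted.
* The photoelectric/coherent partial split is fitted, not tabulated;
  analyses that depend on the interaction-type breakdown (rather than
  totals and Compton) should substitute measured tables.
* Absolute doses inherit the synthetic chamber fixture unless a real
  measured value is supplied; only relative statements are
  fixture-independent.
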