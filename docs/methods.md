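# Methods

## Physical model

### Geometry and coordinates

The domain is the aqueous medium between the dish floor (z = 0), a disk
microelectrode with its insulating glass sheath, and the far bulk. The
electrode axis is r = 0 (x = y = 0 in 3D). The *working distance* is the
optical gap between the electrode face and the apex of the target cell,
so the electrode face sits at z = cap\_height + working\_distance; the
glass body occupies everything above that plane out to the sheath radius.
Cells are spherical caps resting on the floor: base radius r\_b, apex
height h, sphere radius R = (r\_b² + h²)/2h, lateral area 2πRh. The
default cap (r\_b = 12.5 µm, h = 10 µm) represents an adherent,
polygonal-spread cell whose largest dimension sets the base diameter.

Defaults: disk radius a = 12.5 µm, sheath radius 175 µm, working
distance 25 µm. The far (bulk Dirichlet) boundary sits 40 disk radii
away by default; the domain validator refuses anything under 25 radii,
where boundary truncation would visibly inflate the limiting current.

### Transport

Pure diffusion for all species — no convection, no migration (the
supporting electrolyte is concentrated), no temperature field, and no
CO₂/bicarbonate chemistry (the imaging medium is HEPES-buffered by
design). Bulk values: c\_O₂ and pH 7.4 with a 20 mol m⁻³ monoprotic
HEPES buffer, pK\_a 7.5.

Two transport parameter sets are provided:

| set | D\_O₂ (m² s⁻¹) | c\_O₂ (mol m⁻³) | use |
|---|---|---|---|
| `default_medium()` | 2.1 × 10⁻⁹ | 0.26 | baseline (≈ 25 °C literature values) |
| `calibrated_medium()` | 3.0 × 10⁻⁹ | 0.206 | 37 °C values; reproduces the −9.52 nA reference limiting current |

The calibrated pair was fixed once against the measured diffusion-limited
current of the real electrode-over-cell system (−9.52 nA): at the default
geometry the solver's hindrance factor is ≈ 0.80 of the bulk Saito value
4nFDca, and D·c = 6.2 × 10⁻¹⁰ mol m⁻¹ s⁻¹ — within the 37 °C literature
ranges for both factors — closes the gap. Buffer diffusivities are
0.7 × 10⁻⁹ m² s⁻¹ for HA and A⁻ (the same molecule give or take a
proton) and 9.3 × 10⁻⁹ m² s⁻¹ for free H⁺.

### Electrode boundary condition

Galvanostatic operation fixes the integrated flux: the O₂ consumption is
|i|/(nF) mol s⁻¹ spread uniformly over the disk (n = 4 electrons;
the 2-electron peroxide pathway is accepted by the flux converter but no
peroxide species is transported). Two refinements:

- **Limiting current** uses the exact Dirichlet condition c = 0 on the
  disk and integrates the flux, i\_lim = −nF Σ g\_f c\_f.
- **Saturating disk.** Near the transport limit a uniform draw would pull
  the disk-centre concentration negative even for |i| < |i\_lim| (the
  centre is the hardest point to supply). Faces whose concentration would
  go negative therefore switch to c = 0 and the flux deficit is
  redistributed uniformly over the remaining faces — the behaviour of an
  equipotential disk under constant-current control. For |i| ≤ 7 nA at
  the default configuration no face saturates and the condition reduces
  to the plain uniform flux; at −9 nA (95% of i\_lim) a rim of centre
  faces saturates. If the whole disk saturates and still cannot deliver
  the set current, the solver raises instead of fabricating a solution.

Protons are consumed at 4 per O₂, distributed over the disk in
proportion to the *realised* O₂ flux.

### Buffer chemistry

Protonation equilibria are far faster than transport at these scales, so
the chemistry is operator-split: each time step diffuses H⁺, HA and A⁻
independently, then re-equilibrates every cell locally to
[H⁺][A⁻] = K\_a[HA] holding the two conserved totals (total proton
[H⁺]+[HA], total buffer [HA]+[A⁻]) fixed. The equilibration solves the
proton quadratic in a cancellation-free form (H = 2K\_aT\_H/(b+√(b²+4K\_aT\_H))
for b ≥ 0), accurate to ~1e-12 relative even though free H⁺ is a ~10⁻⁶
fraction of the totals. The ORR proton sink is applied to the HA pool —
the proton reservoir that actually carries the flux — and the
equilibration redistributes it; water autoprotolysis is neglected (pH
stays in the 7–8.5 range for every supported configuration, and the
solver raises if a weakly-buffered configuration would exhaust the
total-proton field instead).

Steady pH solves the conserved total [H⁺]+[HA] as one field with the
buffer diffusivity (exact when D\_HA = D\_A, the default) and then
speciates. pH = −log₁₀([H⁺]/10³) with concentrations in mol m⁻³.

### Numerics

Finite volumes on graded structured meshes; all fluxes are conservative
(two-point), so closed-domain mass conservation is exact to roundoff
(verified to 1e-6 over 1000 steps in the tests). Axisymmetric volumes
carry the 2πr weighting. Grading clusters points at the disk edge
(r = a, z = z\_face), where the Dirichlet flux density is singular; each
refinement level halves the edge spacing. Level 2 (the default, ~10⁴
cells) is converged to ~0.3% in the limiting current; level 3 changes it
by < 0.5%.

Transients use backward Euler with a geometric ramp from dt = 1 ms
(plenty below the ~0.6 s gap diffusion time) to t\_end/100, re-using LU
factorisations per (dt, D, saturation-set). Halving dt changes the −7 nA
pH trace by < 1e-3 units. The initial state is the respiration-only
steady field; the disk flux switches on at t = 0.

The cell cap surface is handled by exact z-band quadrature: each axial
slab intersecting [0, h] carries the closed-form band area 2πRΔz, and
both the respiration sink and the surface average use those weights, so
the weights sum to the true cap area and the total respiration is exact
regardless of the stair-step mask.

The 3D solver uses a graded tensor Cartesian grid (fine spacing
2.5–6 µm over the cells and disk), stair-step masks for the electrode
body and the caps, Jacobi-preconditioned conjugate gradients with warm
starts (the systems are SPD; direct factorisation is prohibitive at
~10⁵ cells), and face-area-weighted averages over each cap's exposed
faces with respiration scaled to the true cap area. The quality gate is
agreement with the axisymmetric solver for a single centred cell: 0.3%
at 3 µm resolution, well inside the 5% acceptance bound. The 3D solver
transports O₂ only (pH is an axisymmetric question — the buffer
perturbation is strongly localised under the disk) and uses the plain
uniform-flux disk, so it refuses currents close to the transport limit
rather than saturating; the supported scenes run at −7 nA, 74% of i\_lim.

### Respiration

The cellular O₂ consumption is an areal flux of 2.15 × 10⁻⁸ mol m⁻² s⁻¹
over the cap surface (≈ 1.7 × 10⁻¹⁷ mol s⁻¹ for the default cap, a
typical single-cell respiration rate). A whole-cell reading of the
underlying literature figure (2.15 pmol s⁻¹) is dimensionally untenable
here — its 4-electron current equivalent (~0.8 µA) would exceed the
~10 nA transport limit of the whole electrode by two orders of
magnitude — so the areal interpretation is used and is configurable.
Respiration perturbs the field by < 0.1% of bulk; it is kept for
fidelity, not for effect. The flux is constant (not O₂-dependent), which
is adequate while local O₂ stays well above the Michaelis constant of
mitochondrial consumption (~1 µM); at deep depletion it slightly
overstates consumption.

## Headline model outputs

At the default calibrated configuration the solvers give (computed, not
asserted): i\_lim = −9.505 nA (level 2); at −7 nA the cell-surface O₂
plateaus at 68% of bulk within ~10–14 s (5% criterion) and the cell pH
rises by 0.047 after 5 min; at −9 nA the 5-min pH swing is 0.061. The
pH swing carries the largest model uncertainty: it scales inversely with
the buffer's total concentration × diffusivity, for which only
literature values are available, and the 5-min value is still ~40%
short of its (slow, domain-scale) steady state of ~0.13.

## Fluorescence pipeline

Exactly the standard confocal workflow: sum-projection over z (sum, not
mean, so slice count drops out of normalised quantities), per-cell mean
over a supplied label mask (segmentation is out of scope; masks under
20 px are excluded as degenerate), normalisation by the challenge-onset
frame, OLS slope of normalised intensity against time in minutes.
Statistics: paired two-sided t-test on per-cell differences (the control
window is the same cells before the challenge, hence paired); F-test
with the larger variance in the numerator against the upper-tail
critical value at α = 0.05 (2.2 at (18, 18) d.o.f.); Pearson r between
mask area (a dye-loading proxy) and rate. Sample SD uses the n−1
denominator throughout. All statistics are invariant to a global
intensity scale.

## Synthetic-data generator

What it emulates: 512 × 512 fields with ~19 convex-polygonal cells at
30–50% labelled confluency (jittered-grid placement guarantees
disjointness; lognormal areas, re-sampled until the band is met);
5 z-slices per stack at 30 s frame spacing; an irreversible dye whose
activation rate is k\_cell · max(0, 1 − c/c\_ref) — linear in the O₂
deficit, constant in time under constant exposure, accumulated
monotonically even if O₂ recovers; lognormal per-cell multipliers on
k\_max as the stand-in for metabolic heterogeneity; additive Gaussian
pixel noise; exponential photobleaching at 0.003 min⁻¹ (which is what
makes control slopes slightly negative).

Calibration (done at import, by quadrature over the lognormal plus a
2-unknown root solve): k\_max and σ are set so that the *measured*
challenged-slope statistics — through the exact pipeline, including the
~7% attenuation from onset-frame normalisation and bleaching — equal
0.169 min⁻¹ mean and √(0.072² − 0.009²) between-cell SD at the default
challenge deficit of 0.322 (the solver's −7 nA steady-state cap-surface
deficit). The pixel noise SD is set in closed form so the control-group
slope SD is 0.009 min⁻¹ at the default mask area; the model attributes
the whole control spread to detector noise, which makes individual
pixels very noisy (SNR ≈ 0.1) and mask means clean — adequate for the
pipeline, not for visual realism.

What it does *not* emulate: optics (no PSF, no z-profile), Poisson
photon statistics, cell texture or motion, focus drift, and any true
dose–response curve of the dye beyond monotone linearity in the deficit.
Passing tests therefore demonstrate that the pipeline and statistics are
correct and well-calibrated under these idealisations — not that the
biological variability of a real population is lognormal.

## Design choices made where the design was open

- **Steady state** is defined as within 5% of the final change (exposed
  as a parameter); the time-to-steady measurement requires the trace to
  have actually flattened and errors otherwise.
- **Rate fits use normalised intensities** over the full window
  including the onset frame (consistent with how normalised time-lapse
  data are plotted and fit in practice).
- **c\_ref defaults to bulk O₂**: any depletion activates the dye.
  Michaelis-type saturation was rejected as unconstrained by available
  observations (fluorescence grows linearly at constant current).
- **F-test critical value** is one-tailed: the printed 2.2 at n = 19 per
  group matches the upper-tail value at (18, 18) d.o.f.
- The bundled three-cell cluster scene places neighbours at 40 and
  45 µm from the axis (similar radial distances from the target); the
  coordinates are exposed as configuration, not hard-coded.

## Problem sizes

Default refinement level 2 (~10⁴ FV cells) for axisymmetric production
runs and level 1 (~3 × 10³) for quick checks; 3D grids at 2.5–6 µm fine
spacing (3 × 10⁴–10⁵ cells). Synthetic experiments default to n = 19
cells, 11 frames per window; power statements rest on 200 seeded
replicates. These sizes were chosen as the coarsest that keep every
reported quantity inside its verification tolerance (mesh-convergence
and cross-solver gates above).

## Known limitations

- The uniform-flux/saturating disk is an approximation to the true
  mixed boundary condition of a galvanostatic equipotential disk; it is
  exact in total flux, approximate in distribution.
- pH results depend linearly on buffer parameters known only from
  literature; treat absolute swings as ±30%.
- The 3D stair-step caps under-resolve curvature at coarse grids; use
  the 5% axisymmetric gate, not grid-free convergence, as the accuracy
  statement.
- No electrode kinetics (Butler–Volmer), no potential prediction, no
  biological feedback (HIF signalling, metabolic adaptation) — the cell
  is a passive O₂ sink with a static respiration flux.
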