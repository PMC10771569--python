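# Methods

## Physical model

A pulse train is modeled in the quasi-static conduction limit: during a
pulse the potential satisfies ∇·(σ∇φ) = 0 with the energized needle at
the pulse amplitude and its partner grounded. Capacitive and transient
membrane dynamics, electrode–electrolyte interface impedance, and Joule
heating are outside the model's scope (bench temperature rises are
measured, not simulated). The field magnitude |∇φ| is the quantity
compared against the irreversible-electroporation threshold.

Conductivity is per-region and either

* **constant** — used for hydrogels calibrated from an inter-electrode
  resistance readout (Hep-G2 small-well hydrogels fall in
  0.022–0.032 S/m; the package default is the 0.027 S/m midpoint), and
  for the two-region co-culture model (tumor core 1.26 S/m, endothelial
  ring 1.46 S/m); or
* **field-dependent** — a logistic sigmoid
  σ(E) = σ₀ + (σ_f − σ₀)·s((E − E_c)/E_w) rising from σ₀ = 0.4 S/m to
  σ_f = 1.6 S/m as electroporation raises membrane conductance. The
  transition parameters are not fixed by any measurement we rely on;
  the defaults E_c = 500 V/cm, E_w = 100 V/cm place the transition
  across the reversible-to-irreversible range and are configurable.
  Note σ(0) = 0.408 S/m rather than exactly σ₀, the usual property of a
  logistic transition with finite width.

## Discretization and solver

Domains are regular Cartesian grids with an embedded boundary: a cell
belongs to the domain (and a region) iff its center does. Wells are
solved as 2D axial cross-sections — the validation data are ablation
*areas* in imaging planes — with currents and resistances scaled by the
3 mm modeled electrode height; tumor models use the same solver on 3D
voxel grids. Default spacings are 0.01 cm for wells and 0.5 mm tumor
voxels, chosen so refinement tests (area change < 2% at half spacing)
pass at desk-scale runtimes.

The scheme is cell-centered finite volumes with harmonic-mean face
conductivities (5-point/7-point stencils), giving a symmetric M-matrix,
so the discrete maximum principle holds exactly. Linear systems are
solved by a sparse direct factorization for 2D sections and by
Jacobi-preconditioned conjugate gradients (rtol 1e-10) for large 3D
grids; both are deterministic for fixed inputs. The σ(|E|) fixed point
is resolved by Picard iteration with under-relaxation 0.5 on the
conductivity field, declared converged when the relative max-norm change
of the field magnitude drops below 1e-3 (at most 50 iterations; failure
raises an error carrying the residual). The current out of the energized
needle is the sum of discrete face fluxes leaving its cell set; discrete
conservation makes this contour-independent, which a test checks by
dilating the contour.

Boundary handling: the well wall is zero-normal-flux (insulating
plastic). A grounded-wall Dirichlet option exists solely to realize the
coaxial-resistor oracle (single centered needle), whose closed forms
φ(r) = V·ln(R/r)/ln(R/a), E(r) = V/(r·ln(R/a)) and
R = ln(R/a)/(2πσh) validate potential, field and resistance to 2–3%.
The oracle tests use a 0.1 cm electrode radius — larger than the G19
needle — so the staircase representation of the metal boundary is well
resolved at the test spacing; the convergence test confirms the error
shrinks under refinement.

**Inactive electrodes** are removed from the conducting domain (treated
as insulating holes) while other pairs fire. The floating-conductor
alternative (equipotential body at the charge-neutral potential) would
locally raise the field near the idle needle; the insulating choice is
the simpler of the two idealizations and is applied uniformly. Metal
interiors carry zero field and are excluded from tissue accounting.

## Superposition and ablation accounting

Sequential activations do not coexist in time, so vector or scalar
summation of fields would be unphysical; the cumulative exposure is the
**pointwise maximum** of the per-activation field magnitudes. This makes
the cumulative map idempotent under plan repetition and monotone under
plan extension — both tested.

The ablation sweep counts tissue cells with cumulative magnitude ≥ t
(boundary cells count as ablated) times the cell measure, over threshold
ladders of 200–1200 V/cm in 1 V/cm steps for small wells and 20 V/cm
steps for larger domains and tumors. No sub-cell correction is applied;
accuracy comes from grid refinement, which the tests bound at < 2% for a
halved spacing. Coverage fractions divide by the tissue measure of the
chosen region (whole well, co-culture core/ring, or tumor voxels), and
the tri-level coverage map labels each cell untreated / above the
experimental 544 V/cm threshold / above the reported in-vivo 800 V/cm
threshold, ties resolving to the higher label.

Treatment time is Σ n_pulses/frequency over the plan — pulse width and
count otherwise enter only as metadata, since the pulse-number dependence
of the threshold is an experimental observation, not part of this model.

## Threshold inversion

Inversion interpolates the monotone (threshold, area) table piecewise
linearly at the measured area; among exact ties the smallest threshold is
returned, so flat stretches of the table resolve conservatively.
Measured areas larger than any simulated ablation raise an explicit
out-of-range error rather than clamping silently (the simulation cannot
explain them); areas below the ladder's reach return the ladder maximum
with a warning. Replicates pool as arithmetic mean ± sample SD (n−1);
grouping by protocol or replicate is left to the caller.

## Synthetic data

The generators are pure functions of (parameters, seed), one seeded
generator per call, no global state.

* **Measured areas**: A(true_threshold)·(1 + ε), ε ~ N(0, cv²), clipped
  to [0, domain measure]. Noise is multiplicative because replicate
  scatter grows with ablation size; the default cv = 0.05 is a package
  choice of realistic inter-replicate variability, not a measured value.
  The reference recovery condition (24-well pair, 1100 V, cv 0.05,
  n = 9) recovers a 544 V/cm truth with bias well inside the
  experimental 61 V/cm spread across seeds.
* **Tumors**: star-convex masks r(θ,φ) = R·(1 + b·p(θ,φ)) with p a
  seeded real spherical-harmonic sum (degrees 1..n_lobes) normalized to
  unit peak, so bumpiness b < 0.5 guarantees star-convexity; b = 0 gives
  a sphere whose voxelized volume matches (4/3)πR³ to ~3% at 0.5 mm
  voxels. Radii 5.2/6.4/9.3 mm reproduce the 0.6/1.1/3.4 cm³ tumor-mold
  volumes. These emulate the size and lumpiness of CT segmentations, not
  their anatomy: passing coverage tests shows the pipeline handles
  irregular 3D targets, not that any specific patient tumor is covered.
* **Resistances**: the constant-σ forward resistance times (1 + ε).
* **Live/dead z-stacks**: binary pages of the super-threshold region
  (2 mm total stack thickness by default), measured back by pixel
  counting; the render → measure loop reproduces the sweep's area
  exactly at native pixel size, closing the simulation ↔ "imaging" loop.

What the synthetic data do **not** emulate: optical point-spread and
staining kinetics, partial cell death near the threshold, conductivity
heterogeneity within a region, electrode insertion damage, and thermal
effects. Test passes therefore validate the computational pipeline, not
these biological factors.

## Problem sizes

Default test and validation runs use 2D well grids of roughly 80–320
cells across (0.04–0.005 cm spacing) and 3D tumor grids of ~40³ voxels
at 0.5 mm — sizes chosen so the full suite and the recovery study run
comfortably on a single CPU while keeping discretization errors inside
the stated tolerances.

## Known limitations

* 2D well sections ignore vertical field fringing at the 3 mm electrode
  ends; resistances are per modeled height.
* The insulating treatment of idle needles is an idealization (see
  above); coverage near an idle needle is slightly conservative.
* The sweep's cell counting has O(h·perimeter) error; thresholds
  inverted from areas near the domain boundary inherit it.
* Calibration assumes the measured resistance reflects the
  pre-electroporation (low-field) conductivity; if a readout came from
  late pulses in a strongly electroporated gel it would recover an
  effective, higher σ.
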