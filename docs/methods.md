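# Methods

`palpinv` estimates the diameter `d` (mm), depth `h` (mm, surface to
inclusion top) and Young's modulus `E` (kPa) of a stiff spherical inclusion
embedded in soft tissue, from tactile features measured at the tissue
surface.  The package contains the complete study apparatus: a
finite-element forward model, a synthetic tactile-image renderer with pixel
feature extractors, a pixel-to-simulation calibration, a small neural
inversion network with two from-scratch trainers, and hold-out /
leave-one-out validation harnesses.

## Forward model

### Geometry and assumptions

The tissue is an isotropic linear-elastic slab, 120 × 120 mm laterally and
20 mm thick, fixed to a rigid base (tissue over bone).  Background modulus is
5 kPa; Poisson's ratio is 0.49 everywhere (soft tissue is nearly
incompressible).  The inclusion is a sphere of diameter `d` whose top lies
`h` mm below the surface, centred on the probe axis, with modulus
`E_inc > E_bg`.  A square elastic probe block (25 × 25 mm footprint) rests on
the surface and is driven downward by a prescribed indentation of its top
face (default 2 mm, 10% of slab thickness — small-strain regime).  The
probe–tissue interface is a frictionless vertical tie: normal displacements
are coupled, lateral slip is free.  This replaces true unilateral contact;
for monotone indentation without lift-off the tied approximation is standard
and keeps the system linear.

The probe block is a single homogeneous layer, 5 mm tall at 30 kPa.  This
emulates the soft sensing layer of the layered optical waveguide: the
deformation of its bottom face is what the camera sees.  A thick, stiff
probe behaves as a plate and spreads the inclusion's imprint laterally until
it is invisible; a thin, moderately soft block localizes it.  Both modulus
and height are configurable (`probe_modulus_kpa`, `probe_height_mm`).

### Discretization

Structured, axis-aligned 8-node trilinear hexahedra.  The lateral grid is
uniform (default 1 mm) over a central region that always covers the largest
inclusion (`fine_extent = 8` mm ≥ d/2 for d ≤ 14 mm) and grows geometrically
toward the far boundary, with spacing capped at 2.5 mm under the probe and
the probe edge (±12.5 mm) always on a grid line; the vertical grid is
uniform.  The fine region is deliberately scenario-independent so that every
scenario under one configuration shares an identical mesh; this makes
feature differences attributable to material changes only, and lets the
homogeneous reference (below) be solved once and cached.

Material assignment is voxel-wise: an element takes the inclusion modulus if
its centroid lies inside the sphere.  A model is refused if fewer than two
elements span the inclusion diameter in any axis.

At ν = 0.49 fully integrated linear hexahedra lock volumetrically.  The
element splits the stiffness into a shear part (full 2×2×2 Gauss) and a
volumetric part integrated at the centroid only (selective reduced
integration).  A 2×2×2-element confined-compression patch test reproduces
the closed-form uniform-strain solution to machine precision, and a finer
confined slab reproduces the linear-in-depth displacement profile to 0.5%.

Because the inclusion always sits on the probe axis, the default solve uses
a quarter model with symmetry planes (u_n = 0) through the axis and mirrors
the probe-bottom field; `symmetry=False` builds the full mesh (the test
suite checks quarter/full agreement and the mirror symmetry of the full
solution).  The reduced system is solved with Jacobi-preconditioned
conjugate gradients (rtol 1e-10) with an automatic fallback to a SuperLU
factorization; both paths are gated by a 1e-8 relative-residual check.  CG
was adopted as the default because on these graded meshes it is about three
times faster than the direct solve at identical accuracy.

### Observable field and features

The raw solve yields `w_raw = u_z + indent` on the probe bottom — how far
each point of the probe's bottom face is pushed up into the probe relative
to the rigid travel of its top.  `w_raw` is dominated by two
scenario-independent components: a uniform compression of the probe against
the slab, and a pressure ring at the probe edge (the flat-punch edge
concentration).  Neither carries inclusion information, and in the optical
sensor uniform contact scatters no measurable light.  The *observable* field
is therefore the excess over the homogeneous-slab reference solved on the
identical mesh,

    w = max(w_raw − w_ref, 0)  zeroed below the detectability floor (2 µm),

where the floor models the smallest waveguide deformation that produces
measurable scattering.  A series-stiffness argument shows why the reference
subtraction is necessary and not cosmetic: at fixed indentation the *total*
extra force of a stiff inclusion is nearly independent of its depth, so the
raw field's sum cannot decrease with depth — only the localized excess
pattern (peak decaying, halo spreading) carries the depth signal.

Features of the excess field on a 26 × 26 cell-centred grid over the probe
footprint:

* `f1` — maximum deformation (mm),
* `f2` — total deformation (mm), the grid sum,
* `f3` — deformation area (mm²), cells above the 10 µm area threshold
  (`area_eps_mm`) times the cell area.

The two thresholds (2 µm floor, 10 µm area) were fixed by requiring the
documented qualitative trends — all three features nondecreasing in `d` and
`E`, nonincreasing in `h` — to hold across 5-point sweeps, and kept fixed
thereafter.  With a near-zero area threshold the thresholded area of a deep
inclusion *grows* with depth (the sub-µm halo widens as the peak decays),
contradicting the expected trend; 10 µm is the deformation needed to light a
blob pixel.

## Tactile image rendering and pixel features

The renderer is an explicit proxy for the optics, not a ray-traced model:
bilinear resampling of the excess field to 1024 × 768 (probe footprint
across the full width), an affine gain of 400 px/mm, a Gaussian point-spread
blur (8 px), optional seeded Gaussian noise, clipping and 8-bit
quantization.  The gain is chosen so the blob threshold k = 5 corresponds to
12.5 µm of deformation, matching the simulation-side detectability scale;
with this choice the end-to-end (image + calibration) monotonicity suite
passes and all calibration R² exceed 0.9.

Pixel features at threshold k = 5: the pixel value at the intensity-weighted
centroid of the above-k blob (`tsis1_mode="centroid"`, with a plain-maximum
fallback and a `"max"` config switch), the sum of all pixel values, and the
count of pixels above k.

## Calibration

Per-channel ordinary least squares with the pixel feature as predictor and
the FEM feature as response, fitted on the nine calibration-phantom
inclusions (sizes {2, 8, 14} mm, depths {3, 6, 9} mm, moduli {40, 80, 120}
kPa, off-grid parameters at d = 8 mm, h = 5 mm, E = 120 kPa).  The direction
is pixels → FEM units because the inversion network is trained in FEM
feature units while deployment-time inputs are images.  With only nine
points a robust loss would be underdetermined; plain OLS is used.  The area
channel is floored at zero after mapping.

## Inversion network

Three weighted layers of 3, 4 and 3 neurons (sigmoid, sigmoid, linear), 43
parameters; layer sizes and activations are configurable (a two-layer
reading, where the first "3 neurons" are just the input fan-in, is available
through the same config).  Inputs and targets are min–max scaled to
[0, 1] on the *training* split only (held-out records may scale outside the
unit interval — accepted, to avoid leakage).  Training minimizes
E(x) = Σ eᵢ², the sum of squared residuals in scaled space.  Initialization:
U(−1, 1)/√fan-in weights, zero biases, seeded.

**Levenberg–Marquardt.**  Steps solve (JᵀJ + µI) Δx = Jᵀe with J assembled
by batched backpropagation (one row per record-output residual).  µ is
divided by β = 10 on an accepted step and multiplied by β on a step that
would increase E(x), with the previous weights restored; µ₀ = 1e-3.  The
accepted-step history is nonincreasing by construction.  Large µ makes the
step parallel to the negative gradient, small µ recovers Gauss–Newton (both
are asserted in tests, including the monotone rotation of the step direction
as µ sweeps).

**Scaled conjugate gradient.**  Møller's algorithm: curvature along the
search direction from a forward-difference Hessian–vector product with
σ_k = σ/|p_k| (σ = 1e-4), λ-regularization with sign repair when the
directional curvature δ_k ≤ 0, step α_k = µ_k/δ_k, comparison parameter
Δ_k = 2δ_k(E(x_k) − E(x_k + α_k p_k))/µ_k², acceptance iff Δ_k ≥ 0, restart
to steepest descent every N iterations (N = 43), λ halved when Δ_k ≥ 0.75
and quadrupled when Δ_k < 0.25; λ₁ = 1e-6.  δ_k = 0 is treated as an
unsuccessful step with λ escalation.  Memory is O(N): only vectors are
stored, never a Hessian.  On a 5-variable SPD quadratic the implementation
reaches the minimum to 1e-8 at iteration 5 (conjugate-gradient finite
termination).

Both trainers share exact backprop gradients (checked against central
finite differences to 1e-6 over 20 random configurations).

## Validation

* **Hold-out**: train on the complement of a named id set (canonically the
  9 calibration inclusions out of 134), evaluate on the held-out set.
* **Leave-one-out**: n folds, each record tested exactly once (audited);
  the final error is the average of per-fold errors.

Each repeat re-initializes the network with seed `base_seed + repeat` and
refits scalers on the training portion.  Errors are reported in two modes:
`rms_relative` (headline) — per output, 100·rms of (T − Y)/T on physical
values — and `as_printed` — the plain signed average of scaled residuals
× 100.  The signed mode is retained only for comparability: positive and
negative residuals cancel, so it reads near zero for even a badly scattered
predictor and must not be used as an accuracy claim.

## Problem sizes and defaults

The canonical experiment samples 134 scenarios uniformly from d ∈ [2, 14]
mm, h ∈ [3, 12] mm, E ∈ [20, 120] kPa (triples violating
h + d ≤ 20 mm are redrawn), computes FEM features at the default 1 mm mesh
(about 20k unknowns per quarter-model solve, a few seconds each), and runs
SCGA/LOOCV at 100 iterations averaged over 10 seeds — the configuration of
`scripts/acceptance.py`.  The distribution family of the sampled triples and
the exact ranges are package choices (the ranges bracket every concrete
phantom value used in the study); the 9 calibration scenarios are constructed
deterministically and used as the canonical hold-out set.

## Known limitations

* **Modulus identifiability.**  The three surface features saturate in
  `E_inc` at high stiffness contrast: a 24:1 inclusion already behaves
  nearly rigidly, so ∂(features)/∂E → 0 toward the top of the modulus
  range.  No inversion — the 3-4-3 network, or far larger reference
  regressors — can recover E to few-percent relative error from these
  features; recovered moduli carry tens of percent rms relative error.
  Size and depth are recovered to high single-digit percent under LOOCV at
  desk scale.  The signed-average error mode, by contrast, reads well below
  1% for all three outputs, which says only that the estimator is unbiased.
* The tied-contact approximation excludes lift-off and friction; the linear
  kinematics exclude large indentation; viscoelasticity and layered probe
  materials are not modeled.
* The image renderer is a monotone proxy; it preserves ordering and
  approximate linearity but no optical physics, so pixel-domain values have
  no absolute meaning beyond the fitted calibration.
* Voxelized material assignment quantizes the effective inclusion size at
  the mesh scale (default 1 mm), which adds feature noise for the smallest
  inclusions; small deep inclusions can fall entirely below the
  detectability floor and contribute irreducible inversion error.
* Synthetic tests and synthetic images cannot validate the real optical
  transfer; passing the suite demonstrates the simulation/inversion
  machinery, not hardware performance.
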