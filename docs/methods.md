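# Methods

## Surface model

A corneal surface is modelled as the zero set of a general second-order
implicit polynomial in three variables (ten coefficients, coordinates in mm).
This is the standard biconic/ellipsoid approximation of the corneal cap: the
quadric that fits a healthy or moderately ectatic cornea is a real ellipsoid,
and its canonical form x′²/a² + y′²/b² + z′²/c² = 1 yields the clinical
parameters Rx = a²/c, Ry = b²/c (apical radii of curvature, mm) and
Qx = (a/c)² − 1, Qy = (b/c)² − 1 (asphericities). These satisfy the conicoid
sag identity r² = 2Rz − (1+Q)z² along each principal meridian, which the test
suite checks symbolically against the ellipsoid section. Healthy corneas are
prolate (Q ≈ −0.3); Q drifts toward −1 with advancing keratoconus.

Because Q is homogeneous in its coefficients, the all-zero vector is a
trivial global minimiser of any algebraic residual. The coefficient vector is
therefore kept on the unit Euclidean sphere throughout (projection after
every variation step), with the sign fixed so a33 ≥ 0. Pinning a11 = 1 is the
classical alternative and is available in the least-squares fitter
(`constrain_a11=True`), but the norm constraint is the default: it has no
preferred monomial and behaves better when the true surface has a small a11.

Two error measures are kept strictly separate:

* **algebraic fitness** (1/N) Σ Q(P_s)² — the optimisation objective of every
  fitter (dimensionless, unit-norm coefficients);
* **elevation MSE** (1/N′) Σ (ẑ − z)² in mm² — the reported goodness of fit,
  where ẑ solves the quadric's z-quadratic at each node's (x, y), taking the
  real root nearer the measured elevation. Nodes where the fitted surface has
  no real elevation are excluded from the MSE but counted and reported
  (`unresolved_nodes`); the MSE presumes ẑ exists, so silently averaging over
  a partial column would hide a defective surface.

## Discretisation

Tomographer grids are 24 rings × 256 semi-meridians per surface (6144 nodes).
Ring i (1-based) sits at radius i·0.2 mm — first ring at 0.2 mm, outermost at
4.8 mm — and meridian j at angle (j−1)·2π/256, counter-clockwise, column 1 at
0°, right-handed axes with z along the instrument axis. Elevations are
absolute z in mm; the sentinel −1000.0 (exact) marks invalid samples and is
part of the CSV format contract. Conversion to Cartesian drops sentinels, so
N_points + N_sentinels = 6144 always. The CSV dialect (delimiter, decimal
mark, orientation, ring spacing) is configurable since vendor exports vary;
the writer prints 17 significant digits so round-trips are bit-exact.

## Preconditioning

Quadric scatter matrices in raw mm units are severely ill-conditioned. Every
fitter centres the cloud on its centroid and scales the maximum radius to 1,
fits in that frame, and maps the coefficients back analytically (the map is
linear on the (A, b, k) blocks, followed by renormalisation).

## The genetic-algorithm fitter

Configuration follows the settings that work for this problem class:
population 1000 (100 individuals per variable), crossover rate 0.8,
elite/cloning rate 0.2, mutation rate 0, size-2 tournament selection, blend
(BLX-α, α = 0.5) crossover, genes initialised uniformly in [−1, 1] and
projected to the unit sphere, function/constraint tolerance 10⁻⁵⁰. The
tolerance is below double-precision resolution, so it is paired with a
50-generation stall window (stop when the best fitness improves by less than
the tolerance over the window — in practice, when it is bit-flat) and a
generation cap (500 per restart).

The quadratic objective on the sphere is extremely anisotropic: its Hessian
eigenvalues span ~30 orders of magnitude for noiseless data. Plain
axis-aligned BLX with zero mutation collapses the population before it
reaches the global valley and stalls many orders of magnitude above the
optimum. Three design choices fix this while keeping the algorithm a plain
elitist real-coded GA:

1. **Rotation-invariant blend.** Crossover intervals are formed in the
   population's principal-axes frame (SVD of the centred population each
   generation), so the offspring distribution follows the valley instead of
   the coordinate axes. Axis-aligned BLX remains available
   (`crossover="blend_alpha"`).
2. **Rank guard.** Each principal direction's blend interval is floored at
   10⁻² of the parent-pair distance. With zero mutation, a direction whose
   population variance hits zero could never be regenerated; the floor keeps
   the offspring distribution full-rank at a scale that still contracts.
3. **Stall boost (step-size control).** While the best fitness has improved
   by less than 20× over the last 40 generations, every blend interval is
   widened by 1.5× per generation. Selection contracts the spread again as
   soon as progress resumes, so the population spread self-regulates to the
   scale of the remaining distance to the optimum rather than collapsing
   prematurely into a drift-limited creep. Once truly converged the boost
   only produces discarded offspring (elitism preserves the best), and the
   bit-flat stall window still terminates the run.

Surfaces that miss part of the data column (no real z at some nodes) are
penalised by (fraction of unresolved nodes)·(2·z-range)², measured on a fixed
stride subsample of ≤128 nodes per generation for speed; the penalty vanishes
near any surface covering the cloud, so optima are unchanged.

Two independent restarts are pooled (the landscape occasionally traps a
single population; two independent draws make that event quadratically
rarer), then a refinement phase (subpopulation 250, up to 120 generations)
polishes the top candidates against the *exact* mean squared residual in the
original mm frame — the quantity reported and compared across methods — and
the final answer is the candidate minimising exactly that reported pipeline
(back-transform, normalisation, residual, penalty). Inside the coarse phase
the fitness is evaluated through the 10×10 triangular QR factor of the design
matrix, which gives the same value and numerical floor as the full N×10
product at ~1/1000 the cost.

With a fixed seed the whole fit is bit-reproducible; `FitResult.converged`
records whether any phase stopped on the tolerance/stall rule rather than the
generation cap. Fitting one 6144-node surface takes ~2 s on one CPU core.

## Baselines

* `fit_direct_linear` — the right singular vector of the design matrix with
  the smallest singular value: the exact global minimiser of the norm-
  constrained algebraic problem. Deterministic, no iteration; it serves as
  the oracle in tests. Clouds whose second-smallest singular value also
  vanishes (e.g. coplanar points) do not determine a unique quadric and raise
  a degeneracy error.
* `fit_lsq_trra` — scipy's trust-region reflective least squares on the
  weighted residuals, scale-invariant form r = √w·(M c)/‖c‖ (or a11 pinned to
  1). Default weights are uniform; `radial_weights` offers
  w = 1/(1 + (r/r_max)²) as a model of noisier peripheral samples. The
  iteration starts from a neutral 7.8 mm sphere tangent to the cloud apex (a
  typical anterior cornea) so the baseline is reproducible.
* `fit_sqp` — SLSQP on the quadratic form under the unit-norm equality
  constraint, same sphere start. As a local method it can land in poor minima
  on deformed or incomplete clouds; failures are surfaced through
  `converged`/`fq`, never patched.

## Synthetic data

The generator inverts the morphometric relations: c = Rx/(1+Qx) and
a = Rx/√(1+Qx) (likewise b, c from Ry, Qy). A single shared c-axis is used —
a true ellipsoid, inside the fitted model family — so recovery tests are
exact; when the x- and y-derived c differ, their geometric mean is taken and
the recorded truth is recomputed from the realised axes. Optional apex
offset and tilt about x exercise the pose-handling paths. Defaults emulate a
healthy anterior surface: Rx = Ry = 7.8 mm, Q = −0.3, apex at the origin.

Measurement imperfections are modelled as (i) i.i.d. Gaussian elevation noise
(3 µm for control presets, 5 µm for keratoconus presets — the scale of
Scheimpflug elevation repeatability), (ii) sentinel dropout: `random`
(scattered invalid nodes), `wedge` (a contiguous angular sector, as under a
lid or tear-film break), `ring` (peripheral rings, where acquisition fails
first), and (iii) a Gaussian bump A·exp(−d²/2w²) added to the elevations as a
keratoconus-like cone (out of the quadric family — the stress test for the
fitters). Cohort presets step the cone amplitude 0.02/0.05/0.10 mm and draw Q
toward −1 with steeper radii for grades 1/2/3–4.

What this does **not** emulate: physically based Scheimpflug ray-path noise
(real noise is radially heteroscedastic and spatially correlated), posterior-
surface coupling to pachymetry, registration/fixation error, or real
keratoconus topography (cones are symmetric Gaussians). Passing tests
therefore demonstrate correctness of the algorithms under controlled,
in-family truth plus idealised corruptions — not clinical performance.

## Numerical choices and edge cases

* Coefficient sign canonicalised a33 ≥ 0 (first nonzero second-order entry
  positive if a33 = 0); applied at construction, not inside the evolution
  loop (flipping mid-search splits the population across the ± symmetry).
* Elites and tournament clones are copied bit-exactly; only crossover
  offspring are re-projected to the sphere. Renormalising an elite would
  perturb its fitness at the ulp level and break strict elitism.
* z-quadratics with |a33| < 10⁻¹² (unit-norm scale) are solved linearly;
  nodes with negative discriminant return NaN and are handled by callers.
* `to_canonical_ellipsoid` assigns the canonical c-axis to the eigenvector
  with the largest |z| component (the optical axis), x to the remaining
  eigenvector with the larger |x| component, signs fixed non-negative and the
  y-axis completed right-handed — a deterministic pose.
* `check_quadric_order` flags fq = 1 both when the second-order block norm
  falls below 10⁻⁶ (plane-like degeneration) and when the eigenvalue
  signature is not that of a real ellipsoid (paraboloid, hyperboloid,
  imaginary ellipsoid).
* STL is written binary, units mm; the format stores float32 vertices, so
  on-surface residuals of a written file are single-precision. The float64
  sampling is exposed (`sample_cap`) for exact checks.

## Problem sizes

Validation batches use full 6144-node grids: 20 noiseless clouds for oracle
equivalence, 20 noisy clouds (σ = 5 µm) for parameter recovery, 40 noisy
clouds with up to 30% dropout (all three modes, every fourth with a cone) for
the failure-rate check, and Monte-Carlo noise-floor checks over five clouds.
These sizes give binomial resolution of one failure in twenty at a few
minutes of total compute, which is what the package's own acceptance script
and test suite run.

## Known limitations

* The GA's advantage over the local baselines on *real* pathological data
  cannot be demonstrated here (no distributable patient data); the synthetic
  cone cohorts exercise the machinery but are kinder than real ectasia.
* The quadric is a global model: a single ellipsoid cannot represent a true
  cone; on cone-deformed clouds all methods converge to the best ellipsoidal
  compromise and the MSE floor rises with amplitude (by design).
* One surface per CSV file; paired anterior/posterior handling and solid
  (two-surface) cornea construction are out of scope.
* "Non-dominated sorting" in the multi-objective sense is not implemented:
  with a single scalar objective and the norm constraint enforced by
  projection, feasibility ranking reduces to plain fitness ranking, so NSGA
  machinery would be vacuous.
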