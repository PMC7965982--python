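# Methods

This note documents the models implemented in `impactdmn`, the synthetic
data they are exercised on, the numerical choices made where the design
was open, and the limitations those choices imply.

## Constitutive model

Brain tissue is modeled at a material point by an additive volumetric /
isochoric split of the Cauchy stress.  The kinematics follow the standard
multiplicative split F = J^{1/3} F*, J = det F, B* = F*F*ᵀ,
I₁* = tr(F*ᵀF*), and for white matter I₄* = a·C*a with C* = F*ᵀF* and a
the reference axonal direction (structural tensor A₀ = a⊗a).

* Isochoric matrix: a Gent solid, (μ_m/J)·[1 − (I₁*−3)/j_m]⁻¹·dev(B*).
  The Gent factor locks as I₁*−3 → j_m; the implementation raises a
  dedicated `GentLimitError` there rather than returning an unbounded
  stress.  In the small-strain simple-shear limit the shear stress slope
  is exactly μ_m (verified to 0.1% at γ = 10⁻⁴).
* Fiber reinforcement (white matter only):
  (2k₁/J)(I₄*−1)exp[k₂(I₄*−1)²]·dev(F*A₀F*ᵀ).  The tabulated k₂ carries
  stress units in the source literature but multiplies the square of a
  dimensionless invariant; it is treated as dimensionless, and k₂ = 0 for
  the shipped white-matter set makes the exponential 1 (k₂ > 0 is
  accepted).  Setting k₁ = 0 reduces white matter exactly to the gray
  formulation.
* Volumetric response: σ_vol = −[K₀/(Λ₀+1)]·[(ρ/ρ₀)^{Λ₀+1} − 1]·I with
  ρ/ρ₀ = 1/J from mass conservation (the density ratio is never carried
  as an independent state variable).

Parameters ship in a versioned YAML (`data/materials.yaml`): white matter
ρ₀ = 1140 kg/m³, K₀ = 2.19 GPa, Λ₀ = 6.15, μ_m = 550 kPa, j_m = 1.1,
k₁ = 2.14 kPa, k₂ = 0; gray matter identical volumetrically with
μ_m = 450 kPa, j_m = 1.4 and no fiber term.

Two scalar measures feed the damage rules.  Von Mises stress
√(3/2·dev σ:dev σ) indicates skull fracture against the 92.72 MPa
ultimate strength of cranial bone, with the case discarded when strictly
more than 4% of skull elements exceed it (the fraction spanning the
maximum skull thickness).  The gray-matter criterion is the **shear
energy rate**, defined here as the deviatoric stress power density
dev(σ):dev(D) (units MJ/m³/s).  This definition is the module's single
most consequential interpretation — the damage literature does not fix
the algebraic form — and it is isolated behind one pure function of
(σ, D) so an alternative (e.g. the isochoric strain-energy rate) can be
swapped without touching anything else.  The default damage threshold is
1 MJ/m³/s, calibrated for blunt impact; a 100 MJ/m³/s "blast" preset is
retained for reference.

## DMN element mapping

A binary DMN voxel mask is mapped to mesh elements in two steps: select
every node whose world coordinates fall inside a true voxel, then take
every element sharing at least one selected node, restricted to gray
matter.  Voxel containment uses the voxel-center convention
v = floor(A⁻¹x + 0.5) with 0-based indices, matching NIfTI semantics
where the affine maps voxel centers to world coordinates.  "Connected to"
means sharing ≥1 node, not face adjacency.  Restricting the output to
gray elements (rather than restricting the node selection) is a choice;
the alternative would only differ for elements straddling tissue
boundaries.

## Synthetic fixtures

The generators define the study conditions; their defaults are fixed and
all of them are bit-reproducible given (spec, seed).

* **Toy head.**  A jittered cubic lattice clipped to a 9 cm radius and
  Delaunay-tetrahedralized, labeled by centroid radius into a white core
  (< 0.45R, radial fibers), gray rind (0.45–0.70R), CSF gap (0.70–0.77R)
  and skull shell (> 0.77R).  Resolution 6 (the default study mesh) gives
  ~5,600 elements.  I/O as legacy ASCII VTK.
* **DMN template.**  Sum of Gaussian blobs on a 16³ grid, rescaled to a
  peak z of 6; the default has an anterior and a posterior midline blob
  inside the gray rind, echoing the medial-prefrontal/posterior-cingulate
  core of the network.  Binarization at z > 3.1 gives the mask whose
  volume is the damage-load denominator.
* **Impact surrogate.**  Peak shear energy rate of gray element j at
  distance d_j from the impact point:
  e_j = A·(v/v_ref)^α·exp(−d_j/λ)·(1+β cos θ)·(R_ref/R)^γ·(1+η_j), with
  multiplicative truncated-Gaussian noise η_j (truncated at −0.9 to keep
  fields positive); skull von Mises follows the analogous linear law
  B·v·(R_ref/R)^γ·exp(−d_j/λ).  Defaults: A = 2 MJ/m³/s, v_ref = 8 m/s,
  α = 2, λ = 0.06 m, β = 0.5, γ = 0.25, R_ref = 0.036 m,
  B = 9 MPa·s/m, noise_cv = 0.05.  λ and B were calibrated once against
  two structural goals: the library's positive-class fractions should
  span roughly 0.45→0.06 across damage thresholds 10→90% (so every
  threshold is learnable, mirroring realistic campaign balance), and
  fracture should remove ~10% of scenarios.  On the toy head a shorter
  decay (λ = 0.04 m) would leave the far DMN blob permanently below the
  1 MJ/m³/s criterion and make damage > 90% unreachable.  This surrogate
  is a desk-scale stand-in with the qualitative structure the learning
  layer needs — monotone in velocity, decaying with distance, sharper
  impactors more damaging — not a mechanical simulation: it has no time
  integration, no contact, no wave propagation, and its noise is
  element-independent, so passing tests show that the learning and
  inversion machinery works on data with this structure, not that the
  surrogate predicts real injuries.
* **Default library grid.**  5 locations × 4 impactors × velocities
  2–14 m/s step 2 × angles {−45°, 0°, 45°} = 420 scenarios, the order of
  magnitude of a realistic pre-computed campaign; density is
  configurable.  Impact points are fixed representative surface points
  per location label; the impact direction is the inward normal tilted by
  the angle about a tangent axis.
* **rsfMRI cohort.**  Subject series = Σ_k s_k(t)·M_k(voxel) + Gaussian
  noise with AR(1) time courses s_k (φ = 0.4, innovation variance
  1−φ²); defaults 16³ grid, 120 timepoints, 18 controls + 1 patient,
  2 networks, noise sd 1.  The patient's DMN loading is multiplied by
  (1 − deficit_effect) inside a contiguous region grown by breadth-first
  search from the template peak, covering deficit_fraction (default 15%)
  of the binarized mask.  The generator emulates network-driven
  covariance and a focal connectivity deficit; it does not emulate
  physiological noise spectra, motion, spatial autocorrelation of scanner
  noise, or registration error, so calibration results here are
  best-case.

## Machine-learning layer

One binary classifier per network-damage threshold: label = 1 iff the
record's damage percentage strictly exceeds the threshold (fractured
records must be filtered first; the labeler enforces this).  Candidate
features, in the declaration order that also breaks selection ties:
velocity, five location indicators, a perpendicular-impact flag (angle
exactly 0), impactor radius of curvature, distance from impact point to
the nearest DMN element centroid, and the angle between the impact
direction and the direction to that centroid (defined 0 at zero
distance).  Location enters as five indicators so selection can pick
individual locations; the binary perpendicular flag and the continuous
angle both stay in the candidate pool and selection decides.

Greedy forward selection maximizes mean stratified 5-fold CV AUC of a
logistic regression, stopping when the best improvement is below 1e-4.
The ensemble fits five members on z-scored continuous features
(indicators pass through): logistic regression, linear discriminant
analysis (the Gaussian discriminant with shared covariance), k-NN with
k = round(√n) odd-adjusted, Gaussian naive Bayes, and an RBF SVM whose
decision scores are mapped to probabilities by a sigmoid fitted on the
training scores (a probability is required for averaging; the member
hyperparameters are library defaults, deliberately untuned).  The
ensemble probability is the arithmetic mean of the five member
probabilities.

Leave-one-out validation refits the ensemble n times; feature selection
runs once on the full library, mirroring its use as a pre-processing
step.  This leaks a small amount of information into the held-out
predictions (an optimistic bias accepted knowingly; with ~10 candidate
features and AUCs near 1 the effect is small).  AUC is the rank statistic
on pooled held-out probabilities; sensitivity/specificity/accuracy use a
0.5 cutoff; dataset balance is the positive fraction.

## Velocity inversion

Holding all boundary conditions but velocity fixed, the trained ensemble
is evaluated on a 1–15 m/s grid (step 0.1).  The plateau probability P_f
is the mean over the top decile of the grid — a window mean was chosen
over the curve maximum or last sample because member probabilities can
oscillate in the upper plateau — with optional isotonic smoothing (off by
default, recommended for noisy ensembles).  The onset velocity is the
first grid velocity with P(v) ≥ 0.95·P_f; an all-zero curve is flagged
not-reached.

**Known limitation (plateau-onset bias).**  On noise-free libraries where
damage is a deterministic threshold rule in velocity, the 95%-of-plateau
rule overestimates the true onset v₀ by ~2–3 m/s.  The mechanism is
structural: P_f approaches 1 on separable data, so 0.95·P_f sits near the
top of the sigmoid, and while the k-NN/SVM/logistic members can be
arbitrarily sharp at the boundary, the discriminant-analysis and naive
Bayes members have data-limited sigmoid slopes (velocity spreads over the
full range within each class), dragging the five-member mean.  The bias
is insensitive to member regularization and library grid density.
Velocity estimates from this rule should be read as upper bounds;
rankings across thresholds are reliable (onset velocity is monotone in
the damage threshold, which is tested).

## Functional damage

Dual regression, stage 1: each timepoint's volume is regressed on the
template spatial maps, giving per-network time courses.  Stage 2: each
voxel's time series is regressed on the variance-normalized time
courses, giving per-network beta maps.  Maps are z-normalized as
beta / SE(beta) from the voxel-wise OLS standard error (one of several
variants in the dual-regression literature; the raw beta map is also
returned, and is the quantity used for exact-recovery checks on noiseless
data, where the standard error degenerates to zero).  Rank-deficient
designs raise an error reporting the condition number.

The single-case statistic is the Crawford–Howell t,
(mean_c − patient)/(sd_c·√(1+1/N)) — equivalent to the two-group GLM with
n = 1 vs N — for the controls > patient contrast; zero-variance voxels
get t = 0 and are flagged.  The null is generated by sign flipping: all
N+1 maps are centered on the pooled mean, each subject's centered map is
multiplied by a random ±1 per permutation, and the statistic is
recomputed; TFCE is applied to the observed and every permuted map, and
the voxel-wise uncorrected p is (1 + #{perm ≥ observed})/(n_perm + 1).
A flag switches to raw-t permutation p-values.  TFCE integrates
e(h,v)^E·h^H·dh over thresholds h = dh, 2dh, … ≤ stat(v), with e the
6-connected component size at height h; E = 0.5, H = 2 (the published
defaults), dh adaptive at 0.1·max(stat) unless given explicitly;
negative statistic values contribute nothing.  Defaults: 5,000
permutations (500 in the test profile for desk-scale runtimes).

**Known limitation (single-case sign-flip calibration).**  Sign flipping
around an *estimated* center is not exact for a single-case statistic:
the patient's deviation survives (only sign-flipped) in every
permutation, and in the ~half with the patient's sign unflipped the
permuted statistic tracks the observed one.  Voxel-wise p-values under a
pure null are therefore conservative (never anticonservative — the
type-I rate is deflated, not inflated), and pooled null p-values are not
uniform; flipping around the true mean, available only in simulation, is
exactly calibrated.  Power is nonetheless real for large deficits because
pooled-mean centering transfers a fraction of the patient's deviation
into the permuted control mean, and TFCE's spatial aggregation recovers
coherent deficit regions essentially completely (a planted −5 sd block is
fully detected at p < 0.05 with 500 permutations).  Damage loads from
this pipeline should be read as lower bounds.

The damage load counts voxels with p < α (default 0.05) inside the
binarized DMN mask (optionally intersected with a gray-matter mask); the
denominator is always the full mask volume.

## Forensic kinematics

Simple point-mass reconstruction: fall heights compose algebraically
(rounded to 0.1 m), impact velocity is √(2gh) with g = 9.81 m/s² (the
value that reproduces the canonical case numbers) and a configurable
rounding profile (integer or 1 decimal, as case reports mix both), force
is m·a with a in multiples of g (2 decimals, kN), and 1 mph =
0.44704 m/s exactly.  No initial velocity and no arc of rotation are
modeled.  Nine case files transcribe canonical reconstruction narratives;
one of them carries a printed fall-height total that disagrees with its
own components by 0.2 m — the implementation reports both and the
discrepancy rather than silently correcting either.  Literature-derived
velocity ranges in the case files are constants, not derived quantities.

## Problem sizes and determinism

The default study conditions are the resolution-6 toy head (~5,600
elements, ~360 DMN elements), the 420-scenario library (seed 0,
noise_cv 0.05, ~12% fractured), 16³ rsfMRI grids with 120 timepoints and
18 controls, and 500-permutation inference in tests; these sizes keep the
full test suite and the acceptance script within a few minutes on one
CPU while leaving every statistical check well-powered.  All randomness
flows from explicit integer seeds through `numpy` `SeedSequence` streams
(per-scenario streams are derived from the library seed and a CRC of the
scenario key), so every pipeline is bit-reproducible end to end; the
tests assert this for the mesh, the library, the cohorts and the
permutation maps.
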