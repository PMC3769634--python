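# Methods

This note documents the models, estimators, numerical choices and known
limitations of hippomorph, in the order the pipeline applies them.

## Surface representation (SPHARM-PDM)

A closed genus-zero surface with a spherical parameterization — per-vertex
polar angle θ ∈ [0, π] and azimuth φ ∈ [0, 2π), injective away from the two
pole vertices — is expanded coordinate-wise in *real, orthonormal* spherical
harmonics up to degree L (default **L = 12**): high enough to express the
bending and tapering of a hippocampus-like body at the 1,002-vertex
sampling, low enough to act as a mild smoother of segmentation noise. The
expansion is an ordinary least-squares fit of the three coordinate
functions against the ((L+1)²)-column design matrix; it requires at least
(L+1)² vertices and a full-rank design (a rank-deficient fit indicates a
degenerate parameterization and is an error, not a warning).

Basis bookkeeping that downstream code relies on:

* Y₀₀ = 1/√(4π), so the degree-0 coefficient vector times Y₀₀ is the
  surface's spherical-mean position (the centroid for an exactly
  represented surface).
* The degree-1 harmonics are √(3/4π) times the unit-direction components
  (Y₁₁ ∼ x, Y₁,₋₁ ∼ y, Y₁₀ ∼ z). The degree-1 part of the surface is
  therefore a linear image of the unit sphere, and its SVD gives the
  **first-order ellipsoid**: semi-axes = singular values, axis directions =
  left singular vectors. Ties (spheres, surfaces of revolution) are broken
  deterministically: within a tied subspace the axis closest to +z is
  taken first, then the one closest to +x; axis signs are fixed by making
  the leading non-zero component (z, then x, then y) positive.

The point-distribution model samples every subject's expansion at the same
fixed parameter locations: a frequency-10 geodesic subdivision of an
icosahedron oriented with one vertex at each pole (V = 10·10² + 2 = 1,002
vertices, F = 2,000 triangles). The sampling is generated deterministically
in code — bit-identical vertices, faces and (θ, φ) on every call — which is
what vertex-wise correspondence across subjects rests on.

## Head-size correction and alignment

* **ICV scaling** multiplies vertices about the surface centroid by
  (ICV_ref / ICV_subject)^(1/3), with ICV_ref the cohort mean, so enclosed
  volumes scale by the ICV ratio. It is applied before alignment: head-size
  is a property of the subject, not of the template fit.
* **Rigid alignment** matches centroids and first-order-ellipsoid axes.
  Aligning only the longitudinal axis leaves a spin and sign ambiguity;
  both are resolved by also mapping the second axis and choosing, among the
  four proper sign combinations, the one minimizing the sum of squared
  vertex distances. No scaling enters the transform.
* **Template**: vertex-wise mean surface of *all* subjects (controls and
  patients), refined by (re-align, re-average) iterations (default 2).
  Two stabilizers make this well-posed: summation order is canonicalized
  (sorted by a hash of each vertex array) so the template is bit-identical
  under input permutation, and each new mean is rigidly aligned back to the
  previous template. The second is a gauge fix: for near-circular
  cross-sections the ellipsoid spin is nearly free, and without anchoring
  the template rotates by a constant small angle every iteration instead of
  converging.

## Volume maps (Jacobian of the interpolated displacement)

Displacement vectors are subject-minus-template vertex differences; their
signed normal components use angle-weighted vertex normals. The template
interior is rasterized at **1.0 mm** isotropic spacing (configurable) by an
even–odd ray parity test at voxel centers (vertical rays per grid column,
offset by a fixed sub-voxel epsilon so analytic meshes cannot place
vertices exactly on a ray). Dirichlet voxels — interior voxels with an
exterior 6-neighbor, plus voxels containing surface vertices — take
inverse-distance-weighted values from their 3 nearest surface vertices.

The "heat equation" step is the steady state: the unique bounded
interpolant of the boundary data, one 7-point-stencil Laplace solve per
vector component (sparse LU up to 200k unknowns, conjugate gradients with
rtol 1e-8 beyond). Constants and linear fields are reproduced exactly
(linear fields are discrete-harmonic on this stencil), and the discrete
maximum principle holds, which the tests exploit as oracles.

J = det(I + ∇u) is computed per voxel with central differences (one-sided
at mask edges) and read at each vertex half a voxel inward along the
normal (trilinear; nearest valid voxel within 3 voxels as fallback, beyond
that an error) because one-sided gradients on the mask rim are noisier.
The Jacobian is defined on the *mapping* x → x + u(x): it equals 1 at rest
and under any rigid motion of the subject, which is what makes the volume
metric insensitive to residual misalignment.

**Spatial response.** The harmonic interpolant answers a volumetric
question. A surface patch pushed inward compresses tissue through the whole
cross-section beneath it and stretches the flanks where the field decays
back to zero; the projected map therefore shows a real negative response
below the band (weaker, all longitudes) and positive flanks at its edges.
Group maps should be read with the growth/shrinkage sign: "areas of
atrophy" are the significant *shrinkage* (J − 1 < 0) vertices. The spatial
resolution of the map is on the order of the local cross-section radius,
not one mesh ring — a limitation inherited from using a boundary-value
interpolant as the deformation model.

## Medial axis (MEMAX)

The prime meridians are the model evaluated at (θ_k, 0) and (θ_k, π),
θ_k = kπ/(K+1), k = 1..K equiangular (default **K = 50**). The MEMAX is
their pair-wise Euclidean midpoint — the translation-invariant reading of
"averaging the two point sets"; a coordinate-wise geometric mean is neither
translation-invariant nor defined for negative coordinates. An open
3×K strip (rows: upper meridian, MEMAX, lower meridian; 4(K−1) triangles)
supports the curvature estimate; a crude edge-through-face test warns (not
fails) on self-intersecting strips.

**Signed Gaussian curvature.** |κ| is the intrinsic angle-deficit estimate
(2π − Σ incident angles)/A_mixed with Meyer's Voronoi-mixed area; the sign
is the sign of the discrete mean curvature (cotangent Laplacian dotted with
the consistent strip normal), so bending convex toward the normal is
positive. Two consequences are deliberate and documented: (i) mirroring a
strip flips every sign exactly while |κ| is unchanged (an isometry); (ii)
at points where the continuous mean curvature vanishes — a perfect saddle
center, flat points — the sign is taken from the discrete estimate and is
not stable; tests probe saddles slightly off the symmetry locus where H is
strictly signed. The strip's end columns have no interior angle deficit;
they copy the nearest interior value and are flagged.

Because the MEMAX is the exact midpoint of each meridian pair, the strip is
a ruled surface, and a pure fixed-axis bend of the tail is near-developable
(κ stays ~0). Bending becomes visible to κ through its torsion component —
which is also the anatomically reported pattern (medial bending with
rotation about the long axis); the synthetic bend effect is parameterized
accordingly (below).

## Statistics

* Per-vertex two-sample **pooled-variance t-tests** (volume and curvature
  maps), two-sided; zero-pooled-variance vertices are flagged and excluded
  rather than imputed.
* Point-wise two-sample **Hotelling T²** on 3D position vectors, pooled
  covariance, p-values via the exact F transform
  F = T²(n−d−1)/(d(n−2)), d = 3; a singular pooled covariance is ridged by
  1e-10·trace and flagged.
* **Ipsi/contra pooling**: each patient contributes the hemisphere
  ipsi-/contralateral to their focus side, z-transformed against the
  control distribution of the same *anatomical* hemisphere (no mirroring);
  controls are z-transformed against their own hemisphere distribution.
* **FDR**: Benjamini–Hochberg step-up at q < 0.05, applied separately per
  metric and per hemisphere. Note that BH is adaptive: with many true
  rejections the effective per-vertex threshold relaxes, and up to a
  fraction q of the discovery set is expected contamination — recovery
  tests allow exactly that many strays.
* **Global volumetry**: z-scores of left volume, right volume and the
  asymmetry index 2(L−R)/(L+R) against controls; a side is atrophic when
  its volume z < −2 or the asymmetry z exceeds +2 against it, hypertrophic
  when its volume z > +2; labels compose per side. The inequalities are
  strict: exactly ±2 SD classifies as normal.
* **Covariate correlation**: per-vertex Pearson r against a subject
  covariate with t-distributed p-values and BH correction across vertices.

## Synthetic data: what it emulates, what it does not

The shape family is a curved tapered tube defined analytically in the
spherical parameters (θ along the long axis, φ around it): centerline an
in-plane arc (default 40° over 40 mm), radius profile
r_max·sin θ·(1 − taper·g) with r_max = 5 mm, taper 0.35, and axial position
proportional to (1 − cos θ)/2 — with the sine radius profile this gives
blunt elliptical end caps (an unbent, untapered tube is exactly an
ellipsoid, i.e. band-limited at degree 1) rather than needle tips, keeping
every surface vertex within reach of the voxel grid.

Injectable effects, all with exact per-vertex ground truth:

* **Atrophy/hypertrophy bands**: radial contraction/expansion toward the
  analytic centerline inside a (θ, φ) band, weight 1 on the band core with
  a raised-cosine rim over the outer 30% of the extent (subfield borders
  are anatomically sharp; the half-maximum truth mask then sits close to
  the detectable support). Default band: lateral, half the circumference,
  half the length, magnitude 0.15.
* **Bend with torsion**: a smoothstep rotation ramp from a hinge latitude
  (default 2π/3) to the tail pole about an axis tilted 45° from the
  in-plane normal toward the local tangent. The tangent (torsion) component
  is what makes the bend visible to the strip curvature (a pure fixed-axis
  bend is near-developable); it emulates malrotation-like rotation about
  the long axis combined with medial displacement.
* **Shift**: a global translation.
* **Noise**: per-vertex isotropic Gaussian displacement (default SD 0.25 mm
  = 5% of the maximum radius), averaged once over the 1-ring to mimic the
  smoothness of manual-segmentation error.
* **Head size**: subject ICV is lognormal (median 1.5·10⁶ mm³, σ_log 0.05)
  and *drives* a global (ICV/ref)^(1/3) scaling of the subject's surfaces,
  so the pipeline's inverse ICV correction removes real variance, as it
  does in vivo.
* **Covariate**: disease duration is built from per-subject atrophy
  severity (lognormal, σ_log 0.25) plus noise orthogonalized against
  severity, so the realized patient-sample correlation equals the requested
  r exactly (default 0.4) before the ≥ 0.5-year floor.

All randomness flows from one integer seed through `SeedSequence` spawning
(one child per subject plus one for cohort-level draws), so any single
subject is reproducible in isolation.

What the generator does **not** emulate: real subfield geometry and
histology, voxel-level segmentation artifacts, MRI intensity properties,
inter-subject anatomical variability beyond pose/size/noise, and
correlated bilateral disease. Passing recovery tests therefore demonstrates
that the estimators localize the effects they are built for under
controlled conditions, not clinical performance.

## Problem sizes in tests and the acceptance script

Recovery experiments run at 20 controls vs 20 patients (one hemisphere,
1,002 vertices, 1 mm grid); the null calibration uses 100 synthetic null
cohorts of the same size at the statistics layer and 2,000 Hotelling null
draws; the duration correlation uses 20 vs 60 patients (the generator's
covariate-calibration size). These sizes are chosen to match the
generator's study conditions while keeping any single experiment in the
tens of seconds on one CPU.

## Known limitations

* Position vectors (and, through template contamination, any
  alignment-dependent quantity) are not invariant to the rigid-alignment
  step; a purely local volume deficit shifts the aligned surface
  everywhere, which shows up in the position maps. Operator-recovery tests
  for bending therefore run in generation pose with alignment disabled.
* The volume map's spatial resolution is the cross-section scale (see
  above): significant shrinkage extends beyond a one-ring dilation of the
  injected surface band, by construction of the volumetric interpolant.
* The curvature sign is undefined where the mean curvature vanishes.
* `fit_spharm` assumes the provided (θ, φ) is a reasonable spherical
  parameterization; the package does not compute area-preserving spherical
  maps for arbitrary segmentations, and topology repair is out of scope.
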