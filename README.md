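# hippomorph

Surface-based morphometry for hippocampus-like structures: disentangle
**where a structure has lost or gained volume** from **where it merely sits
or bends differently**.

Clinical questions about hippocampal shape — atrophy of a subfield, medial
positioning, bending of the tail ("malrotation") — confound two different
kinds of anomaly. A vertex sitting inside the template surface may mark
tissue loss, or a perfectly preserved structure that is displaced. This
package implements a framework that separates the two on corresponding
surfaces:

* **Local volume change.** Each subject surface is expressed as a
  spherical-harmonic point-distribution model (SPHARM-PDM: the coordinate
  functions of a closed genus-zero surface expanded in real spherical
  harmonics and sampled at 1,002 fixed parameter locations, giving
  vertex-wise correspondence across subjects). The template-to-subject
  displacement vectors are extended into the enclosed volume as the steady
  state of the heat equation (one discrete Laplace problem per component,
  Dirichlet data on the rasterized surface), and the Jacobian determinant of
  the mapping x → x + u(x),

      J(x) = det(I + ∇u(x)),

  is projected back to the surface: J − 1 > 0 growth, J − 1 < 0 shrinkage.
  Unlike raw normal displacements, J is invariant to rigid misalignment.

* **Position and bending.** The spherical parameterization's two prime
  meridians (longitudes 0 and π) are averaged pair-wise into a mean meridian
  axis (MEMAX) — a skeleton that inherits the SPHARM correspondence and
  needs no external reference. Per-point 3D position vectors quantify
  shifting; a signed Gaussian curvature (angle-deficit magnitude, sign from
  the mean curvature w.r.t. the strip normal) quantifies bending.

* **Statistics.** Vertex-wise pooled-variance t-tests (volume, curvature),
  point-wise Hotelling T² (position vectors), optional z-transformation
  against the matching control hemisphere for ipsi/contralateral pooling,
  Benjamini–Hochberg FDR at q < 0.05, and a 2-SD global volumetry
  classifier on absolute volumes and the asymmetry index 2(L−R)/(L+R).

Because no imaging data ship with the package, a first-class synthetic
generator produces hippocampus-like curved tapered tubes with injectable,
analytically known effects (subfield-band atrophy/hypertrophy, bending with
torsion, positional shift, smoothed segmentation noise, an ICV-coupled head
size, and a disease-duration covariate with a requested correlation to
atrophy severity), so every stage is testable against ground truth.

## Worked example

```python
import hippomorph as hm

sim = hm.simulate_cohort(
    12, 12, seed=7, focus_side="left",
    effect_spec=hm.EffectSpec(atrophy=hm.BandEffect(magnitude=0.15),
                              noise_sd=0.25, covariate_r=0.4))
model = hm.ShapeAnalysis.from_simulation(sim)
res = model.fit()
print(res.summary())
```

```
Surface-based shape analysis
============================================================
subjects: 12 controls, 12 patients; comparison: by anatomical hemisphere; FDR q < 0.05

[left hemisphere]
  volume     ( t):  722/1002 significant ( 72.1%), min p = 8.19e-12
  curvature  ( t):    0/50 significant (  0.0%), min p = 3.28e-02
  position   (T2):   48/50 significant ( 96.0%), min p = 3.72e-06
  duration r: 0 significant vertices, peak r = -0.71

[right hemisphere]
  volume     ( t):    0/1002 significant (  0.0%), min p = 5.95e-03
  curvature  ( t):    0/50 significant (  0.0%), min p = 9.35e-03
  position   (T2):    0/50 significant (  0.0%), min p = 3.67e-02
  duration r: 0 significant vertices, peak r = -0.77

global volumetry (2-SD rule):
  atrophy-L                12
```

All 12 patients carry a 15% radial contraction band on the left: the left
volume map flags 72% of vertices (the injected band plus the real
through-thickness compression and edge flanks of the interpolated
deformation field), the right hemisphere — identical up to noise — flags
nothing, the 2-SD volumetry rule labels every patient `atrophy-L`, and the
left position map lights up because atrophy genuinely shifts the aligned
surface (the confound the Jacobian metric is designed to factor out —
compare the clean right-hemisphere maps). Curvature is silent, as it should
be for a pure volume effect.

The same analyses are scriptable from the shell:

```sh
hippomorph run --seed 7 --out results_dir     # simulate → align → maps → stats
hippomorph simulate --seed 7 --out cohort_dir # just the synthetic cohort
```

Surfaces travel as VTK legacy / PLY / GIFTI with per-vertex `theta`/`phi`
parameterization arrays and named overlays; volumes as NIfTI-1; cohorts as
CSV.

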