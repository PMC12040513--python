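# lesiondir

Directional analysis of white-matter lesions in multiple sclerosis: do
lesions orient, grow and repair along anatomically meaningful directions —
veins, white-matter tracts, and the "surface-in" gradient away from the
ventricular surface — or at random?

`lesiondir` is an analysis pipeline over co-registered 3D MRI volumes
(NIfTI): a labelled lesion mask, a ventricle mask, a voxelwise tract
direction field, a vein mask, MT-on/MT-off image pairs at two timepoints and
a baseline-to-follow-up displacement field. Because trial MRI of this kind
is not freely redistributable, the package ships a synthetic phantom
generator that emulates all of these inputs with exact ground truth, and the
whole pipeline is validated against it.

## The model

**Lesion shape.** Each lesion is summarized as an ellipsoid via the
eigen-decomposition of the second central moment matrix of its voxel centres
(world mm). Eigenvalues map to principal axis lengths
λᵢ = 2√(5 mᵢ) (solid-ellipsoid convention), with the major axis ε₁ the
principal eigenvector. Shape anisotropy uses the fractional-anisotropy form

FA = √½ · √((λ₁−λ₂)² + (λ₂−λ₃)² + (λ₃−λ₁)²) / √(λ₁²+λ₂²+λ₃²) ∈ [0, 1].

**Reference axes.** Per lesion: the surface-in gradient g (normalized
gradient of the Euclidean distance transform from the ventricles, averaged
component-wise over the lesion), the tract axis w (principal eigenvector of
the sign-free dyadic tensor Σᵢ uᵢuᵢᵀ of the tract field), the vein axis v
(principal moment axis of the vein voxels inside the lesion; undefined when
fewer than 3 intersect), and the orthogonal-to-vein axis v90 (projection of
ε₁ onto the plane ⟂ v).

**Orientation category.** A lesion is attributed to every feature whose axis
lies within 45° of ε₁ (axial angle, strict inequality), yielding 11 named
categories (G, GV, W, WV, V, GW, GWV, V90, GV90, WV90, GWV90) or NONE. Under
the null of a uniformly random axis, the chance of aligning with one fixed
axis is the spherical-cap fraction 1 − cos 45° ≈ 29 %; joint category
probabilities for a lesion's actual axis geometry are estimated by
Monte-Carlo sphere sampling.

**Longitudinal change.** Volume change is the Jacobian determinant
det(I + ∇u) of the displacement field; a lesion is expanding/contracting
when its mean determinant is ≥ 1 cohort SD above/below the cohort mean
(≈ 8 % volume change over 6 months in the motivating cohort). The major axis
of expansion is the principal eigenvector of the magnitude-weighted
orientation tensor of the (bulk-motion-corrected) lesion displacements, and
is classified against the same reference axes. Myelin change is tracked by
the magnetization transfer ratio, MTR = ((MToff − MTon)/MToff) × 100 pu,
averaged over the baseline lesion mask.

## Worked example

```
python analysis/01_simulate_cohort.py      # 20 patients x 15 lesions
python analysis/02_baseline_orientation.py
python analysis/03_longitudinal_dynamics.py
python analysis/04_cohort_summary.py
```

The drivers write per-lesion and cohort tables under `results/` and print,
for the default seed:

```
major-axis recovery: mean 1.16 deg, max 4.17 deg
category recovery: 100.0% overall
...
cohort Jacobian band: mean 1.0080, SD 0.0493 (cuts at 0.9587 / 1.0573)
  expanding: 12.0% of lesions
  stable: 82.7% of lesions
  contracting: 5.3% of lesions
dynamics recovery beyond the SD cut: 100.0% of 52 lesions
MTR change recovery: max abs error 0.0000 pu
...
MTR change by category and arm (pu):
category  n_active  mean_active  n_placebo  mean_placebo  arm_difference
      GV        19          0.6         20           0.0             0.6
```

Every generated lesion's ellipsoid axis is recovered to within a few degrees
of the injected ground truth; the orientation category is recovered for all
lesions; the ±1 SD Jacobian rule recovers every injected expansion (volume
ratio 1.12) and contraction (0.88); and the +0.6 pu MTR treatment effect
injected into active-arm GV lesions appears only in that row of the group
table — the pipeline does not smear effects across orientation categories.

Library use mirrors the scripts:

```python
from lesiondir import AnalysisConfig, summarize_lesion, classify_lesion
from lesiondir.pipeline import analyze_cohort
from lesiondir.synthetic import sample_cohort, build_phantom

bundles = [build_phantom(s) for s in sample_cohort(n_patients=4, seed=0)]
result = analyze_cohort(bundles, AnalysisConfig(angle_threshold_deg=45.0))
print(result.cohort_proportions)
```

## Layout

- `src/lesiondir/` — library: `io_core` (volumes, NIfTI, config),
  `shape` (ellipsoid fits, anisotropy), `direction_fields` (g/w/v/v90 axes),
  `orientation` (angles, 11-category taxonomy, chance model),
  `longitudinal` (MTR, Jacobians, expansion axes), `cohort` (per-patient
  aggregation and tests), `synthetic` (phantom generator), `pipeline`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — models, conventions, parameter choices, limitations.
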