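# Methods

This note records the models implemented in `lesiondir`, the conventions and
tunable parameters, what the synthetic phantoms do and do not emulate, and
the design choices made where the problem was genuinely open.

## Coordinate and axis conventions

All geometry is computed in world millimetres (RAS): voxel indices are
0-based and mapped through the 4×4 voxel-to-world affine before any moment,
angle or gradient is taken. This makes every direction and distance
independent of voxel anisotropy — the same world-space lesion sampled on a
1×1×1 mm and a 1×1×3 mm grid yields the same axes up to digitization error
(tested to 5°).

Directions fall into two classes. *Axes* (lesion major axis, tract
eigenvectors, vein axes, surface normals) are sign-free equivalence classes
{u, −u}; storage normalizes to the representative whose largest-magnitude
component is non-negative, and all angles between axes are folded into
[0°, 90°] via |a·b|. *Displacements* are signed world-mm vectors.
Consequently, averaging is signed (component-wise) only where a consistent
sign exists — the outward distance-transform gradient — and sign-free
(dyadic orientation tensor Σ uuᵀ, principal eigenvector) everywhere a
per-voxel sign is arbitrary: tract eigenvector maps and displacement
orientations. A component-wise mean of a sign-arbitrary field would be
ill-defined, which is why the two averaging rules coexist.

## Lesion shape

The second central moment matrix of a lesion's world voxel centres is
eigen-decomposed; moment eigenvalues mᵢ convert to full principal-axis
lengths λᵢ = 2√(5 mᵢ), the convention under which a solid uniform ellipsoid
with semi-axes (a,b,c) reports (2a,2b,2c) and a digitized ball of radius r
reports λ ≈ 2r. Anisotropy is the fractional-anisotropy functional applied
to (λ₁,λ₂,λ₃); since FA is invariant to a common scale factor, the choice of
axis-length convention does not affect it. Whether the FA formula should
consume axis lengths or raw moment eigenvalues (which differ by a square) is
ambiguous in the literature this analysis descends from; axis lengths are
the default and `AnalysisConfig.anisotropy_on = "moments"` switches to the
alternative.

Degenerate cases: a single-voxel lesion gets isotropic axes at voxel scale
and a `degenerate_single_voxel` flag; λ₁ within 1 % of λ₂ flags the major
axis `major_axis_ill_defined` (the lesion is still classified — the angle to
a near-degenerate axis is noise, and the flag lets downstream users filter).
Labels are taken as given: disconnected components under one label are kept
as one object, as confluent lesions should be.

Lesions below the minimum volume (default 3 mm³, a conventional minimum
lesion size in MS imaging) are excluded with a recorded reason. World
volume is voxel count × |det A₃ₓ₃|.

## Reference axes per lesion

- **Surface-in gradient (g).** The Euclidean distance transform from the
  ventricle mask is computed with world-mm sampling and differentiated
  (central differences, world frame). On the surface this gradient is the
  outward normal; unlike a tangent-plane construction it stays defined
  throughout the white matter, which is required for non-periventricular
  lesions. The exact distance field of a *digitized* surface carries facet
  structure, so the distance map is smoothed with a 1 mm Gaussian before
  differentiation; this leaves planar and far-field normals unchanged while
  reducing voxel-level normal error from ~4–5° mean to ~2°. Voxels inside
  the mask, and ridge voxels where the gradient norm collapses below 0.5,
  are undefined. The per-lesion axis is the signed component-wise mean,
  renormalized; a mean resultant norm below 0.2 (vectors nearly cancelling,
  e.g. a lesion straddling a distance-map ridge) marks the axis undefined
  with a dispersion flag.
- **Tract axis (w).** Principal eigenvector of Σ uᵢuᵢᵀ over the lesion's
  nonzero tract vectors. When the top two tensor eigenvalues differ by less
  than 20 % relative, the lesion gets a `crossing_fibre` flag — two fibre
  populations of similar weight make the "dominant" direction unstable.
- **Vein axis (v).** The vein mask voxels inside the lesion are pooled
  (all vein labels binarized) and their second-moment principal axis taken,
  the same estimator as the lesion ellipsoid. Fewer than 3 vein voxels
  cannot determine a line above noise, so the axis is undefined and the
  lesion is excluded from vein-dependent classification — mirroring the
  situation where a vein atlas misses small-calibre veins.
- **Orthogonal-to-vein (v90).** The projection of the lesion major axis onto
  the plane perpendicular to v, renormalized: the unique in-plane direction
  nearest ε₁, which makes "expansion orthogonal to the vein" measurable per
  lesion. If ε₁ ∥ v within 1° the projection is degenerate and a
  deterministic fallback v × e is used (e the canonical basis vector least
  aligned with v), flagged. An alternative "plane" rule — aligned with V90
  whenever the angle to v exceeds the threshold — is selectable via
  `AnalysisConfig.v90_mode`; at a 45° threshold the two coincide, below it
  they differ.

## Orientation classification and the chance model

A feature is in the aligned set iff its axis is defined and the axial angle
to the lesion axis is strictly below the threshold (default 45°, the
halfway point between parallel and perpendicular; 30° as sensitivity
setting). The aligned subset of {G, W, V, V90} maps to one of 11 canonical
categories or NONE. For orthonormal-ish v and v90, cos²θ_v + cos²θ_v90 ≤ 1
makes simultaneous V and V90 alignment impossible at thresholds ≤ 45°; for
larger thresholds the implementation keeps the closer axis.

A consequence of the projection construction worth stating explicitly: for
the *baseline* lesion axis, angle(ε₁, v90) = 90° − angle(ε₁, v), so at the
45° threshold V90-alignment of the lesion shape is exactly the complement of
V-alignment, and the exclusive categories G, W, GW and NONE can occur only
on the decision boundary. The construction is non-degenerate for the
*expansion* axis, which is an independent direction classified against the
same v90. Tightening the threshold only removes alignments, so the NONE
group can only grow from 45° to 30° (tested).

Chance model: an axis uniform on the sphere falls within t of a fixed axis
with probability 1 − cos t (the double-cone solid-angle fraction), 29.3 % at
45°. Joint probabilities over the 12 mutually exclusive categories, given a
lesion's actual inter-axis geometry, are Monte-Carlo estimates over
uniformly sampled axes (default n = 100,000, seeded; SE ≤ 0.5 %); they sum
to 1 by construction. Observed-vs-chance comparisons use the exact binomial
test of pooled lesion counts against the theoretical probability, with a
per-patient above/below summary; p-values are unadjusted by default, with a
Benjamini–Hochberg option.

## Longitudinal measures

MTR = ((MToff − MTon)/MToff) × 100 pu voxelwise; MToff ≤ 0 yields an
undefined voxel (counted, never an exception), and values outside
[−10, 100] pu are flagged but not clipped, preserving raw computation while
exposing acquisition artefacts. Per-lesion change is
mean(follow-up) − mean(baseline) over the baseline lesion mask.

Volume change is det(I + ∇u) of the world-mm displacement field on the
baseline grid — the Jacobian of the mapping x ↦ x + u(x), not of u itself —
with ∇u by central differences in world coordinates (one-sided at
boundaries), the standard tensor-based-morphometry estimator. A lesion is
expanding iff its mean determinant ≥ μ + kσ and contracting iff ≤ μ − kσ,
with μ, σ over all included lesions of the whole cohort pooled (not per
patient) and k = 1 by default; the pooled rule is the literal reading of the
cohort-SD criterion this analysis follows. At k = 0 the inclusive cuts both
hold at the exact mean, which stays "stable".

The expansion axis subtracts the lesion-mean displacement first (growth
direction should not be confounded by bulk motion or registration drift —
tested by translation invariance), then takes the principal eigenvector of
Σ ‖uᵢ‖ ûᵢûᵢᵀ. Whether the "major axis of expansion" should derive from
displacement vectors or from the strain tensor is an open modelling choice;
the displacement orientation tensor is the default and
`expansion_axis_mode = "strain"` uses the principal stretch of the
least-squares lesion-mean deformation gradient instead (the two agree on
linear stretch fields). Top-two eigenvalues within 10 % relative — e.g.
isotropic radial growth — mark the axis undefined, and such lesions drop
out of directional tallies.

## Synthetic phantoms

The generator builds world-space scenes with exact ground truth: a slab (or
spherical) ventricle, ellipsoidal lesions digitized by centre-of-voxel
inclusion (matching the moment convention), one vein tube (radius 0.6 mm)
through each lesion centre, a piecewise-uniform tract field, MT pairs
satisfying the MTR identity exactly before optional Gaussian noise, and
compactly supported analytic stretch fields that are linear (hence
closed-form Jacobian, equal to the injected volume ratio) on every lesion
voxel and taper to zero within the lesion's 30 mm lattice cell.

Intended orientation categories are realized by construction with ≥ 20° of
margin from the 45° boundary (shared-with-gradient categories tilt the axis
25° from the surface normal), then decorated with a random in-plane rotation
and a ≤ 3° rigid jitter; the generator recomputes the true category from the
realized axes analytically and refuses specs whose intent is not realized.
Only the eight categories realizable off the decision boundary under the
projection v90 (V, GV, WV, GWV, V90, GV90, WV90, GWV90) can be requested.

Default study conditions: 20 patients × 15 lesions at 1 mm isotropic,
noise-free; category mixture loosely following the observed cohort
distribution restricted to the realizable set (V .33, WV .31, GV .13,
GWV .11, V90 .04, GV90 .03, WV90 .03, GWV90 .02); dynamics mixture 13 %
expanding (volume ratio 1.12), 7 % contracting (0.88), 80 % stable; arms
alternate placebo/active with a +0.6 pu MTR-change effect confined to
active-arm GV lesions. Lesion semi-axes draw the major axis from
U(5.0, 6.5) mm with minor axes U(1.8, 2.5) mm, plus a 10 % low-anisotropy
tail at (6.0, 4.2, 3.9) mm (FA ≈ 0.24) so phantoms cover anisotropy on both
sides of 0.27; sizes are chosen so the major axis stays well determined at
1 mm digitization (≈ 1° mean, ≤ 4° max axis error).

What the phantoms do **not** emulate: MRI physics (bias fields, partial
volume beyond digitization, Rician noise), registration error, vein-atlas
miss rates, crossing-fibre tract fields within a lesion, irregular lesion
shapes, or spatially correlated lesion placement. Passing recovery tests
therefore demonstrates the *algorithmic* correctness of the estimators on
geometry satisfying the model's assumptions — not robustness to real
acquisition artefacts, where registration noise and segmentation error
dominate.

## Numerical choices and degenerate inputs

- Strict `<` at the angle threshold: exact-equality ties (measure-zero but
  reachable synthetically) fall to "not aligned".
- Percentages are rounded only at the reporting layer; all comparisons use
  unrounded values.
- Distance-map smoothing σ = 1 mm; gradient-norm ridge cut 0.5; mean-norm
  dispersion cut 0.2; crossing-fibre eigen-gap 20 %; expansion-axis
  degeneracy gap 10 %; minimum vein voxels 3. Each lives in
  `AnalysisConfig` or the relevant function signature.
- Zero-variance Jacobian cohorts classify everything stable with a warning;
  empty categories in group tables are flagged cells, not errors.
- Monte-Carlo and generator randomness flow from explicit integer seeds
  (`numpy.random.default_rng`); fixed seed ⇒ bit-identical phantoms.

## Known limitations

- The orthogonal-to-vein construction is underdetermined by the source
  description; both implemented variants are defensible and they disagree
  below the 45° threshold. Baseline-shape V90 results should be read with
  the complement property above in mind.
- Near-spherical lesions at small volumes carry intrinsically ill-determined
  major axes; at 1 mm resolution, axis errors of several degrees are
  unavoidable below roughly 100 voxels and the QC flags, not the estimates,
  are the reliable signal there.
- The per-voxel surface-in field is accurate to a few degrees near a curved
  digitized surface; only the lesion-averaged axis reaches ~1° accuracy.
- Expansion direction from two timepoints cannot distinguish growth from
  displacement of a boundary; slowly-evolving-lesion style analyses need
  three or more timepoints and are out of scope.
- Covariate-adjusted models (mixed-effects, logistic) on the emitted tables
  are deliberately out of scope; the pipeline produces the tidy per-lesion
  table such models consume.
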