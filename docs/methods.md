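# Methods

## Overview

`hippomorph` implements a contour-based morphometry pipeline for elongated
subcortical structures, with the hippocampus as the motivating case. The
input is the classical manual-segmentation product: per subject, an ordered
stack of closed planar contours traced on coronal slices, plus a covariate
table (group, age, total intracranial volume, optional clinical scores).
The pipeline computes (i) planimetric volumes, (ii) a corresponded
parametric surface per subject, (iii) a medial curve and a radial distance
map on that surface, and (iv) group statistics: TIV-adjusted volume
comparisons and vertex-wise shape inference with permutation-based
family-wise error control.

All stages assume contours arrive in a common, rigidly aligned space
(millimetres, parallel slice planes at `z = slice_index × thickness`).
Registration is upstream of this package and out of its scope.

## Volumetry

The volume of a contour stack is the planimetric estimate

    V = Σ_slices A_k × Δz,

where `A_k` is the shoelace area of the slice-k polygon and `Δz` the slice
thickness. Contours are stored open (no duplicated terminal vertex) and are
normalized to counter-clockwise orientation on read, because the tracing
direction of a human rater carries no information. Self-intersecting or
collinear contours are rejected at validation with the offending slice
named. Volume is exact for the stored polygon; there is no smoothing or
partial-volume model.

## Surface parameterization

Each slice contour is resampled to `C` points equally spaced in arc length
(default `C = 100`), and `L` longitudinal levels (default `L = 150`) are
generated by piecewise-linear interpolation between adjacent resampled
slices at uniform normalized slice positions, giving an `L × C` grid of
15,000 vertices with fixed correspondence across subjects.

Correspondence requires a circumferential origin and a consistent twist:

* point 0 of each resampled contour is the intersection of the boundary
  with the ray from the section centroid in the global +x direction (the
  nearest crossing; unique for star-shaped sections);
* each subsequent slice is then re-anchored by the integer cyclic shift
  minimizing the summed squared point-to-point distance to the previous
  slice (computed in O(C log C) via FFT correlation). This suppresses
  twist artifacts that a naive per-slice arc-length origin produces on
  non-circular sections.

Piecewise-linear longitudinal interpolation is the default because it is
reproducible and has a transparent error bound; at `L = 150, C = 100` the
radial reconstruction error on smooth analytic tubes is below 2% (checked
against the generating radius profile in the test suite). Nearly
degenerate terminal slices (area < 0.5 mm², a common byproduct of freehand
tracing of the tapering tail) are dropped with a warning, because
arc-length resampling of near-collinear rings is numerically unstable.

## Medial curve and radial distance

The medial curve is the per-level arithmetic centroid of the C resampled
points. Because the points are equally spaced in arc length this is a
perimeter-weighted center: deterministic, exact for symmetric sections,
and free of the branch ambiguities of a true medial-axis (Blum) skeleton,
which is deliberately not attempted. The radial map is

    R[l, c] = ‖ grid[l, c] − medial[l] ‖,

the Euclidean distance from a level's medial point to each of its surface
vertices. Distance-to-centroid is used instead of ray casting because it
is identical for star-shaped sections and avoids multiple-intersection
ambiguity on non-convex ones. `R` is the dependent variable of all
vertex-wise statistics. A cohort template surface (vertex-wise mean grid)
is produced for visualisation overlays.

## Volume statistics

Head-size correction uses the covariance method: the slope α of volume on
TIV is estimated by OLS in controls only, and every subject's volume is
shifted to the control mean TIV,

    HV_adj = HV − α (TIV − mean_TIV_controls).

Two algebraic identities follow and are enforced by tests: a subject at
the control mean TIV is unchanged, and the adjusted control volumes have
exactly zero TIV slope (and an unchanged control mean). Adjusted volumes
are compared between groups with a fixed-effects linear model
`HV_adj ~ group + age` (partial F for the group term, via statsmodels);
significance for per-hemisphere volume tests is flagged at the
Bonferroni-adjusted α = 0.025 (two hemispheres). Clinical associations
use Spearman rank correlations with pairwise deletion of missing scores.

## Vertex-wise inference

At every grid vertex an independent OLS fit of radial distance on
[intercept, group, age, TIV] is computed (patients coded 1), with the
group-contrast t statistic and two-sided p from the t distribution on
`n − rank` degrees of freedom. Negative t means the patient surface lies
inward of the control surface. Perfect fits (zero residual variance at
machine precision) are assigned a capped |t| = 1e6 when the effect itself
is above rounding level, and t = 0 otherwise.

Cluster inference: the t map is thresholded two-sided at a vertex-level
cluster-forming p (default 0.05), separately for the inward and outward
signs. Connected components are found by flood fill under 4-neighbor
connectivity with circumferential wrap (column 0 adjacent to column C−1 —
the grid is a tube; no wrap across levels; 8-connectivity is available).
Family-wise error control compares each observed cluster's vertex count
with the permutation distribution of the *maximum* cluster size over both
signs. Corrected p-values use the add-one estimator
`(1 + #{null ≥ size}) / (n_perm + 1)`, so p = 0 is impossible and the
corrected p is monotone in observed size by construction.

Because age and TIV are in the model, plain label permutation is not
exact; the default scheme is Freedman–Lane: residuals of the reduced
(covariates-only) model are row-permuted, the reduced fit is added back,
and the full model is refit on the reconstructed responses. Plain
group-label permutation is available for transparency, and when it admits
fewer distinct relabelings than requested the test enumerates them
exhaustively with a warning. A seed is mandatory; results are
bit-reproducible.

Cluster extent is counted in vertices (not mm²): the statistic of record
is an integer cluster size, which is also what the permutation null is
built from.

TFCE (threshold-free cluster enhancement) is provided as an alternative
enhancer on the same grid connectivity: per vertex, the discrete sum over
thresholds `h = dh, 2dh, …` of `extent(h)^E · h^H · dh` with defaults
E = 0.5, H = 2, dh = max|t|/100 (the standard parameterization); negative
values are enhanced on the negated map and returned signed. The discrete
right-sum converges from above as dh → 0 and scales as `s^(H+1)` when the
map is scaled by `s` together with dh — both properties are tested.

Region-of-interest analyses split the longitudinal axis into head (anterior),
body and tail bands — equal thirds by default, configurable — and re-run the
permutation test restricted to each band, with the max-cluster null computed
within the band. Anatomical head/body/tail boundaries are not standardized;
equal thirds is an explicit convention, not an anatomical claim.

## Synthetic cohorts

The generator produces two-group cohorts with fully known ground truth:

* **Template**: a tube around a gently curved medial arc (~40 mm long,
  lateral bend 6 mm), radius profile `ρ(t, θ)` = body radius 2.6 mm +
  sinusoidal taper amplitude 1.2 mm + Gaussian anterior head bulge
  (amplitude 2.4 mm at t = 0.17, width 0.13), giving radii within
  roughly 2.6–6 mm and a template volume near 2,000 mm³, traced as 40
  slices of 120 boundary points at 1 mm spacing. Cross-sections are
  circular by default so that the analysis grid's arc-length
  parameterization coincides exactly with the generative angle
  parameterization; an elliptical `eccentricity` option deliberately
  breaks that coincidence for robustness studies.
* **Subjects**: a per-subject log-normal scale (sd 0.05 on the log scale)
  applied as a *similarity transform* — radii, medial arc and slice
  spacing all scale together — so the noiseless volume is exactly scale³
  times the template volume, consistent with the TIV model
  `TIV = κ · scale³ · (1 + ε)`, κ = 1.5 × 10⁶ mm³, ε ~ N(0, 0.03).
  White Gaussian radial noise (default σ = 0.3 mm) perturbs every traced
  boundary point independently; radial perturbation of a star-shaped
  section cannot self-intersect, so every generated stack is valid. An
  optional circular Gaussian smoothing of the noise field produces
  spatially correlated tracing error for studies of how correlation
  inflates cluster-size nulls.
* **Deformation**: patients receive a localized inward deformation — the
  radius is multiplied by (1 − δ), default δ = 0.15, inside a patch
  defined in normalized grid coordinates (default: anterior head levels
  4–30% of the axis, 15–55% of the circumference), so the ground-truth
  mask aligns exactly with the analysis grid and correspondence error is
  excluded from recovery tests by construction.
* **Covariates**: patient/control ages N(62.8, 13.0²) / N(61.8, 5.9²)
  years, a clinical disability score N(37.8, 5.4²) clipped to [0, 48] and
  a log-normal disease duration (median ≈ 15 months) in patients only —
  a demographically plausible two-group design of 30 + 30 by default.
* **Seeding**: one seed, split by `numpy.random.SeedSequence.spawn`
  (stream 0 → covariates, stream i+1 → subject i's noise), so cohorts are
  byte-reproducible and any subject can be regenerated in isolation.

What the generator does **not** emulate: true hippocampal anatomy
(digitations, subfield boundaries, C-shaped infolding), rater bias and
slice-to-slice tracing correlation, segmentation error models, or
imaging artifacts. Passing recovery tests therefore demonstrates that the
*pipeline* is correct and calibrated on tube-like geometry with white
tracing noise — not that any specific anatomical effect in real data
would be detected with the same power.

## Numerical choices

* Cluster-forming threshold defaults to two-sided p < 0.05; it is a
  configuration knob, and sensitivity to it is the user's to explore.
* The permutation null loop computes t in single precision (the statistic
  only enters a threshold comparison; the loop is memory-bandwidth bound);
  observed maps, p-values and all reported statistics are double
  precision.
* Degenerate (zero-residual) vertex fits are detected relative to the data
  scale and the floating-point epsilon of the working dtype.
* Ties in null max-cluster sizes make the corrected p conservative at the
  margin, as for any discrete permutation statistic.
* Resampling a contour is idempotent to 1e-6 mm; surfaces, medial curves
  and radial maps are translation-equivariant to 1e-9 mm (tested).

## Problem sizes used in the checked studies

The test suite runs the type-I calibration at 500 replicate null cohorts
(30 + 30 subjects, σ = 0.3 mm) × 500 permutations on a reduced 50 × 40
grid, and the deformation-recovery study at 50 replicate cohorts
(δ = 0.15) × 500 permutations on the same grid. The acceptance script
repeats the same studies at 200 null and 50 recovery replicates. The
reduced grid keeps the full studies at desk scale; the per-vertex model
and the cluster machinery are identical at 150 × 100.

## Known limitations

* The medial curve is a centroid curve, not a true medial axis; for
  strongly bent or non-star-shaped sections the radial map conflates
  bending with thickness change.
* Slicing is perpendicular to a fixed axis; strongly curved structures
  would need oblique reslicing upstream.
* Vertex-count cluster extent ignores vertex area differences; on strongly
  tapered surfaces mm²-based extent would weight the head and tail
  differently.
* The permutation test assumes exchangeability of reduced-model residuals
  across subjects (Freedman–Lane); heteroscedastic groups are not
  specially handled.
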