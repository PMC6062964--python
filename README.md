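# hippomorph

Contour-based shape morphometry for elongated subcortical structures —
built around manual hippocampus tracings. Given per-subject stacks of
closed planar contours (coronal tracings in a rigidly aligned space) and a
covariate table, the package computes planimetric volumes, corresponded
parametric surfaces with medial-curve radial-distance maps, TIV-adjusted
volume statistics, and vertex-wise group inference with permutation-based
cluster correction. A synthetic cohort generator with known ground truth
makes every stage testable without MRI data.

## The method

**Volumetry.** For a stack of traced contours, volume is the planimetric
sum `V = Σ_k A_k · Δz` (shoelace area per slice × slice thickness).

**Shape.** Each contour is resampled to C points uniform in arc length and
the stack is interpolated onto an L × C parametric grid (default
150 × 100 = 15,000 vertices) with fixed vertex correspondence across
subjects. A medial curve `m_l` (per-level centroid) runs along the
anterior–posterior axis, and the radial distance map

    R[l, c] = ‖ x[l, c] − m_l ‖   (mm)

is the dependent variable of shape inference.

**Statistics.** Volumes are head-size corrected by the covariance method,
`HV_adj = HV − α (TIV − mean TIV of controls)` with α the control-only
regression slope, then compared with `HV_adj ~ group + age` (Bonferroni
α = 0.025 for two hemispheres); clinical scores use Spearman correlations.
At each vertex an OLS of R on [1, group, age, TIV] yields a group-contrast
t map (negative t = patient surface inward). Supra-threshold clusters
(two-sided vertex p < 0.05, flood fill with circumferential wrap) are
tested against the permutation null of the maximum cluster size
(Freedman–Lane residual permutation, add-one corrected p), whole-surface
and within head/body/tail ROI bands. TFCE is available as a
threshold-free enhancer on the same grid.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a 30 + 30 cohort with a 15% inward deformation of the anterior
(head) surface in patients, extract volumes and radial maps on a 50 × 40
grid, and run the statistics stage:

```sh
hippomorph simulate --out cohort --seed 17 --n-patients 30 --n-controls 30
hippomorph extract  --cohort cohort --out extracted -L 50 -C 40
hippomorph stats    --extract extracted --covariates cohort/covariates.csv \
                    --out stats --seed 17 --n-perm 1000
hippomorph report   --stats stats --out report
```

which prints

```
wrote 60 contour stacks to cohort
extracted 60 subjects (0 failed) into extracted
stats complete: 159 clusters, 4 significant at corrected p <= 0.05
report written to report
```

`stats/volume_tests.csv` shows the volume analysis: the control TIV slope
α = 0.00126 mm³/mm³, and a group deficit in adjusted volume of
−79.7 mm³ (F = 27.0, p = 2.8e-06 — significant at the 0.025 level), the
expected global footprint of the simulated 15% head deformation.
`stats/clusters.csv` begins

```
cluster_id,size,corrected_p,roi,sign
1,215,0.000999000999000999,whole,inward
2,158,0.000999000999000999,whole,inward
3,3,0.955044955044955,whole,outward
```

two large *inward* clusters at the minimum attainable corrected p
(1/(n_perm+1) ≈ 0.001) over the deformed head patch, and nothing but
noise-sized clusters elsewhere. The per-ROI rows of the same table show
the effect is confined to the head band. `report/report.md` renders the
flat t map and cluster outlines.

The clinical correlations (`stats/spearman.csv`) are null by construction
— simulated disability scores are independent of the deformation — e.g.
ALSFRS-R: rho = 0.24, p = 0.21.

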