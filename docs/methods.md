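# Methods

This note documents the models, numerical choices and limitations of the
`lungwater` package: what the synthetic cohort and digital-thorax phantom
emulate, how each processing stage works, and which design decisions were
genuinely open.

## Synthetic cohort

Two groups are simulated — healthy controls and patients at risk of heart
failure — with marginal distributions matched to published baseline
summaries. Variables reported as median [IQR] (age, BMI, lung volume,
atrial and ventricular sizes, LV mass, native T1, ECV) are drawn lognormal
with log-moments solved from the printed quartiles
(σ = ln(q3/q1) / (2·0.6745)); variables reported as mean ± SD (LWD, GLS,
systolic BP) are Gaussian, with LWD clipped to (1, 99) % as a physical
range. Binary comorbidities use group-specific prevalences; the at-risk
native T1 / ECV distributions are reused for controls, whose values are
not separately reported.

Associations are built from latent standard normals:

- **LWD–BMI**: within each group, `lwd = μ + β(bmi − E[bmi]) + ε` with
  β = r·σ_lwd/σ_bmi and var(ε) = σ_lwd²(1 − r²), so the group mean/SD are
  preserved exactly and the within-group correlation equals the target
  r = √0.323 ≈ 0.568 (univariable R² 0.323).
- **Lung volume**: log-volume loads −√0.09 on the BMI latent (reduced
  functional residual capacity in obesity), +0.40 on standardized height,
  with the remainder independent.
- **Cardiac size variables** (LV mass, ventricular volumes, atrial size)
  share a 0.40 loading on the height latent, making lung water volume
  (emergent as LWD × volume / 100) track body size and male sex.
- Height marginals are not published; M ~ N(1.71, 0.06) m and
  F ~ N(1.60, 0.06) m are used as plausible adult values. Weight follows
  from BMI·height², BSA from the Du Bois formula
  (0.007184·h_cm^0.725·w_kg^0.425), the standard convention for CMR
  indexing. Global LV wall thickness is the closed form
  0.05 + 1.60·LVM^0.84·LVEDV^(−0.49) mm.

A single integer seed makes the cohort byte-reproducible.

## Digital-thorax phantom

Anatomy is procedural (ellipsoids and tubes), not atlas-based, so it is
desk-scale, fully seeded and download-free. The torso is an elliptical
muscle cylinder with a subcutaneous fat shell whose thickness grows with
BMI (4–40 mm); inside sit two lung ellipsoids cut below by a flat
diaphragm plane, a heart scaled with LVEDV, a liver under the right
diaphragm, a spine rod, and two pairs of conduit vessels entering each
lung. The diaphragm plane rises 0.6 mm per BMI unit (reduced FRC in
obesity). The lateral lung semi-axes are solved by bisection so the lung
label volume at end-expiration equals the subject's ground-truth volume on
the actual voxel grid (within about a voxel); when a large target volume
cannot fit a small rib cage, the chest is widened stepwise (big lungs go
with big chests) before failing with a geometry error.

Water density is 100 % in every solid tissue (the composite reference),
the subject's LWD in lung parenchyma, 0 in air. Airways (trachea/bronchi)
are not rendered; the segmentation's optional minimum-density floor flag
therefore has no effect on phantoms but is available for real data.

**Coil shading** is a strictly positive multiplicative field: seeded white
noise low-passed at a 60 mm correlation length plus an anterior–posterior
linear trend, rescaled to [0.6, 1.4]. **Noise** is additive Gaussian at
2 % of the solid-tissue signal; a Rician model is deliberately omitted at
these signal levels. **Respiratory motion** is simulated in image space:
the navigator displacement d(t) = A(1+cos(2πt/T+φ))/2 is an
arbitrary-unit diaphragm surrogate (larger = more expired); each of the 7
repeats over 84 s is a snapshot of the anatomy at the mean displacement
over that repeat's navigator burst (1.5 s of samples every 108 ms at the
window centre), with the diaphragm (and liver) dropped by A − d. Breathing
period is drawn per subject in 5 ± 0.8 s. There is no k-space model: the
analysis consumes reconstructed volumes, so navigator physics is out of
scope.

What the phantom does **not** emulate: partial-volume mixing at tissue
boundaries (labels are pure), T1/T2* contrast, coil-array geometry,
deformable motion, airway trees, and intra-repeat motion blur. Passing
tests therefore demonstrate correctness of the processing chain under the
stated image model, not clinical performance on patient data.

## Processing chain

**Gating.** One phase decision per complete acquisition: a repeat's phase
is its mean navigator displacement. Repeats at or beyond the
(1 − frc_fraction) quantile of all samples are averaged; default
frc_fraction 0.3 (the gating window of the original reconstruction is not
published). With no qualifying repeat the single most-expired repeat is
used. Polarity is a documented flag.

**Normalization.** The body is thresholded at 25 % of the 99th intensity
percentile, closed (6 mm) and hole-filled. Solid tissue is identified by
comparing each voxel against a 25 mm Gaussian-smoothed local body signal
(threshold 0.75), which makes the decision shading-invariant. The mask is
eroded by 5 mm to suppress partial-volume edges, but edge voxels whose
intensity is within 90 % of the local solid reference are reinstated —
only genuinely depressed boundary voxels stay excluded. The normalization
map is fit by masked smoothing-by-diffusion: 40 iterations of "keep masked
values, in-paint the rest with the previous estimate, Gaussian low-pass at
σ = quarter wavelength of the 1/(60 mm) cutoff". This interpolates the
solid signal smoothly through lungs and air. Division by the map yields
percent LWD with the solid reference at 100 %; values are clipped to
[0, 120] % by default (noise can produce nonphysical values; the flag can
be disabled). The fit family and cutoff of the original implementation are
unpublished, so this stage is validated by its shading-invariance
property (≤ 2 percentage points LWD change under a [0.6, 1.4] band-limited
field) rather than by equivalence to any reference code.

**Segmentation.** Seeds are the two largest low-intensity 6-connected
components inside the body; growth to voxels < 70 % LWD equals taking the
seeds' connected components. Defaults (grow 70 %, vessel exclusion 85 %)
are chosen so healthy (~25 %) and congested (~40 %) parenchyma are
included while blood (~100 %) is excluded; the original thresholds are
unpublished and both are exposed as flags. One-voxel holes are closed,
voxels ≥ 85 % removed as conduit vessels, components < 10 mL discarded.

**Metrics.** LWD is the plain mean over the mask; LWV sums voxel density ×
voxel volume, so LWV = LWD/100 × lung volume holds exactly; LWVi divides
by BSA. Reports round LWD to one decimal and volumes to whole mL; full
precision is kept internally.

## Statistics

Group comparisons gate on Shapiro–Wilk at α = 0.05 per group (n = 2 groups
go to the non-parametric branch, since Shapiro–Wilk needs n ≥ 3);
categorical tables use Pearson χ² without continuity correction.
Correlation defaults to the Pearson product-moment coefficient with a
Spearman flag. Stepwise regression: candidates are covariates with
univariable p < 0.05; collinear pairs (|r| ≥ 0.7) are resolved before
entry by keeping the smaller univariable p (exclusions logged with their
partner); forward steps add the best candidate with p < 0.05 and a
backward pass removes members with p ≥ 0.10. Ties in entry order follow
column order. ROC analysis is empirical over all observed thresholds with
trapezoidal AUC and a DeLong 95 % CI (the CI method of the original
analysis is not named); the Youden cut-off breaks ties toward higher
specificity (a documented flag flips this). Predictive values are computed
from sensitivity/specificity and prevalence by Bayes' rule (the formula
path reproduces the published NPV; an empirical 2×2 path is available via
the cut-off helper). No multiple-testing correction is applied, and no
survival analysis is attempted.

## Problem sizes and numerics

The package default grid is 2.5 mm isotropic, matching the interpolated
resolution of the emulated acquisition; the test-suite and the acceptance
script run at 5 mm, where one phantom subject processes in about a second
and a 170-subject cohort in a few minutes. Spacing is a parameter
everywhere, and tolerances on volume checks are stated in voxel layers.
The acceptance script simulates 60 subjects per group — enough that the
Monte-Carlo standard error of a group LWD mean is ~0.6 percentage points.
Bisection for the lung size runs 40 iterations (volume is a step function
of scale, resolved to well under a voxel layer). Map fitting uses 40
diffusion iterations, sufficient to fill a lung-sized cavity at the
default cutoff.

## Known limitations

- Ground truth is phantom-based; no claim is made about agreement with any
  clinical reconstruction or vendor pipeline.
- The gated volume averages repeats within the end-expiration bin; when
  those repeats sit at slightly different diaphragm positions, mixed
  boundary voxels can bias lung volume upward by up to a few tens of mL
  (well inside the reported tolerances at the default amplitude).
- LWV inherits variance from both LWD and lung volume; the synthetic
  cohort's LWV spread is wider than a real cohort's, where water content
  and lung inflation are physiologically co-regulated.
- Absolute water density (g/mL) is out of scope: all values are relative
  to the composite multi-tissue reference defined as 100 %.
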