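# lungwater

Quantification of **lung water density (LWD)** from cardiovascular-MR
proton-density-weighted volumes, with a fully synthetic digital-thorax
cohort for validation, and the cohort-level diagnostic statistics used to
evaluate LWD as a marker of pulmonary congestion in patients at risk of
heart failure.

Pulmonary oedema — extravascular fluid accumulating in the lung parenchyma —
is a hallmark of heart failure, yet routine non-invasive quantification is
lacking. Free-breathing, short-echo 3D gradient-echo CMR produces images
whose contrast is primarily water density; after correcting surface-coil
shading against the surrounding solid tissues, the mean parenchymal
intensity becomes a relative water-density map. This package implements
that processing chain end to end and, because no patient data are public,
validates it against a seeded, procedural thorax phantom whose cohort
statistics are calibrated to published group summaries.

## The method

For each subject the acquisition is repeated over tidal breathing with a
respiratory navigator. The pipeline:

1. **Respiratory gating** — repeats whose mean navigator displacement lies
   in the end-expiration bin are averaged into one volume at functional
   residual capacity (FRC, minimum lung volume).
2. **Signal normalization** — all solid tissues surrounding the lungs are
   fit with a low-spatial-frequency normalization map, interpolated across
   the full field of view, and the volume is divided by the map. The
   composite solid-tissue reference is assigned 100 %, so lung voxels read
   directly in relative LWD (%).
3. **Lung segmentation** — region growing from the two largest
   low-intensity components inside the body, excluding conduit vessels
   (voxels ≥ 85 % LWD).
4. **Metrics** — with lung mask M, voxel volume v and BSA the body surface
   area:

   - LWD = mean over M of the normalized intensity (%)
   - lung volume = |M| · v (mL)
   - LWV = Σ_M (LWD_voxel / 100) · v (mL), so LWV = LWD/100 × lung volume
   - LWVi = LWV / BSA (mL/m²)

5. **Cohort statistics** — Shapiro–Wilk-gated t / Mann–Whitney group
   comparisons, χ² for categorical variables, univariable and
   forward-stepwise multivariable linear regression with collinearity
   screening (|r| ≥ 0.7), empirical ROC with Youden's index (DeLong 95 % CI)
   and prevalence-based diagnostic performance:
   LR+ = sens/(1−spec), inverse LR− = spec/(1−sens), PPV/NPV by Bayes' rule.

The synthetic cohort draws two groups (healthy controls and at-risk
patients) with LWD 27.2 ± 4.3 % vs 30.4 ± 5.0 %, lung volume, BMI, BSA and
cardiac covariates matched to the published summary table, an LWD–BMI
coupling with univariable R² ≈ 0.32, and an inverse lung-volume–BMI
coupling (R² ≈ 0.09). Each subject is rendered as a 3D phantom with
multiplicative coil shading, tidal diaphragm motion across seven repeats,
a navigator trace, and Gaussian noise.

## Worked example

```python
import lungwater as lw
from lungwater.pipeline import quantify_subject

params = lw.CohortParams.default(seed=1)
subject = lw.sample_cohort(params, 1, 0)[0]
result = quantify_subject(subject, lw.GridSpec(spacing=5.0), seed=1)
print(f"true LWD {subject.true_lwd:.1f}%  estimated {result.lwd:.1f}%")
print(f"lung volume {result.lung_volume:.0f} mL  LWV {result.lwv:.0f} mL  "
      f"LWVi {result.lwvi:.0f} mL/m2")
```

prints

```
true LWD 23.1%  estimated 23.1%
lung volume 2523 mL  LWV 583 mL  LWVi 311 mL/m2
```

i.e. the full gate → normalize → segment → quantify chain recovers this
subject's ground-truth parenchymal density to within a tenth of a
percentage point, and the water volume follows as density × volume.

The same flow is available from the shell:

```bash
lungwater simulate --n-control 2 --n-risk 2 --spacing 5 --out sim/
lungwater quantify --in sim/ --out results.csv
lungwater analyze --results results.csv --cohort sim/cohort.csv --out report/
```

`analyze` emits group-comparison, regression and ROC tables plus a JSON
report; `--cutoff` recomputes diagnostic performance at a chosen LWD
threshold instead of the Youden optimum.

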