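# pvgrad — periventricular T1-gradient analysis

In multiple sclerosis, tissue damage in the white matter is not spatially
uniform: quantitative MRI metrics are most abnormal next to the lateral
ventricles and improve gradually with distance — the *periventricular
gradient*. `pvgrad` implements this analysis for quantitative T1 relaxometry
(e.g. MP2RAGE T1 maps), for researchers who want single-subject,
atlas-referenced abnormality maps rather than group comparisons of raw T1:

1. **Normative atlas.** On a healthy-control cohort co-registered to a common
   template grid, fit per voxel r an ordinary least-squares model

   E[T1](r) = β₀(r) + β_sex(r)·sex + β_age(r)·age_c + β_age2(r)·age_c²

   with sex coded male = 1 / female = 0, age centred at the healthy-cohort
   mean, and the per-voxel residual RMSE stored alongside the coefficients.
2. **Z-score maps.** For one subject, z(r) = (T1(r) − E[T1](r)) / RMSE(r).
   Prolonged T1 (demyelination, axonal loss, oedema) gives positive z.
3. **Periventricular bands.** Average the healthy cohort's ventricle masks,
   threshold at p ≥ 50%, assign each supratentorial-WM voxel its Euclidean
   distance (mm) to the nearest ventricle voxel, round to the nearest
   integer, and keep bands 1–30; the first band is excluded from metrics to
   limit partial-volume effects, as are infratentorial regions.
4. **Band metrics and gradients.** Per band, compartment (NAWM = WM minus
   the cube-dilated lesion mask; lesions) and threshold τ ∈ {0,1,2,3}:
   mean |z| above τ, suprathreshold volume (normalized by band volume), and
   lesion volume.  Gradients between band pairs (1–2, 1–5, 1–10, 1–20,
   1–30) are the inner-minus-outer metric difference divided by the band
   distance in mm.
5. **Disability association.** Spearman correlation of every gradient (and
   conventional lesion count/volume) with EDSS, and two-sided Wilcoxon
   rank-sum comparisons between early and progressive patients.  Exact
   small-sample null distributions are enumerated; large samples use
   tie-corrected asymptotics.

Because the method's inputs (coregistered T1 maps, tissue and lesion masks)
come from clinical data that cannot ship with the code, the package includes
a first-class synthetic cohort generator: a nested-ellipsoid 3D phantom with
the same statistical structure the analysis assumes — voxel-wise linear
age/sex T1 dependence, Gaussian residual noise, a patient abnormality field
decaying exponentially with ventricle distance, distance-decaying lesion
rates, and EDSS coupled monotonically to the injected gradient severity.
All parameter-recovery and calibration tests run against this generator's
known ground truth.

## Worked example

```python
import pandas as pd
from pvgrad.pipeline import PipelineConfig, run_full_pipeline

config = PipelineConfig(
    grid_shape=(48, 48, 48), voxel_size_mm=(2.0, 2.0, 2.0),
    n_hc=20, n_early=8, n_progressive=10, seed=1, write_volumes=False,
)
out = run_full_pipeline(config, "demo")

assoc = pd.read_csv(out / "associations_progressiveMS.csv")
nawm = assoc[(assoc.compartment == "NAWM")
             & (assoc.metric == "mean_abs_z") & (assoc.tau == 2.0)]
print(nawm[["pair", "rho", "p_value"]].round(3).to_string(index=False))
print(assoc[assoc.compartment == "conventional"]
      [["metric", "rho", "p_value"]].round(3).to_string(index=False))
```

prints

```
pair   rho  p_value
 1-2 0.704    0.027
 1-5 0.587    0.079
1-10 0.636    0.053
1-20 0.790    0.009
1-30 0.722    0.022
           metric   rho  p_value
     lesion_count 0.606    0.067
lesion_volume_mm3 0.536    0.113
```

Each row is the Spearman correlation (with exact permutation p-value at
this sample size) between EDSS and the NAWM mean-|z| gradient for one band
pair at τ = 2, in the simulated progressive cohort: disability tracks the
steepness of the periventricular abnormality decline.  The two
"conventional" rows are the lesion count and lesion volume correlations.
The same library surface is scriptable from the shell:

```bash
pvgrad run --simulate --seed 1 --out demo/        # full pipeline
pvgrad simulate / fit-atlas / zscore / bands / metrics / gradients / correlate
```

`demo/` then contains the atlas (NIfTI coefficient maps + JSON metadata),
the band label map, per-patient z-maps, and long-format CSVs for metrics,
gradients, associations and group comparisons, plus a manifest with the
config hash and seed; re-running the same config reproduces every CSV
byte-identically.

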