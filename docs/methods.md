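# Methods

## The normative model and z-scores

The healthy reference is a voxel-wise ordinary least-squares fit of T1 (ms)
on `[1, sex, age_c, age_c²]`, with sex ∈ {0 female, 1 male} and `age_c` the
age minus the healthy-cohort mean age (stored in the atlas and always
reapplied at prediction time, so an atlas fitted at one centring constant
never silently re-centres).  The per-voxel residual RMSE uses the residual
degrees of freedom n − 4 by default (unbiased residual variance); a
denominator of n is available via `rmse_dof="n"` for compatibility with
implementations that use the biased form.  The model is fit only inside a
brain fit mask; outside it, coefficient maps carry NaN and all downstream
consumers treat NaN as missing.  No spatial smoothing or robust regression
is applied — deviations from a raw per-voxel OLS are out of scope.

A subject's z-map is `(T1 − E[T1]) / RMSE` evaluated at the subject's age
and sex.  The denominator is the raw model RMSE, not a prediction-interval
width; the 95%-confidence interpretation enters downstream as the |z| >
1.96 threshold.  Consequences worth knowing:

* For held-out healthy subjects the pooled z standard deviation is slightly
  above 1 (prediction variance; bounded by √(1 + 5/n) for the 4-parameter
  model).  At n = 92 the pooled fraction |z| > 1.96 is ≈ 0.055–0.06 rather
  than 0.05; the calibration tests assert the [0.04, 0.07] window for this
  reason.
* Voxels with RMSE = 0 (degenerate constant training data) are flagged
  missing, never ±∞; their count is logged.

## Distance bands

The consensus ventricle mask includes a voxel when its across-subject
frequency is ≥ 50% — the threshold is inclusive because the band adjacent
to the ventricles is defined by proximity, and a strict threshold would
drop exact-tie voxels arbitrarily.  Distances are centre-to-centre voxel
Euclidean distances (scipy's exact EDT, anisotropic voxel sizes honoured),
rounded to the nearest integer mm with ties going away from zero: banker's
rounding would assign 1.5 mm to band 2 or band 1 depending on parity, which
is incoherent for a monotone distance binning.  Both the tie rule and the
strictness are configurable.  Bands run 1–30; band 1 is excluded from
metric computation (partial-volume contamination at the ventricle wall) but
retained in the label map for visualization, and infratentorial tissue
never enters the analysis.

### Band-pair numbering

Published band-pair gradients are indexed "1–2 … 1–30" even though band 1
is excluded, which leaves two readings.  The default mode `retained` treats
the reported index k as the k-th retained band (reported 1 → the 2-mm bin),
capping at the outermost band since a 31-mm bin does not exist; mode
`literal` uses the printed mm bins, including bin 1.  Both are implemented;
neither is asserted as the original analysis's convention.

## Band metrics and gradients

Per (band, compartment, τ): the count and mean of |z| over compartment
voxels with |z| > τ, the suprathreshold volume normalized by the band's
total supratentorial-WM voxel count (so NAWM and lesion fractions of one
band are commensurable and sum ≤ 1), the unnormalized suprathreshold volume
in mm³, the total lesion volume in the band, and the signed mean z over all
valid compartment voxels.  When no voxel exceeds τ the mean is recorded as
0 with the count kept at 0, so cohort code can decide between "0" and
"missing" without subjects silently disappearing.  Lesion metrics use the
undilated lesion mask; dilation (3×3×3 cube) exists only to carve NAWM out
of WM.  Thresholded metrics default to |z| (damage prolongs T1, but edge
voxels can go negative); a signed z > τ option exists.

The signed `mean_z` column exists because it is the unbiased estimator of
an injected abnormality profile: E|N(μ,1)| ≠ μ at small μ, so decay
constants fitted to mean-|z| profiles would be biased at low signal.
Recovery experiments fit log(mean_z) against band index.

Gradients are (inner − outer)/(outer − inner) in metric units per mm, so a
periventricular-dominant abnormality is positive.  Missing band metrics
propagate to NaN gradients with a log message, never an exception.

## Rank statistics

Spearman's ρ is the Pearson correlation of mid-ranks.  For n ≤ 10 the
two-sided p is exact, by enumeration of all n! permutations conditional on
the observed tie pattern (the sorted null distribution is cached on the
rank multisets, so a battery of many metrics against one EDSS vector pays
the enumeration once); above that, the usual t-approximation.  The
rank-sum test enumerates all C(N, n_a) group assignments for combined
N ≤ 12 and otherwise uses the tie-corrected normal approximation without
continuity correction.  EDSS is ordinal in 0.5 steps, so ties are the rule:
mid-ranks and tie-corrected variances are mandatory, not optional.
Association batteries report unadjusted p-values (matching the exploratory
design); a Benjamini–Hochberg column is available behind a flag and is an
extension, not part of the reference analysis.  Demographics omnibus
testing (ANOVA/Kruskal–Wallis with post hocs) is deliberately not part of
the package surface.

## The synthetic cohort generator

The generator defines the conditions under which the pipeline is validated.
Anatomy is a nested-ellipsoid phantom: head ellipsoid, thin GM rim, WM
interior, two lateral-ventricle ellipsoids near the centre, a disjoint
inferior blob labelled infratentorial with a small fourth-ventricle
component inside it.  Ellipsoids make the realizability of all 30 one-mm
bands provable, and the constructor refuses grids where they are not,
naming the maximum realizable band.  The standard phantom is 96³ at 1 mm;
cohort-scale simulations use the same anatomy in mm sampled at 48³/2 mm,
where the 1-mm bin is empty (no voxel centre lies below 1.5 mm) — harmless,
since band 1 is excluded by design.

Healthy T1 is the linear model surface plus independent Gaussian noise.
Defaults: WM β₀ ≈ 850 ms, GM ≈ 1400 ms, CSF ≈ 3500 ms, β_sex ≈ 12 ms,
β_age ≈ 1.6 ms/y, β_age2 ≈ 0.02 ms/y², σ ≈ 30 ms, all with low-frequency
spatial modulation so coefficient fields are non-constant.  Ages are
Normal(37, 10) clipped to [18, 80] and sex is Bernoulli(0.37 male),
matching the healthy reference cohort the model targets (mean age 37.3 ±
10.6, 63% female).  Patients add, on a random `affected_fraction` subset of
supratentorial WM, a diffuse abnormality `severity · A · exp(−d/λ)` with
defaults A = 60 ms, λ = 10 mm — the exponential form and the amplitudes are
generator choices, chosen as plausible and documented as illustrative, not
calibrated to any clinical dataset, which reports the gradient's shape only
qualitatively.  Lesions are spheres (2.5 mm radius) with per-band Poisson
counts proportional to exp(−d/10 mm) and a fixed +350 ms T1 elevation;
the lesion process is independent of the per-subject severity, so lesion
count carries no disability signal unless coupled explicitly.  EDSS is a
group baseline (2.0 early, 5.5 progressive) plus `edss_coupling_slope ×
severity` plus Gaussian noise, quantized to 0.5 steps and clipped to
[0, 10].  Per-subject RNG streams are spawned from (cohort seed, subject
index), so enlarging a cohort never reshuffles earlier subjects.

What the generator does **not** emulate — and hence what passing tests do
not show about clinical data: realistic brain anatomy and tissue
boundaries, registration error and template construction, MR acquisition
physics (B1, inversion efficiency), partial-volume mixing at tissue
interfaces, spatially correlated noise, lesion morphology beyond spheres,
and any GM/cortical pathology.  Results on the phantom demonstrate the
correctness and statistical behaviour of the pipeline's computations, not
clinical effect sizes.

## Numerical and validation choices

* Problem sizes: cohort experiments run at 48³/2 mm with n = 92 healthy
  controls (the reference cohort size), 50 held-out controls for
  calibration, n = 52 progressive patients for the association ordering,
  and 12 Monte-Carlo repetitions — sizes chosen so the whole validation
  battery completes in minutes on one CPU while keeping Monte-Carlo error
  well inside the asserted tolerances.
* Coefficient recovery is asserted as ≥ 99% of voxels within 3 analytic
  standard errors per coefficient: under the model itself ~0.27% of voxels
  exceed 3 SE by chance, so a literal "every voxel" criterion would fail
  with probability → 1 as the voxel count grows; the 99% bound sits ~17
  binomial SDs below the expected 99.73% at the tested voxel counts.
* Null-gradient behaviour is asserted on the max of ~35 correlated
  group-mean t statistics.  Because all patients share one estimated atlas,
  the statistics carry a common atlas-error component and are slightly
  heavier-tailed than t(19); the bound (max |t| < 5.5, median |t| < 1.5)
  reflects that.
* The decay-constant fit uses bands 2–25 at high signal-to-noise
  (A = 200 ms ≫ σ): beyond that distance the per-band signal approaches the
  band-mean noise floor and the log transform becomes unstable.
* Exact-test thresholds: Spearman enumeration up to n = 10 (3.6M
  permutations, vectorized and cached), rank-sum enumeration up to combined
  N = 12; tolerances of 1e−9 guard floating-point tie comparisons.

## Known limitations

* No spatial resampling: all inputs must share one voxel grid; the package
  assumes co-registration has happened upstream.
* The atlas serialization stores float64 NIfTI volumes for bit-exact round
  trips; general `write_volume` defaults to float32.
* Exact Spearman p for n = 10 allocates ~36 MB of cached permutation
  indices on first use.
* The generator's disability model is a convenience (no published
  generative EDSS model exists); its slope/noise defaults produce realistic
  rank correlations but are not fitted to patient data.
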