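# Methods

## Tissue classification model

A CT voxel is assigned exactly one of ten classes: background, SAT, VAT,
IMAT, EAT, PAT, muscle, bone, excluded air, or unclassified. Classification
combines the HU value with the voxel's semantic body region, in this
precedence order:

1. background region → background;
2. HU in the air window [−1024, −800] → excluded air, regardless of region
   (see *Air-exclusion scope* below);
3. bone region → bone (no HU window is used for bone — skeletal attenuation
   spans too wide a range for a single threshold, and the upstream
   segmentation already delineates it);
4. HU in the adipose window [−190, −30] → adipose subclass by region:
   subcutaneous tissue → SAT, abdominal cavity → VAT, muscle → IMAT,
   pericardium → EAT, mediastinum (outside the pericardium) → PAT; adipose
   HU in the thoracic cavity proper has no named compartment and stays
   unclassified;
5. HU in the muscle window [−29, 150] inside the muscle region → muscle;
6. everything else → unclassified.

**Window boundaries at float HU.** The printed windows are inclusive and
contiguous at integer HU. After noise or interpolation HU values are real,
so the adipose/muscle junction is split at the midpoint: adipose is
[−190, −29.5), muscle [−29.5, 150]. This is the least surprising float
extension and is exercised explicitly in the tests.

**EAT vs PAT.** Adipose inside the pericardium region is epicardial;
adipose in the mediastinum outside the pericardium is paracardial. This
follows standard cardiac-fat anatomy and is overridable through the
region→tissue map argument.

**Air-exclusion scope.** Air-window voxels are removed from the body-voxel
denominator "to reduce inconsistencies" from bowel gas and lung. By default
the exclusion applies in every non-background region — restricting it to
the abdominal cavity would let lung air inflate the denominator
inconsistently between scans with different thoracic coverage. A config
flag (`air-exclusion-scope: abdominal`) restores the narrower reading.

**Biomarkers.** BFR = 100 × (adipose voxels)/N_body and
SMR = 100 × (muscle voxels)/N_body with N_body = non-background −
excluded-air. Both are spacing-invariant; volumes in litres
(count × voxel volume) are reported too but depend on the header spacing,
which for thick-slice (5 mm) reconstructions is a real source of
between-protocol variation.

## Agreement statistics

* **Pearson r** via the product-moment formula with the two-sided
  non-correlation t-test p-value (scipy). Constant vectors raise a
  degenerate-sample error rather than returning r = 0.
* **Lin's concordance correlation coefficient**
  ρC = 2s_xy/(s_x² + s_y² + (x̄ − ȳ)²) with n-denominator moments, per the
  original 1989 definition — at small n this differs from an (n−1)-moment
  variant, and the original is the citable convention. The 95% CI uses the
  Fisher z-transform with Lin's asymptotic standard error; when |ρC| = 1
  the variance formula degenerates and the CI collapses to the point
  estimate. The implementation is cross-checked in the tests against an
  explicit-summation oracle and hand-derived values (1, −1, 4/7).
* **Bland–Altman**: differences d = x − y in the order the methods are
  listed (CT-based BCA is listed first, so a method reading low yields a
  positive mean difference). Limits of agreement use the classical 1.96
  multiplier with the sample (n−1) sd; confidence intervals use the t
  quantile with SE(d̄) = s_d/√n and SE(LoA) = s_d·√(3/n).
* **Shapiro–Wilk** normality screening (scipy's Royston implementation),
  valid for 3 ≤ n ≤ 5000.
* **Stratification**: each comparison is run overall plus per BMI group
  (half-open WHO cut points 18.5/25/30 kg/m²) or per sex. Pairs with a
  missing value are dropped per comparison (pairwise-complete, matching
  designs where modalities have different coverage); strata with fewer
  than 3 complete pairs are skipped with a warning. No multiple-testing
  correction is applied.

## Synthetic data

**Phantom generator.** Body voxels (a cylinder along z, or an explicit
voxel list for hand-built fixtures) are partitioned into the requested
tissue counts (fractions rounded to the nearest voxel; the remainder
becomes unclassified soft tissue). Each voxel's HU is drawn uniformly
strictly inside its tissue's window, and Gaussian noise (default sd 5 HU,
a typical noise magnitude for low-dose CT) is truncated so the value never
crosses a window boundary; the region label always matches the intended
subclass. Quantification of any phantom therefore recovers the constructed
counts with zero error — this is the pipeline's exactness oracle, and it is
deliberately insensitive to the noise level. What the phantom does *not*
emulate: partial-volume voxels at tissue interfaces, beam-hardening,
segmentation errors, or anatomy; passing the phantom tests shows the
classifier and bookkeeping are correct, not that the HU windows are
biologically optimal.

**Cohort generator.** Subjects are allocated to BMI groups
healthy/overweight/obese with weights 22/35/17 (largest-remainder exact
allocation by default; multinomial optional). BMI is uniform within
[18.5, 25), [25, 30), [30, 40] — the upper obese bound of 40 is a modelling
choice, as the emulated design states no maximum. Latent true BFR and SMR
are Gaussian per group with the CT-derived group means ± sd as defaults
(BFR: 32.43 ± 11.25, 40.36 ± 7.04, 49.79 ± 7.65; SMR: 27.84 ± 4.90,
26.57 ± 4.19, 23.65 ± 5.17 %); treating the published group summaries as
Gaussian parameters is a modelling choice, not an observed distribution.
Each modality reading is latent + bias_intercept + bias_slope·(group index)
+ Gaussian noise, clipped to [0, 100]; the bias is injected after the
latent draw so the latent remains the estimand. Default error models: the
CT reading is the latent value itself; DXA BFR bias −3.16 − 2.63·g and BIA
BFR bias −3.58 − 3.19·g (fitted to the observed per-group mean
differences, reproducing the divergence that grows with BMI); BIA SMR bias
+6.34 flat (the observed group differences are non-monotone, so a slope is
not defensible); noise sds 0.8/1.12/0.85 points. The shared latent value
induces the cross-method correlation; because the simulated noise is purely
additive-Gaussian, simulated r values run higher than clinical ones — the
recoverable targets are the injected biases, limits of agreement, and ρC
pattern, not r itself.

## Numerical and design notes

* HU values are clamped to [−1024, 3071] (12-bit CT) on load; spacing comes
  from the NIfTI header and volumes are assumed co-registered
  voxel-for-voxel (true by construction for segmentations produced from
  the same grid). No resampling is performed.
* All generators take explicit integer seeds (numpy `default_rng`); the
  same seed reproduces volumes and tables bit-for-bit, and JSON output is
  key-sorted so reports are byte-stable.
* Sample sd uses ddof = 1 everywhere a cohort statistic is reported; a
  single observation reports a missing sd, not zero.
* Problem sizes in the test-suite and acceptance script (phantoms ≤ 64³,
  cohorts of 74 for study-shaped runs and 5 000–100 000 for calibration
  checks) were chosen so each statistical check has Monte-Carlo error well
  below its assertion tolerance while the whole suite stays fast.
* One wording discrepancy is resolved deliberately: agreement is sometimes
  described as "Pearson rank correlation", but Pearson's r is not a rank
  statistic; this package computes product-moment Pearson, consistent with
  how r is reported alongside ρC.

## Limitations

* The seven-compartment model ignores adipose outside the named regions
  (e.g. thoracic-cavity fat stays unclassified) and uses a single HU window
  per tissue regardless of contrast phase or scanner calibration.
* BFR/SMR are voxel-count ratios, not mass fractions; comparison with
  mass-based modalities (DXA/BIA) therefore carries an intrinsic,
  BMI-dependent offset that the agreement analysis measures rather than
  removes.
* The cohort simulator draws independent subjects; repeated measures,
  scanner effects and non-Gaussian tails are out of scope.
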