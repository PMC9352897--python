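# ctbca — CT-based body composition analysis

`ctbca` quantifies body composition from routine CT scans and evaluates how
well the CT-derived biomarkers agree with reference modalities such as
dual-energy X-ray absorptiometry (DXA) and bioelectrical impedance analysis
(BIA). It is aimed at imaging researchers who already have a semantic
body-region segmentation of a CT volume (thoracic cavity, mediastinum,
pericardium, subcutaneous tissue, muscle, abdominal cavity, bone) and want
reproducible tissue quantification plus the standard method-comparison
statistics.

## Method

**Tissue subclassification.** Each voxel is classified by thresholding its
Hounsfield unit (HU) within its semantic region. Adipose tissue occupies
[−190, −30] HU and muscle [−29, 150] HU (inclusive at integer HU; for float
HU the two windows meet at −29.5). Adipose voxels are subclassified by
region into subcutaneous (SAT), visceral (VAT), intermuscular (IMAT),
epicardial (EAT) and paracardial (PAT) adipose tissue; muscle-window voxels
count as muscle only inside the muscle region; the bone region is taken as
bone directly. Voxels in the air window [−1024, −800] HU are excluded from
the denominator. The two biomarkers are

```
BFR = 100 · |SAT ∪ VAT ∪ IMAT ∪ EAT ∪ PAT| / N_body   (body fat ratio, %)
SMR = 100 · |muscle| / N_body                          (skeletal muscle ratio, %)
```

with `N_body` = non-background voxels minus excluded-air voxels. Both ratios
are invariant to uniform voxel-spacing changes; tissue volumes (litres) are
also reported but depend on the spacing in the file header.

**Agreement analysis.** For each modality pair the package computes
Pearson's product-moment r with the two-sided non-correlation p-value,
Lin's concordance correlation coefficient

```
ρC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)
```

(n-denominator moments; |ρC| ≤ |r|, with equality iff means and variances
agree) with a Fisher-z confidence interval, Bland–Altman statistics
(mean difference d̄, limits of agreement d̄ ± 1.96·s_d, t-based CIs), and a
Shapiro–Wilk normality screen — overall and stratified by BMI group
(healthy [18.5, 25), overweight [25, 30), obese ≥ 30 kg/m²) or sex.

**Synthetic data.** Because clinical paired data is rarely shareable, the
package ships generators for (a) CT phantoms whose tissue composition is
known exactly by construction — the oracle used to validate the classifier —
and (b) paired BCA/DXA/BIA cohorts with configurable per-modality bias
(intercept + BMI-group slope), Gaussian noise, and latent-value-induced
cross-method correlation.

## Worked example

```sh
python examples/cohort_agreement.py
```

```
cohort: 74 subjects, 40 male / 34 female
BFR bca vs dxa [overall   ] n=74  r=0.98  ccc=0.83  mean diff=+5.48%  LoA=(+1.08, +9.87)
BFR bca vs dxa [healthy   ] n=22  r=1.00  ccc=0.95  mean diff=+2.74%  LoA=(+1.39, +4.09)
BFR bca vs dxa [overweight] n=35  r=0.99  ccc=0.71  mean diff=+5.71%  LoA=(+4.40, +7.02)
BFR bca vs dxa [obese     ] n=17  r=0.99  ccc=0.44  mean diff=+8.55%  LoA=(+6.74, +10.37)
...
SMR bca vs bia [overall   ] n=74  r=0.98  ccc=0.53  mean diff=-6.22%  LoA=(-8.03, -4.41)
```

The CT method reads body fat about 5–6 percentage points above DXA/BIA and
muscle about 6 points below BIA; r stays high everywhere while ρC drops in
the obese stratum — precise but increasingly biased agreement as BMI grows.
`examples/phantom_quantify.py` shows exact ground-truth recovery on a
phantom, and `examples/bland_altman_plot.py` renders a mean-difference plot.

A thin CLI wraps the same library calls:

```sh
bca --seed 7 simulate cohort --out cohort.csv
bca compare --table cohort.csv --group-by bmi --out results/
bca --seed 7 simulate phantom --out-ct v.nii.gz --out-seg s.nii.gz --out-truth t.json
bca quantify --ct v.nii.gz --seg s.nii.gz --out report.json
```

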