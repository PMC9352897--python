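"""Simulate a 74-subject multi-modality cohort and analyse agreement.

The default cohort emulates a three-group BMI design (22 healthy / 35
overweight / 17 obese) with CT-derived latent BFR/SMR distributions and
per-modality error models. Pearson's r measures linear association, Lin's
concordance coefficient penalises bias away from the identity line, and
the Bland-Altman mean difference is the systematic offset between methods
in percentage points.
"""

from ctbca import CohortSpec, compare_methods, generate_cohort

table = generate_cohort(CohortSpec(n_subjects=74, seed=1))
print(f"cohort: {len(table)} subjects, "
      f"{(table['sex'] == 'male').sum()} male / {(table['sex'] == 'female').sum()} female")

for metric, pair in (("bfr", ("bca", "dxa")), ("bfr", ("bca", "bia")),
                     ("smr", ("bca", "bia"))):
    for stratum, agr, ba in compare_methods(table, metric, pair, stratify="bmi"):
        print(f"{metric.upper()} {pair[0]} vs {pair[1]:3s} [{stratum:10s}] "
              f"n={agr.n:2d}  r={agr.r:.2f}  ccc={agr.ccc:.2f}  "
              f"mean diff={ba.mean_diff:+.2f}%  LoA=({ba.loa_low:+.2f}, {ba.loa_high:+.2f})")
# A high r with a lower ccc (e.g. the obese stratum) signals precise but
# biased agreement: the methods rank subjects alike yet disagree on the level.
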