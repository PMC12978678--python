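"""The five covariate-controlled reading contrasts and score derivation.

Shows how class accuracies are pooled, what dependent variable and
covariate block each built-in contrast assembles, and the inverse-duration
transform used for reading-speed analyses.
"""
from strokemap import (CONTRASTS, CohortParams, build_contrast_target,
                       inverse_duration, score_accuracy, simulate_cohort)

cohort = simulate_cohort(CohortParams(with_durations=True), seed=3).cohort_table

acc = score_accuracy(cohort, ("PW0M", "PW1M", "PWMM"))
print(f"pooled pseudoword accuracy, first 3 subjects:")
print(acc.head(3).round(3).to_string())
print()

for name, spec in CONTRASTS.items():
    target = build_contrast_target(cohort, spec)
    covs = [" + ".join(c) for c in spec.behavioral_covariates]
    print(f"{name}:")
    print(f"  y = accuracy({' + '.join(spec.target_class)}), "
          f"mean {target.y.mean():.3f}")
    print(f"  behavioral covariates: {covs}")
    print(f"  nuisance: lesion volume, age, education "
          f"({target.nuisance_covariates.shape[1]} columns), "
          f"n = {len(target.subject_ids)}")
print()

d = cohort.durations["seconds"].iloc[0]
print(f"example item duration {d:.2f} s -> inverse duration {inverse_duration(d):.3f}")
print("(1/time-on-item normalizes the right-skewed duration distribution;")
print(" trials time out at 10 s, so inverse durations are >= 0.1)")
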