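"""Internal validation: bias-corrected bootstrap of the path coefficients.

Resamples patients with replacement, refits the final model on every
resample, and summarizes each free unstandardized path with a
bias-corrected standard error and 95% confidence interval.
"""

import warnings

import pathprog as pp

warnings.filterwarnings("ignore")

cohort = pp.generate_cohort(pp.SyntheticConfig(seed=5))
complete, _ = pp.apply_missingness_policy(cohort, cohort.names)
spec = pp.final_model_spec(include_eliminated=False)

result = pp.bootstrap_fit(complete, spec, reps=1000, seed=5)
summary = result.summary_frame()

print("bootstrap summary for day-7 trait anxiety (strongest outcome):")
rows = summary.loc[summary.index.str.startswith("t1_stai_trait<-")]
print(rows.round(3).to_string())
print(f"\nfailed replicates: {result.failures}/{result.reps}")
print("""
Reading: 'b' is the full-sample unstandardized coefficient; 'se' the plain
replicate SD; 'bc_se' folds the bootstrap bias into the spread; the CI is
the bias-corrected percentile interval.  Intervals excluding 0 mark paths
whose sign is stable under resampling of patients.""")
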