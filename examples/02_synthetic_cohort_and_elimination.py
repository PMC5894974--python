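"""Generate a synthetic cohort and run the backward elimination on it.

The generator draws patient-level data whose observed moments match the
published tables (latent-normal dichotomization for the binary columns),
appends eleven near-null baseline columns standing in for the variables
the study eliminated, and applies the study's ~4% loss to follow-up.
"""

import warnings

import pathprog as pp
from pathprog.pipeline import EDUCATION_GROUP, initial_model_spec

warnings.filterwarnings("ignore")

cohort = pp.generate_cohort(pp.SyntheticConfig(seed=12))
complete, dropped = pp.apply_missingness_policy(cohort, cohort.names)
print(f"enrolled {cohort.n_enrolled}, complete at day 7: {complete.n_enrolled}")

trace = pp.eliminate_backward(
    complete, initial_model_spec(), groups=EDUCATION_GROUP)
print()
print(trace.to_text())

fit = trace.final_fit
chi2, p = fit.chi_square()
print(f"\nfinal model: chi2 = {chi2:.1f}, df = {fit.df}, P = {p:.2f}")
print("""
Reading: predictors leave one at a time when their coefficient p-value
exceeds 0.20 on at least four of the seven outcomes, unless zeroing their
paths costs real fit (model-fit P dropping by 0.10 or more).  At n=398 the
guard cannot always tell a genuinely null column from a weak real one, so
an occasional null survives -- the trace records every decision.""")
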