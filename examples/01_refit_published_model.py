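"""Refit the final prognostic model from the packaged moment tables.

The package ships the published sufficient statistics of a 398-patient
day-case surgery cohort (383 complete at day-7 follow-up): means, SDs and
the 17x17 correlation matrix of two binary demographics, eight baseline
questionnaire scores, and seven day-7 outcomes.  Refitting the joint path
model on these moments reproduces the published standardized coefficients
and explained variances.
"""

import pathprog as pp

moments = pp.daycase_moments(repaired=True)
spec = pp.final_model_spec(include_eliminated=False)
fit = pp.fit_ml(moments, spec)

print("adjusted R^2 per day-7 outcome (n=383, k=10):")
for outcome, r2 in zip(spec.outcomes, fit.r2_adj):
    print(f"  {outcome:<16}{r2:6.2f}")

print("\nprominent standardized effects (|B| >= 0.20):")
for pred, out, B in pp.important_effects(fit, 0.20):
    print(f"  {pred:<16} -> {out:<16} B = {B:5.2f}")

lo, hi, _ = pp.residual_correlation_summary(fit)
print(f"\noutcome residual intercorrelations: {lo:.2f} to {hi:.2f}")
print("""
Reading: each B is the expected SD change in a day-7 outcome per SD of the
baseline predictor, holding the other nine predictors fixed.  Baseline
trait anxiety dominates (B ~ 0.5 on day-7 trait anxiety); the residual
intercorrelations show the outcomes remain moderately related even after
conditioning on all baseline information.""")
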