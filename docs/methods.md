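# Methods

## The model

`pathprog` fits a joint linear path model — a structural equation model
among observed variables only, with no latent factors — for prognostic
questions with several correlated outcomes.  With baseline predictors
x (length k) and follow-up outcomes y (length q),

    y = a + b'x + e,    e ~ (0, Ψ),    Ψ unstructured,

the exogenous moments are fixed at their sample values and selected paths
b[i, j] may be constrained to zero.  The model-implied covariance over
(x, y) is

    Σ(θ) = [ Sxx        Sxx b      ]
           [ b'Sxx   b'Sxx b + Ψ   ]

and estimation minimizes the maximum-likelihood covariance-structure
discrepancy F(θ) = ln|Σ| + tr(S Σ⁻¹) − ln|S| − p.  Degrees of freedom are
counted as sample moments p(p+1)/2 minus free parameters, which reduces to
the number of zero-constrained paths: a predictor "eliminated" from the
regression stays in the variable set with all q of its paths fixed at
zero, contributing q degrees of freedom.

Two estimation routes coexist and cross-check each other:

- **Closed form.** When every outcome has the same free-predictor set
  (always the case after whole-predictor elimination), the minimizer is
  per-equation least squares on the retained predictors with
  Ψ = Syy − Syx Sxx⁻¹ Sxy.
- **Quasi-Newton.** For arbitrary zero-path patterns, L-BFGS-B on the free
  b entries and the Cholesky factor of Ψ (which keeps Ψ positive
  semidefinite), with the analytic gradient dF/dΣ = Σ⁻¹(Σ−S)Σ⁻¹ chained
  through the structure.  On equal-regressor problems the two routes agree
  to 1e−6; the test suite also checks the iterative route against an
  independent Nelder–Mead minimization of F.

Standardized coefficients are B = b·sd(x)/sd(y).  Explained variance per
outcome is R²_j = 1 − Ψ_jj / implied var(y_j), adjusted as
1 − (1−R²)(n−1)/(n−k−1) with k the retained-predictor count.  Standard
errors come from the textbook least-squares formula in the closed-form
branch (residual df n−k−1) and from the expected information of the
regression block otherwise; Wald p-values use the normal reference.

## Fit assessment

Five adequacy measures are computed: the model chi-square
T = (n−1)·F by default (the multiplier convention is a parameter, since
SEM software disagrees; both conventions round the reference RMSEA to the
same 2-dp value), the chi-square/df ratio, CFI and TLI against a full
independence baseline (all covariances zero, variances free, for which
F = −ln|R| in closed form), RMSEA with a 90% interval obtained by
inverting the noncentral chi-square CDF in its noncentrality parameter
(bisection/Brent to 1e−8; bounds with no root are 0), and SRMR as the RMS
difference between sample and implied correlations over the lower triangle
including the diagonal (diagonal residuals are identically zero here
because implied variances match sample variances).

For non-normal data the robust (MLR-style) chi-square divides T by a
Satorra–Bentler-type scaling factor c = tr(UΓ)/df, with Γ the
fourth-moment estimate of the asymptotic covariance of vech(S) and
U = W − WΔ(Δ'WΔ)⁻¹Δ'W the normal-theory residual weight operator; Δ is the
Jacobian of vech(Σ) in all free parameters (exogenous moments included),
evaluated by central differences.  Under multivariate normality c → 1;
heavy tails give c > 1.  The scaled statistic is referred to the central
chi-square with the same df (first-order correction only; mean-and-
variance-adjusted variants are out of scope).

## Backward elimination

Predictors are pruned jointly across all outcomes: a predictor (or
predictor block — the two education indicators move as one, summarized by
their minimum p per outcome) is a candidate when its Wald p exceeds 0.20
on at least four of the seven outcomes.  One candidate is removed per
iteration — the one weak on the most outcomes, ties broken by larger
median p, then roster order — and the removal is accepted unless the
model-fit p-value drops by ≥ 0.10 relative to the model just before it,
in which case the predictor is restored and marked kept.  The procedure is
deterministic, and the returned trace replays exactly to the final
specification.

Two design points deserve emphasis.  First, the loss-of-information guard
applies only when the pre-removal model is testable (df > 0): a saturated
model has no meaningful fit p-value, and comparing against its
conventional p = 1 would veto essentially every first removal.  Second,
the guard is intrinsically noisy: when a genuinely null predictor's seven
paths are zeroed, the fit p-value moves by a central-chi-square(7)
fluctuation, which exceeds the 0.10 threshold with probability roughly
0.12–0.28 depending on the current df.  At n ≈ 400 a 7-df test also
cannot reliably separate a calibrated-null column (noncentrality ≈ 2)
from the weakest genuine predictors such as sex or baseline state anxiety
(noncentrality ≈ 5–10).  Selection stability at this design is therefore
limited by the data, not the implementation; the trace makes every
decision auditable, and domain knowledge (e.g. keeping each outcome's own
baseline) legitimately supplements the statistical rule.

## Bootstrap validation

Internal validation resamples patients (whole rows, preserving the joint
predictor–outcome structure) with replacement, refits the model per
replicate, and summarizes each free unstandardized path.  The default is
1000 replicates.  Bias correction is BC, not BCa: z₀ = Φ⁻¹(fraction of
replicates below the full-sample estimate), endpoints at the replicate
quantiles Φ(2z₀ + z_{α/2}) and Φ(2z₀ + z_{1−α/2}) with linear quantile
interpolation.  Acceleration is omitted because only bias-corrected
standard errors are part of the reference procedure.  Two spreads are
reported: the plain replicate SD and a bias-corrected SE defined as the
RMS deviation of replicates around the full-sample estimate, which folds
the bootstrap bias into the spread.  Replicates whose refit fails
(degenerate resampled covariance) are dropped and counted; more than 10%
failures aborts with an error.

## Reference moment data and repair

The packaged fixture holds the published sufficient statistics of a
prospective day-case surgery cohort: n = 398 enrolled, 383 (96%) complete
at day-7 follow-up; questionnaire means/SDs at both timepoints; sex
(43.7% female) and having children (51.8%) as Bernoulli moments; and the
17×17 correlation matrix printed to two decimals.  Effective n defaults
to 383 since every model involves day-7 variables.  Matrices transcribed
from rounded tables can be indefinite, so a repair is available:
eigenvalue clipping at 1e−8 followed by renormalization to unit diagonal,
iterated to a fixed point (idempotent; a no-op on this particular matrix,
whose smallest eigenvalue is 0.15).

## The synthetic cohort generator

The generator emulates the study conditions so that every pipeline stage
is testable without patient-level data:

- Latent multivariate normal scores with the fixture's means/SDs and
  correlation targets.  Binary columns are dichotomized at the normal
  quantile of their target prevalence; because dichotomization attenuates
  correlations, latent correlations are pre-inflated — closed-form
  point-biserial inflation r·√(p(1−p))/φ(Φ⁻¹(p)) for binary–continuous
  pairs, tetrachoric inversion by root-finding for binary–binary pairs.
- Eleven additional baseline columns stand in for the variables the final
  model fixes at zero (nationality, marital status, religion, education as
  one latent 3-level variable cut at the observed prevalences and expanded
  to low/high indicators, employment, age, BMI, heart rate, baseline
  self-esteem, and the randomized premedication arm, with prevalences and
  quartile-matched moments from the published baseline table).  Their
  cross-correlations are drawn uniformly in ±`null_corr_max`.  The default
  window is 0.025, chosen so the true final model's population discrepancy
  matches the study's own fit statistics (chi-square ≈ 99 on 77 df,
  noncentrality ≈ 22; the misfit grows with the window squared, and a
  ±0.10 window would imply chi-square ≈ 450 — a study in which the
  reported model could not have fit).
- Loss to follow-up as whole-row MCAR deletion of all day-7 scores at
  rate 15/398.
- Scores stay continuous by default so covariance targets hold exactly in
  expectation; `truncate_to_range` rounds and clips to the printed scale
  ranges for realism at the cost of small moment distortions (excluded
  from moment-accuracy assertions).  An item-level generator produces
  parallel items with inter-item correlation α/(k−α(k−1)) for internal-
  consistency studies.

What the generator does **not** emulate: skewed and floor-heavy score
distributions (real HADS/STAS scores pile up near their floors), MNAR
dropout, item-level structure of the real questionnaires, and the mutual
exclusivity constraints among arbitrary binary columns (only education is
generated jointly).  Passing tests on synthetic cohorts therefore
demonstrate correctness of the estimators under the study's second-order
moment structure, not robustness to real questionnaire pathologies — the
robust chi-square exists precisely because real data are not latent-normal.

## Problem sizes used in the test suite

Simulation-backed checks run at sizes chosen to give stable verdicts:
moment consistency and parameter recovery on one cohort of n = 100 000
(standardized coefficients recovered within 0.02); bootstrap coverage on
200 independent cohorts of n = 398 with 199 replicates each (BC 95%
intervals must cover in 90–99%); robust-scaling checks at n = 2000; the
elimination structure-recovery suite over 30 seeded cohorts.

## What is and is not reproducible from the printed summaries

Reproducible, and reproduced by the acceptance tests: the dominant
standardized coefficients (±0.03, the propagation of 2-dp rounding), the
adjusted explained variances (±0.03), the trait-anxiety-only sensitivity
R² (exact at 2 dp), df = 77 (exact), the chi-square/df ratio, RMSEA point
and 90% CI, the ML p-value (exact arithmetic from the printed
chi-squares), and the residual intercorrelation range (±0.05).

Not reproducible from printed summaries alone, hence covered only by
tolerance or property checks: exact CFI/TLI (the original baseline
chi-square is unpublished; an independence baseline computed from the
simulated cohort reproduces 0.99/0.98 within 0.01), the intercept row of
the coefficient tables and the bootstrap CI endpoints (both need the raw
patient records), and the demographic-only and demographic+medical
explained-variance columns (the eliminated variables' correlations with
the outcomes were not printed; synthetic analogues are checked only
qualitatively, ≤ a few percent explained variance).  The published
selection itself combined the statistical rule with clinical–theoretical
judgment, so exact recovery of the predictor set from data alone is not an
implementation target (see the elimination section).

## Numerical conventions

Percentile-type descriptives use linear interpolation between order
statistics.  Binary codings: sex 0 = male / 1 = female; children
0 = no / 1 = yes; education enters as low/high indicators against the
middle-level (modal) reference.  Listwise deletion applies per model; the
pairwise option exists only for descriptive correlation tables.
Optimizer tolerances: ftol 1e−10, gradient norm < 1e−5 required at
convergence.  Reports round to 2 decimals, matching the reference tables;
JSON outputs keep full precision.
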