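# Methods

## Estimand and anchoring

The package estimates the anchored active-vs-active contrast between two
placebo-controlled trials: an index trial with patient-level data (IPD) and
a comparator known only through published aggregates (AgD). Anchoring
through the shared placebo arm means only *effect modifiers* imbalanced
across trials bias the comparison; prognostic imbalance cancels in the
within-trial contrasts. Weighting therefore targets the comparator
population: the combined estimate is the difference of the two
arm-vs-placebo effects, both expressed in the comparator trial's
population.

## Weight model

Weights are exponential-tilting / method-of-moments weights
w_i = exp(x̃_i·β), x̃_i = x_i − x̄_AgD, with β the minimizer of
Q(β) = Σ_i exp(x̃_i·β). Q is smooth and strictly convex on the feasible
set and its gradient is the mean-matching condition Σ w_i x̃_i = 0, so
convergence implies the weighted pooled means/proportions of the matched
covariates equal the aggregate targets *exactly* (the contract asserted in
tests is 1e-8 relative). This is the same estimator that MAIC reports
describe as a logistic model for the propensity of enrollment in the index
trial.

Numerical choices:

- Damped Newton with analytic gradient and Hessian; a full step is accepted
  unless it increases Q beyond float resolution (near the optimum the
  quadratic decrement drops below eps·Q, where a strict-decrease line
  search would stall), otherwise halved. BFGS fallback on Hessian solve
  failure. Iteration cap 500.
- Convergence: gradient max-norm ≤ 1e-10·n. When targets equal the sample
  means the solver exits at iteration 0 with β = 0 exactly.
- Feasibility screens before solving: a target strictly or weakly outside
  the convex hull of a covariate's values raises an infeasibility error
  naming the covariate (this covers binary targets of exactly 0 or 1 with
  both levels present); collinear or identically-zero centered columns are
  rejected with a removal hint. Divergence (‖β‖ exploding) during
  iteration is also reported as infeasibility.
- Weights are estimated once on the pooled two-arm IPD against pooled
  targets; per-arm ESS values are reported from the same weight vector.
- Matching is on first moments only (means/proportions), mirroring how
  aggregate baselines are published; no variance matching.
- Missing matched covariates are handled by complete-case analysis with a
  logged count of dropped patients.

ESS = (Σw)²/Σw² (Kish). It is invariant to rescaling all weights by a
positive constant, equals n iff weights are equal, and never exceeds n.
Rescaling modes `sum_to_n` and `mean_one` coincide numerically; both exist
so exported weight files can state the intended convention.

## Balance diagnostics

Continuous covariates: two-sample Wald z on (mean, SD, n) pairs.
Categorical: Pearson chi-square without continuity correction when all
expected counts are ≥ 5 (the boundary count of exactly 5 stays Pearson),
otherwise the two-sided Fisher exact test (sum of tables with probability
≤ observed). Aggregate-side counts are reconstructed as round(p·n) because
comparator papers print percentages. After matching, the ESS replaces n in
every test — estimated weights inflate variance, and using the raw n would
overstate precision. The weighted SD uses Σw(x−x̄_w)²/Σw rescaled by
ESS/(ESS−1), which reduces to the ordinary unbiased estimator under unit
weights.

A recomputation caveat: the published before-matching BMI comparison
(23.9, SD 3.0, n 305 vs 23.1, SD 3.2, n 321) is reported as p < 0.001, but
the Wald test on those printed summaries gives z = 3.228, p = 0.00125 —
the original analysis evidently used unrounded means. Similarly the
reported sex-imbalance p = 0.003 is not recoverable from the printed
percentages (a 2×2 chi-square on reconstructed counts gives p ≈ 0.039).
The package reports what it computes and does not force agreement.

## Outcome models

Efficacy endpoints: weighted least squares of the change score on a
treatment indicator, study-center fixed effects, and baseline OFF time.
Without a treatment-by-center interaction, the treatment coefficient equals
the least-squares-mean difference between arms. The default SE is the
HC0 sandwich treating estimated weights as fixed — it is invariant to
weight rescaling and reduces to the Welch-type two-sample variance in the
unadjusted case. A patient-level bootstrap that re-estimates weights in
every resample is provided as a cross-check; on well-behaved data the two
agree within ~15%. Fixing the weights ignores their estimation
variability; in practice the balance constraints make the estimator
slightly *less* variable than the fixed-weight sandwich suggests, so the
default errs conservative (the calibration study below measures the net
effect).

Safety endpoints: a weighted 2×2 of effective counts (sums of weights by
arm × event), rescaled so the four cells sum to the ESS, then
log OR = log(ad/bc) with SE √(1/a+1/b+1/c+1/d). A Haldane–Anscombe +0.5 on
all cells is applied and flagged when any cell is empty. The effective-count
route keeps a closed-form oracle and matches how event rates are published;
weighted logistic regression is a documented alternative, not implemented.

The published per-trial safety values (AEs 1.9 (0.26) / 1.1 (0.23), etc.)
are stored under the odds-ratio reading — printed value = arm-vs-placebo
OR, bracketed = log-scale SE. That reading reproduces the published
combined SAE (1.1) and discontinuation (0.7) ORs but yields 1.73 rather
than the printed 1.6 for AEs; the original safety pipeline is ambiguous
and no test forces the AE row.

## Bucher combination

Estimates combine as d₁ − d₂ with variance se₁² + se₂² (log scale for
ORs), CI half-width 1.959964·SE (the published CIs are consistent with a
normal quantile; aggregate-side degrees of freedom are unknown, so no
t-correction), two-sided Wald p. Sign convention: active minus comparator,
so negative differences favor the index-trial treatment on lower-is-better
endpoints. Recombining the printed per-trial contrasts reproduces all
seven published indirect mean differences at one decimal and the CI bounds
that survive input rounding (OFF-time lower bound −1.40; UPDRS III
−5.28/−0.52; mobility −7.84/0.84). The published OFF-time *upper* bound
(−0.02) recomputes to −0.002 from rounded inputs, and the PDQ-39
summary/ADL/emotional/stigma bounds are off by 0.01–0.05: the original
analysis used unrounded intermediates, so those bounds are not asserted.

## Synthetic trial generator

The generator emulates the two source trials to first/second moments of
their published baseline tables: age and BMI from normals truncated at
physiologic bounds (18–90 years, 13–45 kg/m²); sex Bernoulli; baseline OFF
time from a normal resampled until it clears the trial's inclusion
threshold (1.5 h/day index, 1.0 h/day comparator; retry cap 1000 per
patient, then an explicit error). Endpoint changes follow

    y = effect·treat + slope·off_baseline + Σ mod_j·x_j·treat
        + center_effect + noise,

with center effects drawn once per trial (SD 0.2× the endpoint noise SD;
the trials are multicenter but report no center structure — the default of
10 centers is arbitrary) and residuals mixing a shared latent severity
factor (loading 0.3, so quality-of-life dimensions co-move) with an
endpoint-specific term, normalized so the marginal residual SD equals the
configured value. Safety flags are Bernoulli by arm, independent of the
efficacy residuals; no adverse-event severity hierarchy, no dropout or
missingness, no diary time series.

Default effects are the published arm-vs-placebo contrasts of the two
trials (e.g. OFF-time −1.1 vs −0.5 h/day); residual SDs are back-derived
from the published contrast SEs at the published ESS. Left-truncation of
OFF time means its realized mean exceeds the configured parent mean (≈ 6.19
vs 5.7 index-side); tests of moment fidelity therefore use the
truncated-normal mean as the oracle, and the realized cross-trial OFF-time
gap is smaller than the configured one.

Because only first/second moments are emulated, passing tests show the
pipeline's *estimators* behave correctly under covariate shift and effect
modification; they do not certify distributional features of the real
trials (skewness, covariate correlations beyond the latent factor, site
heterogeneity), and the published ESS of 271 is not reproducible without
the original data (the synthetic analogue gives ≈ 280 under the same
shift).

## Effect-modifier defaults for the bias study

The bias study needs a nonzero interaction structure; the defaults
(OFF-time change: BMI +0.25 h per kg/m², male −1.5 h, baseline OFF −0.3 h
per hour, all interacting with treatment) were fixed once as clinically
plausible magnitudes relative to the −1.1 h/day main effect — lighter
patients and women respond somewhat better (consistent with reported
post-hoc sex/weight observations for this drug class), and more baseline
OFF time leaves more room for improvement. With the published-direction
covariate shift these produce a naive-Bucher bias of ≈ 0.3 h/day, carried
mostly by the BMI and sex terms because truncation shrinks the realized
OFF-mean gap.

## Calibration studies (problem sizes)

`null_coverage`: 500 simulated trial pairs at the published sample sizes
(305 + 321), shared conditional effects (truth 0), full pipeline per
replicate; the 95% CI should miss in ≈ 5% of replicates (measured 5.8% at
the default seed). `modifier_bias`: 200 pairs with the default modifiers;
MAIC's absolute mean bias is ~1% of the naive estimate's ≈ 0.33 h/day.
Both studies restrict simulation to the primary endpoint, which keeps the
full suite in seconds on one CPU.

## Known limitations

- Unanchored MAIC, simulated treatment comparison (STC), higher-moment
  matching, and network meta-analysis over more than two trials are out of
  scope.
- The sandwich SE conditions on the estimated weights; the bootstrap is
  the remedy when weights are extreme (low ESS fraction).
- Fisher's exact test is implemented for 2×2 tables only (the only
  categorical covariate here is binary).
- Aggregate-side published SEs are taken at face value; no reconstruction
  from CIs or p-values is attempted.
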