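# Methods

## Model

The package fits a joint selection model for a two-arm randomized trial with
a continuous outcome measured at baseline and follow-up. Writing X for
centre (4 categories, entered as three dummies), T for randomized arm,
Y0/Y1 for the baseline/final scores, R0/R1 for their response indicators,
and optionally Z/R_Z for a carer proxy score and its indicator, each
variable is modelled conditionally on all earlier variables in the order
X, Y0, R0, T, Y1, R1, Z, R_Z; T is independent of everything before it by
randomization. Scores get normal linear regressions; indicators get
logistic regressions. Because the indicator regressions include the
possibly-unobserved scores as covariates, the model is MNAR in general.

Conventions that matter:

* **Standardization.** Wherever a score appears as a covariate it is
  standardized: centred at the mean of the *observed* values and divided by
  the within-centre pooled SD of the observed values (the square root of
  the pooled within-centre variance). The standardizer is frozen once per
  analysis from the observed data; imputed values pass through the same
  map inside the sampler. Selection coefficients are therefore log-odds per
  SD of score, which is also the scale on which expert beliefs are
  elicited.
* **Naming.** `delta.A.B` is the coefficient of A in the regression for B
  (`delta.T.Y1` is the treatment effect). Arm-specific outcome selection
  replaces `delta.Y1.R1` with `delta.Y1.R1.T` and `delta.Y1.R1.C`.
* **Heavy tails.** The final-score regression may use a t distribution with
  fixed df (5 or 10 are the intended choices; df is never estimated). The
  t scale is calibrated as tau^2 = sigma^2 (df-2)/df so that `sigma2.Y1`
  keeps its meaning as the residual variance.
* **All participants contribute.** Participants with neither score are
  retained; their scores are latent variables like any other missing value.

## Sensitivity parameterization

The outcome-selection slope `delta.Y1.R1` (and its baseline counterpart
`delta.Y0.R0`) are not identified by the data and are the sensitivity
parameters. The delta grid fixes them at 0, 0.5 and 1 per SD, including the
arm-specific "worst case" pairs (0,1) and (1,0); the scale comes from the
equal-variance two-pattern normal identity: if the observed and missing
patterns have means mu_o, mu_m and common SD sigma, the log-odds of
response is linear in y with slope b = (mu_o - mu_m)/sigma^2, i.e.
b*sigma per SD. `pattern_mixture_to_selection` /
`selection_to_pattern_mixture` implement this pair (the marginal response
probability does not enter under equal variances).

The per-fit summary `Delta(Y1, arm)` is, per posterior draw, the mean of
the imputed missing final scores minus the (fixed) mean of the observed
final scores in that arm — a measure of departure from missingness
*completely* at random under the fitted assumption.

## Elicitation arithmetic

Experts spread a weight of 100 over nine ordered categories for the
nonresponder-minus-responder mean difference, stated against a responder
distribution with mean 40 and SD 10. Pooling is the unweighted linear
opinion pool; moments use the category midpoints with ±14.5 for the open
extremes. The conditional "revised guess" question maps to a between-arm
belief correlation by linear interpolation between the expert's average
(correlation 0) and maximum (correlation 1) differences, clipped to [0,1];
per-expert correlations are reported but deliberately not pooled — instead
two contrasting analysis presets are offered (one common slope prior vs
independent arm-specific priors). A pooled belief N(m, v) elicited at
reference SD 10 becomes a prior for the per-SD selection slope via
delta ~ N(-m/sigma, v/sigma^2) with sigma = 10, treating the experts as
answering relative to the outcome SD.

## Repeated attempts

The attempts extension replaces the single R1 regression with a logistic
model for success at contact attempt m = 1..9: the intercept alpha_m is
attempt-specific, while the coefficients of attempt type (verbal agreement
or not), centre, centre-by-attempt-index dummies (truncated at attempt 3,
because later attempts are rare), arm, standardized Y0 and Y1, and an
optional arm-by-Y1 interaction are shared across attempts. The shared-slope
assumption is what identifies the outcome coefficient `delta.Y1.Rstar`
("continuum of resistance"). With a single permitted attempt the likelihood
reduces exactly to the single-logistic model, which is tested.

The interaction-screening pre-step used in the motivating analysis
(complete-case logistic fits on the first three attempts, adding two-factor
interactions significant at the 0.01 level) is not re-run by default; the
default covariate set hard-codes its outcome (centre-by-attempt only),
since re-running selection on synthetic data would choose differently run
to run.

## Posterior computation

Sampling is Metropolis-within-Gibbs with data augmentation; everything is
deterministic given the seed (one `SeedSequence` fans out to one
independent stream per chain, and per-stage streams inside the simulator).

* Normal-regression coefficient blocks and variances are conjugate Gibbs
  updates (precision priors gamma(0.001, 0.001); flat coefficient priors
  are uniform(-50, 50) on the standardized scale — wide enough to be
  irrelevant wherever the likelihood is informative — and normal priors
  fold in conjugately). The t family is handled by its gamma scale-mixture
  representation with latent observation weights, which restores
  conjugacy; the precision prior is placed on the scale precision 1/tau^2.
* Logistic-regression blocks use adaptive random-walk Metropolis. The
  proposal covariance is initialized at the inverse Fisher information of
  the block evaluated at the starting value (a normal approximation to the
  conditional posterior), then replaced during burn-in by the empirical
  covariance of the chain (Haario-style), with the global scale tuned
  towards a 23% acceptance rate. All adaptation stops at the end of
  burn-in, so the kept draws come from a fixed-kernel chain. The attempts
  block is split into intercepts and slopes. Blocks are updated twice per
  iteration to balance their mixing against the Gibbs blocks.
* Missing scores are updated by one vectorized scalar random-walk proposal
  per value per iteration (they are conditionally independent given the
  parameters); the proposal scale starts at the observed-score SD and is
  tuned towards 44% acceptance during burn-in. Only the likelihood factors
  that involve the proposed score are evaluated, via rank-one updates of
  the affected design-matrix columns.
* Coefficients listed in `fixed_deltas` are held exactly at their value in
  every draw and recorded as constants.

Defaults are 4 chains, 2,500 burn-in + 2,500 kept iterations — a desk-scale
choice that reproduces its own results stably on the problem sizes used
here; `McmcConfig.paper_scale()` gives 4 x (25,000 + 25,000) for
final-quality runs. Convergence is summarized by the classic
potential-scale-reduction factor sqrt(((n-1)/n W + B/n)/W) per parameter
(no rank-normalization, no degrees-of-freedom correction), flagged above
1.05. Credible intervals are equal-tailed 2.5/97.5 percentiles.

An unconstrained model — outcome-selection slopes free under diffuse priors
with no attempts data and no fixed proxy-independence constraint — is known
to be severely under-identified; constructing one raises an
`IdentificationWarning` rather than an error, since the posterior is still
proper.

## Synthetic data

`simulate_trial` draws each variable forward along the same factorization
the model fits (normal scores, logistic selection, attempts via the shared
slope model), then deletes values whose indicator is 0. The truth record
(pre-deletion scores, indicators, linear predictors) is returned for
testing. Inside the generator, score covariates are standardized with the
full pre-deletion realized sample; the analysis recomputes standardizers
from observed data only. The two differ slightly under strong selection,
by construction — the discrepancy is far below the tolerances tested.

Nonresponders' attempt counts need a stopping policy. Interviewers are
assumed to abandon a participant after each failed attempt with probability
`giveup_prob`, and always after `max_attempts` (9) failures. An
abandonment probability is necessary: the published attempt-band sizes sum
to the full arm sizes, and only ~7% of participants had more than three
attempts while ~10% never responded, so most nonresponders stopped well
before attempt 9.

`calibrated_trial_params()` freezes a parameter set whose expected
marginals match the motivating trial's published summaries: score means
39/41 and pooled SDs 11/12; proxy mean 20, SD 6, complete-case
corr(Y1, Z) ≈ 0.31; missingness fractions near the published
37/18/5-of-409 pattern (with a higher final-score missingness rate in the
intervention arm, 29 vs 13); attempt bands near 42% single-attempt and 7%
more-than-three. The attempt intercepts (-0.40, 1.75, -0.35, -0.50...)
and `giveup_prob = 0.1` were solved from the band-proportion chain
band_m = reach_m [s_m + (1 - s_m) g] with the overall nonresponse fraction
as the extra condition, then verified by large-n simulation and frozen;
the within-band allocation beyond what the published tables pin down is a
free choice. The generating outcome-attempt slope is 0.22 per SD with an
arm effect of -0.85 on the attempt logit. The treatment effect in the
fixture is -0.4 MCS points.

`reference_tables_dataset()` is a different thing: a deterministic
*bookkeeping* fixture (not a simulation) whose pattern table and attempt
bands equal the published counts exactly, with every observed final score
set to its band mean so the descriptive operations reproduce the printed
summaries to the digit.

`simulate_experts` builds expert weight tables by discretizing a normal
belief onto the nine category midpoints with linear interpolation on a fine
grid, which keeps the midpoint mean equal to the (truncated) normal mean;
expert-to-expert spread is half the within-expert SD.

What the generator does **not** emulate: item-level questionnaire
missingness (scores are atomic), interviewer and calendar effects on
attempts, non-normal score distributions (beyond the optional t), centre
differences in missingness, and any measurement structure inside the proxy
score. Passing tests on this synthetic family shows the estimators recover
the mechanisms they model — not that those mechanisms describe any real
trial.

## Problem sizes used by the test suite

Deliberate desk-scale choices: MAR parameter recovery at n = 800 with
4 x (2,500 + 2,500) chains; the delta-grid monotonicity check at n = 500;
attempts-model identifiability at n = 2,000 (true per-SD slope 0.5); the
proxy misspecification direction check at n = 1,500; a 30-replicate
coverage study at n = 150 with short chains (interval coverage asserted at
a binomially tolerant 24/30). The conversion identity is checked against a
logistic fit on 100,000 simulated observations.

## Known limitations

* The sampler is single-process; chains run sequentially.
* Identification through proxies degrades continuously as corr(Y1, Z)
  falls; the package reports dispersion through the convergence flag and
  posterior SDs but draws no automatic "identified / not identified" line.
* The PSRF implementation is the classic one; it can sit slightly below 1
  and is less conservative than rank-normalized variants.
* Uniform(-50, 50) default priors are effectively flat for every quantity
  on the standardized scale but are still proper bounds; fits whose
  likelihood genuinely pushes coefficients to that magnitude (e.g. the
  saturated selection intercepts used in some tests) are truncated there.
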