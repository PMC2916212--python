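# mnartrial

Bayesian exploration of **missing-not-at-random (MNAR) outcome data** in
two-arm randomized trials with a continuous endpoint, built around a joint
*selection model*: normal regressions for the baseline score Y0, the final
score Y1 and an optional carer proxy score Z, together with logistic
regressions for their response indicators R0, R1, R_Z that may depend on the
(possibly unobserved) scores themselves. It is aimed at trial statisticians
who want to go beyond a missing-at-random (MAR) analysis: to quantify how
conclusions move as the untestable missingness assumptions change, and to
exploit ancillary data — elicited expert beliefs, proxy outcomes, and the
number of contact attempts — that carry genuine information about the
missingness mechanism.

## The model

Variables are modelled conditionally along the ordering
X (centre), Y0, R0, T (arm), Y1, R1 [, Z, R_Z]:

```
Y0 | X            ~  N(beta_0 + beta_X, sigma0^2)
R0 | X, Y0        ~  Bernoulli(expit(... + delta_{Y0,R0} * y0~))
Y1 | X, Y0, R0, T ~  N(... + delta_{T,Y1} * T, sigma1^2)          (or scaled t)
R1 | everything   ~  Bernoulli(expit(... + delta_{Y1,R1} * y1~))
```

where `y~` denotes a score standardized by the observed-data mean and
within-centre pooled SD, so each selection coefficient `delta_{A,B}` (the
coefficient of A in the model for B) is a log-odds of response per SD of
score. `delta_{T,Y1}` is the treatment effect; `delta_{Y1,R1}` is the
unidentified outcome-selection slope fixed (or given an elicited prior) in
sensitivity analyses. The equal-variance normal pattern-mixture identity
`b = (mu_o - mu_m) / sigma^2` converts beliefs about the mean difference
between missing and observed scores into this slope and back.

Two extensions make the slope identifiable from data, at the price of other
assumptions: a **proxy outcome** Z with conditional-independence constraints
(e.g. `delta_{R1,Z} = 0`), and a **repeated-attempts** model that replaces
the single R1 regression with a logistic model for success at each contact
attempt m, whose intercepts alpha_m vary with m while all slopes are shared
across attempts (the "continuum of resistance" assumption).

Inference is MCMC with data augmentation: missing scores are latent
variables sampled jointly with the parameters (conjugate Gibbs for the
normal blocks, adaptive Metropolis for the logistic blocks). Posterior
summaries include the treatment effect and `Delta(Y1, arm)`: the posterior
mean of the imputed missing final scores minus the observed mean in that
arm, a direct display of what a given assumption implies about the missing
data.

## Worked example

Simulate a 409-participant trial calibrated to the marginal summaries of a
real multicentre psychiatry trial (score means 39/41, SDs 11/12, ~10%
missing final scores, 42% single-contact-attempt participants), then vary
the outcome-selection slope over 0, 0.5 and 1 SD:

```python
from mnartrial import (
    McmcConfig, calibrated_trial_params, missingness_pattern,
    render_report, run_delta_grid, simulate_trial,
)

dataset, truth = simulate_trial(calibrated_trial_params())
print(missingness_pattern(dataset).table)
cells = run_delta_grid(
    dataset,
    grid=[
        {"label": "A", "delta.Y0.R0": 0.0, "delta.Y1.R1": 0.0},
        {"label": "D", "delta.Y0.R0": 0.0, "delta.Y1.R1": 0.5},
        {"label": "E", "delta.Y0.R0": 0.0, "delta.Y1.R1": 1.0},
    ],
    mcmc=McmcConfig(n_chains=4, n_burn=1000, n_keep=1500, seed=1),
)
print(render_report(cells))
```

Output:

```
               intervention  control  total
baseline_only            25       15     40
final_only               12       10     22
neither                   1        1      2
both                    166      179    345
total                   204      205    409

Model         Fixed deltas                        D(Y1,T) (SD)      D(Y1,C) (SD)      Effect (SD)
--------------------------------------------------------------------------------------------------------
A             delta.Y0.R0=0;delta.Y1.R1=0         -0.65 (2.15)      -0.38 (2.71)      -1.08 (1.07)
D             delta.Y0.R0=0;delta.Y1.R1=0.5       -5.00 (2.18)      -4.79 (2.69)      -1.27 (1.06)
E             delta.Y0.R0=0;delta.Y1.R1=1         -9.08 (2.26)      -9.12 (2.70)      -1.47 (1.10)
```

Reading the table: under the near-MAR model A the imputed missing final
scores sit where the observed ones do (Delta ~ 0); as the assumed selection
slope rises to 1 log-odds per SD, the model concludes the missing scores
were about 9 points (0.75 SD) lower than the observed ones, and the
estimated treatment effect drifts accordingly. SDs are posterior standard
deviations.

The same machinery is exposed as a CLI
(`mnartrial simulate | describe | mar | grid | elicited | proxy | attempts`),
and `mnartrial.elicitation` implements the expert-weight pooling and the
conversion of elicited beliefs into priors for the selection slope.

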