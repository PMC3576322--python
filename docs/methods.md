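# Methods

## Evidence structure and model

The bundled dataset is a star network: 16 randomized trials, each
comparing one anti-TNF agent (possibly at several doses) against placebo
in methotrexate-experienced RA patients. All between-drug comparisons are
therefore indirect, routed through the placebo node, and the usual
consistency checks of network meta-analysis are unavailable by
construction (there are no closed loops). The model makes the standard
exchangeability assumption instead, and the package does not pretend to
test it.

For each active treatment *k* the basic parameter `a[k]` is the pooled
effect versus placebo. Study-level true effects are random between trials
and fixed within a trial: every arm of one (study, drug) pair shares one
`alpha[s,k] ~ Normal(a[k], sigma^2)`, with a single between-trial SD
`sigma` for all comparisons — with at most a handful of trials per drug
there is no information to support comparison-specific heterogeneity.
Multi-dose arms of one trial are deliberately pooled into that one study
effect; dose is not modelled (a meta-regression on dose would not be
comparable across agents, each having its own dosing scale).

**Continuous likelihood.** Each treatment arm contributes its observed
difference in mean improvement against its own control arm,
`delta_obs ~ Normal(alpha[s,k]*lambda + b*(It - Ic), se^2)`. The SE of a
contrast is the two-sample formula `sqrt(sd_t^2/n_t + sd_c^2/n_c)`; no
other construction is possible from arm-level summaries, and the
correlation induced between contrasts sharing one control arm is ignored
in the likelihood (each contrast enters independently). `lambda` is the
treatment arm's baseline HAQ; with the multiplier enabled (the HAQ
analysis) effects are *fractions of baseline disability*, which is the
quantity a downstream economic model needs. The reconstructed continuous
ACR is already defined relative to baseline, so its model omits the
multiplier.

**Binomial likelihood.** Responder counts get a logit model; each study's
control arm enters the likelihood exactly once
(`logit(p.c) = mu_s + b*Ic`), each treatment arm adds `alpha[s,k]` on the
log-odds scale. An optional meta-regression term `gamma*lambda_s` on
baseline HAQ is implemented but off by default (it was explored and found
non-significant in this network).

**Methotrexate.** Co-medication is handled additively through one fixed
coefficient `b` multiplying the treatment/control indicator difference,
so it cancels whenever both arms share MTX status. Only one trial in the
network (a golimumab monotherapy arm against an MTX control) actually
informs `b`; its posterior is accordingly wide, and `b` functions as a
bias adjustment rather than an estimand of interest.

**Priors.** Effects, control logits and `gamma` get Normal(0, 10000)
(variance; SD 100) — read as "variance" rather than "precision" because
the intent is vagueness on the scale of differences and log odds ratios.
`sigma ~ Uniform(0, 2)`, following the standard recommendation of a
uniform prior on a hierarchical SD; 2 is far above any plausible
between-trial spread on either scale, and both hyperparameters are
configurable (`PriorSpec`). `PriorSpec(sigma_fixed=0)` collapses the
hierarchy to a common-effect model, which the tests use for closed-form
conjugate checks.

## Endpoint construction

**Dichotomized HAQ (HAQ20/HAQ50).** An arm reporting mean (SD) HAQ
improvement is converted to responder counts at a threshold of 20% (50%)
of the arm's own baseline HAQ, with response defined as improvement `>=`
the threshold. The reference procedure draws 1000 normal patient
improvements, takes the responder proportion and scales it to the arm
size; the package's `analytic` mode (the default for testing) computes
the same quantity as the normal tail probability — the infinite-draw
limit. Scaled counts are rounded half away from zero; `sd = 0` is a point
mass (all or no responders). The baseline used is the arm-level baseline,
not a trial average.

**Continuous ACR (ACRcont).** Nested ACR20/50/70 counts split an arm into
four response groups (none, 20-only, 50-only, 70). Given a mean
improvement `m_i` per group, the arm mean is the count-weighted mean and
the SD uses the population divisor N (not N−1) — the reconstruction
treats the N group-mean values as the data. Treated arms use group means
estimated from an external treated-patient cohort (`meanACR` default,
`ACRhybrid` as a sensitivity option); control arms use conservative
interval midpoints (0.00, 0.35, 0.60, 0.85), since no control-arm
patient-level estimates exist. Both choices are explicit arguments, and
reusing treatment means for controls is available as the sensitivity
analysis.

**Missing data.** Missing values are an explicit marker, never zero. SDs
reported as IQRs are converted by the normal approximation
`sd = IQR / (2 * z_0.75) ≈ IQR / 1.349`; remaining missing SDs take the
maximum SD observed anywhere in the dataset (0.7 HAQ units here) — a
deliberately conservative inflation — with every imputed cell listed in a
report. Arms without a mean cannot be imputed and drop out of the
continuous analysis (3 of 16 trials, leaving 13 for HAQ; all 16 report
ACR).

## Inference

Two samplers, both deterministic given a seed:

* `metropolis_within_gibbs` (default) — a blocked sweep on the centered
  parameterization: per-group and per-study random-walk Metropolis
  updates whose acceptance ratios use only the likelihood terms touching
  the coordinate (the likelihood factorizes by group and by study), plus
  *exact* conjugate draws for the basic effects (`a[k] | alpha, sigma` is
  normal) and for the heterogeneity (`sigma^2 | alpha, a` is a truncated
  inverse-gamma). This mirrors the classical Gibbs treatment of these
  models, mixes `sigma` well even when its posterior piles up near 0, and
  runs the full default lengths in under two minutes per fit.
* `ensemble` — an affine-invariant ensemble (emcee) with
  differential-evolution moves, run as independent ensembles per chain on
  a non-centered parameterization (`alpha = a + sigma*z`). Used for
  prior-only sampling and as a cross-check; the default stretch move and
  the centered parameterization both mix poorly here (the small-`sigma`
  funnel), which is why the defaults are what they are.

Defaults keep 2 chains, 50,000 burn-in and 100,000 kept draws per chain;
`McmcConfig.fast()` (4 chains × 2,500 kept) is justified by diagnostics
rather than run length — bulk ESS and split-R̂ (via arviz) are computed
for every fit, and `summary()` prints the worst of them. The test suite
runs its full-network fits at 10,000/30,000, which yields effective
sample sizes two orders of magnitude above what its tolerances need for
the basic effects and `sigma`. The MTX coefficient `b` is the slowest
coordinate (single informing trial); it is reported but no numerical
assertion depends on it. Initialization is at empirical effect estimates
(per-drug mean contrast, or empirical log odds ratios) with per-chain
jitter; `init="prior"` draws starting points from the prior instead.

Reporting: equal-tailed 80% credible intervals (configurable); the 80%
level is a deliberate shift away from the 95% accept/reject convention.
Odds ratios are summarized by exponentiating LOR draws *before*
averaging, i.e. the posterior mean of the OR itself. This matters:
`mean(exp(x)) > exp(mean(x))`, and for heavy-tailed posteriors (ACR70,
HAQ50) the two differ by more than 20%; reference tables that quote
geometric means will sit systematically below this package's OR column
while the interval endpoints agree.

## Synthetic data

`synthetic_data.generate_network` instantiates the same generative
equations with known parameters on a star topology. Defaults mirror the
fitted regime of the real network: effects 0.10–0.31 of baseline,
`sigma = 0.03`, `b = 0.05`, 3 trials per drug, 120 patients per arm,
baseline HAQ uniform on 1.3–1.9, per-patient improvement SD 0.55, control
response rate 0.3 (the control-arm mean is calibrated so the 20%-of-
baseline threshold is exceeded with that probability), and a 15% chance
that a treatment arm lacks MTX (giving `b` something to inform). The
`joint` mode thresholds the *same* latent patient improvements that
produce the continuous summaries — so continuous and binary endpoints
describe one underlying response and the power comparison can be run as
an experiment; the `logistic` mode generates counts exactly from the
binomial model (truth on the log-odds scale, lower-threshold counts
thinned from ACR20 to guarantee nesting) for clean recovery tests.

What the generator does **not** emulate: dose structure within drugs,
non-normal patient responses, missingness mechanisms, correlated
endpoints beyond the shared latent, or inconsistency between direct and
indirect evidence (the star has no loops). Passing recovery tests
therefore certify the estimation machinery, not robustness to those
real-data features.

`recovery_experiment` fits the matching model over replicated networks
and reports per-parameter bias and credible-interval coverage; at the
defaults, 80% intervals for the basic effects cover truth at the nominal
rate within binomial error.

## Known data-table inconsistencies

The bundled reference table of derived endpoints (HAQ20/HAQ50 counts and
ACRcont values per arm) carries the Monte-Carlo noise of its 1000-draw
construction — per-arm SD `n*sqrt(p(1-p)/1000)`, up to ~6 responders for
the largest arms — plus three apparent transcription faults, transcribed
as printed and handled explicitly where tests compare against it:

1. the two high-dose adalimumab arms of one trial (n = 207/212) appear
   with transposed sample-size labels (all derived cells follow the
   row order, not the printed n); arms are therefore matched by position
   within (trial, drug), never by n;
2. the n = 112/106 adalimumab arms of another trial have exactly their
   HAQ20/HAQ50 cells swapped (their ACRcont cells are not);
3. one control-arm ACRcont mean prints 0.22 where the reconstruction
   formula gives 0.2286 (→ 0.23) from the printed counts — verified
   against a patient-level enumeration oracle; the other 99 printed
   values match at 2 decimal places.

The strict full-table tests in `tests/test_acceptance.py` assert the
printed values literally and therefore fail on exactly these cells; the
statistical consistency test (4 MC SDs + rounding, pair-order-free for
item 2) passes on all 50 arms.

## Numerical choices and degenerate inputs

Rounding of scaled responder counts: half away from zero. Thresholds use
`>=`. Normal tail probabilities via `scipy.stats.norm.sf`; binomial
log-likelihoods via `log_expit` for stability at extreme logits. The
truncated inverse-gamma draw for `sigma^2` uses CDF inversion and keeps
the current value in the (never observed in practice) case of numerical
underflow; with fewer than two study-effect groups it falls back to a
Metropolis step. Empty datasets are legal and yield the prior. Zero-SD
arms are point masses. `se = 0` contrasts are rejected at validation.

## Limitations

Doses are pooled within drug; only RCT evidence is modelled; the
ACRcont reconstruction inherits the uncertainty of external group means
(which its SE does not propagate); the risk-ratio reparameterization and
formal inconsistency models are out of scope.
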