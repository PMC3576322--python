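# ra-mtc — Bayesian mixed treatment comparison of anti-TNF agents in RA

`ra_mtc` estimates the relative efficacy of the five anti-TNF agents
licensed for rheumatoid arthritis in Europe — adalimumab (Ada),
infliximab (Inf), etanercept (Eta), golimumab (Gol) and certolizumab
(Cert) — from the arm-level summaries of 16 placebo-controlled RCTs, and
uses that network to demonstrate a methodological point: **dichotomizing a
continuous endpoint throws away power to detect differences between
treatments** in network meta-analysis.

No head-to-head trials of these agents exist, so all pairwise contrasts
are obtained indirectly through the common placebo comparator (a *mixed
treatment comparison*, MTC). The package is aimed at evidence-synthesis
statisticians and health-economics analysts who want the full pipeline —
data validation, endpoint construction, hierarchical Bayesian fitting,
reporting — as reusable, tested code.

## The model

Every active treatment *k* has a basic parameter *a*<sub>k,P</sub>, its
pooled effect versus placebo; any comparison is a difference of basic
parameters, IC<sub>k,l</sub> = *a*<sub>k,P</sub> − *a*<sub>l,P</sub>.
Random effects between trials, fixed effects within a trial: all arms of
one study and drug share a study-level effect

&nbsp;&nbsp;α<sub>s,k</sub> ~ N(*a*<sub>k,P</sub>, σ²),

with a common between-trial SD σ. Two likelihoods:

* **continuous** (HAQ improvement, reconstructed continuous ACR): each
  arm-vs-control difference Δ<sub>j</sub> with sampling SE σ<sub>j</sub>
  contributes Δ<sub>j</sub> ~ N(α<sub>s(j),k</sub>·λ<sub>j</sub> +
  *b*·(I.t<sub>j</sub> − I.c<sub>s(j)</sub>), σ<sub>j</sub>²), where
  λ<sub>j</sub> is baseline HAQ (so effects are fractions of baseline) and
  *b* is an additive effect of concurrent methotrexate;
* **binomial** (ACR20/50/70 and dichotomized HAQ responders): a logit
  model whose control arm enters once per study,
  logit(p.t<sub>j</sub>) = μ<sub>s(j)</sub> + *b*·I.t<sub>j</sub> +
  α<sub>s(j),k</sub>; basic parameters are log odds ratios.

Priors are vague: N(0, 10000) on all effects and control logits,
Uniform(0, 2) on σ. Inference is MCMC (a blocked Metropolis-within-Gibbs
sampler with exact conjugate updates for *a* and σ, or an
affine-invariant ensemble sampler), 2 chains with 50,000 burn-in and
100,000 kept draws by default, with bulk-ESS and split-R̂ diagnostics.
Results are reported as posterior means with 80% equal-tailed credible
intervals; a comparison is "significant" when its interval excludes the
null.

Two endpoint transforms close the loop between scales:

* **HAQ 20/50** — responder counts built from each arm's mean (SD) HAQ
  improvement by thresholding simulated patient improvements at 20%/50%
  of baseline HAQ;
* **ACRcont** — a continuous ACR response reconstructed from the nested
  ACR20/50/70 counts via group means: mean = (1/N) Σ N<sub>i</sub>
  m<sub>i</sub>, sd = √((1/N) Σ N<sub>i</sub> (m<sub>i</sub> − mean)²).

## Worked example

```python
from ra_mtc import datasets, workflows
from ra_mtc.inference import McmcConfig

trials = datasets.anti_tnf_trials()          # bundled 16-trial network
results = workflows.fit_outcome(trials, "haq", McmcConfig.fast(seed=1))
print(results.summary())
```

```
MTC results (continuous likelihood, 4 chains x 2500 draws)
 comparison      scale  mean  lo80  hi80 significant
   Ada vs P difference  0.21  0.18  0.23           *
   Inf vs P difference  0.10  0.05  0.15           *
   Eta vs P difference  0.31  0.24  0.38           *
   Gol vs P difference  0.23  0.16  0.29           *
  Cert vs P difference  0.25  0.22  0.29           *
 Inf vs Ada difference -0.11 -0.16 -0.05           *
 Eta vs Ada difference  0.10  0.03  0.18           *
 Eta vs Inf difference  0.21  0.12  0.30           *
 Gol vs Ada difference  0.02 -0.05  0.09
 Gol vs Inf difference  0.13  0.05  0.20           *
 Gol vs Eta difference -0.09 -0.18  0.01
Cert vs Ada difference  0.05  0.00  0.09           *
Cert vs Inf difference  0.16  0.10  0.22           *
Cert vs Eta difference -0.06 -0.14  0.02
Cert vs Gol difference  0.03 -0.04  0.10
      sigma         sd  0.03  0.01  0.06
min ESS 141, max R-hat 1.026
```

Read: etanercept improves HAQ by a further 31% of baseline relative to
placebo (80% CrI 24–38%); every agent beats placebo; etanercept beats
infliximab indirectly (0.21, CrI 0.12–0.30); the between-trial SD is
small (σ ≈ 0.03). Fitting the *dichotomized* version of the same endpoint
(`outcome="haq20"`) flags fewer pairwise differences — the power cost of
dichotomization. `results.forest_plot("haq.png")` draws the comparison
table; `results.comparisons()` returns it as a DataFrame.

The same surface works from a shell:

```bash
ra-mtc validate my_trials.csv
ra-mtc transform my_trials.csv --target acrcont --out acrcont.csv
ra-mtc fit my_trials.csv --outcome acr20 --seed 1 --plot forest.png
ra-mtc simulate --seed 7 --out synthetic.csv
```

Synthetic networks with known ground truth (`ra_mtc.synthetic_data`)
generate trials from the same equations the models fit, so interval
coverage and bias of the whole pipeline are themselves testable.

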