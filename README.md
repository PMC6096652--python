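# shootddm

Hierarchical Bayesian drift-diffusion modelling of deadline-limited
shoot/don't-shoot decisions, with a hierarchical signal-detection
baseline and a synthetic-data generator for validation by parameter
recovery.

## The problem

In the first-person shooter task a target appears holding either a gun or
a harmless object, and the participant must press "Shoot" or "Don't
Shoot" before a tight response deadline (630-850 ms).  Depending on the
deadline, race bias in such data shows up in error rates, in response
times, or weakly in both — which makes purely choice-based analyses
(signal detection theory) blind to part of the effect and unable to say
*where* in the decision process a manipulation acts.

`shootddm` models each trial as a drift diffusion process: evidence
accumulates from a start point `z = β·α` between absorbing boundaries at
`0` ("Don't Shoot") and `α` ("Shoot") with drift `δ` (positive toward
"Shoot") and unit diffusion coefficient, and the observed response time
is `rt = t_d + NDT`.  The four process parameters — relative start point
`β` (response bias), threshold separation `α` (speed-accuracy trade-off),
drift rate `δ` (evidence quality) and non-decision time `NDT` — are
estimated hierarchically: subject values are truncated-normal draws
around condition-specific group means `μ_i` with parameter-level
precisions `τ`,

    θ_{i,j} ~ N(μ_i, τ)  truncated,   μ ~ Uniform,   τ ~ Gamma.

Because short-deadline studies often *censor* late trials (choice and RT
unrecorded), censored trials enter the likelihood through their survivor
mass `1 − F_upper(w) − F_lower(w)` at the window `w`; ignoring this
demonstrably inflates drift estimates.  Condition effects are summarized
as posterior contrasts `μ_A − μ_B` with 95% highest-density intervals and
standardized effects `d = (μ_A − μ_B)·√τ`.  Start point and threshold may
vary over race/context/blur/study but never over object type (an
identifiability constraint); drift and NDT may also vary by object.

The intended users are decision scientists and social cognition
researchers analysing many-subjects / few-trials choice-RT designs.

## Worked example

`examples/02_fit_hierarchical_ddm.py` generates a 25-subject × 80-trial
dataset in which *only* the drift rate carries a race effect (+0.5 for
Black targets), fits the full hierarchical model (2 chains, 600 warmup +
600 kept sweeps, a few seconds on one CPU) and prints:

```
25 subjects, 2000 trials
parameter                     cell    mean  hdi_lo  hdi_hi  rhat     ess
     beta               race=black   0.527   0.485   0.569 1.012 156.675
     beta               race=white   0.553   0.514   0.600 1.024 119.196
    alpha               race=black   1.079   1.019   1.145 1.015 119.800
    alpha               race=white   1.072   1.012   1.132 1.014 184.541
    delta    race=black,object=gun   2.569   2.249   2.932 1.023 126.411
    delta race=black,object=nongun  -1.489  -1.832  -1.215 1.013 162.566
    delta    race=white,object=gun   1.787   1.492   2.073 1.007 170.869
    delta race=white,object=nongun  -1.880  -2.191  -1.576 1.004 176.812
      ndt    race=black,object=gun   0.303   0.288   0.324 1.005 245.636
      ndt race=black,object=nongun   0.330   0.312   0.347 1.005 160.425
      ndt    race=white,object=gun   0.299   0.282   0.318 1.020 286.474
      ndt race=white,object=nongun   0.339   0.321   0.356 1.005 130.880
 ...
race contrasts (black - white), marginal over the other factors:
  beta   M = -0.026 [-0.081, +0.038] d = -0.32
  alpha  M = +0.007 [-0.076, +0.094] d = +0.07
  delta  M = +0.586 [+0.243, +0.948] d = +1.15 *
  ndt    M = -0.003 [-0.019, +0.015] d = -0.06
```

Each row gives a group-level mean per design cell with its 95% HDI and
convergence diagnostics (drift is signed: positive toward "Shoot", hence
gun cells near +2 and non-gun cells near −2).  In the contrast block the
planted drift effect is the only one whose HDI excludes zero (`*`): the
model localizes the manipulation to the right process parameter, with
`d` expressing it in units of the group-level SD.

The other examples cover the Wiener core against brute force (`01`), the
SDT baseline (`03`), what censoring-blind fitting does to drift (`04`), a
miniature selective-influence suite (`05`) and the cross-study composite
fit (`06`).  A thin CLI exposes the pipeline
(`shootddm simulate|run|fit|sdt|contrast|ppc|recover|composite|report`).

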