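# crmkit

Bayesian continual reassessment method (CRM) dose-finding for
cohort-synchronous phase I trials, plus a Fleming–A'Hern single-stage
phase II calculator. The package covers the full statistical life cycle
of a model-based dose-finding design: calibrating the prior (skeleton
and slope SD), running the escalation engine on accumulated trial data,
auditing the design by exhaustive dose-transition-pathway enumeration,
and estimating operating characteristics by Monte-Carlo simulation.

It is written for trial statisticians designing early-phase studies —
the default configuration is a five-level design (200–1000 mg daily
seliciclib in rheumatoid arthritis, target DLT rate 35%, cohorts of 3,
maximum 21 patients), but every parameter is configurable.

## The model

The probability of a dose-limiting toxicity (DLT) at scaled dose *x* is
a one-parameter logistic curve with fixed intercept,

&nbsp;&nbsp;&nbsp;&nbsp;ϑ(x, β) = exp(3 + e^β x) / (1 + exp(3 + e^β x)),

with prior β ~ N(0, σ_β²). Writing the slope as e^β keeps the curve
increasing in dose for every β. The scaled doses are pinned to the
skeleton p₁ < … < p_K of prior DLT probabilities through
x_k = logit(p_k) − 3, so that ϑ(x_k, 0) = p_k. After each cohort the
posterior p(β | data) ∝ exp(−β²/2σ_β²) · ∏ᵢ ϑ(xᵢ,β)^{yᵢ}(1−ϑ(xᵢ,β))^{1−yᵢ}
is evaluated by adaptive quadrature, and the next cohort is assigned the
level whose estimated DLT probability is closest to the target θ,
without skipping untested levels on escalation.

Two early-stopping rules apply: (1) stop for toxicity when the posterior
probability that the lowest dose's DLT rate exceeds θ passes 0.7;
(2) stop and confirm the MTD once four consecutive cohorts sat at one
level that remains the recommendation.

Calibration follows the indifference-interval approach: for a half-width
δ, the skeleton is built by the `getprior`-style recursion around the
prior MTD level, and σ_β is chosen *least informative* — the value at
which the prior distribution of the MTD level has the SD of a discrete
uniform, √((K²−1)/12).

## Worked example

Calibrate the default design and inspect it:

```
$ crmkit skeleton --delta 0.06
 dose_level  skeleton
          1  0.135547
          2  0.233124
          3  0.350000
          4  0.468711
          5  0.574698

$ crmkit sigma-li --delta 0.06
0.264800
```

The skeleton rounds to (0.14, 0.23, 0.35, 0.47, 0.57) and the
least-informative prior SD to 0.265: dose level 3 (600 mg) carries the
target 35% a priori, and with σ_β = 0.265 each of the five levels has
prior probability ≈ 0.2 of being the MTD.

Run the engine on a trial in progress — two clean-ish cohorts, at level
2 (0/3 DLTs) then level 3 (1/3):

```
$ crmkit recommend --history hist.csv
state: continue
recommended_level: 4
mtd_level: None
beta_mean: 0.0976...
prob_lowest_toxic: 0.0197...
posterior_dlt_probs: [0.087, 0.165, 0.271, 0.390, 0.506]
```

The posterior pulls the curve down (β̂ > 0: drug safer than the prior
expected), level 4's estimated DLT rate 0.39 is closest to 35%, and the
probability that the lowest dose is over-toxic is negligible, so the
trial escalates to level 4.

Simulate operating characteristics under a curve whose true MTD is
level 3 (true DLT probabilities 0.21/0.21/0.35/0.52/0.52):

```
$ crmkit simulate --scenario 0.21,0.21,0.35,0.52,0.52 --reps 500 --seed 1
 true_mtd_level   pcs  ...  mean_prop_overdose  mean_prop_within_one  mean_n_treated
              3 0.598  ...            0.219048                0.9463           19.74
```

About 60% of simulated trials select the correct MTD, 95% of patients
are treated within one level of it, and trials average ~19.7 of the 21
allowed patients (early MTD confirmation shortens some).

Size the phase II study (reject the drug below a 25% composite response
rate, pursue it above 50%, α ≤ 0.15, β ≤ 0.20):

```
$ crmkit ahern --p0 0.25 --p1 0.50 --alpha 0.15 --beta 0.20
n = 15, critical responses r = 6 (attained alpha = 0.1484, power = 0.8491)
```

Other commands: `prior-mtd` (prior MTD distribution for any σ_β),
`calibrate-delta` (the δ-grid simulation harness), `dtp`
(dose-transition pathway enumeration as JSON/CSV), `phase2-evaluate`
(composite two-of-three response evaluation), `report` (per-dose
posterior DLT table with 90% probability intervals).

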