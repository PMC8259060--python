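# Methods

## Dose-toxicity model

The design uses the one-parameter Bayesian logistic model
ϑ(x, β) = expit(3 + e^β x) with a fixed intercept of 3 and a single
slope parameter β ~ N(0, σ_β²). The exponentiated slope guarantees a
monotone increasing dose-toxicity curve for every β. Doses enter the
model only through their scaled values x_k = logit(p_k) − 3, where p_k
is the skeleton entry of level k; the administered mg amounts are
labels. Because every skeleton entry of interest is far below
expit(3) ≈ 0.95, all scaled doses are negative and toxicity at every
level is *decreasing* in β: positive posterior means indicate a drug
safer than the prior guess.

The maximum tolerated dose (MTD) is defined throughout as the level
whose (estimated or true) DLT probability is closest to the target θ,
with ties broken toward the lower, safer level. Ties occur only on a
measure-zero set of β, so the convention matters for determinism, not
for results.

## Posterior computation

All posterior quantities are one-dimensional integrals over β:

* normaliser Z = ∫ exp(−β²/2σ²) L(β) dβ, with L the Bernoulli
  likelihood of the accumulated (dose, DLT) pairs;
* posterior mean of β;
* the rule-1 statistic P(ϑ(x₁, β) > θ_L | data) = ∫_{−∞}^{β_L} p(β|data) dβ,
  with β_L = log((logit(θ_L) − 3)/x₁), the slope below which the lowest
  dose's DLT rate exceeds θ_L.

Integrals use adaptive quadrature (scipy QUADPACK, absolute tolerance
1e−12, relative 1e−10) on β ∈ [−L, L] with L = max(10 σ_β, 8). The
integrand decays super-exponentially on the right (the likelihood
involves e^β) and is prior-dominated on the left; at L the prior tail
mass is below 1e−12. The likelihood is evaluated in log space
(`logaddexp`) to avoid underflow for extreme β. A `QuadratureError`
with diagnostics is raised if the estimated quadrature error is not
small relative to the result. A test cross-checks the quadrature
against importance sampling from the prior (10⁶ draws, 20 randomised
histories, three Monte-Carlo SEs) and against dense-grid trapezoid
integration.

Per-dose toxicity estimates default to the *plug-in* convention,
ϑ(x_k, E[β|data]) — the convention of the dfcrm software lineage. The
posterior-mean convention E[ϑ(x_k, β)|data] is available via
`DesignSpec(tox_estimate="posterior_mean")`; which one the original
trial software used is not documented, so both are supported and the
default is stated here. The two differ by well under a percentage point
for realistic histories and never change the examples tested.

Posterior computations are memoised on the per-level sufficient
statistics (n treated, n DLT), which is what makes whole-trial
simulation with a full quadrature posterior per cohort affordable:
thousands of simulated trials revisit a few hundred distinct count
states.

## Calibration

Skeleton: for an indifference-interval half-width δ, level ν (the prior
MTD) is pinned at θ. Upward from ν, the slope e^b solving
ϑ(x_k, b) = θ − δ places x_{k+1} where that same curve reaches θ + δ;
downward the roles of θ ± δ are exchanged. Skeleton entries are the
placed doses evaluated at β = 0. With δ = 0.06, θ = 0.35, ν = 3, K = 5
this yields (0.1355, 0.2331, 0.35, 0.4687, 0.5747).

Prior MTD distribution: since every level's toxicity decreases in β,
MTD(β) = argmin_k |ϑ(x_k, β) − θ| is nondecreasing in β and each
level's selection region is an interval. The switch point between
levels k and k+1 solves ϑ(x_k, β) + ϑ(x_{k+1}, β) = 2θ (the two levels
straddle the target equally) and is found by Brent root-finding; the
probabilities are normal-CDF differences. This exact integration
replaces the Monte-Carlo sampling used by the classical `mtrials`
routine; the Monte-Carlo version survives as a test oracle. Exactness
matters for the next step: the least-informative σ_β is the root of
sd(MTD index)(σ) = √((K²−1)/12) (≈ √2 for K = 5), found by Brent's
method on [0.01, 5] after verifying sd is increasing across the
bracket. For the δ = 0.06 skeleton the root is 0.26480; the design
default uses the published rounded value 0.265.

## Escalation engine

Decisions are cohort-synchronous. After each complete cohort, in order:

1. **Rule 1 (toxicity):** stop without an MTD if
   P(DLT rate at level 1 > θ_L | data) > 0.7. θ_L defaults to θ.
2. **Rule 2 (MTD confirmed):** stop and declare the current level the
   MTD if the most recent 4 cohorts all sat at it *and* it is also the
   next recommendation. Only the most recent unbroken run counts.
3. **Sample-size cap:** at 21 patients, declare the model argmin over
   all K levels.

Rule 1 is evaluated before rule 2 so a toxic signal dominates; the
source design lists the rules in this order without stating precedence.
The next-cohort recommendation is the model argmin capped at one level
above the highest level yet administered (no skipping on escalation;
de-escalation is never restricted). The cap governs *assignment* only:
the MTD declared at the cap is the uncapped argmin, on the view that
the declaration should reflect the model, not the path; a
`restrict_mtd_to_tested` switch confines it to administered levels.

A consequence verified by exhaustive pathway enumeration: the only
first-cohort outcome that de-escalates from the level-2 start is 3/3
DLTs (2/3 makes the engine stay), and on that pathway 2 or 3 DLTs among
the first level-1 cohort trigger rule 1. A standalone history of just
3 patients at level 1 with 2 DLTs yields a rule-1 probability of 0.46 —
below the threshold — because it lacks the de-escalation cohort's
evidence; 3/3 alone yields 0.72.

## Operating-characteristics simulation

Trials are simulated by driving the real escalation engine with
Bernoulli cohort outcomes under an assumed true dose-DLT curve. The
benchmark curves are the plateau calibration configurations for
θ = 0.35: 0.21 below the true MTD, 0.35 at it, 0.52 above. Measures:

* **PCS** — probability of selecting the true MTD. Trials stopped by
  rule 1 select nothing: they stay in the denominator and contribute to
  a no-selection mass (selection probabilities plus no-selection sum to
  one). Toxic stops are rare (< 1%) on curves 2–5, so this convention
  is numerically inconsequential there.
* **Accuracy index** A = 1 − c·(Σ_k ρ_k|π_k − θ|)/(Σ_k |π_k − θ|), with
  ρ the selection and π the true-toxicity vectors. Both the standard
  K-multiplied form (c = K) and the unmultiplied variant (c = 1) are
  reported, because the source tables are internally inconsistent: the
  δ-grid summary (~0.46) matches c = K while the scenario table (≥0.91)
  matches c = 1. Neither is treated as a reproduction target.
* **Allocation measures** — per-trial proportions of patients treated
  above, and within one level of, the true MTD, averaged per trial then
  across trials (each trial weighted equally regardless of its size);
  and the mean number treated.

Replicates draw from independent child streams spawned from the seed
(`numpy` SeedSequence), so results are bit-reproducible and independent
of evaluation order. The δ-grid harness rebuilds the skeleton and
recomputes σ_β^LI for each δ before simulating, and summarises curves
2–5 (the levels where accuracy matters; level 1 was considered unlikely
to be efficacious) including the 4-value sample SD of the accuracy
index.

Default problem sizes: the package ships with 2,000 replicates per
curve in the harness, tests and acceptance script; the original
calibration used 20,000. At 2,000 the Monte-Carlo SE of a selection
probability is ≈ 0.011, small against the effects of interest; the
`simulate` command prints the SE implied by the chosen replicate count.
Tests compare simulated measures to reference values within three
combined Monte-Carlo standard errors.

## Dose-transition pathways

`enumerate_pathways` expands every (cohort, DLT-count) sequence up to a
horizon, recording for each branch exactly the engine's action — the
branching factor is cohort size + 1, and stop branches are leaves.
Exports are nested JSON or a flat edge-list DataFrame/CSV (optionally
with per-path probabilities under a true curve); no figure rendering.
`selection_distribution` pushes binomial branch weights through the
full-horizon tree, giving the *exact* selection distribution of the
design under a scenario; a test confirms the Monte-Carlo simulator
agrees within sampling error. `next_cohort_table` is the one-step
look-ahead used during conduct: the action for every possible outcome
of the pending cohort.

## Phase II

The Fleming–A'Hern calculator searches n = 1, 2, … and r = 0..n for the
first pair satisfying the exact binomial constraints
P(X ≥ r | n, p0) ≤ α and P(X ≥ r | n, p1) ≥ 1 − β; attained errors are
reported. The stated error bounds are printed as strict inequalities in
the source; they are implemented as ≤ with configurable bounds, since
exact ties are measure-zero in the inputs. For p0 = 0.25, p1 = 0.50,
α ≤ 0.15, β ≤ 0.20 the enumeration gives (n = 15, r = 6); the original
trial recruited 18 with an undisclosed critical value, so the
calculator reports the enumerated optimum rather than hard-coding 18.
The composite response rule is mechanical: responder iff assessable at
12 weeks and at least two of the clinical / histological / imaging
flags are true, with missing flags counting as not met; the response
rate denominator is all patients who started treatment.

## What the simulations do and do not show

The simulator emulates the design's stochastic behaviour exactly as
specified: binomial cohort outcomes from a fixed true curve, full
cohorts, instant outcome availability. Real trials deviate — attrition
within cohorts, partial follow-up at decision time, outcome
misclassification, and drift in the patient population are not
modelled. Operating characteristics here validate the *design logic*,
not the clinical conduct. Known limitations: a single binary toxicity
endpoint (no TITE weighting for late-onset events, no two-parameter or
EWOC variants); the plateau curves are tabulated only for θ = 0.35;
the rule-1 statistic assumes the one-parameter model is correctly
specified at the lowest dose.
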