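# Methods

## Effect-size harmonization

Published associations between a striatal dopamine PET measure and a
discounting index arrive in heterogeneous forms. Harmonization proceeds in
three steps.

1. **To a correlation.** If a study reports t and df instead of r,
   r = sign(t)·√(t²/(t² + df)). Partial correlations and Spearman
   coefficients are accepted as reported; no additional correction is
   applied.
2. **To Fisher z.** z = artanh(r), SE = 1/√(n − 3). The n − 3 convention is
   used for *all* effects, including partial correlations — no
   degrees-of-freedom penalty for covariates. This matches the convention of
   the published table the package reproduces (e.g. n = 109 → SE = 0.097)
   and keeps weights comparable across rows.
3. **Sign alignment.** Indices that *increase* with discounting (k, Ln k,
   proportion of smaller/sooner choices) keep their sign; indices that
   *decrease* with it (area under the discounting curve, proportion of
   larger/high-effort choices) are flipped, as is an effect reported against
   a drug-occupancy measure that is inversely related to the underlying
   availability measure (`occupancy_correlate`). After alignment, positive z
   always means "more of the dopamine measure goes with steeper
   discounting".

When a study reports one correlation per within-task sub-condition,
`pool_subcondition_effects` averages the Fisher-z values arithmetically.

Effects from the same sample (e.g. baseline-binding and release measures in
the same 12 subjects) enter as independent rows. This mirrors the analysis
being reproduced but understates their joint information; a multilevel model
would be the principled alternative and is a known limitation. A study
reporting only a quadratic (inverted-U) relation carries an explicit exclude
flag in the bundled table rather than being silently omitted.

## Random-effects meta-regression

Model: zᵢ ~ N(xᵢ'β, vᵢ + τ²) with vᵢ = seᵢ² known. τ² is estimated by
restricted maximum likelihood, profiling the restricted log-likelihood

    ℓ(τ²) = −½(k−p)·log 2π + ½log|X'X| − ½Σ log(vᵢ+τ²)
            − ½log|X'WX| − ½Σ wᵢ(zᵢ − xᵢ'β̂)²,   wᵢ = 1/(vᵢ+τ²),

over τ² ∈ [0, max(10·Var(z), 1)] with a bounded scalar optimizer
(tolerance 1e−10, cap 1000 iterations); τ² snaps to 0 when the boundary is
at least as good. β̂ is weighted least squares at the optimum, with Wald
(normal) tests and 95% CIs using the fixed multiplier 1.959964 — not
t/Knapp–Hartung, since the results being reproduced report Z statistics.
The log|X'X| constant is retained so AIC = −2ℓ + 2(p+1) (τ² counted as a
parameter) follows the convention of mainstream meta-analysis software and
is directly comparable with it. REML likelihoods across different
fixed-effect structures are not strictly comparable; `compare_models` ranks
by AIC but flags this caveat.

Heterogeneity statistics: QE is the weighted residual sum of squares at
fixed-effect (τ² = 0) weights; QM is the joint Wald statistic of the
non-intercept coefficients (of the intercept in the intercept-only model);
I² = 100·τ²/(τ² + s²) with the generalized typical within-study variance
s² = (k−p)/tr(P), P = W − WX(X'WX)⁻¹X'W at fixed-effect weights, which
reduces to the Higgins–Thompson form for an intercept-only model and stays
defined under moderators.

Moderators are dummy-coded with healthy group and D2-receptor target as
reference levels. In the group × tracer interaction model several cells are
empty (addiction effects exist only for D2-receptor tracers; the only DAT
effect is in the other-psychopathology group), so the corresponding columns
are empty or collinear. They are dropped with a logged message and surfaced
in the fit report (`dropped_columns`) rather than silently discarded.

Degenerate inputs: fits require at least as many effects as coefficients;
with fewer than p + 2 effects τ² is weakly identified and a warning is
logged (the saturated case pins τ² at 0). Back-transformed group
predictions use r = tanh(z) applied to the point estimate and both CI
endpoints.

## Publication-bias diagnostics

The Egger-type test augments the chosen moderator design with each effect's
standard error as one more fixed effect and refits the same REML
random-effects model; the Wald z of the SE coefficient is the statistic.
This is the moderated-model variant (equivalent to the "predictor = sei"
regression-test convention) rather than the classical weighted OLS of z/se
on 1/se, because the test is applied to moderated models. One variant is
applied uniformly to all model structures. Funnel data are residuals
(observed z minus model prediction) against SE, with two-sided
pseudo-confidence bands at 0.90/0.95/0.99 of half-width
z_crit·√(se² + τ²).

Under a simulated null (no small-study effect) the test's empirical type-I
error at α = 0.05 is verified to lie in [0.01, 0.10] over 1000 replicates of
30-effect collections.

## Discounting model estimation

The Bernoulli log-likelihood of the observed choices under
P(smaller) = logistic(slope·ΔSV) is maximized over (k, slope) in the box
k ∈ [0, 5] (per unit transformed cost), slope ∈ [0, 50] (per currency
unit). The likelihood is multimodal-prone and flat in several regimes, so
the scheme is deterministic multistart: the likelihood is evaluated on a
fixed 8×8 log-spaced lattice of start values, bounded L-BFGS-B runs are
launched from the eight best lattice points, and the best converged optimum
is returned. No stochastic optimizer is used, so fits are exactly
reproducible.

A fit is flagged `boundary` when (a) every choice was the same option,
(b) a parameter lies at the box edge, or (c) the optimum fails to beat the
random-responder model (slope = 0, P = ½ everywhere) by the joint 95%
likelihood-ratio bound, 2·ΔLL < χ²₀.₉₅(2) — in that regime the likelihood
is essentially flat in k and the parameters are not identified. The
flat-likelihood clause exists because a pure box-edge check cannot detect
unidentifiable random responders whose fitted slope is small but nonzero.

Both k and Ln(k + 1) are reported (the latter because k is strongly
right-skewed across subjects), plus the model-free proportion of
smaller-reward choices.

Time costs are expressed in days with week = 7 and month = 30 for menu
construction. Expected choice proportion increases with k only over the
behaviorally plausible range: as k → ∞ all costly options approach zero
value and choice drifts back to indifference, so monotonicity checks are
restricted to that range.

## Synthetic data

**Choice datasets.** Trials are drawn from the factorial task menus: time —
today/2 wk/1 mo vs 2 wk/1 mo/6 wk (84 trials, younger-adult variant) or
today/2 mo/4 mo vs 2 mo/4 mo/6 mo (82 trials, life-span variant);
probability — higher win probability 50/75/100% with the lower one 25 or 50
points below (82 trials); effort — lower requirement 35/55/75% of maximum
press rate with the higher one 20 or 40 points above, capped at 95%
(82 trials). The larger magnitude is uniform on 10–50 currency units
(configurable; only the relative discount is externally constrained) and
the smaller option is 1–50% lower, uniformly. Choices are Bernoulli draws
from the softmax model, deterministic given the seed.

What this does *not* emulate: trial-order effects, within-session learning
or fatigue, the individually calibrated button-press counts of the effort
task, and real subjects' deviations from the hyperbolic/softmax form.
Passing recovery tests therefore demonstrates estimator correctness under
the assumed model, not model adequacy for real data.

**Effect collections.** Each simulated effect draws a group label from
configurable proportions (default 0.50/0.29/0.21, mirroring the 7/4/3
composition of the bundled table), a sample size uniform on 10–30
(small-study regime), a true Fisher z = group mean + N(0, τ²), and an
observed z = true z + N(0, 1/(n−3)). Default group means (−0.138, −0.754,
0.655) mirror the group-level values implied by the published moderated
fit; default τ² = 0.05 is of the order estimated there. `noise_scale`
scales both noise terms (0 gives exact group means, useful for degenerate
checks). The generator assumes the estimating model is true — no selective
reporting, no correlated effects within study — so recovery results
quantify estimator behavior, not robustness to misspecification.

## Verification strategy and problem sizes

The bundled 14-effect table is checked row-for-row against the published
harmonized values at printed precision, and every fitted quantity
(coefficients, SEs, τ², Q statistics, I², AIC, back-transformed
correlations, Egger Z) is additionally cross-checked at tight tolerance
against frozen values from an independent reference implementation run on
identical inputs. REML τ² is verified against an iteratively refined dense
grid search of the restricted likelihood (agreement to 1e−6); the
discounting MLE against a dense log-spaced likelihood lattice (the MLE must
match or beat the best cell and lie within one cell of it — log-spaced
because both parameters are scale parameters and a linear lattice cannot
resolve the small-k region).

Simulation studies use: 200 subjects per domain for discounting recovery
(k log-uniform over ranges matching observed per-task Ln(k+1)
distributions, slope 0.5), 500 replicates of 50-effect collections for
meta-regression coefficient recovery (means within 3 Monte-Carlo SEs of
truth), 300 replicates for τ² recovery (median within 15%), and 1000
replicates for Egger calibration. These sizes keep the full suite to a few
minutes on one CPU while leaving Monte-Carlo error well below the tested
tolerances.

## Known limitations

- Same-sample effects are treated as independent (no multilevel nesting).
- The Egger variant is applied uniformly; results for variants differing
  from the original analyses may differ slightly.
- AIC comparability relies on a specific restricted-likelihood constant
  convention; AICs from software using other conventions differ by a
  constant.
- The interaction model's coefficients depend on which empty-cell columns
  are dropped; the dropping order (groups, then tracers, then interactions)
  is fixed and surfaced, but other orders would parameterize the same fit
  differently.
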