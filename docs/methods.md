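# Methods

`wprdm` implements a blinded, two-stage Bayesian analysis of the worst
performance rule (WPR) — the claim that the *slowest* response-time (RT)
quantiles of an elementary two-choice task correlate most strongly
(negatively) with cognitive ability — together with its diffusion-model
explanation, on synthetic populations whose causal structure is fully
controlled.

## The decision model

Each trial is a Wiener diffusion between absorbing bounds at 0 and α
(boundary separation), starting at z = w·α with w = 0.5, drifting at rate ν
with within-trial diffusion coefficient s; observed RT adds a non-decision
time τ.  We fix **s = 1** throughout: only ν/s and α/s are identified, and a
single documented scaling constant avoids silently rescaled parameters (the
0.1 convention common elsewhere multiplies drifts and boundaries by 10).
Typical magnitudes under s = 1 are therefore ν ≈ 1–4 and α ≈ 1–2.

The fitted likelihood is the **4-parameter** first-passage density
f(t−τ | ν, α, w): across-trial variability parameters of the fuller
seven-parameter model are available in the simulator (`sv`) but are never
part of the estimated likelihood — they are weakly identified at the trial
counts modelled here, and every estimand of interest (correlations of ν and
α with an ability score) is defined in the 4-parameter core.

The density is evaluated by the standard pair of series expansions in
standardized time u = (t−τ)/α²: the small-time representation (sum over
mirrored start points) and the large-time representation (sine series),
switching to whichever needs fewer terms for truncation error below 1e-7.
This keeps both RT tails accurate; the normalisation check in the tests
(|∫(upper+lower) − 1| < 1e-4 over a parameter grid) exercises exactly this
rule.  The closed-form absorption probability
P(upper) = (1 − e^{−2νzw·α})/(1 − e^{−2να}) uses the analytic ν→0 limit w.

### Simulator

`simulate_trials` integrates the SDE by Euler–Maruyama, default
dt = 0.5 ms.  Discrete-time monitoring of a continuous barrier
systematically *misses* crossings, biasing choice fractions and mean
decision times by O(√dt) — larger than Monte-Carlo error at the n = 20000
calibration sizes used in the tests.  Both barriers are therefore shifted
inward by the continuity correction 0.5826·s·√dt, after which the residual
bias is O(dt) and invisible next to sampling noise.  The synthetic-data
generator uses dt = 1 ms (with the same correction) since population-level
correlations are insensitive at that resolution; the per-trial default
remains 0.5 ms.

## The synthetic populations

`synthetic_data` draws participant parameters from a six-dimensional
multivariate normal over (ν_easy, ν_hard, ν_undoable, log α, log τ, WMC);
boundary and non-decision time live on the log scale so positivity is
structural, and all configured correlations are correlations of that latent
normal.  Defaults mirror the task the analyses assume: 916 participants,
90 easy + 90 hard + 45 "undoable" 50/50 trials, responses at or beyond
3.5 s censored (cutoff closed: rt ≥ 3.5 s is excluded), WMC standard
normal.  Population means/SDs — ν_easy ~ (3.0, 1.0), ν_hard ~ (1.5, 0.8),
ν_undoable ~ (0, 0.3), α median 1.4 (log-SD 0.25), τ median 0.30 s
(log-SD 0.20), easy–hard drift correlation 0.6 — were chosen once as
values a practitioner would call typical for a dot-discrimination task
(they imply ≈96% easy and ≈85% hard accuracy and mean RTs near 0.5–0.7 s)
and are not tuned thereafter.  The undoable-trial count, unstated in the
task description we emulate, defaults to 45 and is configurable.

Three shipped presets differ only in the coupling to WMC:

* **wpr_true** — WMC correlates with drift (0.4 easy, 0.5 hard), not with
  caution.  The diffusion account then *predicts* the WPR: quantile–WMC
  correlations negative and steepening with quantile level.
* **caution_confound** — WMC correlates with log boundary (0.5) only:
  positive correlations that *increase* over levels, the signature that
  can mask a true WPR.
* **null** — no coupling at all.

Contamination (`apply_contamination_and_censoring`) replaces a configured
Bernoulli fraction of trials with uniform-RT (0.1 s to cutoff),
random-response trials — the standard contaminant model, present to
exercise the exclusion filters, default rate 0.

What the generator does **not** emulate: the item-level working-memory
battery (a single score stands in), sequential effects, practice and
fatigue drifts, response biases (w ≠ 0.5), and site/demographic structure.
A passing recovery test therefore shows the *inference machinery* is
correct under the stated population model, not that real data meet it.

## Preprocessing and the correlation curve

Default exclusions: censored trials, rt ≥ 3.5 s (closed cutoff), and fast
guesses rt < 0.2 s; every dropped row is accounted per filter and per
participant, and participants left with < 20 correct trials per difficulty
are flagged.  These rules are explicit stand-ins for choices an analyst
would freeze during the blinded stage.

Per participant and difficulty we take correct-trial RT quantiles at
levels I = (1/6, …, 5/6) with the linear order-statistic interpolation
convention (`numpy` "linear"), so results are bit-reproducible.  The
correlation curve is the Pearson correlation r_i between WMC and the
quantile *values* at each level; "mean RT within each band" is an
alternative reading of the same construct, provided as `mode="band_mean"`
(six bands cut at the five quantiles) behind a config switch, with the
quantile-value mode the documented default because it is deterministic
given the levels and matches the descriptive panel axes.

## Blinding

`blind_key_variable` permutes *only* the WMC column with a seeded
permutation, sealed in a JSON `BlindingRecord` (seed, permutation, key
column, timestamp); `unblind` verifies the record is a bijection of the
right length and restores the original order exactly.  The pipeline's gate
is enforced, not advisory: a confirmatory run in blinded mode refuses to
start without a valid record, rejects the identity permutation, and stamps
every summary "meaningless by construction".

## The confirmatory models

**H1 (linear WPR).**  Sample correlations are taken to the Fisher z scale,
where z_i = atanh(r_i) ~ N(atanh(ρ_i), 1/(n−3)) independently over the five
levels, with ρ_i = β0 + β1·I_i.  The model itself specifies only the
priors and the linear link; the independent Fisher-z likelihood is the
standard sampling model for a correlation and is our documented choice —
the ignored between-level dependence (quantiles of the same participants)
makes the test mildly conservative in the Bayes factor's favour at these
n.  Priors: β0, β1 ~ U(−1, 0) independently (the confirmatory direction:
all correlations negative, steepest admissible slope −1), jointly truncated
to keep every ρ_i inside (−1, 1) — without the truncation ρ at I = 5/6
could leave the admissible range.  The exploratory "released" variant uses
U(−1, 1)² with the same truncation.  Evidence for β1 = 0 is the
Savage–Dickey ratio BF10 = p(β1=0|H1)/p(β1=0|data,H1); the prior ordinate
is computed by quadrature of the truncated region (12/7 ≈ 1.714 at the
default levels, constrained mode).

**H2 (difficulty difference).**  Both curves are refit jointly with
negative slopes of magnitude β1*_c ∈ (0,1), probit-orthogonalized:
Φ⁻¹(β1*_hard) = μ + δ/2, Φ⁻¹(β1*_easy) = μ − δ/2, with μ ~ N(0,1),
δ ~ N(0,1)⁺ (folded normal) and per-condition intercepts β0_c ~ U(−1,0).
δ = 0 is tested by Savage–Dickey; the prior ordinate is again
truncation-aware (numerically ≈ 0.84, vs the untruncated folded-normal
mode 2φ(0) ≈ 0.798).

**H3 (drift–WMC correlation).**  Full hierarchical fit of one difficulty:
per-trial 4-parameter Wiener likelihood, accuracy-coded (upper boundary =
correct; left/right collapsed; response coding retained only for the
undoable trials, whose own drift ~ N(μ_u, σ_u²) is centred near zero and
whose trials sharpen α_p and τ_p).  WMC enters as an observed variable in
the population model: (ν_p, WMC_p) bivariate normal, WMC standardized, so
ν_p | w_p ~ N(μ_ν + ρσ_ν w_p, σ_ν²(1−ρ²)) with ρ ~ U(0,1) under the
alternative.  Group priors (all configurable): μ_ν ~ N(2,3),
σ_ν ~ half-N(2); μ_α ~ N(1.5,1)⁺, σ_α ~ half-N(1); μ_τ ~ N(0.3,0.3)⁺,
σ_τ ~ half-N(0.5); μ_u ~ N(0,1), σ_u ~ half-N(1).  Boundary and
non-decision latents are truncated normals (α_p > 0.05;
0 < τ_p < 0.95·min observed RT of p, the non-identifiability guard), and
their truncation constants are included in the group-level conditionals.
Censored trials are excluded rather than likelihood-truncated — simpler,
and consistent with the preprocessing defaults.  The truncated-normal
group location parameters are *not* the latent means when the bounds bind
(τ especially); per-participant posterior means are the interpretable
summaries.

**H4 (difference of correlations).**  (ν_easy, ν_hard, WMC) trivariate
normal with ρ_hard = Φ(μ + δ/2), ρ_easy = Φ(μ − δ/2), μ ~ N(0,1),
δ ~ N(0,1)⁺, and a free drift–drift correlation r ~ U(−1,1); positive
definiteness of the implied 3×3 correlation matrix is enforced by
rejection.  α_p and τ_p are shared across difficulties (the assumed
design).  The fit exports per-participant boundary posterior means for the
caution-subgroup analysis.  The prior ordinate of δ at 0 under the
PD truncation evaluates to 2φ(0)·(2/3)/Z by quadrature (the admissible
r-interval at δ=0 has length 2(1−Φ(μ)²), and E[1−Φ(μ)²] = 2/3).

## Samplers

No general-purpose MCMC backend for hierarchical likelihoods of this form
is bundled with the package's dependency set, so sampling is split by
model size:

* The 2–4 dimensional curve models use the affine-invariant ensemble
  sampler (`emcee`), 16 walkers × (750 burn + 1000 kept) by default.
  Because walkers within one ensemble interact, the convergence gate runs
  **four independent ensembles** from different seeds and computes split
  R-hat *across* ensembles (arviz); the default gate is R-hat < 1.01 and a
  violation raises a diagnostics error rather than returning silently.
* The hierarchical diffusion models use a bespoke adaptive
  Metropolis-within-Gibbs sampler: per-participant random-walk updates
  (drift; a joint boundary/non-decision block) vectorised across
  participants through a compiled per-participant log-likelihood kernel,
  then component-wise random-walk updates of the group parameters
  (repeated three times per sweep).  Proposal scales adapt by
  Robbins–Monro toward acceptance 0.44 (scalar blocks) / 0.30 (the 2-D
  block) during warmup and are frozen afterwards.  Defaults: 2 chains ×
  (600 warmup + 1000 kept); split R-hat across chains on the group
  parameters, gate 1.05.  Initial values come from EZ-style moment
  estimates (accuracy, RT mean and variance) jittered per chain.

## Bayes-factor estimation

`bayes_eval.savage_dickey_bf` estimates posterior ordinates by Gaussian
KDE with Silverman bandwidth and **reflection** about any finite support
bound: kernel mass leaking outside the support is folded back, which
removes the factor-of-two bias of a plain KDE at an edge (the uniform test
case recovers an ordinate of 1.0 at the boundary rather than 0.5).  The
estimator, bandwidth and sample count are recorded in every result.

For the two curve models the package instead uses a **Rao-Blackwellised
conditional ordinate**: the 1-D conditional density of the test parameter
(β1 or δ) is integrated exactly on a grid for each retained draw of the
remaining parameters, after re-expressing those parameters in linear
combinations decorrelated from the test parameter (otherwise the ridge
correlation between intercept and slope makes the conditional ordinate
itself high-variance).  This estimator is free of boundary bias and has
far smaller Monte-Carlo error than the KDE at equal chain length — with
the KDE, the ordinate at the constrained boundary fluctuated by ~10–15%
across seeds; the conditional estimator brings agreement with direct
quadrature of the marginal likelihoods to a few percent.  Savage–Dickey
ordinate ratios are only quantitatively meaningful while the posterior
retains visible mass at the null point; once a BF exceeds ~10³ the
reported magnitude says "overwhelming" and no more.

The descriptive scatter panels are annotated with default-prior slope
Bayes factors: the Zellner–Siow mixture-of-g BF for a single standardized
covariate, scale √2/4, computed by 1-D quadrature of the closed per-g
Bayes factor against the InverseGamma(1/2, n·r²/2) mixing density; it is
invariant to affine rescaling of both variables.

## Pipeline, seeds, determinism

`run_confirmatory` executes the stages in a fixed order; every stage
derives its seed from the master seed through a named SHA-256 substream
(`stage_seed`), so a rerun with the same configuration writes
byte-identical summary JSON.  Provenance (config hash, stage seeds,
software versions) is embedded in every bundle.  `run_exploratory` adds
the released-constraint refits, the ten caution-decile subgroup reruns
(cut points at the .1–.9 empirical quantiles of the exported boundary
means; right-closed; groups under 10 participants skipped with a warning),
and the student/non-student split (participants with a missing student
flag are excluded from the split and counted).

## Problem sizes used in the tests

The shipped test suite runs the full pipeline at desk scale: curve-model
checks at the study's n = 916 with 90-trial conditions; diffusion recovery
at 150 participants × 60 trials × 20 replicates (bias of the posterior
mean ρ under 0.05, 95%-interval coverage ≥ 85% at ρ_true = 0.3); mechanism
signatures over 20 (drift-coupled) and 10 (caution-coupled) seeded
populations.  These sizes are the package's choice of a scale at which the
properties under test are decisive yet the whole suite stays convenient to
run routinely.

## Known limitations

* The Fisher-z likelihood treats the five quantile correlations as
  independent; a participant-bootstrap of their 5×5 covariance would relax
  this but is not implemented.
* The diffusion likelihood omits across-trial variabilities; data
  generated with `sv > 0` will fit with mildly attenuated drift effects.
* Extreme Bayes factors are order-of-magnitude statements (see above).
* Truncated-normal group locations are parameterization artifacts near
  binding bounds; read the per-participant posterior means instead.
* The caution-subgroup analysis conditions on estimated (not true)
  boundary separation; with only ~90 trials per difficulty the grouping
  variable carries estimation noise, exactly as in the workflow it
  reproduces.
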