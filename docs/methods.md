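# Methods

## The task and its representation

A session is 42 go/no-go motor gambles: 6 payoff combinations (reward:
certain +10 vs gamble for 20/60/100-or-0; punishment: certain −10 vs
gamble for 0-or-−20/−60/−100) crossed with 7 target-size levels. The
schedule is block-structured: levels 1–3 are assigned one-per-block (in
random order) to blocks 1–3, levels 4–6 likewise to blocks 4–6, and level
7 fills block 7; within each block the 6 payoff combinations appear once
in random order. The published task description states only that the easy
levels were presented "randomly" within the first three blocks; assigning
exactly one level per block is this package's reading, chosen because it
preserves the exact 6 × 7 balance of the design. How the six combinations
were ordered within a block is likewise unstated; a uniform random
permutation is assumed. Trajectory angles are drawn uniformly in [0, 360]°
and carried for completeness only — task difficulty enters the models
solely through the target level.

Success probabilities are estimated from the data, not modelled: in
`group` mode a trial's probability is the mean motor-success rate over all
gambled trials sharing (age group, screen bin, target level); in
`individual` mode, over the participant's own gambled trials at that
level. Screen sizes are binned to the nearest of {4, 6, 8, 10} inches with
ties toward the smaller bin (only the bin centres are given in the source
material, so the tie rule is a repository convention). Cells with no
gambled trials are *missing*, never zero — a silent zero would bias the
utilities of every trial mapped to that cell; downstream fitting drops
trials with missing probability and reports the count.

## Choice models

The 24-model family crosses four factors: joint vs separate risk
preference α, joint vs separate inverse temperature μ, Pavlovian offset δ
absent/joint/separate, and linear vs weighted probability. Value follows
v(O) = O^α for gains and −λ(−O)^α for losses with λ ≡ 1 (no gamble mixes
gains and losses, so loss aversion is not identifiable and is fixed).
Utilities combine as U = w(p)·v(O₁) + (1−w(p))·v(O₂); since one gamble
outcome is always 0 and v(0) = 0, this equals the single-outcome form
p·v(O) in the reward domain while handling punishment gambles (success
outcome 0) symmetrically. The choice rule is a softmax in the utility
difference; the Pavlovian offset is added *after* the softmax and the sum
clamped to [0, 1] — the offset itself is never clamped, so the order of
operations is softmax → add δ → clamp. On reward trials the (+) member of
any split parameter applies, on punishment trials the (−) member.

Bounds: α ∈ [0, 1], μ ∈ (0, 10] (implemented lower bound 1e−6 since the
interval is open), δ ∈ [−1, 1]. γ is bounded to (0, 5] with starting
value 1; no bound is given in the source material and the weighted models
lose on model selection anyway, so the choice is inconsequential. The
model-family table's numeric row ordering is not recoverable from the
extracted text; `enumerate_models()` therefore uses a declared stable
order (δ-mode, then weighting, then α/μ splitting) and the two winning
variants are exposed as named constants (`AA_WINNER` = [α, μ, δ⁺, δ⁻],
`PT_WINNER` = [α⁺, α⁻, μ⁺, μ⁻]) rather than by row number.

## Estimation

Per participant, the Bernoulli log-likelihood of the observed choices is
maximised by L-BFGS-B within the bounds, restarted from uniform-random
points in the box; the best restart wins. The clamped choice rule can
produce predicted probabilities of exactly 0 or 1, which the log cannot
absorb, so probabilities are clamped to [ε, 1−ε] with ε = 1e−9 *inside
the logarithms only*. The study protocol used 200 restarts; that is the
default of `fit_mle`, while the test suite and pipeline default to 10–30
restarts, which the grid-oracle equivalence check shows is already
sufficient on 42-trial sessions. Restart streams are derived from
(seed, participant id), so cohorts can be fitted in any order or in
parallel with identical results. The contract for optimiser quality is
not a particular algorithm but equivalence with `grid_oracle`, an
exhaustive evaluation of the likelihood on a regular grid over the box
(step expressed on unit-scaled parameters; ≤ 4 free parameters and ~1e7
points, else the call is rejected as misuse).

Model comparison uses AIC = −2logL + 2k and BIC = −2logL + k·lnN (natural
logs; N counts only trials that entered the likelihood). Pseudo-R² is
1 − logL(model)/logL(null) with the null model forcing α = μ = δ = 0,
i.e. F = 0.5 on every trial and logL(null) = N·ln½. The cohort winner is
the smallest summed criterion; exact per-subject ties in the winner
tallies count half to each side, and summed-criterion ties break toward
fewer parameters, then lexicographic model code (tie handling is
unstated in the source material). Winner-vs-alternative differences are
tested by paired two-sided t-tests with Bonferroni correction over the
alternatives. The per-individual likelihood-ratio tests compare joint vs
separate parameters (df = 1 each): split δ against the joint-δ base
model, then split α and split μ against the winning split-δ model.

## Recovery diagnostics

Parameter recovery simulates choices from "typical participant" parameter
sets on a real 42-trial schedule, refits, and summarises the recovered
clouds (median, central 80% interval, median absolute error). The source
material does not print its generating values, so the defaults
(`TYPICAL_AA_SETS`: α 0.7–0.9, μ 0.3–1, δ⁺ 0.1–0.3, δ⁻ −0.3–−0.1) are
placed in the region where fitted participants cluster; recovery, not
numerical replication, is the check. At 42 trials μ is only weakly
identified (its cloud is wide and its median can sit far from truth —
visible in the recovery report) while the clouds still contain the truth;
at ~1000 trials all parameters tighten, which the tests verify
(median absolute error < 0.1 for α and δ, μ within a factor of 2).

Model recovery simulates cohorts under each winning variant (with
participant-level truncated-Gaussian jitter, sd 0.05) and refits both;
summed BIC credits the cohort to a family. Model falsification works
through `predicted_curves`: averaging fitted trial-wise gamble
probabilities within EV-difference bins. Only split-δ models can produce
the reward > punishment gamble-rate gap at EV-difference ≈ 0; a pure
prospect-theory fit predicts the *opposite* ordering there, because at
equal expected values the power-law value function makes the reward
gamble subjectively worse than certain (+5.49 vs +6.31) and the
punishment gamble subjectively better than certain (−5.49 vs −6.31).

## Behavioural statistics

Optimality discrepancy codes the EV-maximising choice (gamble iff
EV_gamble − EV_certain > 0) and averages |choice − optimal| per domain.
Trials with EV difference exactly zero are excluded (either action is
optimal; the source defines only strict inequalities); "exactly zero" is
implemented as |diff| < 1e−9 to absorb floating-point noise in
p·O products. Gamble-rate curves bin EV differences into half-open
intervals [lo, lo + width) anchored at 0 (width 10 by default) and carry
binomial-bootstrap 95% CIs; the exponential fit y = a·exp(−b·x) + c is
nonlinear least squares with b ≥ 0, initialised at c = mean of the last
two points, a = first-point residual, b = 0.01.

The partial Spearman correlation ranks the variable, the ordinal age
group and the covariates (gender and education, the latter as ordinal
ranks school < university < advanced), residualises the first two on the
covariates by least squares, and correlates the residuals. Confidence
intervals are BCa bootstrap over participants (default 10,000 resamples);
p-values come from permuting the age labels (default 10,000 shuffles),
two-sided, with the add-one correction p = (1 + #{|r| ≥ |r_obs|})/(1 + n),
so p is never exactly 0. The permutation loop exploits the fact that
ranking a permuted vector permutes its ranks, so only the residual
projection is recomputed per shuffle. Whether the original analysis was
one- or two-sided is unstated; two-sided is assumed. The control-study
calibration error is estimate% − 100% on successful trials and
estimate% − 0% on failures, averaged.

## Synthetic cohorts

The generator's defaults are the study conditions of every test: 42-trial
sessions; a success surface logit-linear in target level (rate 0.95 at
the largest target) whose slope steepens by up to 35% from the youngest
to the oldest group and by up to 30% from the largest to the smallest
screen bin, clipped to [0.02, 0.98]; an age–screen association whereby
older groups tend toward larger devices; and choices generated from the
winning approach-avoidance model with age-graded medians interpolated
linearly between young and old anchors — δ⁺ declining steeply
(0.35 → 0.05), δ⁻ mildly more negative (−0.10 → −0.25), α mildly
declining (0.85 → 0.65), μ flat (0.6) — plus truncated-normal
participant heterogeneity (sd 0.08 for α and δ, 0.20 for μ). These
anchors mirror the qualitative age profiles of the original cohort
(approach bias declining most steeply; temperature flat); the spreads are
chosen so that 42-trial fits remain informative. Motor success is never
generated for skipped trials (it is unobservable in the task).

What the generator does *not* emulate: tap kinematics, movement times and
the timing windows (success is a single Bernoulli bit); real demographic
composition beyond group counts; device-specific difficulty beyond the
screen bin; and any model misspecification — real participants are not
guaranteed to be approach-avoidance agents, so passing tests demonstrate
that the pipeline recovers what the generator put in, not that the model
is true of human data.

## Problem sizes and numerical choices

The test suite runs the recovery analyses at 50 simulations per parameter
set (matching the study's recovery protocol), model recovery at one
cohort of 200 participants per generator, and the end-to-end age-profile
check on a 600-participant cohort; these sizes keep the full suite in the
minutes range on a single core while leaving all conclusions
comfortably away from their thresholds. Statistical replicate defaults
(10,000 bootstrap/permutation) are used in production; tests use 50–1,000
with fixed seeds. All randomness flows through numpy Generators seeded
explicitly; per-participant and per-stage streams are derived from the
master seed so partial reruns reproduce exactly.

## Known limitations

- μ is weakly identified from 42 trials; treat individual μ̂ values with
  caution (the recovery report quantifies this).
- With probabilities clamped at 0/1 by large |δ|, the likelihood is flat
  in several directions; multi-start local search handles this in
  practice (verified against the grid oracle) but single-start fits can
  land on plateaus.
- The group success table conditions on age × screen × level only; any
  residual individual skill differences leak into the utilities, which is
  inherent to the original estimation strategy (the individual-mode table
  is provided as the alternative).
- The economic-gambling cross-task analyses, movement-time/precision
  analyses and the real-cohort success-rate regression are out of scope.
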