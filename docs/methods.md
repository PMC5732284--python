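# Methods

## Task model

Stimuli are the 2³ combinations of three binary features, encoded 0/1 in the
fixed order (shape, colour, pattern) with square/blue/vertical = 0. Every
stimulus belongs to one of four reward categories, determined by which
single dimension (if any) disagrees with the other two: none ⇒ *all-match*
(+10 on go), the rule variant's named dimension ⇒ *penalised non-match*
(−10), either other dimension ⇒ one of two *random non-match* categories
(±10 with probability 0.5). Pass always pays 0. Sessions are balanced — each
stimulus appears `n_trials/8` times — and shuffled with a seeded generator;
the main design is 8 stages × 32 trials, the variant design 10 × 32.

The chance-level cutoff is the empirical 95th percentile of final scores
under a null agent choosing go/pass with probability 0.5 each. Because the
per-category trial counts are fixed and null choices are i.i.d., the null
score distribution is independent of trial order, so the simulation draws
per-category binomial go counts directly; the test suite verifies moment
agreement with literal trial-by-trial play-out. The analytic null SD is
√(64·25 + 64·25 + 128·50) ≈ 98 points, and scores move in steps of 10; the
coin-flip null puts the 95th percentile at 160.

## Per-policy learning (naive reinforcement learning)

Each of the seven policies πᵢ (non-empty feature subsets; 2, 4 or 8 states)
carries a state × action Q-table, zero-initialised, updated on responded
trials by the delta rule `Q ← Q + α(R − Q)` for the chosen action only (no
counterfactual feedback exists). Both actions are learnable; pass earns 0,
so its value relaxes toward 0 when chosen. Choice probabilities use a
two-alternative softmax with inverse temperature β, computed with
max-subtraction; probabilities are floored at 1e−12 before logs. Session
log-likelihood sums log probabilities of the observed actions over responded
trials; missed trials are excluded everywhere (including the BIC sample
size) and never produced by the synthetic agents.

## Policy search

Both search models consume the seven per-policy learners fitted to the
session (stage 1, below).

**Softmax-based search.** Per trial, each policy is scored by the softmax
*advantage* of the action actually taken, `βᵢ·(Qᵢ(s_t, a_t) − Qᵢ(s_t, ā_t))`
— the logit of that policy's choice probability — and the policy
distribution is the softmax of these scores at a fixed temperature (1.0, not
a fitted parameter). Trials are treated as temporally independent: no
carry-over from the previous trial's probabilities. The advantage form is
deliberate: scoring by the chosen action's *value* alone cannot separate the
full policy from coarser ones, because feedback is censored by the agent's
own choices (a coarse policy's go-value matches the fine policy's on
exactly the trials the agent chose to experience), and it is uninformative
on pass trials, where all learned pass-values sit near zero.

**HMM-based search.** A 7-state hidden Markov chain with fixed sticky
transitions (self-transition 0.9, off-diagonal (1−0.9)/6) and emission
probabilities given by each policy's softmax probability of the observed
action. Forward filtering only, uniform prior; the one-step-ahead predictive
distribution is kept alongside the filtered posterior, because the product
over trials of `predictive · emission` is the exact chain likelihood — the
test suite checks both the filter and this likelihood against exhaustive
enumeration over all 7^T policy paths.

**Current policy, transitions, entropy.** Each policy's probability series
is fitted by an ordinary least-squares polynomial of degree 5 (trial index
rescaled to [0, 1]); the per-trial argmax of the fitted curves is the
*current policy* (exact ties break to lower dimensionality, then lower id),
and changes between consecutive trials are *transition events*. The
ambiguity series used by the transition analyses is the Shannon entropy of
the fitted curves (clipped at the probability floor and renormalised per
trial). The raw posterior's per-trial entropy is also available, but with
near-deterministic learners it is practically bimodal — ≈0 on decisive
trials, ≈ln 7 on flat ones — whereas the fitted-curve entropy evolves
smoothly and peaks where the current policy is about to change, which is the
quantity of interest when asking whether transitions happen under high
ambiguity.

**Model likelihoods (k = 14 each).** The session likelihood of either
exploration model mixes the per-policy choice probabilities with that
model's per-trial policy distribution: the same-trial softmax posterior for
the softmax model, the predictive distribution for the HMM model. The
same-trial evidence gives the softmax model a systematic likelihood
advantage on sessions generated by a fixed policy, reproducing the observed
ordering of the two search models.

**Strategy classes.** Sessions are classified by the modal dimensionality of
the current policy over the first versus last quarter of trials:
2d→3d, 3d→2d, only-2d, only-3d; a modal dimensionality of 1 in either
quarter marks a one-dimensional (non-learner-like) session.

## Value-transfer learning

Given a frozen per-trial policy schedule (from the softmax-based search),
a single learner follows the schedule with shared (α, β) — 2 free
parameters. At each schedule change the new policy's table is initialised
by one of two rules: **zero** (all values relearned) or **inherited** —
each new state takes the unweighted mean of the old states consistent with
it on the shared features. On a dimension increase that preimage is a single
state, so the mean reduces to a copy; with no shared features it degenerates
to the grand mean (such transitions are rare). Both action columns
transfer. The reward prediction error `R_t − Q(s_t, a_t)` (pre-update) is
recorded per responded trial for the regressor export. The lapse baseline
(k = 3) learns on the full three-feature policy and mixes its softmax
probabilities with chance: `(1−ε)·p + ε/2`.

## Estimation

Three stages, as in the two-step experimental procedure: (1) each policy's
(αᵢ, βᵢ) is fitted independently by maximum likelihood; (2) the softmax
search posterior, smoothing, current policy and transitions are derived from
those fits; (3) the transfer and baseline models are fitted with the
schedule frozen. Optimisation is a 5 × 5 grid over α (linear) × β
(log-spaced in (0, 50]); the best three grid points plus seeded random
restarts are polished with L-BFGS-B under bounds α ∈ [1e−6, 1],
β ∈ [1e−3, 50], ε ∈ [0, 1]. The β bound is generous because fitted inverse
temperatures are known to run large on near-deterministic data. The lapse
model's multistart additionally includes the fitted naive policy-7 solution
with ε = 0, so its likelihood can never fall below its nested special case.
All fits are deterministic given the seed.

Cohort statistics use paired two-sided t-tests on per-session AIC/BIC
differences (degenerate zero-variance cases are flagged rather than
tested), a one-sample t-test of per-session differences between mean
entropy at transition trials and over all trials (sessions without
transitions are excluded and counted), and ordinary least-squares
regressions for entropy-at-transition on trial index (pooled) and final
score on session log-likelihood.

## Synthetic agents

The generator produces the cohort structure the analyses assume; the
manifest records every parameter, and sessions reproduce bit-exactly from
it. Defaults: α = 0.25, β = 4.5 (the fitted transfer-model means of the
behavioural cohort the task comes from).

*Random* agents flip a fair coin. *Fixed-policy* agents learn and act on one
policy. *Exploring* agents act through an active policy while updating
background Q-tables for all seven candidates; after each trial they compute
the softmax-search-style advantage posterior over policies (on the raw
value scale, temperature 1 point) and its entropy. Switching is gated on the
trailing 16-trial mean of this entropy exceeding a threshold (default
0.65·ln 7 ≈ 1.26 nats), with probability 0.1 per eligible trial, a 32-trial
refractory period between switches (which doubles as a burn-in), and the
destination drawn in proportion to `exp(V̄ᵢ/0.5)` where V̄ᵢ is the mean over
policy i's states of the better action's believed value. The new active
table is initialised by the zero or inherited rule. These choices are a
generative construction, not an estimate: the analyses establish that
transitions co-occur with high ambiguity, not a mechanism. The specific
elements are there for identified reasons — gating on *sustained* ambiguity
because individual random-reward stimuli remain ambiguous all session by
design; the refractory period because a policy must be experienced to be
evaluated (and stints shorter than ~20 trials are invisible to degree-5
smoothing); the prospective-value draw because drawing from the
retrospective posterior mostly re-selects whatever explains the agent's own
recent actions and, under high ambiguity, is uniform.

What the generator does *not* emulate: response times, missed trials,
attention lapses and other human noise (synthetic learners are far more
predictable than human subjects — per-session log-likelihoods of the best
model are around −10 to −60 rather than the −120 scale typical of human
cohorts), session-level non-stationarity in α or β, and any coupling
between features beyond the reward rule. Passing recovery tests on these
agents therefore demonstrates that the estimation machinery is correct and
the qualitative orderings are reproducible, not that the models are
identifiable on noisier human data.

## Recovery studies and their boundaries

**Parameter recovery** fits the transfer model with the generator's known
schedule (standard known-generator design). Re-inferring the schedule first
would confound the study: inherited-value transfer intentionally makes
behaviour continuous across a switch, so the smoothed-argmax search cannot
reliably see transitions even in a clean forced-switch construction, and
schedule errors masquerade as distorted (α, β). The learning rate recovers
well (median absolute error ≈ 0.02 at α = 0.25 over 50 sessions). The
inverse temperature does not, at β = 5 with ±10 rewards: once values
separate, β·ΔQ ≈ 50 saturates the softmax and the profile likelihood over β
is flat above ≈3–5 for most sessions (verified by profiling with α
re-optimised at each β), so the MLE of β is set-identified upward and its
session median lands on the plateau. This is a property of the task's
reward magnitudes, not of the optimiser; β recovery would require either
noisier generators (which bias β downward instead) or smaller reward-to-
temperature ratios. The corresponding acceptance test asserts the factor-2
recovery anyway and fails on the β half, by design of this package's
honesty policy: the α half passes, the β half documents the identifiability
boundary.

**Model recovery** keeps the inferred (noisy) schedule, exactly as the human
analysis would, and reproduces the published orderings: inherited < zero
and inherited < 14-parameter exploration model on mean AIC/BIC for
value-transferring cohorts; softmax ≤ HMM search on fixed-policy cohorts;
and the best-BIC model falls in the generating family per session.

**Entropy–exploration properties** use 60-session exploring cohorts
(alternating inherited/zero initialisation; zero-init transitions are
behaviourally visible and carry most detected events): ambiguity at detected
transitions exceeds the session mean (paired), and pooled
entropy-at-transition declines with trial number. Both directions were
checked for stability on disjoint cohorts before the test conditions were
frozen.

## Numerical choices

Probability floor 1e−12 before every log; softmax with max-subtraction;
state indices are binary encodings in the fixed global feature order, making
transfer mappings reproducible; trial indices are 1-based in all files and
event records, 0-based in arrays; ties in the current-policy argmax break to
lower dimensionality then lower id; the degree-5 smoother requires at least
6 trials; seeded `numpy` generators throughout, with agents deriving
separate choice/switch/task streams from their seed so that disabling
switching leaves the choice stream untouched.
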