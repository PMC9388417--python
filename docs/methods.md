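# Methods

This note documents the models, the numerical choices, and the reasoning
behind the parameter presets, in the order a reader meets them in the code.

## Trial scenarios as factored POMDPs

Both trial scenarios have three timepoints (start → cue stage → outcome) and
two hidden-state factors:

* **context** — the ball that is coming, `normal` or `changeup`, fixed within
  a trial (identity transition table);
* **behaviour** — the observer's own stage.  Simple scenario:
  `start, observing, committed_normal, committed_changeup`.  Trade-off
  scenario: `start, observing` plus early/late committed states.

The behavioural factor exists so that stage-dependent observability and the
early/late reward asymmetry can be expressed through *static* A and C tables:
the cue modality (`null, cue_normal, cue_changeup`) is informative only in the
`observing` state, with believed reliability ρ; the feedback modality is
emitted only in committed states and is deterministic given (ball, commitment)
by default (`q_hit = 1`, configurable).  Committed states are absorbing, so an
early commitment in the trade-off scenario receives its (higher) reward
preference at both remaining timepoints — the standard discrete-POMDP encoding
of "acting early captures more of the trial", and the source of the early/late
asymmetry analysed below.

Policies are complete action sequences: two in the simple scenario
(wait→commit either ball), four in the trade-off scenario (commit either ball
immediately, or wait then commit).  Early policies carry `wait` as a no-op
placeholder for the post-commitment transition.  Habit weights over policies
exist in the interface but default to uniform and are unused.

## Inference

State inference sweeps over factors; for each factor it runs exact
forward–backward smoothing along the three timepoints, taking the likelihood
evidence for the other factor in expectation (an expected-log contraction).
Sweeps repeat until the largest absolute belief change is below 1e-6 (cap 64;
hitting the cap flags a warning rather than raising).  Because the behavioural
factor is deterministic given the policy, the fixed point coincides with exact
Bayesian smoothing of the context factor; the test suite pins this against a
brute-force enumeration of the full joint on 1000 random parameterisations.
A naive fully-factorised mean field over the per-timepoint copies of the
context state would *not* have this property — the identity transition makes
consensus messages winner-take-all — which is why the structured scheme is
used.  Probabilities are floored at 1e-16 inside logarithms.

Variational free energy is accumulated as per-factor complexity against the
forward prior-predictive message minus the expected log-evidence of observed
outcomes; at the fixed point it upper-bounds the negative log evidence, and
the suite checks its closed-form values (0 for perfectly predicted nulls,
ln 2 for a fair-coin cue) and its weak decrease over sweeps.

## Policy evaluation and action selection

For each policy still consistent with the actions already taken, expected free
energy is summed over future timepoints and modalities:
risk = KL from predicted outcomes to the softmax of that timepoint's C column,
ambiguity = expected conditional entropy of A, and, only while cue learning is
on, a novelty bonus — the expected Dirichlet information gain
½·E[1/a − 1/a₀] under the predicted cue/ball joint.  The decomposition
G = risk + ambiguity − novelty is exact by construction and asserted in tests.
Policy posteriors are softmax(ln habits − γG); the action marginal over
consistent policies is sampled (default) or taken by argmax with ties broken
toward the lowest action index.  Within a trial the agent re-evaluates G after
each observation, so a waiting agent that sees the cue commits on what the cue
revealed even though each policy is a fixed sequence.

Learnable components use the digamma expected-log parameterisation
(ψ(count) − ψ(column sum)) during inference; components with learning disabled
use their stated probabilities.  Count magnitude therefore acts as precision
primarily through learning dynamics: weak counts are quickly overwritten by
experience while strong counts persist, which is exactly what flips the
dominant action between the strong-cue and strong-context conflict conditions.

## Learning

After each trial, with learning rate η:
`d += η · posterior(ball)` (context learning) and
`a[observed cue, :] += η · posterior(ball at cue time)` (cue learning).
The counts stored in `DirichletBeliefs` are the 2-vector **d** and the 2×2
cue/ball contingency **a** for the observing state — the only learnable
elements in these scenarios; the full A tensor is rebuilt from **a** whenever
cue learning is on.  B is not learnable (the within-trial dynamics are known),
and whether the original simulations also learned B is unknowable from the
source material; the gap is deliberate.

## The early/late trade-off in closed form

With preference distribution σ(C) over
`(null, early_correct, late_correct, incorrect)` at utilities
`(0, R_e, R_l, −L)`, a belief q in the committed ball, and a perfectly
reliable late cue, the entropy and cue-epistemic terms cancel exactly between
an early policy and its matching late policy, leaving

    G(early) − G(late) = q·(2R_e − R_l) − (1−q)·L .

Early commitment is preferred once q exceeds q* = L / (L + 2R_e − R_l).  This
is the lever behind the reward sweep presets (below): L = 14 with
R_e ∈ {1, 4, 8} and R_l = R_e/2 puts q* at 0.90 / 0.70 / 0.54, so the
low-reward observer always waits, the high-reward observer commits almost
immediately, and the medium-reward observer crosses its threshold mid-session
as context learning (η = 0.1 from flat counts, truth 80/20) sharpens q.

## The hierarchical (volatility) model

The two-level observer tracks the ball frequency with Dirichlet counts (lower
level) and, above it, a hidden Markov regime (`mostly_normal`,
`mostly_changeup`; emissions 0.8/0.2) with believed persistence κ (default 1:
the observer expects one regime to hold all session).  The higher level runs
on a slower timescale: it accumulates evidence for `update_interval` trials
(default 10) and revises its regime belief once per interval, the frozen
belief supplying each trial's predictive distribution in between.  Two
free-energy streams are exposed per trial: the observation surprisal
−ln p(o<sub>t</sub> | o<sub><t</sub>) and the belief-update free energy
KL(new belief ‖ transition-propagated old belief).

The slow timescale is load-bearing, not cosmetic.  A regime filter that
updates every trial is count-driven (with κ = 1 its posterior depends on the
outcome counts alone, not their order), and empirically a stable 50/50 stream
then causes *at least as much* belief churn as a volatile one, because an
unbiased random walk lingers in the belief region where single observations
move the posterior most.  Chunked updating makes order structure visible:
stable 50/50 intervals are evidence-balanced and force almost no revision,
while a volatile order alternating 80/20 and 20/80 blocks forces a large
revision at every reversal.  At matched marginals this yields several-fold
higher summed belief-update free energy under volatility with equivalent
lower-level beliefs (≈ 0.50 change-up in both schedules) — expected vs
unexpected uncertainty, separated.  Aligning the default interval with the
default block length (both 10) makes the demonstration crisp; mismatched
intervals weaken but do not destroy the effect, since straddling chunks still
conflict with the stability-linked belief.

## Condition presets

The registered conditions are repo presets chosen to make each qualitative
phenomenon unambiguous at its study size; none of them is an empirical claim
about a particular sport.

* **Learning curves (principle-1 set)** — truth 80/20, true cue reliability
  0.8, naive agents (flat d, cue believed uninformative at strength 2), η = 1,
  γ = 0.5.  The low policy precision matters: naive learners with γ = 16 turn
  a two-count imbalance into deterministic action choice and the learning
  curve degenerates into a step.  γ = 0.5 gives the gradual, stochastic curves
  (and wide across-observer intervals) the phenomenon is about.  The reversal
  variants flip the context to 20/80 at trial 25 of 50.
* **Single-trial precision pairs** — strong prior (counts 40/10) with weak
  believed cue (ρ = 0.6, strength 5) versus weak prior (4/1) with precise cue
  (ρ = 0.95, strength 40); argmax actions; a change-up arrives with a truthful
  deterministic cue.  The committed action follows whichever source carries
  more precision.
* **Congruency grid** — informed agents (prior and cue contingency at strength
  20, ratio 4:1, γ = 0.5) crossed over cue/context congruency; incongruent
  context means the prior counts favour the minority ball at the same 4:1
  ratio.  Strength 20 makes incongruent beliefs take ~20 trials to unlearn, so
  the early block cleanly shows both-congruent ≥ single-incongruent ≥
  both-incongruent, with the last below chance.
* **Precision conflict** — truth 50/50, cue stream forced to indicate
  change-up, both sources at the same 4:1 ratio; count magnitudes 5 vs 50
  swapped between cells.  Both learning toggles on: the weak source unlearns
  within a few trials and the strong source dominates the session's actions.
* **Policy precision sweep** — trade-off model, learning off, fixed prior
  counts (4, 3) giving an early-vs-late G gap near 1 nat, γ ∈ {16, 4, 2, 1}.
  The gap size is what lets the sweep spread wait fractions (≈ 0%, 3%, 16%,
  34%) rather than saturating at 0 or ½.
* **Reward sweep** — as derived above; 20 observers × 60 trials.
* **Volatility pair** — stable: i.i.d. 50/50; volatile: ten-trial blocks
  alternating 20/80 and 80/20 (identical scheduled marginal); 50 observers ×
  100 trials.

## What the synthetic environments do and do not emulate

The generative processes produce exactly the statistical structure the models
reason about: Bernoulli outcome sequences (optionally block-volatile), cues
with controllable reliability, congruency and forced direction, and
deterministic feedback.  They do not emulate kinematics, timing noise,
opponent adaptation (explicitly out of scope), within-trial continuous
dynamics, or motor execution error.  Passing batteries therefore demonstrates
that the *belief and policy machinery* produces the right orderings under
controlled statistics — not that these parameter values describe human
athletes.

## Numerical and interface details

Tolerances: normalisation checked to 1e-10; inference fixed point 1e-6 with
cap 64; log floor 1e-16.  Dirichlet counts are kept strictly positive (floor
1e-3 at initialisation when ρ ∈ {0, 1}).  Confidence intervals in summaries
are normal approximations across observers (zero-width and flagged for a
single observer).  Success is feedback in {correct, early_correct,
late_correct}; plots use a 5-trial moving mean, summary statistics never do.
All randomness flows through one seeded generator per observer, spawned from
the base seed; identical seeds give byte-identical CSVs.  Run configurations
are validated against a closed schema (unknown keys rejected, probabilities
bounds-checked) and echoed with a hash into every output directory.

## Known limitations

Policies are depth-2 action sequences — no deeper planning.  Only d and a are
learnable.  The hierarchical model is a deliberately compact regime filter,
not a full nested POMDP, and its update interval is a fixed structural prior
rather than an inferred quantity.  Feedback is binary and immediate; there is
no model of partial or delayed knowledge of results.
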