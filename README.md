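# strikesim

Active-inference simulations of skilled anticipation in striking sports.

In time-constrained interception tasks — returning a tennis serve, facing a
baseball pitch or a cricket delivery — performers cannot react to ball flight
alone.  They anticipate, by combining **prior contextual knowledge** (how often
does this opponent throw the slower "change-up"?) with **current sensory cues**
(early kinematic information), each weighted by its expected reliability.
`strikesim` implements this as a family of discrete partially observable Markov
decision process (POMDP) agents that perceive, act and learn by minimising
(expected) free energy, and reproduces the canonical behavioural phenomena of
the anticipation literature — chance performance before learning, congruency
effects, precision-weighted dominance of one information source over another,
reward/information trade-offs, and volatility-induced prediction errors — as
reproducible, seeded simulation batteries.

## The model

An observer's generative model for one trial (three timepoints: start, cue,
outcome) is the standard categorical tuple

- **A** — likelihood mappings p(o<sub>τ</sub> | s<sub>τ</sub>) linking hidden
  states (ball type `normal`/`changeup` × behavioural stage) to observations
  (a cue modality and a feedback modality),
- **B** — transition tables p(s<sub>τ+1</sub> | s<sub>τ</sub>, a); the ball is
  fixed within a trial, the behavioural stage is controlled by the actions
  `wait`, `commit_normal`, `commit_changeup`,
- **C** — prior preferences (log utilities) over outcomes: reward for a
  correct interception, loss for a miss,
- **D** — priors over initial states; the context prior is the normalised
  Dirichlet count vector **d**.

State inference minimises variational free energy by factor-wise
forward–backward sweeps to a fixed point; on these models the result equals
exact Bayesian smoothing (verified against brute-force enumeration to 1e-6).
Policies π (anticipate-normal vs anticipate-changeup; plus early-vs-late
commitment in the trade-off scenario) are scored by their expected free energy

    G(π) = risk + ambiguity − novelty
    risk      = KL[ Q(o|π) ‖ σ(C) ]
    ambiguity = E_Q(s|π)[ H[p(o|s)] ]

with a count-based novelty (information-gain) bonus while cue learning is
enabled, and selected through softmax(−γ·G) with policy precision γ.  After
each trial, Dirichlet counts over the context prior (**d**) and the cue
contingency (**a**) are incremented by the trial's posteriors — learning is
just counting.  A two-level (hierarchical) variant adds a slow regime state
over trials to separate *expected* uncertainty (outcome stochasticity) from
*unexpected* uncertainty (volatility of the trial order).

## Worked example

```bash
python examples/reward_tradeoff.py
```

prints (seeded, reproducible):

```
low    reward (R_early=1, R_late=0.5, loss=14): early actions   0.0%  (first 10:   0.0%, last 10:   0.0%)
medium reward (R_early=4, R_late=2, loss=14): early actions  57.5%  (first 10:   4.0%, last 10:  89.5%)
high   reward (R_early=8, R_late=4, loss=14): early actions  95.3%  (first 10:  72.0%, last 10: 100.0%)
```

Committing early is worth more than committing after the late cue, but risks
the loss while the context is uncertain.  At low reward the observers always
wait for the cue (information seeking); at high reward they commit immediately
(reward seeking); at the medium reward they wait early in the session (4% early
actions over the first ten trials) and switch to early commitment (89.5% over
the last ten) once roughly sixty trials of 80/20 outcomes have sharpened their
context prior past the commitment threshold q* = L/(L + 2R_early − R_late).

The other examples — `single_trial_beliefs.py` (precision-weighted cue/prior
dominance within a trial), `learning_curves.py` (chance floor and learning),
`congruency_grid.py` (congruent/incongruent information), `volatility.py`
(stable vs volatile trial orders) — follow the same pattern: build a condition,
run seeded observers, print what the numbers mean.

## Command line

```bash
strikesim list-conditions                  # seven batteries and their cells
strikesim run --battery congruency --seed 7 --out results/
strikesim run --condition conflict_strong_cue --seed 7 --set rho_agent=0.9 --out results/
strikesim validate-config my_run.yaml
```

`run` writes one tidy CSV per condition (observer, trial, ball, cue, action,
action probability, success, posteriors, per-policy G, free energy), a JSON
summary, and a provenance log (seed, versions, config hash).  Identical seeds
give byte-identical artifacts.

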