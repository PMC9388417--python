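"""Generative processes: true trial sequences, cue emission, feedback delivery,
and the registry of named experimental conditions.

The environment is deliberately distinct from the observer's generative model:
it holds the *true* context probability, the *true* cue reliability, the
congruency flags, and (optionally) a block-wise volatility schedule.  Observers
never see these quantities directly — only the observations the environment
emits.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .hierarchy import HierarchicalParams
from .model import (
    ACTION_LABELS,
    CONTEXT_LABELS,
    SimpleScenarioParams,
    TradeoffScenarioParams,
)

AgentParams = SimpleScenarioParams | TradeoffScenarioParams | HierarchicalParams


# ---------------------------------------------------------------------------
# specification of the generative process
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnvironmentSpec:
    """Ground-truth settings for one condition.

    ``cue_congruent = False`` flips the direction of the emitted cue (the cue
    indicates the opposite ball).  ``context_congruent`` is bookkeeping for the
    congruency grid: the condition builder uses it to point the agent's initial
    context counts at the majority (congruent) or minority (incongruent) ball.
    ``forced_cue`` overrides cue emission entirely (used when the sensory
    stream always indicates one ball regardless of the truth).
    """

    scenario: str = "simple"  # simple | tradeoff | hierarchical
    p_changeup_true: float = 0.5
    rho_true: float = 0.8
    cue_congruent: bool = True
    context_congruent: bool = True
    volatility_schedule: tuple[tuple[int, float], ...] | None = None
    forced_cue: str | None = None
    reward_schedule: str = "default"

    def __post_init__(self) -> None:
        for p in (self.p_changeup_true, self.rho_true):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.volatility_schedule is not None:
            if len(self.volatility_schedule) == 0:
                raise ValueError("volatility schedule must not be empty")
            for length, p in self.volatility_schedule:
                if length <= 0:
                    raise ValueError("block lengths must be positive")
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"block probability {p} outside [0, 1]")
        if self.forced_cue is not None and self.forced_cue not in (
            "cue_normal", "cue_changeup"
        ):
            raise ValueError(f"unknown forced cue {self.forced_cue!r}")

    def scheduled_marginal(self, n_trials: int) -> float:
        """Analytic change-up marginal of the first ``n_trials`` trials."""
        if self.volatility_schedule is None:
            return self.p_changeup_true
        probs = []
        for length, p in _cycle_schedule(self.volatility_schedule, n_trials):
            probs.extend([p] * length)
        return float(np.mean(probs[:n_trials]))


def _cycle_schedule(
    schedule: tuple[tuple[int, float], ...], n_trials: int
) -> Iterable[tuple[int, float]]:
    covered = 0
    while covered < n_trials:
        for length, p in schedule:
            yield min(length, n_trials - covered), p
            covered += length
            if covered >= n_trials:
                return


@dataclass
class EnvState:
    """Mutable per-trial state of the generative process."""

    ball: str
    behaviour: str = "start"
    committed: str | None = None
    commit_stage: str | None = None  # early | late (trade-off only)


@dataclass(frozen=True)
class TrialOutcome:
    """Everything one trial's environment produced."""

    ball: str
    cue_emitted: str
    feedback: str


# ---------------------------------------------------------------------------
# trial-sequence generation
# ---------------------------------------------------------------------------


def generate_trial_sequence(
    spec: EnvironmentSpec, n_trials: int, rng: np.random.Generator
) -> tuple[list[str], float]:
    """Draw the true ball sequence; returns (labels, realised change-up fraction).

    Without a volatility schedule the draws are i.i.d. at ``p_changeup_true``;
    with one, blocks are drawn at their scheduled probabilities, cycling the
    schedule as needed.  Fully determined by the generator passed in.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    if spec.volatility_schedule is None:
        p = np.full(n_trials, spec.p_changeup_true)
    else:
        probs: list[float] = []
        for length, block_p in _cycle_schedule(spec.volatility_schedule, n_trials):
            probs.extend([block_p] * length)
        p = np.asarray(probs[:n_trials])
    draws = rng.random(n_trials) < p
    labels = [CONTEXT_LABELS[1] if d else CONTEXT_LABELS[0] for d in draws]
    return labels, float(np.mean(draws))


# ---------------------------------------------------------------------------
# within-trial dynamics
# ---------------------------------------------------------------------------


def step_environment(
    state: EnvState,
    action: str,
    tau: int,
    spec: EnvironmentSpec,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Advance the generative process by one action and emit observations.

    The cue is emitted while the observer occupies the observing state, with
    reliability ``rho_true`` (direction flipped when the cue is incongruent,
    overridden entirely by ``forced_cue``).  Feedback is emitted once
    committed — tagged early/late in the trade-off scenario — and null
    otherwise.  Issuing a commit action after commitment is an error (the
    committed states are absorbing); ``wait`` is a legal no-op there.
    """
    if action not in ACTION_LABELS:
        raise ValueError(f"unknown action {action!r}")
    if state.committed is not None and action != "wait":
        raise ValueError("cannot commit again: commitment is absorbing")

    if state.committed is None:
        if action == "wait":
            state.behaviour = "observing"
        else:
            ball = action.removeprefix("commit_")
            stage = "early" if (spec.scenario == "tradeoff" and tau == 0) else "late"
            state.committed = ball
            state.commit_stage = stage
            if spec.scenario == "tradeoff":
                state.behaviour = f"committed_{stage}_{ball}"
            else:
                state.behaviour = f"committed_{ball}"

    obs: dict[str, str] = {"cue": "null", "feedback": "null"}
    if state.behaviour == "observing":
        obs["cue"] = _emit_cue(state.ball, spec, rng)
    elif state.committed is not None:
        obs["feedback"] = _emit_feedback(state, spec)
    return obs


def _emit_cue(ball: str, spec: EnvironmentSpec, rng: np.random.Generator) -> str:
    if spec.forced_cue is not None:
        return spec.forced_cue
    indicated = ball
    if not spec.cue_congruent:
        indicated = "changeup" if ball == "normal" else "normal"
    if rng.random() >= spec.rho_true:
        indicated = "changeup" if indicated == "normal" else "normal"
    return f"cue_{indicated}"


def _emit_feedback(state: EnvState, spec: EnvironmentSpec) -> str:
    hit = state.committed == state.ball
    if spec.scenario == "tradeoff":
        if not hit:
            return "incorrect"
        return "early_correct" if state.commit_stage == "early" else "late_correct"
    return "correct" if hit else "incorrect"


# ---------------------------------------------------------------------------
# condition registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Condition:
    """A fully specified experimental cell: environment + agent configuration."""

    name: str
    spec: EnvironmentSpec
    agent: AgentParams
    n_observers: int = 50
    n_trials: int = 50
    note: str = ""


def _p1_agent(**kw) -> SimpleScenarioParams:
    # naive observer: flat context prior, cue believed uninformative until learnt
    defaults = dict(d_counts=(1.0, 1.0), rho_agent=0.5, a_strength=2.0,
                    reward=4.0, loss=4.0, gamma=0.5, eta=1.0)
    defaults.update(kw)
    return SimpleScenarioParams(**defaults)


def _congruency_agent(context_congruent: bool) -> SimpleScenarioParams:
    # informed observer: prior points at the majority (or minority) ball at 4:1
    d = (16.0, 4.0) if context_congruent else (4.0, 16.0)
    return SimpleScenarioParams(
        d_counts=d, rho_agent=0.8, a_strength=20.0, gamma=0.5,
        learn_context=True, learn_cue=True, eta=1.0,
    )


def _registry() -> dict[str, Condition]:
    conditions: list[Condition] = []
    p1_env = EnvironmentSpec(scenario="simple", p_changeup_true=0.2, rho_true=0.8)
    reversal_env = replace(
        p1_env, volatility_schedule=((25, 0.2), (25, 0.8)), p_changeup_true=0.5
    )
    conditions += [
        Condition("p1_no_learning", p1_env, _p1_agent(), note="chance-floor control"),
        Condition("p1_context_learning", p1_env, _p1_agent(learn_context=True)),
        Condition("p1_cue_learning", p1_env, _p1_agent(learn_cue=True)),
        Condition("p1_both_learning", p1_env,
                  _p1_agent(learn_context=True, learn_cue=True)),
        Condition("p1_reversal_context_learning", reversal_env,
                  _p1_agent(learn_context=True),
                  note="context frequency flips at the mid-session point"),
        Condition("p1_reversal_cue_learning", reversal_env,
                  _p1_agent(learn_cue=True)),
    ]

    # single-trial belief updating: a change-up is coming in both cells
    single_trial_env = EnvironmentSpec(scenario="simple", p_changeup_true=1.0, rho_true=1.0)
    conditions += [
        Condition(
            "single_trial_strong_prior_weak_cue", single_trial_env,
            SimpleScenarioParams(d_counts=(40.0, 10.0), rho_agent=0.6,
                                 a_strength=5.0, action_mode="argmax"),
            n_observers=1, n_trials=1,
            note="precise context prior overrides an uncertain opposing cue",
        ),
        Condition(
            "single_trial_weak_prior_precise_cue", single_trial_env,
            SimpleScenarioParams(d_counts=(4.0, 1.0), rho_agent=0.95,
                                 a_strength=40.0, action_mode="argmax"),
            n_observers=1, n_trials=1,
            note="precise cue overrides a weak opposing prior",
        ),
    ]

    # congruency grid
    for name, cue_c, ctx_c in [
        ("congruency_both_congruent", True, True),
        ("congruency_cue_incongruent", False, True),
        ("congruency_context_incongruent", True, False),
        ("congruency_both_incongruent", False, False),
    ]:
        env = EnvironmentSpec(
            scenario="simple", p_changeup_true=0.2, rho_true=0.8,
            cue_congruent=cue_c, context_congruent=ctx_c,
        )
        conditions.append(
            Condition(name, env, _congruency_agent(ctx_c), n_trials=100)
        )

    # precision conflict: prior says normal, the cue stream always says change-up;
    # the belief ratio is four to one in both cells, only the count magnitude moves
    conflict_env = EnvironmentSpec(
        scenario="simple", p_changeup_true=0.5, rho_true=0.8,
        forced_cue="cue_changeup",
    )
    conditions += [
        Condition(
            "conflict_strong_cue", conflict_env,
            SimpleScenarioParams(d_counts=(4.0, 1.0), rho_agent=0.8,
                                 a_strength=50.0, learn_context=True,
                                 learn_cue=True),
            note="cue counts sum to 50 per column, context counts to 5",
        ),
        Condition(
            "conflict_strong_context", conflict_env,
            SimpleScenarioParams(d_counts=(40.0, 10.0), rho_agent=0.8,
                                 a_strength=5.0, learn_context=True,
                                 learn_cue=True),
            note="context counts sum to 50, cue counts to 5 per column",
        ),
    ]

    # policy precision sweep: fixed confident prior, gamma decreases B1 -> B4
    tradeoff_env = EnvironmentSpec(scenario="tradeoff", p_changeup_true=0.2,
                                   rho_true=1.0)
    for gamma in (16.0, 4.0, 2.0, 1.0):
        conditions.append(
            Condition(
                f"policy_precision_gamma_{gamma:g}", tradeoff_env,
                TradeoffScenarioParams(d_counts=(4.0, 3.0), rho_agent=1.0,
                                       gamma=gamma),
            )
        )

    # reward sweep: naive 50/50 prior, veridical cue knowledge, slow context learning
    for label, r_early in (("low", 1.0), ("medium", 4.0), ("high", 8.0)):
        conditions.append(
            Condition(
                f"reward_{label}", tradeoff_env,
                TradeoffScenarioParams(
                    d_counts=(1.0, 1.0), rho_agent=1.0,
                    r_early=r_early, r_late=r_early / 2.0, loss=14.0,
                    learn_context=True, eta=0.1,
                ),
                n_observers=20, n_trials=60,
            )
        )

    # volatility: stable vs block-wise volatile orders with matched marginals
    hier_agent = HierarchicalParams()
    conditions += [
        Condition(
            "volatility_stable",
            EnvironmentSpec(scenario="hierarchical", p_changeup_true=0.5),
            hier_agent, n_trials=100,
        ),
        Condition(
            "volatility_volatile",
            EnvironmentSpec(
                scenario="hierarchical", p_changeup_true=0.5,
                volatility_schedule=((10, 0.2), (10, 0.8)),
            ),
            hier_agent, n_trials=100,
        ),
    ]
    return {c.name: c for c in conditions}


CONDITIONS: dict[str, Condition] = _registry()


def make_condition(name: str) -> Condition:
    """Look up a named experimental cell (environment spec + agent config)."""
    try:
        return CONDITIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown condition {name!r}; known: {sorted(CONDITIONS)}"
        ) from None
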