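"""Factored categorical generative models for the anticipation scenarios.

An observer faces a ball that is either *normal* or *change-up* (the hidden
context), receives a kinematic cue part-way through the trial, and must commit
to anticipating one of the two trajectories.  The observer's beliefs are a
discrete POMDP generative model in the usual (A, B, C, D) form:

* ``A`` — likelihood mappings from hidden states to observations,
* ``B`` — per-action transition tables for each hidden-state factor,
* ``C`` — prior preferences (log utilities) over observations per timepoint,
* ``D`` — priors over initial hidden states.

Two trial scenarios are built here. In the *simple* scenario the cue arrives
before the commitment deadline, so both policies wait one step and then commit.
In the *trade-off* scenario the observer may commit early for a higher reward
or wait for the cue and accept a discounted reward.  Stage-dependent cue
availability and the early/late reward asymmetry are expressed through a
behavioural state factor (start / observing / committed-*) so that A and C can
stay time-invariant.

Learnable quantities (the context prior and the cue contingency) are shadowed
by Dirichlet concentration counts in :class:`DirichletBeliefs`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .distributions import (
    NORM_TOL,
    CategoricalDist,
    normalize_counts,
    softmax,
)

# ---------------------------------------------------------------------------
# shared label vocabularies
# ---------------------------------------------------------------------------

CONTEXT_LABELS = ("normal", "changeup")
ACTION_LABELS = ("wait", "commit_normal", "commit_changeup")
CUE_LABELS = ("null", "cue_normal", "cue_changeup")

SIMPLE_BEHAVIOUR = ("start", "observing", "committed_normal", "committed_changeup")
SIMPLE_FEEDBACK = ("null", "correct", "incorrect")

TRADEOFF_BEHAVIOUR = (
    "start",
    "observing",
    "committed_early_normal",
    "committed_early_changeup",
    "committed_late_normal",
    "committed_late_changeup",
)
TRADEOFF_FEEDBACK = ("null", "early_correct", "late_correct", "incorrect")

HORIZON = 3  # start, cue stage, outcome stage


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LikelihoodMapping:
    """Conditional probability table P(o | s1, s2) for one observation modality.

    ``table`` has shape ``(n_outcomes, *factor_sizes)``; every column
    (conditioned on a state combination) must be a valid categorical
    distribution.
    """

    modality: str
    outcomes: tuple[str, ...]
    table: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        table = np.asarray(self.table, dtype=float)
        object.__setattr__(self, "table", table)
        if table.shape[0] != len(self.outcomes):
            raise ValueError(f"{self.modality}: leading axis must index outcomes")
        if np.any(table < 0):
            raise ValueError(f"{self.modality}: negative probability")
        colsums = table.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > NORM_TOL):
            raise ValueError(f"{self.modality}: columns must sum to 1")


@dataclass(frozen=True)
class TransitionMapping:
    """Per-action transition tables P(s' | s, a) for one hidden-state factor.

    ``tables`` has shape ``(n_states, n_states, n_actions)``; uncontrollable
    factors carry exactly one action-indexed table.
    """

    factor: str
    states: tuple[str, ...]
    tables: np.ndarray = field(repr=False)
    controllable: bool = False

    def __post_init__(self) -> None:
        tables = np.asarray(self.tables, dtype=float)
        object.__setattr__(self, "tables", tables)
        n = len(self.states)
        if tables.ndim != 3 or tables.shape[0] != n or tables.shape[1] != n:
            raise ValueError(f"{self.factor}: tables must be (n, n, n_actions)")
        if not self.controllable and tables.shape[2] != 1:
            raise ValueError(f"{self.factor}: uncontrollable factor needs one table")
        if np.any(tables < 0):
            raise ValueError(f"{self.factor}: negative probability")
        colsums = tables.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > NORM_TOL):
            raise ValueError(f"{self.factor}: columns must sum to 1")

    @property
    def n_actions(self) -> int:
        return self.tables.shape[2]


@dataclass(frozen=True)
class PreferenceMapping:
    """Prior preferences (log utilities) per modality, outcome and timepoint.

    Values are real-valued and only relative differences within a timepoint
    matter: the preference *distribution* used for the risk term is the softmax
    of each timepoint's column, so adding a constant leaves policy posteriors
    unchanged.
    """

    log_preferences: dict[str, np.ndarray]  # modality -> (n_outcomes, horizon)

    def __post_init__(self) -> None:
        clean = {}
        for modality, c in self.log_preferences.items():
            c = np.asarray(c, dtype=float)
            if not np.all(np.isfinite(c)):
                raise ValueError(f"{modality}: preferences must be finite")
            clean[modality] = c
        object.__setattr__(self, "log_preferences", clean)

    def distribution(self, modality: str, timepoint: int) -> np.ndarray:
        """Preference distribution sigma(C) for one modality at one timepoint."""
        return softmax(self.log_preferences[modality][:, timepoint], axis=-1)


@dataclass(frozen=True)
class PolicySet:
    """Candidate action sequences over the controllable behavioural factor.

    ``actions`` has shape ``(n_policies, horizon - 1)`` holding indices into
    :data:`ACTION_LABELS`.  Habit weights (a prior over policies) default to
    uniform and are deliberately unused by the built-in scenarios.
    """

    labels: tuple[str, ...]
    actions: np.ndarray = field(repr=False)
    habit_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        actions = np.asarray(self.actions, dtype=int)
        object.__setattr__(self, "actions", actions)
        if actions.ndim != 2 or actions.shape[0] != len(self.labels):
            raise ValueError("actions must be (n_policies, n_transitions)")
        if self.habit_weights is not None:
            hw = np.asarray(self.habit_weights, dtype=float)
            CategoricalDist(self.labels, hw)  # validates
            object.__setattr__(self, "habit_weights", hw)

    @property
    def n_policies(self) -> int:
        return len(self.labels)

    @property
    def n_transitions(self) -> int:
        return self.actions.shape[1]

    def habits(self) -> np.ndarray:
        if self.habit_weights is None:
            return np.full(self.n_policies, 1.0 / self.n_policies)
        return self.habit_weights


@dataclass(frozen=True)
class GenerativeModel:
    """An observer's full categorical generative model for one trial scenario."""

    scenario: str
    state_factors: dict[str, tuple[str, ...]]
    modalities: dict[str, tuple[str, ...]]
    A: tuple[LikelihoodMapping, ...]
    B: tuple[TransitionMapping, ...]
    C: PreferenceMapping
    D: tuple[CategoricalDist, ...]
    policies: PolicySet
    horizon: int = HORIZON
    gamma: float = 16.0
    alpha: float | str = "sample"  # action-selection determinism

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        self.validate()

    # -- consistency checks -------------------------------------------------
    def validate(self) -> None:
        factor_sizes = tuple(len(s) for s in self.state_factors.values())
        for a in self.A:
            if a.table.shape[1:] != factor_sizes:
                raise ValueError(f"A[{a.modality}] shape mismatch with state factors")
            if a.outcomes != self.modalities[a.modality]:
                raise ValueError(f"A[{a.modality}] outcome labels mismatch")
        for b, (name, states) in zip(self.B, self.state_factors.items()):
            if b.factor != name or b.states != states:
                raise ValueError(f"B[{b.factor}] does not match factor {name}")
        for d, (name, states) in zip(self.D, self.state_factors.items()):
            if d.labels != states:
                raise ValueError(f"D for factor {name} has wrong support")
        for modality, c in self.C.log_preferences.items():
            if c.shape != (len(self.modalities[modality]), self.horizon):
                raise ValueError(f"C[{modality}] must be (n_outcomes, horizon)")
        if self.policies.n_transitions != self.horizon - 1:
            raise ValueError("policies must span horizon - 1 transitions")

    # -- convenience lookups ------------------------------------------------
    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(self.state_factors)

    @property
    def modality_names(self) -> tuple[str, ...]:
        return tuple(self.modalities)

    def factor_index(self, name: str) -> int:
        return self.factor_names.index(name)

    def modality_index(self, name: str) -> int:
        return self.modality_names.index(name)

    def behaviour_labels(self) -> tuple[str, ...]:
        return self.state_factors["behaviour"]


@dataclass(frozen=True)
class DirichletBeliefs:
    """Dirichlet concentration counts shadowing the learnable model elements.

    ``d_counts`` (2,) shadows the context prior D; ``a_counts`` (2, 2) is the
    cue contingency table for the observing state, rows indexed by cue outcome
    (cue_normal, cue_changeup) and columns by true ball (normal, changeup).
    Only these two elements are learnable in the built-in scenarios; the full
    A tensor is rebuilt from the counts whenever cue learning is enabled.
    """

    d_counts: np.ndarray
    a_counts: np.ndarray
    learn_context: bool = False
    learn_cue: bool = False
    learning_rate: float = 1.0

    def __post_init__(self) -> None:
        d = np.asarray(self.d_counts, dtype=float)
        a = np.asarray(self.a_counts, dtype=float)
        object.__setattr__(self, "d_counts", d)
        object.__setattr__(self, "a_counts", a)
        if d.shape != (2,) or a.shape != (2, 2):
            raise ValueError("d_counts must be (2,) and a_counts (2, 2)")
        if np.any(d <= 0) or np.any(a <= 0):
            raise ValueError("concentration counts must be strictly positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")

    def context_prior(self) -> np.ndarray:
        return normalize_counts(self.d_counts, axis=0, name="d_counts")

    def cue_reliability_table(self) -> np.ndarray:
        return normalize_counts(self.a_counts, axis=0, name="a_counts")


# ---------------------------------------------------------------------------
# scenario parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimpleScenarioParams:
    """Parameters of the simple anticipation scenario.

    ``d_counts`` sets both the strength and the direction of the context
    prior (count magnitude encodes precision).  ``rho_agent`` is the believed
    cue reliability and ``a_strength`` the per-column concentration of the
    corresponding cue contingency counts.
    """

    d_counts: tuple[float, float] = (1.0, 1.0)
    rho_agent: float = 0.8
    a_strength: float = 10.0
    reward: float = 4.0
    loss: float = 4.0
    gamma: float = 16.0
    q_hit: float = 1.0  # P(correct feedback | matching commitment)
    learn_context: bool = False
    learn_cue: bool = False
    eta: float = 1.0
    action_mode: str = "sample"

    def __post_init__(self) -> None:
        _check_common(self.rho_agent, (self.reward, self.loss), self.gamma, self.eta)


@dataclass(frozen=True)
class TradeoffScenarioParams:
    """Parameters of the trade-off scenario (early high reward vs late cue)."""

    d_counts: tuple[float, float] = (1.0, 1.0)
    rho_agent: float = 1.0
    a_strength: float = 10.0
    r_early: float = 4.0
    r_late: float = 2.0
    loss: float = 6.0
    gamma: float = 16.0
    q_hit: float = 1.0
    learn_context: bool = False
    learn_cue: bool = False
    eta: float = 1.0
    action_mode: str = "sample"

    def __post_init__(self) -> None:
        _check_common(self.rho_agent, (self.r_early, self.r_late, self.loss),
                      self.gamma, self.eta)
        if self.r_early <= 0 or self.r_late <= 0:
            raise ValueError("rewards must be positive")
        if self.r_late >= self.r_early:
            raise ValueError(
                f"degenerate trade-off: r_late ({self.r_late}) must be below "
                f"r_early ({self.r_early})"
            )


def _check_common(rho: float, utilities: Sequence[float], gamma: float, eta: float) -> None:
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"cue reliability must lie in [0, 1], got {rho}")
    for u in utilities:
        if not np.isfinite(u):
            raise ValueError("utilities must be finite")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if eta <= 0:
        raise ValueError("learning rate must be positive")


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def initial_beliefs(params: SimpleScenarioParams | TradeoffScenarioParams) -> DirichletBeliefs:
    """Dirichlet counts implied by a scenario's prior settings."""
    rho = params.rho_agent
    a = params.a_strength * np.array([[rho, 1.0 - rho], [1.0 - rho, rho]])
    a = np.maximum(a, 1e-3)  # counts must stay positive even at rho in {0, 1}
    return DirichletBeliefs(
        d_counts=np.asarray(params.d_counts, dtype=float),
        a_counts=a,
        learn_context=params.learn_context,
        learn_cue=params.learn_cue,
        learning_rate=params.eta,
    )


def _cue_likelihood(reliability: np.ndarray, behaviour: tuple[str, ...]) -> np.ndarray:
    """Assemble the cue modality table from a 2x2 reliability table.

    The cue is informative only in the ``observing`` behavioural state; every
    other state emits the null cue with certainty.
    """
    n_b = len(behaviour)
    table = np.zeros((3, 2, n_b))
    table[0, :, :] = 1.0  # null everywhere...
    obs = behaviour.index("observing")
    table[0, :, obs] = 0.0  # ...except while observing
    table[1:, :, obs] = reliability
    return table


def _feedback_likelihood_simple(q_hit: float) -> np.ndarray:
    table = np.zeros((3, 2, len(SIMPLE_BEHAVIOUR)))
    table[0, :, :] = 1.0
    for j, committed in ((2, "normal"), (3, "changeup")):
        table[0, :, j] = 0.0
        for c, ball in enumerate(CONTEXT_LABELS):
            hit = q_hit if ball == committed else 1.0 - q_hit
            table[1, c, j] = hit
            table[2, c, j] = 1.0 - hit
    return table


def _feedback_likelihood_tradeoff(q_hit: float) -> np.ndarray:
    table = np.zeros((4, 2, len(TRADEOFF_BEHAVIOUR)))
    table[0, :, :] = 1.0
    spec = {2: ("normal", 1), 3: ("changeup", 1), 4: ("normal", 2), 5: ("changeup", 2)}
    for j, (committed, reward_row) in spec.items():
        table[0, :, j] = 0.0
        for c, ball in enumerate(CONTEXT_LABELS):
            hit = q_hit if ball == committed else 1.0 - q_hit
            table[reward_row, c, j] = hit
            table[3, c, j] = 1.0 - hit
    return table


def _behaviour_transitions(behaviour: tuple[str, ...], early_commit: bool) -> np.ndarray:
    """Per-action behaviour-state transitions.

    ``early_commit`` distinguishes the trade-off layout (commitments from the
    start state land in the early-committed states, commitments from the
    observing state in the late-committed ones) from the simple layout.
    """
    n = len(behaviour)
    tables = np.zeros((n, n, 3))
    idx = {s: i for i, s in enumerate(behaviour)}

    def dest(action: str, source: str) -> str:
        if source.startswith("committed"):
            return source  # absorbing
        if action == "wait":
            return "observing"
        ball = action.removeprefix("commit_")
        if early_commit:
            stage = "early" if source == "start" else "late"
            return f"committed_{stage}_{ball}"
        return f"committed_{ball}"

    for a, action in enumerate(ACTION_LABELS):
        for s, source in enumerate(behaviour):
            tables[idx[dest(action, source)], s, a] = 1.0
    return tables


def build_simple_model(params: SimpleScenarioParams | None = None) -> GenerativeModel:
    """Three-timepoint model: start, see the cue, commit and observe the outcome.

    Two policies — anticipate-normal and anticipate-changeup — both wait through
    the cue stage and then commit.
    """
    params = params or SimpleScenarioParams()
    beliefs = initial_beliefs(params)
    rho = params.rho_agent
    reliability = np.array([[rho, 1.0 - rho], [1.0 - rho, rho]])

    factors = {"context": CONTEXT_LABELS, "behaviour": SIMPLE_BEHAVIOUR}
    modalities = {"cue": CUE_LABELS, "feedback": SIMPLE_FEEDBACK}

    A = (
        LikelihoodMapping(
            "cue", CUE_LABELS,
            _cue_likelihood(reliability, SIMPLE_BEHAVIOUR),
        ),
        LikelihoodMapping("feedback", SIMPLE_FEEDBACK,
                          _feedback_likelihood_simple(params.q_hit)),
    )
    B = (
        TransitionMapping("context", CONTEXT_LABELS,
                          np.eye(2)[:, :, None], controllable=False),
        TransitionMapping("behaviour", SIMPLE_BEHAVIOUR,
                          _behaviour_transitions(SIMPLE_BEHAVIOUR, early_commit=False),
                          controllable=True),
    )
    C = PreferenceMapping({
        "cue": np.zeros((3, HORIZON)),
        "feedback": np.tile(
            np.array([0.0, params.reward, -params.loss])[:, None], (1, HORIZON)
        ),
    })
    D = (
        CategoricalDist(CONTEXT_LABELS, beliefs.context_prior()),
        CategoricalDist(SIMPLE_BEHAVIOUR, np.array([1.0, 0.0, 0.0, 0.0])),
    )
    policies = PolicySet(
        labels=("anticipate_normal", "anticipate_changeup"),
        actions=np.array([[0, 1], [0, 2]]),
    )
    return GenerativeModel(
        scenario="simple", state_factors=factors, modalities=modalities,
        A=A, B=B, C=C, D=D, policies=policies,
        gamma=params.gamma, alpha=params.action_mode,
    )


def build_tradeoff_model(params: TradeoffScenarioParams | None = None) -> GenerativeModel:
    """Trade-off model: commit early for a higher reward, or wait for the cue.

    Four policies of two transitions each: early-normal, early-changeup,
    wait-then-late-normal, wait-then-late-changeup.  Early policies use
    ``wait`` as a no-op placeholder once committed.
    """
    params = params or TradeoffScenarioParams()
    beliefs = initial_beliefs(params)
    rho = params.rho_agent
    reliability = np.array([[rho, 1.0 - rho], [1.0 - rho, rho]])

    factors = {"context": CONTEXT_LABELS, "behaviour": TRADEOFF_BEHAVIOUR}
    modalities = {"cue": CUE_LABELS, "feedback": TRADEOFF_FEEDBACK}

    A = (
        LikelihoodMapping(
            "cue", CUE_LABELS,
            _cue_likelihood(reliability, TRADEOFF_BEHAVIOUR),
        ),
        LikelihoodMapping("feedback", TRADEOFF_FEEDBACK,
                          _feedback_likelihood_tradeoff(params.q_hit)),
    )
    B = (
        TransitionMapping("context", CONTEXT_LABELS,
                          np.eye(2)[:, :, None], controllable=False),
        TransitionMapping("behaviour", TRADEOFF_BEHAVIOUR,
                          _behaviour_transitions(TRADEOFF_BEHAVIOUR, early_commit=True),
                          controllable=True),
    )
    C = PreferenceMapping({
        "cue": np.zeros((3, HORIZON)),
        "feedback": np.tile(
            np.array([0.0, params.r_early, params.r_late, -params.loss])[:, None],
            (1, HORIZON),
        ),
    })
    D = (
        CategoricalDist(CONTEXT_LABELS, beliefs.context_prior()),
        CategoricalDist(TRADEOFF_BEHAVIOUR, np.array([1.0] + [0.0] * 5)),
    )
    policies = PolicySet(
        labels=("early_normal", "early_changeup", "late_normal", "late_changeup"),
        actions=np.array([[1, 0], [2, 0], [0, 1], [0, 2]]),
    )
    return GenerativeModel(
        scenario="tradeoff", state_factors=factors, modalities=modalities,
        A=A, B=B, C=C, D=D, policies=policies,
        gamma=params.gamma, alpha=params.action_mode,
    )


def with_preferences(model: GenerativeModel, feedback_utilities: np.ndarray) -> GenerativeModel:
    """Return a copy of ``model`` whose feedback utilities are replaced.

    Used for reward sweeps, which by construction differ only in C.
    """
    c = dict(model.C.log_preferences)
    c["feedback"] = np.tile(np.asarray(feedback_utilities, float)[:, None],
                            (1, model.horizon))
    return replace(model, C=PreferenceMapping(c))
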