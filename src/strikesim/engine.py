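"""Per-trial inference: state posteriors, free energies, action selection,
and Dirichlet learning.

State inference is a fixed-point scheme: it sweeps over hidden-state factors,
and for each factor runs exact forward--backward message passing along the
trial's three timepoints, with the likelihood evidence for the other factor
taken in expectation (an expected-log contraction).  Sweeps repeat until the
largest belief change falls below tolerance.  On the built-in scenarios the
behavioural factor is deterministic given the policy, so the scheme coincides
with exact Bayesian smoothing of the context factor — a property the test
suite pins against a brute-force enumeration oracle.

Policy evaluation uses the expected free energy

    G(pi) = risk + ambiguity - novelty,

where risk is the KL divergence from predicted outcomes to the preference
distribution sigma(C), ambiguity is the expected conditional entropy of the
likelihood mapping, and novelty (nonzero only while cue learning is enabled)
is the expected information gain about the cue's Dirichlet counts.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .distributions import (
    dirichlet_expected_log,
    entropy,
    floored_log,
    kl_divergence,
    normalize_counts,
    softmax,
)
from .model import (
    CUE_LABELS,
    DirichletBeliefs,
    GenerativeModel,
    PolicySet,
    _cue_likelihood,
)

MAX_ITERS = 64
CONV_TOL = 1e-6

Observations = dict[int, dict[str, str]]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class StatePosteriors:
    """Posterior (and predictive) state beliefs under one policy.

    ``marginals[f]`` is a ``(horizon, n_states)`` array for factor ``f``;
    timepoints with no observation yet hold the policy-conditioned predictive
    distribution.  Policy-averaged marginals are produced by
    :func:`policy_averaged_marginals`.
    """

    factor_names: tuple[str, ...]
    marginals: list[np.ndarray]
    converged: bool
    iterations: int
    warning: bool = False

    def factor(self, name: str) -> np.ndarray:
        return self.marginals[self.factor_names.index(name)]


@dataclass
class EFEReport:
    """Expected free energy per policy, decomposed into its terms.

    The identity ``G = risk + ambiguity - novelty`` holds exactly by
    construction and is asserted in the tests; novelty is zero whenever cue
    learning is disabled.
    """

    policies: tuple[str, ...]
    G: np.ndarray
    risk: np.ndarray
    ambiguity: np.ndarray
    novelty: np.ndarray


# ---------------------------------------------------------------------------
# effective model tables (plain or expected-log, depending on learning)
# ---------------------------------------------------------------------------


def effective_tables(
    model: GenerativeModel, dirichlet: DirichletBeliefs | None
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Return (A_probs, D_probs, ln_A, ln_D) for inference and prediction.

    When a component is learnable its log table is the Dirichlet expected log
    (digamma-based); its probability table is the normalised mean of the
    counts.  Otherwise the model's stated probabilities are used directly.
    """
    A_probs = [a.table.copy() for a in model.A]
    D_probs = [d.probs.copy() for d in model.D]
    ln_A = [floored_log(t) for t in A_probs]
    ln_D = [floored_log(p) for p in D_probs]

    if dirichlet is None:
        return A_probs, D_probs, ln_A, ln_D

    # components that are not being learned keep the model's stated beliefs;
    # learnable components are rebuilt from the current counts
    if dirichlet.learn_context:
        ci = model.factor_index("context")
        D_probs[ci] = dirichlet.context_prior()
        ln_D[ci] = dirichlet_expected_log(dirichlet.d_counts)
    if dirichlet.learn_cue:
        cue_i = model.modality_index("cue")
        behaviour = model.behaviour_labels()
        obs_j = behaviour.index("observing")
        A_probs[cue_i] = _cue_likelihood(dirichlet.cue_reliability_table(), behaviour)
        ln_A[cue_i] = floored_log(A_probs[cue_i])
        ln_A[cue_i][1:, :, obs_j] = dirichlet_expected_log(dirichlet.a_counts)
    return A_probs, D_probs, ln_A, ln_D


def _observation_indices(model: GenerativeModel, observations: Observations) -> dict:
    idx: dict[int, dict[int, int]] = {}
    for tau, obs in observations.items():
        idx[tau] = {}
        for modality, label in obs.items():
            m = model.modality_index(modality)
            idx[tau][m] = model.modalities[modality].index(label)
    return idx


def _policy_actions(model: GenerativeModel, policy: int) -> np.ndarray:
    return model.policies.actions[policy]


def _evidence_logs(
    model: GenerativeModel,
    f: int,
    q: list[np.ndarray],
    ln_A: list[np.ndarray],
    obs_idx: dict[int, dict[int, int]],
) -> np.ndarray:
    """Expected log-likelihood evidence for factor ``f`` at every timepoint."""
    T = model.horizon
    n_f = q[f].shape[1]
    ev = np.zeros((T, n_f))
    other = 1 - f  # two factors in the built-in scenarios
    for tau, modalities in obs_idx.items():
        for m, o in modalities.items():
            lnA_o = ln_A[m][o]  # (n_context, n_behaviour)
            if f == 0:
                ev[tau] += lnA_o @ q[other][tau]
            else:
                ev[tau] += q[other][tau] @ lnA_o
    return ev


def _forward_backward(
    D: np.ndarray,
    B: np.ndarray,
    actions: np.ndarray,
    ev: np.ndarray,
    controllable: bool,
) -> np.ndarray:
    """Exact smoothing for one factor given fixed evidence weights."""
    T, n = ev.shape
    w = np.exp(ev - ev.max(axis=1, keepdims=True))
    alpha = np.zeros((T, n))
    a0 = D * w[0]
    alpha[0] = a0 / a0.sum()
    for tau in range(1, T):
        a_idx = actions[tau - 1] if controllable else 0
        pred = B[:, :, a_idx] @ alpha[tau - 1]
        joint = w[tau] * pred
        total = joint.sum()
        alpha[tau] = joint / total if total > 0 else np.full(n, 1.0 / n)
    beta = np.ones((T, n))
    for tau in range(T - 2, -1, -1):
        a_idx = actions[tau] if controllable else 0
        msg = B[:, :, a_idx].T @ (w[tau + 1] * beta[tau + 1])
        beta[tau] = msg / msg.max() if msg.max() > 0 else np.ones(n)
    post = alpha * beta
    return post / post.sum(axis=1, keepdims=True)


def infer_states(
    model: GenerativeModel,
    observations: Observations,
    policy: int,
    dirichlet: DirichletBeliefs | None = None,
    max_iters: int = MAX_ITERS,
    tol: float = CONV_TOL,
    tables: tuple | None = None,
) -> StatePosteriors:
    """Infer per-timepoint state posteriors under one policy.

    ``observations`` maps timepoint -> {modality: outcome label} for the
    timepoints observed so far; later timepoints receive the policy-conditioned
    predictive beliefs.  Iterates factor-wise exact smoothing until the largest
    absolute belief change is below ``tol`` (cap ``max_iters``; hitting the cap
    sets a warning flag instead of raising).
    """
    _, _, ln_A, ln_D = tables if tables is not None else effective_tables(model, dirichlet)
    obs_idx = _observation_indices(model, observations)
    actions = _policy_actions(model, policy)
    T = model.horizon

    q = [np.full((T, len(s)), 1.0 / len(s)) for s in model.state_factors.values()]
    converged = False
    iterations = 0
    for iterations in range(1, max_iters + 1):
        max_delta = 0.0
        for f, b in enumerate(model.B):
            ev = _evidence_logs(model, f, q, ln_A, obs_idx)
            q_new = _forward_backward(
                np.exp(ln_D[f]) / np.exp(ln_D[f]).sum(),
                b.tables, actions, ev, b.controllable,
            )
            max_delta = max(max_delta, float(np.abs(q_new - q[f]).max()))
            q[f] = q_new
        if max_delta < tol:
            converged = True
            break

    return StatePosteriors(
        factor_names=model.factor_names,
        marginals=q,
        converged=converged,
        iterations=iterations,
        warning=not converged,
    )


# ---------------------------------------------------------------------------
# free energies
# ---------------------------------------------------------------------------


def variational_free_energy(
    model: GenerativeModel,
    posteriors: StatePosteriors,
    observations: Observations,
    policy: int,
    dirichlet: DirichletBeliefs | None = None,
    tables: tuple | None = None,
) -> float:
    """Variational free energy of the beliefs given the observations so far.

    Computed as the complexity of each factor's beliefs against its forward
    prior-predictive message, minus the expected log-evidence of the observed
    outcomes.  At the inference fixed point this bounds the negative log
    evidence of the observations from above.
    """
    _, D_probs, ln_A, _ = tables if tables is not None else effective_tables(model, dirichlet)
    obs_idx = _observation_indices(model, observations)
    actions = _policy_actions(model, policy)
    T = model.horizon

    F = 0.0
    for f, b in enumerate(model.B):
        qf = posteriors.marginals[f]
        if qf.shape[0] != T:
            raise ValueError("posterior horizon does not match the model")
        prior = D_probs[f]
        for tau in range(T):
            F += kl_divergence(qf[tau], prior)
            if tau < T - 1:
                a_idx = actions[tau] if b.controllable else 0
                prior = b.tables[:, :, a_idx] @ qf[tau]
    for tau, modalities in obs_idx.items():
        for m, o in modalities.items():
            lnA_o = ln_A[m][o]
            F -= float(posteriors.marginals[0][tau] @ lnA_o @ posteriors.marginals[1][tau])
    return F


def expected_free_energy(
    model: GenerativeModel,
    posteriors: StatePosteriors,
    policy: int,
    dirichlet: DirichletBeliefs | None = None,
    from_time: int = 0,
    tables: tuple | None = None,
) -> tuple[float, float, float]:
    """(risk, ambiguity, novelty) summed over the policy's future timepoints.

    ``posteriors`` must contain the policy-conditioned predictive beliefs (as
    produced by :func:`infer_states` with the observations received up to
    ``from_time``).  Risk and ambiguity are accumulated per modality; novelty
    (the expected Dirichlet information gain about the cue contingency) enters
    only while cue learning is enabled.
    """
    A_probs = (tables if tables is not None else effective_tables(model, dirichlet))[0]
    T = model.horizon
    behaviour = model.behaviour_labels()
    obs_j = behaviour.index("observing")
    cue_i = model.modality_index("cue")

    risk = 0.0
    ambiguity = 0.0
    novelty = 0.0
    for tau in range(from_time + 1, T):
        q_c = posteriors.marginals[0][tau]
        q_b = posteriors.marginals[1][tau]
        for m, name in enumerate(model.modality_names):
            A = A_probs[m]
            qo = np.einsum("oij,i,j->o", A, q_c, q_b)
            risk += kl_divergence(qo, model.C.distribution(name, tau))
            col_entropy = -np.sum(
                np.where(A > 0, A * np.log(np.maximum(A, 1e-300)), 0.0), axis=0
            )
            ambiguity += float(q_c @ col_entropy @ q_b)
            if name == "cue" and dirichlet is not None and dirichlet.learn_cue:
                a = dirichlet.a_counts
                w = 0.5 * (1.0 / a - 1.0 / a.sum(axis=0, keepdims=True))
                rel = normalize_counts(a, axis=0, name="a_counts")
                joint = rel * q_c[None, :] * q_b[obs_j]
                novelty += float(np.sum(joint * w))
    return risk, ambiguity, novelty


def efe_report(
    model: GenerativeModel,
    posteriors_by_policy: dict[int, StatePosteriors],
    dirichlet: DirichletBeliefs | None = None,
    from_time: int = 0,
    tables: tuple | None = None,
) -> EFEReport:
    """Assemble the per-policy expected free energy decomposition."""
    idx = sorted(posteriors_by_policy)
    risk = np.zeros(len(idx))
    amb = np.zeros(len(idx))
    nov = np.zeros(len(idx))
    for k, p in enumerate(idx):
        risk[k], amb[k], nov[k] = expected_free_energy(
            model, posteriors_by_policy[p], p, dirichlet, from_time, tables=tables
        )
    return EFEReport(
        policies=tuple(model.policies.labels[p] for p in idx),
        G=risk + amb - nov,
        risk=risk,
        ambiguity=amb,
        novelty=nov,
    )


# ---------------------------------------------------------------------------
# policy and action selection
# ---------------------------------------------------------------------------


def policy_posterior(
    G: np.ndarray, gamma: float, habits: np.ndarray | None = None
) -> np.ndarray:
    """softmax(ln habits - gamma * G); gamma = 0 recovers the habit prior."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    G = np.asarray(G, dtype=float)
    if not np.all(np.isfinite(G)):
        raise ValueError("expected free energies must be finite")
    if habits is None:
        habits = np.full(G.shape, 1.0 / G.size)
    return softmax(floored_log(habits) - gamma * G, axis=-1)


def select_action(
    policy_post: np.ndarray,
    policy_actions: np.ndarray,
    mode: str = "sample",
    rng: np.random.Generator | None = None,
) -> tuple[int, float]:
    """Marginalise the policy posterior onto the next action and choose one.

    ``policy_actions`` holds each policy's next action index.  Sampling uses
    the provided generator; argmax breaks ties in favour of the lowest action
    index.  Returns ``(action index, probability of that action)``.
    """
    policy_post = np.asarray(policy_post, dtype=float)
    policy_actions = np.asarray(policy_actions, dtype=int)
    n_actions = int(policy_actions.max()) + 1
    marginal = np.zeros(max(n_actions, 1))
    for p, a in zip(policy_post, policy_actions):
        marginal[a] += p
    marginal = marginal / marginal.sum()
    if mode == "argmax":
        action = int(np.argmax(marginal))
    elif mode == "sample":
        if rng is None:
            raise ValueError("sampling requires a random generator")
        action = int(rng.choice(len(marginal), p=marginal))
    else:
        raise ValueError(f"unknown action-selection mode {mode!r}")
    return action, float(marginal[action])


def policy_averaged_marginals(
    posteriors_by_policy: dict[int, StatePosteriors],
    policy_post: np.ndarray,
) -> list[np.ndarray]:
    """Bayesian model average of state marginals under the policy posterior.

    ``policy_post`` must be ordered by sorted policy index and normalised.
    """
    idx = sorted(posteriors_by_policy)
    if len(idx) != len(policy_post):
        raise ValueError("one posterior weight per policy is required")
    first = posteriors_by_policy[idx[0]]
    out = [np.zeros_like(m) for m in first.marginals]
    for w, p in zip(policy_post, idx):
        for f, m in enumerate(posteriors_by_policy[p].marginals):
            out[f] += w * m
    return out


def consistent_policies(policies: PolicySet, history: list[int]) -> list[int]:
    """Indices of policies whose first actions match the actions taken so far."""
    t = len(history)
    return [
        p for p in range(policies.n_policies)
        if list(policies.actions[p, :t]) == history
    ]


# ---------------------------------------------------------------------------
# learning
# ---------------------------------------------------------------------------


def update_dirichlet(
    dirichlet: DirichletBeliefs,
    context_posterior: np.ndarray,
    cue_observation: str | None = None,
    cue_context_posterior: np.ndarray | None = None,
) -> DirichletBeliefs:
    """Post-trial Dirichlet count updates.

    With context learning on, the trial's final posterior over the ball is
    added to ``d_counts`` (scaled by the learning rate).  With cue learning on
    and an informative cue observed, the posterior over the ball at the cue
    timepoint is added to that cue outcome's row of ``a_counts``.  Disabled
    components are returned unchanged.
    """
    eta = dirichlet.learning_rate
    d = dirichlet.d_counts
    a = dirichlet.a_counts
    if dirichlet.learn_context:
        d = d + eta * np.asarray(context_posterior, dtype=float)
    if dirichlet.learn_cue and cue_observation in CUE_LABELS[1:]:
        if cue_context_posterior is None:
            raise ValueError("cue learning requires the context posterior at cue time")
        row = CUE_LABELS[1:].index(cue_observation)
        a = a.copy()
        a[row, :] += eta * np.asarray(cue_context_posterior, dtype=float)
    return replace(dirichlet, d_counts=d, a_counts=a)
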