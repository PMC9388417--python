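"""Shared fixtures and the brute-force exact-Bayes oracle.

The oracle enumerates every joint hidden-state trajectory of a model (both
factors at every timepoint), scores it with the chain rule — initial priors,
transition probabilities under the policy, and likelihoods of the observed
outcomes — and normalises.  It is deliberately naive (plain Python loops over
the full product space, no message passing) so it stays independent of the
engine's fixed-point scheme.
"""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from strikesim.model import (
    GenerativeModel,
    SimpleScenarioParams,
    TradeoffScenarioParams,
    build_simple_model,
    build_tradeoff_model,
)


def enumerate_posterior(
    model: GenerativeModel,
    observations: dict[int, dict[str, str]],
    policy: int,
) -> list[np.ndarray]:
    """Exact per-timepoint marginals by full joint enumeration."""
    T = model.horizon
    sizes = [len(s) for s in model.state_factors.values()]
    actions = model.policies.actions[policy]
    obs_idx: dict[int, list[tuple[int, int]]] = {}
    for tau, obs in observations.items():
        obs_idx[tau] = [
            (m, model.modalities[name].index(label))
            for m, (name, label) in enumerate(
                (name, obs[name]) for name in model.modality_names if name in obs
            )
        ]

    marginals = [np.zeros((T, n)) for n in sizes]
    total = 0.0
    per_tau_states = list(itertools.product(*[range(n) for n in sizes]))
    for trajectory in itertools.product(per_tau_states, repeat=T):
        p = 1.0
        for f in range(len(sizes)):
            p *= model.D[f].probs[trajectory[0][f]]
        for tau in range(1, T):
            for f, b in enumerate(model.B):
                a = actions[tau - 1] if b.controllable else 0
                p *= b.tables[trajectory[tau][f], trajectory[tau - 1][f], a]
        for tau, pairs in obs_idx.items():
            for m, o in pairs:
                p *= model.A[m].table[(o, *trajectory[tau])]
        if p == 0.0:
            continue
        total += p
        for tau in range(T):
            for f in range(len(sizes)):
                marginals[f][tau, trajectory[tau][f]] += p
    assert total > 0, "observations impossible under the model"
    return [m / total for m in marginals]


def random_simple_model(rng: np.random.Generator) -> GenerativeModel:
    d = rng.uniform(0.2, 5.0, size=2)
    return build_simple_model(
        SimpleScenarioParams(
            d_counts=tuple(d),
            rho_agent=float(rng.uniform(0.05, 0.95)),
            reward=float(rng.uniform(0.5, 6.0)),
            loss=float(rng.uniform(0.5, 6.0)),
            q_hit=float(rng.uniform(0.6, 1.0)),
        )
    )


def random_tradeoff_model(rng: np.random.Generator) -> GenerativeModel:
    d = rng.uniform(0.2, 5.0, size=2)
    r_early = float(rng.uniform(1.0, 6.0))
    return build_tradeoff_model(
        TradeoffScenarioParams(
            d_counts=tuple(d),
            rho_agent=float(rng.uniform(0.05, 0.95)),
            r_early=r_early,
            r_late=float(rng.uniform(0.2, 0.9) * r_early),
            loss=float(rng.uniform(0.5, 8.0)),
            q_hit=float(rng.uniform(0.6, 1.0)),
        )
    )


def random_observations(
    model: GenerativeModel, policy: int, rng: np.random.Generator
) -> dict[int, dict[str, str]]:
    """A random observation history consistent with the policy's behaviour path."""
    # follow the behaviour chain deterministically under the policy
    b_labels = model.behaviour_labels()
    behaviour = ["start"]
    tables = model.B[1].tables
    for a in model.policies.actions[policy]:
        prev = b_labels.index(behaviour[-1])
        behaviour.append(b_labels[int(np.argmax(tables[:, prev, a]))])
    upto = int(rng.integers(1, model.horizon + 1))  # observe tau < upto
    observations: dict[int, dict[str, str]] = {}
    for tau in range(upto):
        obs: dict[str, str] = {}
        if behaviour[tau] == "observing":
            obs["cue"] = str(rng.choice(["cue_normal", "cue_changeup"]))
            obs["feedback"] = "null"
        elif behaviour[tau].startswith("committed"):
            obs["cue"] = "null"
            fb = model.modalities["feedback"]
            b_idx = b_labels.index(behaviour[tau])
            table = model.A[model.modality_index("feedback")].table
            emittable = [
                label for o, label in enumerate(fb)
                if label != "null" and table[o, :, b_idx].max() > 0
            ]
            obs["feedback"] = str(rng.choice(emittable))
        else:
            obs = {"cue": "null", "feedback": "null"}
        observations[tau] = obs
    return observations


@pytest.fixture
def simple_model() -> GenerativeModel:
    return build_simple_model()


@pytest.fixture
def tradeoff_model() -> GenerativeModel:
    return build_tradeoff_model()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
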