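"""Across-trial hierarchical model of contextual volatility.

The lower level tracks the marginal probability of a change-up ball with
Dirichlet counts, exactly as in the flat scenarios.  The higher level is a
hidden Markov model over context *regimes* (e.g. mostly-normal vs
mostly-changeup): each trial's revealed ball is an emission from the current
regime, and the believed regime-persistence probability encodes how stable the
observer expects the wider context to be.

Two per-trial free-energy streams are exposed.  The *observation surprisal*
-ln p(o_t | o_<t) under the regime filter tracks how well the observations are
predicted; with matched outcome marginals it is similar across stable and
volatile orders.  The *belief-update free energy* KL(q_t || prior predictive)
is the complexity cost of revising the regime belief: when the observer
expects a fixed regime but the trial order keeps flipping, every reversal
forces a large revision, so this regime-level prediction error is what
separates a volatile order from a stable one.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import floored_log, normalize_counts


@dataclass(frozen=True)
class HierarchicalParams:
    """Configuration of the regime-level model.

    ``p_changeup_by_regime`` gives each regime's emission probability of a
    change-up ball; ``persistence`` is the believed probability that the
    regime survives from one higher-level step to the next (1 = the observer
    expects a fixed regime for the whole session).  ``update_interval`` is the
    higher level's timescale in trials: the regime belief is revised from the
    accumulated evidence once per interval, while the frozen belief predicts
    each ball within it.
    """

    regimes: tuple[str, ...] = ("mostly_normal", "mostly_changeup")
    p_changeup_by_regime: tuple[float, ...] = (0.2, 0.8)
    persistence: float = 1.0
    update_interval: int = 10
    d_counts: tuple[float, float] = (1.0, 1.0)
    eta: float = 1.0

    def __post_init__(self) -> None:
        if self.update_interval < 1:
            raise ValueError("update interval must be at least 1")
        if len(self.regimes) != len(self.p_changeup_by_regime):
            raise ValueError("one emission probability per regime is required")
        if len(self.regimes) < 2:
            raise ValueError("at least two regimes are required")
        for p in self.p_changeup_by_regime:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"emission probability {p} outside [0, 1]")
        if not 0.0 < self.persistence <= 1.0:
            raise ValueError(
                f"persistence must lie in (0, 1], got {self.persistence}"
            )


@dataclass(frozen=True)
class HierarchicalModel:
    """Regime HMM: transition matrix, emissions, and the initial regime prior."""

    regimes: tuple[str, ...]
    emissions: np.ndarray = field(repr=False)   # (n_regimes, 2): P(normal), P(changeup)
    transition: np.ndarray = field(repr=False)  # (n_regimes, n_regimes), columns sum to 1
    prior: np.ndarray = field(repr=False)

    def predictive_regime(self, belief: np.ndarray) -> np.ndarray:
        return self.transition @ belief

    def predictive_outcome(self, belief: np.ndarray) -> np.ndarray:
        """Predictive distribution over (normal, changeup) for the next trial."""
        return self.emissions.T @ self.predictive_regime(belief)

    def update(
        self, belief: np.ndarray, ball_index: int
    ) -> tuple[np.ndarray, float, float]:
        """One filtering step.

        Returns the new regime posterior, the surprisal of the observed ball
        under the predictive distribution, and the belief-update free energy
        KL(posterior || predictive prior) — the complexity of the revision the
        observation forced on the regime belief.
        """
        prior = self.predictive_regime(belief)
        lik = self.emissions[:, ball_index]
        joint = prior * lik
        evidence = float(joint.sum())
        posterior = joint / evidence if evidence > 0 else prior
        surprisal = float(-floored_log(np.array([evidence]))[0])
        mask = posterior > 0
        update_fe = float(
            np.sum(posterior[mask] * (np.log(posterior[mask])
                                      - floored_log(prior[mask])))
        )
        return posterior, surprisal, update_fe


def build_hierarchical_model(params: HierarchicalParams) -> HierarchicalModel:
    """Construct the regime HMM implied by the parameters.

    The transition matrix keeps the current regime with probability
    ``persistence`` and otherwise switches uniformly among the others.
    """
    n = len(params.regimes)
    p_cu = np.asarray(params.p_changeup_by_regime, dtype=float)
    emissions = np.stack([1.0 - p_cu, p_cu], axis=1)
    kappa = params.persistence
    transition = np.full((n, n), (1.0 - kappa) / (n - 1))
    np.fill_diagonal(transition, kappa)
    prior = np.full(n, 1.0 / n)
    return HierarchicalModel(params.regimes, emissions, transition, prior)


@dataclass
class HierarchicalTrace:
    """Per-trial quantities from running the two-level observer on a sequence."""

    balls: list[str]
    regime_posteriors: np.ndarray      # (n_trials, n_regimes)
    surprisal: np.ndarray              # (n_trials,) regime-filter obs. surprisal
    update_free_energy: np.ndarray     # (n_trials,) regime belief-update KL
    lower_surprisal: np.ndarray        # (n_trials,) surprisal under lower-level belief
    lower_p_changeup: np.ndarray       # (n_trials,) after each trial's count update
    final_d_counts: np.ndarray

    @property
    def total_update_free_energy(self) -> float:
        """Summed regime-level belief-update free energy over the session."""
        return float(self.update_free_energy.sum())

    @property
    def total_surprisal(self) -> float:
        return float(self.surprisal.sum())


def run_hierarchical(
    params: HierarchicalParams, balls: list[str]
) -> HierarchicalTrace:
    """Filter a revealed ball sequence through both levels of the model.

    The lower level updates its change-up counts every trial.  The higher
    level operates on its own slower timescale: within an update interval the
    frozen regime belief supplies the predictive distribution for each ball
    (whose surprisal is recorded per trial), and at the end of the interval
    the belief is revised in one step from the interval's accumulated
    log-likelihood — the belief-update free energy KL(new belief || old
    belief propagated through the transition model) is recorded at that
    boundary trial.
    """
    model = build_hierarchical_model(params)
    belief = model.prior.copy()
    d = np.asarray(params.d_counts, dtype=float)
    n = len(balls)
    n_regimes = len(params.regimes)
    posts = np.zeros((n, n_regimes))
    surprisal = np.zeros(n)
    update_fe = np.zeros(n)
    lower_surprisal = np.zeros(n)
    lower = np.zeros(n)
    chunk_loglik = np.zeros(n_regimes)

    def revise(t: int) -> None:
        nonlocal belief, chunk_loglik
        prior = model.predictive_regime(belief)
        log_post = floored_log(prior) + chunk_loglik
        post = np.exp(log_post - log_post.max())
        post /= post.sum()
        mask = post > 0
        update_fe[t] = float(
            np.sum(post[mask] * (np.log(post[mask]) - floored_log(prior[mask])))
        )
        belief = post
        chunk_loglik = np.zeros(n_regimes)

    for t, ball in enumerate(balls):
        idx = 0 if ball == "normal" else 1
        p_lower = normalize_counts(d)
        lower_surprisal[t] = -floored_log(p_lower[[idx]])[0]
        lik = model.emissions[:, idx]
        surprisal[t] = -floored_log(np.array([float(belief @ lik)]))[0]
        chunk_loglik = chunk_loglik + floored_log(lik)
        if (t + 1) % params.update_interval == 0 or t == n - 1:
            revise(t)
        posts[t] = belief
        d = d + params.eta * np.eye(2)[idx]
        lower[t] = normalize_counts(d)[1]
    return HierarchicalTrace(
        balls=list(balls), regime_posteriors=posts, surprisal=surprisal,
        update_free_energy=update_fe, lower_surprisal=lower_surprisal,
        lower_p_changeup=lower, final_d_counts=d,
    )
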