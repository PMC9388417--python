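"""Batch runners and summaries for the principle-by-principle simulations.

Each named condition pairs an environment specification with an agent
configuration; :func:`run_batch` simulates independently seeded observers and
aggregates tidy per-trial tables, and :func:`run_battery` runs the condition
sets that correspond to the phenomenon-level simulation batteries (learning
curves, single-trial beliefs, congruency grid, precision conflict, policy
precision, reward sweep, volatility).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .engine import (
    EFEReport,
    effective_tables,
    consistent_policies,
    efe_report,
    infer_states,
    policy_posterior,
    select_action,
    update_dirichlet,
    variational_free_energy,
)
from .environments import Condition, EnvState, generate_trial_sequence, step_environment
from .hierarchy import HierarchicalParams, run_hierarchical
from .model import (
    ACTION_LABELS,
    DirichletBeliefs,
    GenerativeModel,
    SimpleScenarioParams,
    TradeoffScenarioParams,
    build_simple_model,
    build_tradeoff_model,
    initial_beliefs,
)

SUCCESS_FEEDBACK = {"correct", "early_correct", "late_correct"}


# ---------------------------------------------------------------------------
# per-trial execution
# ---------------------------------------------------------------------------


@dataclass
class AgentState:
    """An observer mid-session: generative model plus current Dirichlet counts."""

    model: GenerativeModel
    dirichlet: DirichletBeliefs
    action_mode: str = "sample"

    @classmethod
    def from_params(
        cls, params: SimpleScenarioParams | TradeoffScenarioParams
    ) -> "AgentState":
        if isinstance(params, TradeoffScenarioParams):
            model = build_tradeoff_model(params)
        else:
            model = build_simple_model(params)
        return cls(model=model, dirichlet=initial_beliefs(params),
                   action_mode=params.action_mode)


@dataclass
class TrialRecord:
    """Everything one trial produced."""

    trial: int
    ball: str
    observations: dict[int, dict[str, str]]
    posterior_changeup: tuple[float, ...]  # context posterior per timepoint
    efe: EFEReport                         # evaluated at the start of the trial
    actions: tuple[str, ...]
    action_probs: tuple[float, ...]
    committed: str
    commit_stage: str
    wait_first: bool
    feedback: str
    success: bool
    free_energy: float
    d_counts_after: np.ndarray = field(repr=False)
    inference_warning: bool = False

    @property
    def action_prob(self) -> float:
        """Probability of the commitment action at its decision point."""
        decision = 0 if self.commit_stage == "early" else 1
        return self.action_probs[decision]


def run_trial(
    agent: AgentState,
    condition: Condition,
    ball: str,
    rng: np.random.Generator,
    trial_index: int = 0,
) -> TrialRecord:
    """Execute one trial: infer, evaluate G, act, observe, learn.

    At each decision point only the policies consistent with the actions
    already taken remain in play; the chosen action is the (sampled or argmax)
    marginal of the policy posterior.  After the outcome is observed the
    Dirichlet counts are updated in place on ``agent``.
    """
    model = agent.model
    spec = condition.spec
    env_state = EnvState(ball=ball)
    observations: dict[int, dict[str, str]] = {0: {"cue": "null", "feedback": "null"}}
    history: list[int] = []
    actions_taken: list[str] = []
    action_probs: list[float] = []
    report_t0: EFEReport | None = None
    warning = False

    tables = effective_tables(model, agent.dirichlet)
    for t in range(model.horizon - 1):
        cons = consistent_policies(model.policies, history)
        posts = {
            p: infer_states(model, observations, p, agent.dirichlet, tables=tables)
            for p in cons
        }
        warning = warning or any(posts[p].warning for p in cons)
        report = efe_report(model, posts, agent.dirichlet, from_time=t, tables=tables)
        if t == 0:
            report_t0 = report
        habits = model.policies.habits()[cons]
        ppost = policy_posterior(report.G, model.gamma, habits / habits.sum())
        a_idx, prob = select_action(
            ppost, model.policies.actions[cons, t], mode=agent.action_mode, rng=rng
        )
        observations[t + 1] = step_environment(
            env_state, ACTION_LABELS[a_idx], t, spec, rng
        )
        history.append(a_idx)
        actions_taken.append(ACTION_LABELS[a_idx])
        action_probs.append(prob)

    realized = consistent_policies(model.policies, history)[0]
    final = infer_states(model, observations, realized, agent.dirichlet, tables=tables)
    warning = warning or final.warning
    free_energy = variational_free_energy(
        model, final, observations, realized, agent.dirichlet, tables=tables
    )

    q_context = final.factor("context")
    cue_obs = observations[1]["cue"]
    agent.dirichlet = update_dirichlet(
        agent.dirichlet,
        context_posterior=q_context[0],
        cue_observation=cue_obs,
        cue_context_posterior=q_context[1],
    )

    feedback = observations[model.horizon - 1]["feedback"]
    if feedback == "null" and env_state.commit_stage == "early":
        feedback = observations[1]["feedback"]
    return TrialRecord(
        trial=trial_index,
        ball=ball,
        observations=observations,
        posterior_changeup=tuple(float(q_context[tau, 1]) for tau in range(model.horizon)),
        efe=report_t0,
        actions=tuple(actions_taken),
        action_probs=tuple(action_probs),
        committed=env_state.committed or "none",
        commit_stage=env_state.commit_stage or "late",
        wait_first=actions_taken[0] == "wait",
        feedback=feedback,
        success=feedback in SUCCESS_FEEDBACK,
        free_energy=free_energy,
        d_counts_after=agent.dirichlet.d_counts.copy(),
        inference_warning=warning,
    )


# ---------------------------------------------------------------------------
# batch runner
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    """One condition's batch of observer traces plus summary statistics."""

    condition: Condition
    n_observers: int
    n_trials: int
    base_seed: int
    trials: pd.DataFrame
    per_trial: pd.DataFrame
    beta_alpha: float | None = None   # across-observer mean Beta parameters of
    beta_beta: float | None = None    # the change-up belief (alpha = change-up)
    total_free_energy: float = 0.0
    ci_degenerate: bool = False
    extras: dict[str, float] = field(default_factory=dict)

    def mean_success(self, first: int | None = None, last: int | None = None) -> float:
        df = self.trials
        if first is not None:
            df = df[df["trial"] < first]
        if last is not None:
            df = df[df["trial"] >= self.n_trials - last]
        return float(df["success"].mean())


def _observer_rngs(base_seed: int, n_observers: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in
            np.random.SeedSequence(base_seed).spawn(n_observers)]


def run_batch(
    condition: Condition,
    n_observers: int | None = None,
    n_trials: int | None = None,
    base_seed: int = 0,
) -> ExperimentResult:
    """Simulate independently seeded observers under one condition.

    Deterministic given ``base_seed``: every observer draws its trial sequence
    and its action samples from a dedicated child generator.  Aggregates
    per-trial means with normal-approximation 95% confidence intervals across
    observers (a single observer yields zero-width intervals, flagged).
    """
    n_observers = condition.n_observers if n_observers is None else n_observers
    n_trials = condition.n_trials if n_trials is None else n_trials
    if n_observers < 1 or n_trials < 1:
        raise ValueError("n_observers and n_trials must be at least 1")
    if condition.spec.scenario == "hierarchical":
        return _run_batch_hierarchical(condition, n_observers, n_trials, base_seed)

    rows = []
    final_d = np.zeros((n_observers, 2))
    for obs_i, rng in enumerate(_observer_rngs(base_seed, n_observers)):
        agent = AgentState.from_params(condition.agent)
        balls, _ = generate_trial_sequence(condition.spec, n_trials, rng)
        for t, ball in enumerate(balls):
            rec = run_trial(agent, condition, ball, rng, trial_index=t)
            row = {
                "observer": obs_i,
                "trial": t,
                "ball": ball,
                "cue": rec.observations[1]["cue"],
                "action": rec.committed,
                "commit_stage": rec.commit_stage,
                "wait_first": rec.wait_first,
                "action_prob": rec.action_prob,
                "success": rec.success,
                "feedback": rec.feedback,
                "posterior_changeup": rec.posterior_changeup[-1],
                "free_energy": rec.free_energy,
            }
            for label, g in zip(rec.efe.policies, rec.efe.G):
                row[f"G_{label}"] = g
            rows.append(row)
        final_d[obs_i] = agent.dirichlet.d_counts

    trials = pd.DataFrame(rows)
    per_trial = _per_trial_summary(trials, n_observers)
    per_obs_fe = trials.groupby("observer")["free_energy"].sum()
    return ExperimentResult(
        condition=condition,
        n_observers=n_observers,
        n_trials=n_trials,
        base_seed=base_seed,
        trials=trials,
        per_trial=per_trial,
        beta_alpha=float(final_d[:, 1].mean()),
        beta_beta=float(final_d[:, 0].mean()),
        total_free_energy=float(per_obs_fe.mean()),
        ci_degenerate=n_observers == 1,
    )


def _per_trial_summary(trials: pd.DataFrame, n_observers: int) -> pd.DataFrame:
    g = trials.groupby("trial")
    normal = g["action"].apply(lambda s: float((s == "normal").mean()))
    success = g["success"].mean()
    if n_observers > 1:
        sd = g["action"].apply(lambda s: float((s == "normal").std(ddof=1)))
        half = 1.96 * sd / np.sqrt(n_observers)
    else:
        half = pd.Series(0.0, index=normal.index)
    out = pd.DataFrame({
        "trial": normal.index,
        "mean_normal_prop": normal.values,
        "ci_low": np.clip(normal.values - half.values, 0.0, 1.0),
        "ci_high": np.clip(normal.values + half.values, 0.0, 1.0),
        "mean_success": success.values,
    })
    return out.reset_index(drop=True)


def _run_batch_hierarchical(
    condition: Condition, n_observers: int, n_trials: int, base_seed: int
) -> ExperimentResult:
    params = condition.agent
    assert isinstance(params, HierarchicalParams)
    rows = []
    totals = np.zeros(n_observers)
    lower_final = np.zeros(n_observers)
    final_d = np.zeros((n_observers, 2))
    for obs_i, rng in enumerate(_observer_rngs(base_seed, n_observers)):
        balls, _ = generate_trial_sequence(condition.spec, n_trials, rng)
        trace = run_hierarchical(params, balls)
        totals[obs_i] = trace.total_update_free_energy
        lower_final[obs_i] = trace.lower_p_changeup[-1]
        final_d[obs_i] = trace.final_d_counts
        for t in range(n_trials):
            rows.append({
                "observer": obs_i,
                "trial": t,
                "ball": balls[t],
                "higher_free_energy": trace.update_free_energy[t],
                "higher_surprisal": trace.surprisal[t],
                "lower_surprisal": trace.lower_surprisal[t],
                "regime_posterior_changeup": trace.regime_posteriors[t, 1],
                "lower_p_changeup": trace.lower_p_changeup[t],
            })
    trials = pd.DataFrame(rows)
    per_trial = trials.groupby("trial", as_index=False)[
        ["higher_free_energy", "lower_p_changeup"]
    ].mean()
    return ExperimentResult(
        condition=condition,
        n_observers=n_observers,
        n_trials=n_trials,
        base_seed=base_seed,
        trials=trials,
        per_trial=per_trial,
        beta_alpha=float(final_d[:, 1].mean()),
        beta_beta=float(final_d[:, 0].mean()),
        total_free_energy=float(totals.mean()),
        ci_degenerate=n_observers == 1,
        extras={
            "total_higher_free_energy": float(totals.mean()),
            "total_higher_surprisal": float(
                trials.groupby("observer")["higher_surprisal"].sum().mean()
            ),
            "total_lower_surprisal": float(
                trials.groupby("observer")["lower_surprisal"].sum().mean()
            ),
            "final_lower_p_changeup": float(lower_final.mean()),
        },
    )


# ---------------------------------------------------------------------------
# batteries
# ---------------------------------------------------------------------------

BATTERIES: dict[str, tuple[str, ...]] = {
    "principle1": (
        "p1_no_learning", "p1_context_learning", "p1_cue_learning",
        "p1_both_learning", "p1_reversal_context_learning",
        "p1_reversal_cue_learning",
    ),
    "single_trial_beliefs": (
        "single_trial_strong_prior_weak_cue", "single_trial_weak_prior_precise_cue",
    ),
    "congruency": (
        "congruency_both_congruent", "congruency_cue_incongruent",
        "congruency_context_incongruent", "congruency_both_incongruent",
    ),
    "precision_conflict": ("conflict_strong_cue", "conflict_strong_context"),
    "policy_precision": (
        "policy_precision_gamma_16", "policy_precision_gamma_4", "policy_precision_gamma_2", "policy_precision_gamma_1",
    ),
    "reward_sweep": (
        "reward_low", "reward_medium", "reward_high",
    ),
    "volatility": ("volatility_stable", "volatility_volatile"),
}


def run_battery(
    name: str,
    base_seed: int = 0,
    n_observers: int | None = None,
    n_trials: int | None = None,
) -> dict[str, ExperimentResult]:
    """Run every condition of one named battery.

    Observer/trial counts default to each condition's registered values; the
    same base seed is used for every condition so paired conditions share
    their trial sequences where the specs coincide.
    """
    from .environments import make_condition

    if name not in BATTERIES:
        raise KeyError(f"unknown battery {name!r}; known: {sorted(BATTERIES)}")
    return {
        cond_name: run_batch(
            make_condition(cond_name), n_observers, n_trials, base_seed
        )
        for cond_name in BATTERIES[name]
    }


# ---------------------------------------------------------------------------
# belief summaries and writers
# ---------------------------------------------------------------------------


def beta_summary(
    counts: np.ndarray, grid_points: int = 201
) -> dict[str, np.ndarray | float]:
    """Summarise two-category Dirichlet counts as Beta densities.

    ``counts`` is ``(n_observers, 2)`` with the category of interest first;
    each row maps to Beta(alpha, beta) = Beta(counts[0], counts[1]).  Returns
    the across-observer mean parameters and the mean-parameter density
    evaluated on a grid over [0, 1].
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if counts.shape[1] != 2:
        raise ValueError("beta_summary requires exactly two categories")
    if np.any(counts <= 0):
        raise ValueError("Beta parameters must be positive")
    alpha = float(counts[:, 0].mean())
    beta = float(counts[:, 1].mean())
    x = np.linspace(0.0, 1.0, grid_points)
    density = beta_dist.pdf(x, alpha, beta)
    return {"alpha": alpha, "beta": beta, "grid": x, "density": density}


def result_to_csv(result: ExperimentResult, path: Path | str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    result.trials.to_csv(path, index=False)


def battery_summary(results: dict[str, ExperimentResult]) -> dict:
    out = {}
    for name, res in results.items():
        entry = {
            "n_observers": res.n_observers,
            "n_trials": res.n_trials,
            "base_seed": res.base_seed,
            "mean_success": None,
            "total_free_energy": res.total_free_energy,
            "beta_alpha_changeup": res.beta_alpha,
            "beta_beta_changeup": res.beta_beta,
        }
        if "success" in res.trials.columns:
            entry["mean_success"] = float(res.trials["success"].mean())
            entry["wait_fraction"] = float(res.trials["wait_first"].mean())
        entry.update(res.extras)
        out[name] = entry
    return out


def write_battery(
    results: dict[str, ExperimentResult], out_dir: Path | str, battery: str
) -> Path:
    """Write one tidy CSV per condition plus a JSON summary for the battery."""
    out_dir = Path(out_dir) / battery
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, res in results.items():
        result_to_csv(res, out_dir / f"{name}.csv")
    summary_path = out_dir / "summary.json"
    summary_path.write_text(
        json.dumps(battery_summary(results), indent=2, sort_keys=True) + "\n"
    )
    return out_dir
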