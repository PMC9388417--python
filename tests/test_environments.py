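"""Generative-process tests: sequences, within-trial dynamics, condition registry."""
import numpy as np
import pytest

from strikesim.environments import (
    CONDITIONS,
    EnvironmentSpec,
    EnvState,
    generate_trial_sequence,
    make_condition,
    step_environment,
)


class TestGenerateTrialSequence:
    def test_zero_probability_gives_all_normal(self, rng):
        balls, frac = generate_trial_sequence(
            EnvironmentSpec(p_changeup_true=0.0), 50, rng
        )
        assert set(balls) == {"normal"} and frac == 0.0

    def test_same_seed_bit_identical(self):
        spec = EnvironmentSpec(p_changeup_true=0.3)
        a, _ = generate_trial_sequence(spec, 200, np.random.default_rng(9))
        b, _ = generate_trial_sequence(spec, 200, np.random.default_rng(9))
        assert a == b

    def test_eighty_twenty_marginal(self, rng):
        _, frac = generate_trial_sequence(
            EnvironmentSpec(p_changeup_true=0.2), 10_000, rng
        )
        assert frac == pytest.approx(0.2, abs=0.01)

    def test_stable_and_volatile_marginals_match(self, rng):
        stable = EnvironmentSpec(p_changeup_true=0.5)
        volatile = EnvironmentSpec(
            p_changeup_true=0.5, volatility_schedule=((10, 0.2), (10, 0.8))
        )
        assert stable.scheduled_marginal(10_000) == pytest.approx(
            volatile.scheduled_marginal(10_000)
        )
        _, f_s = generate_trial_sequence(stable, 10_000, rng)
        _, f_v = generate_trial_sequence(volatile, 10_000, rng)
        assert f_s == pytest.approx(f_v, abs=0.02)

    def test_schedule_cycles_beyond_its_length(self, rng):
        spec = EnvironmentSpec(volatility_schedule=((3, 0.0), (3, 1.0)))
        balls, _ = generate_trial_sequence(spec, 12, rng)
        assert balls == (["normal"] * 3 + ["changeup"] * 3) * 2

    def test_bad_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_trial_sequence(EnvironmentSpec(), 0, rng)
        with pytest.raises(ValueError):
            EnvironmentSpec(p_changeup_true=1.4)
        with pytest.raises(ValueError):
            EnvironmentSpec(volatility_schedule=())
        with pytest.raises(ValueError):
            EnvironmentSpec(volatility_schedule=((0, 0.5),))


class TestStepEnvironment:
    def _spec(self, **kw):
        return EnvironmentSpec(**kw)

    def test_reliable_congruent_cue_matches_ball(self, rng):
        state = EnvState(ball="changeup")
        obs = step_environment(state, "wait", 0, self._spec(rho_true=1.0), rng)
        assert obs == {"cue": "cue_changeup", "feedback": "null"}

    def test_incongruent_cue_flips_direction(self, rng):
        state = EnvState(ball="changeup")
        obs = step_environment(
            state, "wait", 0, self._spec(rho_true=1.0, cue_congruent=False), rng
        )
        assert obs["cue"] == "cue_normal"

    def test_forced_cue_overrides_ball(self, rng):
        state = EnvState(ball="normal")
        obs = step_environment(
            state, "wait", 0, self._spec(forced_cue="cue_changeup"), rng
        )
        assert obs["cue"] == "cue_changeup"

    def test_late_commit_on_matching_ball_in_tradeoff(self, rng):
        spec = self._spec(scenario="tradeoff")
        state = EnvState(ball="normal")
        step_environment(state, "wait", 0, spec, rng)
        obs = step_environment(state, "commit_normal", 1, spec, rng)
        assert obs["feedback"] == "late_correct"

    def test_early_commit_tagging_and_absorbing_error(self, rng):
        spec = self._spec(scenario="tradeoff")
        state = EnvState(ball="changeup")
        obs = step_environment(state, "commit_changeup", 0, spec, rng)
        assert obs["feedback"] == "early_correct"
        # waiting in a committed state is a legal no-op ...
        obs2 = step_environment(state, "wait", 1, spec, rng)
        assert obs2["feedback"] == "early_correct"
        # ... but committing again is not
        with pytest.raises(ValueError, match="absorbing"):
            step_environment(state, "commit_normal", 1, spec, rng)

    def test_simple_incorrect_feedback(self, rng):
        state = EnvState(ball="changeup")
        step_environment(state, "wait", 0, self._spec(), rng)
        obs = step_environment(state, "commit_normal", 1, self._spec(), rng)
        assert obs["feedback"] == "incorrect"


class TestConditionRegistry:
    def test_unknown_condition_raises(self):
        with pytest.raises(KeyError, match="unknown condition"):
            make_condition("congruency_imaginary")

    def test_congruency_flags(self):
        c = make_condition("congruency_both_congruent")
        assert c.spec.cue_congruent and c.spec.context_congruent
        d = make_condition("congruency_both_incongruent")
        assert not d.spec.cue_congruent and not d.spec.context_congruent

    def test_congruent_and_incongruent_priors_mirror_each_other(self):
        cong = make_condition("congruency_both_congruent").agent.d_counts
        inc = make_condition("congruency_context_incongruent").agent.d_counts
        assert cong == tuple(reversed(inc))

    def test_precision_conflict_scales_one_count_set(self):
        cue = make_condition("conflict_strong_cue").agent
        ctx = make_condition("conflict_strong_context").agent
        # ratio four-to-one in both cells, magnitude swapped between sources
        assert np.isclose(cue.d_counts[0] / cue.d_counts[1], 4.0)
        assert np.isclose(ctx.d_counts[0] / ctx.d_counts[1], 4.0)
        assert sum(cue.d_counts) < sum(ctx.d_counts)
        assert cue.a_strength > ctx.a_strength
        assert cue.rho_agent == ctx.rho_agent == 0.8

    def test_reward_sweep_uses_middle_value(self):
        med = make_condition("reward_medium").agent
        low = make_condition("reward_low").agent
        high = make_condition("reward_high").agent
        assert low.r_early < med.r_early < high.r_early

    def test_registered_study_sizes(self):
        assert make_condition("p1_no_learning").n_observers == 50
        assert make_condition("p1_no_learning").n_trials == 50
        assert make_condition("congruency_both_congruent").n_trials == 100
        assert make_condition("volatility_volatile").n_observers == 50

    def test_volatility_pair_has_matched_scheduled_marginals(self):
        stable = make_condition("volatility_stable").spec
        volatile = make_condition("volatility_volatile").spec
        assert stable.scheduled_marginal(100) == pytest.approx(
            volatile.scheduled_marginal(100)
        )

    def test_every_condition_is_well_formed(self):
        for name, cond in CONDITIONS.items():
            assert cond.name == name
            assert 0.0 <= cond.spec.p_changeup_true <= 1.0
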