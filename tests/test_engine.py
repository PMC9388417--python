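"""Inference-engine tests: exact-Bayes oracle, free energies, action selection,
and Dirichlet learning."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strikesim.engine import (
    consistent_policies,
    efe_report,
    expected_free_energy,
    infer_states,
    policy_posterior,
    select_action,
    update_dirichlet,
    variational_free_energy,
)
from strikesim.model import (
    DirichletBeliefs,
    SimpleScenarioParams,
    build_simple_model,
    initial_beliefs,
)

from conftest import (
    enumerate_posterior,
    random_observations,
    random_simple_model,
    random_tradeoff_model,
)

NO_OBS = {0: {"cue": "null", "feedback": "null"}}


class TestInferStates:
    def test_uninformative_cue_leaves_context_flat(self):
        model = build_simple_model(SimpleScenarioParams(rho_agent=0.5))
        obs = dict(NO_OBS)
        obs[1] = {"cue": "cue_changeup", "feedback": "null"}
        post = infer_states(model, obs, policy=0)
        np.testing.assert_allclose(post.factor("context"), 0.5, atol=1e-9)

    def test_prior_propagates_through_identity_transitions(self):
        model = build_simple_model(SimpleScenarioParams(d_counts=(8.0, 2.0)))
        post = infer_states(model, NO_OBS, policy=0)
        np.testing.assert_allclose(
            post.factor("context"), np.tile([0.8, 0.2], (3, 1)), atol=1e-9
        )
        assert post.converged

    def test_cue_observation_yields_exact_bayes_posterior(self):
        model = build_simple_model(SimpleScenarioParams(rho_agent=0.9))
        obs = dict(NO_OBS)
        obs[1] = {"cue": "cue_changeup", "feedback": "null"}
        post = infer_states(model, obs, policy=0)
        np.testing.assert_allclose(post.factor("context")[1], [0.1, 0.9], atol=1e-9)

    @pytest.mark.parametrize("scenario", ["simple", "tradeoff"])
    def test_matches_enumeration_oracle_on_random_models(self, scenario, rng):
        """Fixed-point posteriors equal brute-force joint enumeration."""
        make = random_simple_model if scenario == "simple" else random_tradeoff_model
        for _ in range(40):
            model = make(rng)
            policy = int(rng.integers(model.policies.n_policies))
            obs = random_observations(model, policy, rng)
            post = infer_states(model, obs, policy)
            exact = enumerate_posterior(model, obs, policy)
            for f in range(2):
                np.testing.assert_allclose(
                    post.marginals[f], exact[f], atol=1e-6,
                    err_msg=f"{scenario} factor {f} obs {obs}",
                )


class TestVariationalFreeEnergy:
    def test_perfect_prediction_gives_zero(self):
        """Posterior equal to the prior and a certainly-predicted observation."""
        model = build_simple_model(SimpleScenarioParams(d_counts=(1.0, 1.0)))
        post = infer_states(model, NO_OBS, policy=0)
        # the null cue and null feedback at tau=0 are predicted with probability 1
        assert variational_free_energy(model, post, NO_OBS, 0) == pytest.approx(0.0, abs=1e-9)

    def test_fair_coin_observation_costs_ln2(self):
        """An uninformative model observing one binary outcome pays ln 2."""
        model = build_simple_model(SimpleScenarioParams(rho_agent=0.5))
        obs = dict(NO_OBS)
        obs[1] = {"cue": "cue_changeup"}
        post = infer_states(model, obs, policy=0)
        assert variational_free_energy(model, post, obs, 0) == pytest.approx(
            np.log(2.0), abs=1e-9
        )

    def test_converged_beliefs_beat_prior_beliefs(self, rng):
        for _ in range(10):
            model = random_simple_model(rng)
            policy = int(rng.integers(2))
            obs = random_observations(model, policy, rng)
            converged = infer_states(model, obs, policy)
            prior_beliefs = infer_states(model, NO_OBS, policy)
            f_conv = variational_free_energy(model, converged, obs, policy)
            f_prior = variational_free_energy(model, prior_beliefs, obs, policy)
            assert f_conv <= f_prior + 1e-9

    def test_weakly_decreases_over_sweeps(self, rng):
        model = random_simple_model(rng)
        obs = dict(NO_OBS)
        obs[1] = {"cue": "cue_changeup", "feedback": "null"}
        fes = [
            variational_free_energy(
                model, infer_states(model, obs, 0, max_iters=k), obs, 0
            )
            for k in (1, 2, 3, 8)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(fes, fes[1:]))


class TestExpectedFreeEnergy:
    def test_decomposition_identity_and_signs(self, rng):
        for make in (random_simple_model, random_tradeoff_model):
            model = make(rng)
            beliefs = DirichletBeliefs(
                np.array([2.0, 1.0]), np.array([[4.0, 1.0], [1.0, 4.0]]),
                learn_cue=True,
            )
            posts = {
                p: infer_states(model, NO_OBS, p, beliefs)
                for p in range(model.policies.n_policies)
            }
            rep = efe_report(model, posts, beliefs, from_time=0)
            np.testing.assert_allclose(rep.G, rep.risk + rep.ambiguity - rep.novelty)
            assert np.all(rep.risk >= -1e-12)
            assert np.all(rep.ambiguity >= -1e-12)
            assert np.all(rep.novelty >= -1e-12)

    def test_novelty_zero_when_cue_learning_off(self, simple_model):
        beliefs = initial_beliefs(SimpleScenarioParams())  # learn_cue defaults off
        posts = {p: infer_states(simple_model, NO_OBS, p, beliefs) for p in range(2)}
        rep = efe_report(simple_model, posts, beliefs, from_time=0)
        np.testing.assert_array_equal(rep.novelty, 0.0)

    def test_symmetric_beliefs_give_equal_G(self):
        """Swapping normal and change-up labels is a symmetry of the model."""
        model = build_simple_model(SimpleScenarioParams(rho_agent=0.8))
        posts = {p: infer_states(model, NO_OBS, p) for p in range(2)}
        rep = efe_report(model, posts, from_time=0)
        assert rep.G[0] == pytest.approx(rep.G[1], abs=1e-10)

    def test_ambiguity_zero_for_deterministic_likelihoods(self):
        model = build_simple_model(SimpleScenarioParams(rho_agent=1.0, q_hit=1.0))
        posts = {p: infer_states(model, NO_OBS, p) for p in range(2)}
        rep = efe_report(model, posts, from_time=0)
        np.testing.assert_allclose(rep.ambiguity, 0.0, atol=1e-9)

    def test_matches_brute_force_enumeration(self):
        """Risk and ambiguity recomputed by direct sums over the two ball states."""
        model = build_simple_model(
            SimpleScenarioParams(d_counts=(1.0, 1.0), rho_agent=0.8,
                                 reward=4.0, loss=4.0)
        )
        post = infer_states(model, NO_OBS, policy=0)  # anticipate normal
        risk, amb, nov = expected_free_energy(model, post, 0, from_time=0)

        # independent recomputation: policy 0 is observing at tau=1, committed
        # normal at tau=2; context marginal stays (0.5, 0.5)
        q = np.array([0.5, 0.5])
        c_cue = np.full(3, 1 / 3)
        c_fb = np.exp([0.0, 4.0, -4.0]) / np.exp([0.0, 4.0, -4.0]).sum()

        def kl(p, c):
            m = p > 0
            return float(np.sum(p[m] * np.log(p[m] / c[m])))

        # tau=1: cue (0, .8q1+.2q2, .2q1+.8q2), feedback null
        qo_cue = np.array([0.0, 0.8 * q[0] + 0.2 * q[1], 0.2 * q[0] + 0.8 * q[1]])
        exp_risk = kl(qo_cue, c_cue) + kl(np.array([1.0, 0.0, 0.0]), c_fb)
        h_cue = -(0.8 * np.log(0.8) + 0.2 * np.log(0.2))
        exp_amb = h_cue  # both cue columns have the same entropy; feedback is crisp
        # tau=2: cue null, feedback (0, q_correct, q_wrong) for commit-normal
        exp_risk += kl(np.array([1.0, 0.0, 0.0]), c_cue)
        exp_risk += kl(np.array([0.0, q[0], q[1]]), c_fb)

        assert risk == pytest.approx(exp_risk, abs=1e-9)
        assert amb == pytest.approx(exp_amb, abs=1e-9)
        assert nov == 0.0


class TestPolicyPosterior:
    def test_equal_G_uniform(self):
        np.testing.assert_allclose(
            policy_posterior(np.array([2.0, 2.0, 2.0]), gamma=7.0), 1 / 3
        )

    def test_zero_gamma_recovers_habits(self):
        np.testing.assert_allclose(
            policy_posterior(np.array([0.0, 99.0]), gamma=0.0), [0.5, 0.5]
        )

    def test_hand_computed_softmax(self):
        post = policy_posterior(np.array([1.0, 2.0]), gamma=1.0)
        np.testing.assert_allclose(post, [0.73105858, 0.26894142], atol=1e-7)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            policy_posterior(np.array([1.0, 2.0]), gamma=-0.1)

    @settings(derandomize=True, max_examples=40)
    @given(
        st.lists(st.floats(min_value=-5, max_value=5), min_size=2, max_size=5),
        st.floats(min_value=0.01, max_value=4.0),
        st.floats(min_value=0.05, max_value=4.0),
    )
    def test_monotone_precision(self, g, gamma, bump):
        """Raising gamma strictly raises the argmin-G policy's probability."""
        g = np.array(g)
        if len(set(np.round(g, 6))) < len(g):
            return  # ties make the argmin ill-defined
        best = int(np.argmin(g))
        low = policy_posterior(g, gamma)
        high = policy_posterior(g, gamma + bump)
        assert high[best] > low[best]


class TestSelectAction:
    def test_degenerate_posterior_deterministic(self, rng):
        action, prob = select_action(
            np.array([1.0, 0.0]), np.array([1, 2]), mode="sample", rng=rng
        )
        assert (action, prob) == (1, 1.0)

    def test_same_seed_reproduces_choice(self):
        draws = [
            select_action(np.array([0.5, 0.5]), np.array([1, 2]),
                          rng=np.random.default_rng(77))[0]
            for _ in range(5)
        ]
        assert len(set(draws)) == 1

    def test_sampling_frequency_matches_marginal(self):
        rng = np.random.default_rng(4)
        hits = sum(
            select_action(np.array([0.75, 0.25]), np.array([0, 1]), rng=rng)[0] == 0
            for _ in range(10_000)
        )
        assert hits / 10_000 == pytest.approx(0.75, abs=0.02)

    def test_argmax_tie_breaks_to_lowest_index(self):
        action, _ = select_action(np.array([0.5, 0.5]), np.array([0, 1]), mode="argmax")
        assert action == 0

    def test_marginal_pools_policies_sharing_an_action(self, rng):
        action, prob = select_action(
            np.array([0.3, 0.3, 0.4]), np.array([0, 0, 2]), mode="argmax"
        )
        assert action == 0
        assert prob == pytest.approx(0.6)


class TestUpdateDirichlet:
    def _beliefs(self, **kw):
        return DirichletBeliefs(np.array([1.0, 1.0]), np.ones((2, 2)), **kw)

    def test_toggles_off_leave_counts_unchanged(self):
        b = self._beliefs()
        out = update_dirichlet(b, np.array([1.0, 0.0]), "cue_normal", np.array([1.0, 0.0]))
        np.testing.assert_array_equal(out.d_counts, b.d_counts)
        np.testing.assert_array_equal(out.a_counts, b.a_counts)

    def test_certain_posterior_adds_unit_count(self):
        b = self._beliefs(learn_context=True)
        out = update_dirichlet(b, np.array([1.0, 0.0]))
        np.testing.assert_allclose(out.d_counts, [2.0, 1.0])

    def test_forty_normals_ten_changeups(self):
        b = self._beliefs(learn_context=True)
        for _ in range(40):
            b = update_dirichlet(b, np.array([1.0, 0.0]))
        for _ in range(10):
            b = update_dirichlet(b, np.array([0.0, 1.0]))
        np.testing.assert_allclose(b.d_counts, [41.0, 11.0])
        np.testing.assert_allclose(b.context_prior(), [41 / 52, 11 / 52])

    def test_cue_update_targets_observed_row(self):
        b = self._beliefs(learn_cue=True, learning_rate=0.5)
        out = update_dirichlet(b, np.array([0.5, 0.5]), "cue_changeup",
                               np.array([0.2, 0.8]))
        np.testing.assert_allclose(out.a_counts, [[1.0, 1.0], [1.1, 1.4]])

    def test_null_cue_leaves_cue_counts(self):
        b = self._beliefs(learn_cue=True)
        out = update_dirichlet(b, np.array([0.5, 0.5]), "null", np.array([0.5, 0.5]))
        np.testing.assert_array_equal(out.a_counts, b.a_counts)


def test_consistent_policies_prunes_on_history(tradeoff_model):
    assert consistent_policies(tradeoff_model.policies, []) == [0, 1, 2, 3]
    assert consistent_policies(tradeoff_model.policies, [0]) == [2, 3]
    assert consistent_policies(tradeoff_model.policies, [1]) == [0]


def test_policy_averaged_marginals_mix_policy_beliefs(simple_model):
    from strikesim.engine import policy_averaged_marginals

    obs = dict(NO_OBS)
    obs[1] = {"cue": "cue_changeup", "feedback": "null"}
    posts = {p: infer_states(simple_model, obs, p) for p in range(2)}
    bma = policy_averaged_marginals(posts, np.array([0.25, 0.75]))
    expected = 0.25 * posts[0].marginals[1] + 0.75 * posts[1].marginals[1]
    np.testing.assert_allclose(bma[1], expected)
    np.testing.assert_allclose(bma[0].sum(axis=1), 1.0)
    with pytest.raises(ValueError):
        policy_averaged_marginals(posts, np.array([1.0]))
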