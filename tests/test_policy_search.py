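import math

import numpy as np
import pytest

from dimrl.naive_rl import LearningParams, NaiveRLResult
from dimrl.policies import enumerate_policies
from dimrl.policy_search import (
    SearchConfig,
    TransitionEvent,
    classify_strategy,
    current_policy,
    detect_transitions,
    hmm_policy_posterior,
    mixture_session_likelihood,
    policy_entropy,
    smooth_posterior,
    smoothed_policy_entropy,
    softmax_policy_posterior,
)
from dimrl.task import ACTION_GO, ACTION_MISSED, ACTION_PASS, SessionArrays

LN7 = math.log(7)


def stub_runs(action_probs=None, q_gaps=None, betas=None):
    """Build seven per-policy result stubs from emission/advantage matrices."""
    ref = action_probs if action_probs is not None else q_gaps
    T = np.asarray(ref).shape[0]
    runs = []
    for i, policy in enumerate(enumerate_policies()):
        ap = (np.asarray(action_probs, dtype=float)[:, i]
              if action_probs is not None else np.full(T, 0.5))
        gap = (np.asarray(q_gaps, dtype=float)[:, i]
               if q_gaps is not None else np.zeros(T))
        q_state = np.column_stack([gap, np.zeros(T)])  # q_go - q_pass = gap
        beta = betas[i] if betas is not None else 1.0
        runs.append(
            NaiveRLResult(
                policy=policy,
                params=LearningParams(0.25, beta),
                choice_probs=np.column_stack([ap, 1 - ap]),
                action_prob=ap,
                chosen_q=gap,
                q_state=q_state,
                q_final=np.zeros((policy.n_states, 2)),
            )
        )
    return runs


def all_go_arrays(T):
    return SessionArrays(stim_index=[0] * T, action=[ACTION_GO] * T,
                        reward=[10.0] * T)


class TestSoftmaxPosterior:
    def test_first_trial_uniform_before_learning(self):
        arr = all_go_arrays(1)
        post = softmax_policy_posterior(arr, stub_runs(q_gaps=np.zeros((1, 7))))
        assert np.allclose(post[0], 1 / 7)

    def test_dominant_advantage_concentrates(self):
        gaps = np.zeros((1, 7))
        gaps[0, 2] = 10.0  # policy 3 assigns advantage 10 to the action taken
        post = softmax_policy_posterior(all_go_arrays(1), stub_runs(q_gaps=gaps))
        expect = math.exp(10) / (math.exp(10) + 6)
        assert post[0, 2] == pytest.approx(expect, rel=1e-9)

    def test_rows_are_distributions(self):
        rng = np.random.default_rng(0)
        gaps = rng.normal(size=(30, 7)) * 5
        post = softmax_policy_posterior(all_go_arrays(30), stub_runs(q_gaps=gaps))
        assert np.allclose(post.sum(axis=1), 1.0)
        assert (post > 0).all()

    def test_missed_trials_carry_posterior_forward(self):
        gaps = np.zeros((3, 7))
        gaps[0, 4] = 5.0
        arr = SessionArrays(stim_index=[0, 0, 0],
                            action=[ACTION_GO, ACTION_MISSED, ACTION_GO],
                            reward=[10.0, 0.0, 10.0])
        post = softmax_policy_posterior(arr, stub_runs(q_gaps=gaps))
        assert np.allclose(post[1], post[0])

    def test_pass_trial_reverses_advantage(self):
        gaps = np.zeros((1, 7))
        gaps[0, 6] = 4.0
        arr = SessionArrays(stim_index=[0], action=[ACTION_PASS], reward=[0.0])
        post = softmax_policy_posterior(arr, stub_runs(q_gaps=gaps))
        assert post[0, 6] < 1 / 7  # a positive go-advantage argues against a pass


def hmm_path_oracle(emissions, stay_prob):
    """Exhaustive enumeration over all 7^T policy paths.

    Returns the posterior over the final state and the total data
    log-likelihood, computed without any forward recursion.
    """
    T, K = emissions.shape
    off = (1.0 - stay_prob) / (K - 1)
    log_trans = np.log(np.full((K, K), off) + np.eye(K) * (stay_prob - off))
    log_em = np.log(emissions)
    log_p = np.full(K, -math.log(K)) + log_em[0]
    last = np.arange(K)
    for t in range(1, T):
        old_len = len(log_p)
        log_p = (log_p[:, None] + log_trans[last] + log_em[t][None, :]).ravel()
        last = np.tile(np.arange(K), old_len)
    total = np.logaddexp.reduce(log_p)
    posterior = np.array(
        [np.exp(np.logaddexp.reduce(log_p[last == i]) - total) for i in range(K)]
    )
    return posterior, float(total)


class TestHMMPosterior:
    def make_inputs(self, T, seed=0):
        rng = np.random.default_rng(seed)
        emissions = rng.uniform(0.05, 0.95, size=(T, 7))
        return all_go_arrays(T), stub_runs(action_probs=emissions), emissions

    def test_identical_emissions_stay_uniform(self):
        arr = all_go_arrays(10)
        filtered, predicted = hmm_policy_posterior(
            arr, stub_runs(action_probs=np.full((10, 7), 0.7))
        )
        assert np.allclose(filtered, 1 / 7)
        assert np.allclose(predicted, 1 / 7)

    def test_uniform_transitions_reduce_to_per_trial_bayes(self):
        arr, runs, emissions = self.make_inputs(8, seed=1)
        config = SearchConfig(stay_prob=1 / 7 + 1e-9)
        filtered, _ = hmm_policy_posterior(arr, runs, config)
        expect = emissions / emissions.sum(axis=1, keepdims=True)
        assert np.allclose(filtered, expect, atol=1e-6)

    @pytest.mark.parametrize("T", [1, 3, 6])
    def test_forward_filter_matches_path_enumeration(self, T):
        arr, runs, emissions = self.make_inputs(T, seed=T)
        filtered, predicted = hmm_policy_posterior(arr, runs)
        oracle_post, oracle_logl = hmm_path_oracle(emissions, 0.9)
        assert np.allclose(filtered[-1], oracle_post, atol=1e-9)
        mix = mixture_session_likelihood(predicted, emissions, arr)
        assert mix == pytest.approx(oracle_logl, abs=1e-9)

    def test_missed_trials_carry_both_distributions(self):
        emissions = np.full((3, 7), 0.5)
        emissions[0, 1] = 0.9
        arr = SessionArrays(stim_index=[0, 0, 0],
                            action=[ACTION_GO, ACTION_MISSED, ACTION_GO],
                            reward=[10.0, 0.0, 10.0])
        runs = stub_runs(action_probs=emissions)
        for i, r in enumerate(runs):
            r.action_prob[1] = np.nan
        filtered, predicted = hmm_policy_posterior(arr, runs)
        assert np.allclose(filtered[1], filtered[0])


class TestEntropy:
    def test_uniform_is_maximal(self):
        assert policy_entropy(np.full(7, 1 / 7)) == pytest.approx(LN7)

    def test_degenerate_is_zero(self):
        p = np.zeros(7)
        p[3] = 1.0
        assert policy_entropy(p) == 0.0

    def test_two_point_distribution(self):
        p = np.array([0.5, 0.5, 0, 0, 0, 0, 0])
        assert policy_entropy(p) == pytest.approx(math.log(2))

    def test_rowwise_on_matrix(self):
        post = np.vstack([np.full(7, 1 / 7), np.eye(7)[0]])
        h = policy_entropy(post)
        assert h == pytest.approx([LN7, 0.0])

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            policy_entropy(np.array([0.9, 0.9, 0, 0, 0, 0, 0]))

    def test_smoothed_entropy_renormalises_fitted_curves(self):
        smoothed = np.tile([0.4, 0.4, -0.1, 0.05, 0.05, 0.1, 0.1], (5, 1))
        h = smoothed_policy_entropy(smoothed)
        assert (h >= 0).all() and (h <= LN7 + 1e-9).all()


class TestSmoothing:
    def test_constant_series_fitted_exactly(self):
        post = np.tile(np.linspace(0.05, 0.25, 7), (20, 1))
        sm = smooth_posterior(post)
        assert np.allclose(sm, post, atol=1e-8)

    def test_polynomial_nests_linear_trend(self):
        x = np.linspace(0, 1, 50)
        post = np.column_stack([0.1 + 0.5 * x] + [np.full(50, 0.1)] * 6)
        sm = smooth_posterior(post)
        assert np.allclose(sm[:, 0], 0.1 + 0.5 * x, atol=1e-8)

    def test_argmax_invariant_to_common_offset(self):
        rng = np.random.default_rng(3)
        post = rng.dirichlet(np.ones(7), size=40)
        a = current_policy(smooth_posterior(post))
        b = current_policy(smooth_posterior(post + 3.0))
        assert (a == b).all()

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            smooth_posterior(np.full((5, 7), 1 / 7))


class TestCurrentPolicyAndTransitions:
    def test_dominant_curve_gives_constant_policy(self):
        sm = np.full((10, 7), 0.1)
        sm[:, 4] = 0.9
        assert (current_policy(sm) == 5).all()

    def test_exact_tie_prefers_lower_dimensionality(self):
        sm = np.full((3, 7), 0.0)
        sm[:, 3] = 0.5  # policy 4 (2-dim)
        sm[:, 6] = 0.5  # policy 7 (3-dim)
        assert (current_policy(sm) == 4).all()

    def test_transitions_at_changes_only(self):
        series = [4] * 10 + [7] * 10 + [4] * 5
        events = detect_transitions(series)
        assert [(e.trial_index, e.from_policy, e.to_policy) for e in events] == [
            (11, 4, 7),
            (21, 7, 4),
        ]

    def test_constant_series_has_no_transitions(self):
        assert detect_transitions([7] * 50) == []

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_transitions([7])

    def test_transition_event_validation(self):
        with pytest.raises(ValueError):
            TransitionEvent(trial_index=5, from_policy=3, to_policy=3)
        with pytest.raises(ValueError):
            TransitionEvent(trial_index=1, from_policy=3, to_policy=4)


class TestStrategyClassification:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([7] * 100, "only_3d"),
            ([4] * 50 + [7] * 50, "2d_to_3d"),
            ([7] * 50 + [5] * 50, "3d_to_2d"),
            ([5] * 100, "only_2d"),
            ([2] * 100, "one_dim"),
            ([2] * 30 + [7] * 70, "one_dim"),
        ],
    )
    def test_first_versus_last_quarter_classes(self, series, expected):
        assert classify_strategy(series) == expected

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            classify_strategy([])


class TestMixtureLikelihood:
    def test_uniform_mixture_of_chance_probabilities(self):
        T = 16
        arr = all_go_arrays(T)
        post = np.full((T, 7), 1 / 7)
        ap = np.full((T, 7), 0.5)
        assert mixture_session_likelihood(post, ap, arr) == pytest.approx(
            T * math.log(0.5)
        )

    def test_degenerate_posterior_reduces_to_single_policy(self):
        T = 10
        rng = np.random.default_rng(5)
        ap = rng.uniform(0.2, 0.9, size=(T, 7))
        post = np.zeros((T, 7))
        post[:, 2] = 1.0
        arr = all_go_arrays(T)
        assert mixture_session_likelihood(post, ap, arr) == pytest.approx(
            np.log(ap[:, 2]).sum()
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mixture_session_likelihood(
                np.full((4, 7), 1 / 7), np.full((5, 7), 0.5), all_go_arrays(4)
            )
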