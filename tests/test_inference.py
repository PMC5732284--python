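import math

import numpy as np
import pytest

from dimrl import inference
from dimrl.inference import (
    ModelFit,
    aic,
    bic,
    compare_models,
    fit_model,
    likelihood_performance_correlation,
    transition_entropy_test,
    transition_timing_regression,
)
from dimrl.policy_search import TransitionEvent
from tests.conftest import make_session


def make_fit(model="transfer_inherited", log_l=-100.0, k=2, n=256):
    return ModelFit(model=model, params={}, log_likelihood=log_l, k=k, n=n,
                    aic=aic(log_l, k), bic=bic(log_l, k, n))


class TestInformationCriteria:
    def test_zero_everything(self):
        assert aic(0.0, 0) == 0.0
        assert bic(0.0, 0, 100) == 0.0

    def test_identities_recomputed_on_real_fits(self):
        _, _, _, arr = make_session(kind="fixed_policy", policy_id=7, seed=1)
        fit = fit_model(arr, "policy7_noise", seed=0)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.log_likelihood)
        assert fit.bic == pytest.approx(
            fit.k * math.log(fit.n) - 2 * fit.log_likelihood
        )
        assert fit.n == arr.n_valid

    def test_invalid_sample_size_rejected(self):
        with pytest.raises(ValueError):
            bic(-10.0, 2, 0)


class TestFitModel:
    def test_same_seed_reproduces_fit(self):
        _, _, _, arr = make_session(kind="fixed_policy", policy_id=5, seed=2)
        a = fit_model(arr, "transfer_inherited", seed=9)
        b = fit_model(arr, "transfer_inherited", seed=9)
        assert a == b

    def test_coin_flip_choices_fit_to_indifference(self):
        _, _, _, arr = make_session(kind="random", seed=3)
        alpha, beta, log_l = inference.fit_policy_params(arr, 7, seed=0)
        assert beta < 1.5
        assert 256 * math.log(0.5) - 0.1 <= log_l <= -160.0

    def test_unknown_model_rejected(self):
        _, _, _, arr = make_session(seed=4)
        with pytest.raises(ValueError):
            fit_model(arr, "transfer_sideways")

    def test_lapse_model_never_fits_worse_than_nested_policy7(self):
        """policy7_noise contains the naive policy-7 model at epsilon = 0."""
        for seed in range(6):
            _, _, _, arr = make_session(
                kind=("fixed_policy" if seed % 2 else "random"),
                policy_id=7, seed=40 + seed,
            )
            _, _, log_l7 = inference.fit_policy_params(arr, 7, seed=seed)
            noise = inference.policy7_noise_fit(arr, seed=seed)
            assert noise.log_likelihood >= log_l7 - 1e-6

    def test_model_family_recovered_by_bic(self):
        """The best-BIC model falls in the generating family: transfer models
        for value-transferring agents, single-policy models for fixed-policy
        agents."""
        transfer_family = {"transfer_inherited", "transfer_zero"}
        single_family = {"transfer_inherited", "transfer_zero", "policy7_noise"}
        hits = 0
        cases = []
        for i in range(5):
            cases.append(("exploring_transfer", (5, 6, 4)[i % 3],
                          8200 + i, transfer_family))
        for i in range(5):
            cases.append(("fixed_policy", 7, 8300 + i, single_family))
        for kind, policy_id, seed, family in cases:
            _, _, _, arr = make_session(kind=kind, policy_id=policy_id, seed=seed)
            stage1 = inference.fit_per_policy(arr, seed=seed)
            schedule = inference.schedule_from_search(arr, stage1).schedule
            bics = {
                "transfer_inherited": inference.transfer_fit(
                    arr, schedule, "inherited", seed=seed).bic,
                "transfer_zero": inference.transfer_fit(
                    arr, schedule, "zero", seed=seed).bic,
                "naive_softmax_search": inference.exploration_fit(
                    arr, "softmax", per_policy_params=stage1).bic,
                "naive_hmm_search": inference.exploration_fit(
                    arr, "hmm", per_policy_params=stage1).bic,
                "policy7_noise": inference.policy7_noise_fit(arr, seed=seed).bic,
            }
            hits += min(bics, key=bics.get) in family
        assert hits >= 0.7 * len(cases)


class TestCompareModels:
    def test_identical_fit_sets_flagged_degenerate(self):
        fits = [make_fit(log_l=-100.0 - i) for i in range(5)]
        result = compare_models(fits, list(fits), criterion="aic")
        assert result.degenerate
        assert result.mean_difference == 0.0
        assert result.p == 1.0

    def test_constant_nonzero_difference_flagged(self):
        a = [make_fit(log_l=-100.0 - i) for i in range(5)]
        b = [make_fit(log_l=-102.0 - i) for i in range(5)]
        result = compare_models(a, b)
        assert result.degenerate
        assert result.mean_difference == pytest.approx(-4.0)  # A fits better

    def test_paired_t_statistic_directions(self):
        rng = np.random.default_rng(0)
        base = -100 + rng.normal(size=10)
        a = [make_fit(log_l=l) for l in base]
        b = [make_fit(log_l=l - 3 - rng.random()) for l in base]
        result = compare_models(a, b, criterion="bic")
        assert result.mean_difference < 0  # model A fits better
        assert result.t < 0
        assert result.p < 0.01

    def test_unpaired_sessions_rejected(self):
        with pytest.raises(ValueError):
            compare_models([make_fit()], [make_fit(), make_fit()])


class TestTransitionEntropyTest:
    @staticmethod
    def events(*trials):
        return [TransitionEvent(t, 4, 7) for t in trials]

    def test_constant_entropy_gives_zero_difference(self):
        entropies = [np.full(100, 1.2)] * 3
        transitions = [self.events(10), self.events(20, 60), self.events(90)]
        result = transition_entropy_test(entropies, transitions)
        assert result.mean_difference == pytest.approx(0.0)

    def test_elevated_entropy_at_transitions_detected(self):
        rng = np.random.default_rng(1)
        entropies, transitions = [], []
        for s in range(8):
            e = 0.5 + 0.01 * rng.normal(size=100)
            trials = [10 + s, 40 + s]
            for t in trials:
                e[t - 1] = 1.5
            entropies.append(e)
            transitions.append(self.events(*trials))
        result = transition_entropy_test(entropies, transitions)
        assert result.mean_difference > 0.9
        assert result.p < 1e-6
        assert result.n_excluded == 0

    def test_sessions_without_transitions_excluded_and_counted(self):
        entropies = [np.ones(50)] * 4
        transitions = [self.events(10), [], self.events(20), []]
        result = transition_entropy_test(entropies, transitions)
        assert result.n_sessions == 2
        assert result.n_excluded == 2

    def test_single_usable_session_rejected(self):
        with pytest.raises(ValueError):
            transition_entropy_test([np.ones(50), np.ones(50)],
                                    [self.events(10), []])


class TestTimingRegression:
    def test_collinear_points_fit_exactly(self):
        points = [(t, 2.0 - 0.005 * t) for t in (10, 50, 100, 200)]
        result = transition_timing_regression(points)
        assert result.slope == pytest.approx(-0.005)
        assert result.r_squared == pytest.approx(1.0)

    def test_shuffled_entropy_uncorrelated(self):
        rng = np.random.default_rng(2)
        points = [(t, e) for t, e in zip(rng.integers(1, 256, 200),
                                         rng.uniform(0, 2, 200))]
        result = transition_timing_regression(points)
        assert result.r_squared < 0.05

    def test_too_few_or_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            transition_timing_regression([(10, 1.0), (20, 1.1)])
        with pytest.raises(ValueError):
            transition_timing_regression([(10, 1.0), (10, 1.1), (10, 0.9)])


class TestLikelihoodPerformanceCorrelation:
    def test_exact_linear_relation(self):
        log_l = np.linspace(-150, -50, 20)
        scores = 2.0 * log_l + 400
        result = likelihood_performance_correlation(log_l, scores)
        assert result.r_squared == pytest.approx(1.0)
        assert result.slope == pytest.approx(2.0)

    def test_constant_scores_uncorrelated(self):
        result = likelihood_performance_correlation(
            np.linspace(-150, -50, 10), np.full(10, 100.0)
        )
        assert result.r_squared == 0.0

    def test_mixed_ability_cohort_shows_positive_relation(self):
        """Better-explained sessions score higher across a cohort spanning
        random, 2-dim and 3-dim agents."""
        log_ls, scores = [], []
        for i, (kind, policy_id) in enumerate(
            [("random", 7), ("fixed_policy", 5), ("fixed_policy", 7)] * 4
        ):
            _, score, _, arr = make_session(kind=kind, policy_id=policy_id,
                                            seed=60 + i)
            stage1 = inference.fit_per_policy(arr, seed=i)
            schedule = inference.schedule_from_search(arr, stage1).schedule
            fit = inference.transfer_fit(arr, schedule, "inherited", seed=i)
            log_ls.append(fit.log_likelihood)
            scores.append(score)
        result = likelihood_performance_correlation(log_ls, scores)
        assert result.slope > 0
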