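"""Scikit-learn style estimators for the behavioural models.

Each estimator's ``fit`` takes a session — a list of trial records, a session
TSV path, or a :class:`~dimrl.task.SessionArrays` — and exposes fitted
parameters and information criteria as trailing-underscore attributes.  The
estimators are thin presentation layers over :mod:`dimrl.inference`; they
compose with sklearn tooling (``get_params``/``set_params``/``clone``).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import inference
from .io import as_session_arrays
from .naive_rl import LearningParams, run_naive_rl
from .policies import enumerate_policies
from .policy_search import (
    SearchConfig,
    action_prob_matrix,
    classify_strategy,
    hmm_policy_posterior,
    mixture_session_likelihood,
    softmax_policy_posterior,
)
from .value_transfer import (
    Policy7NoiseSpec,
    TransferModelSpec,
    run_policy7_noise,
    run_value_transfer,
)


class PolicyExplorationModel(BaseEstimator):
    """Seven-policy exploration model with a softmax- or HMM-based search.

    Stage 1 fits an independent (alpha_i, beta_i) delta-rule learner per
    policy (14 free parameters); stage 2 infers the per-trial policy
    distribution with the chosen search model.  The session likelihood mixes
    each policy's choice probability with that distribution.

    Parameters
    ----------
    search : 'softmax' or 'hmm'
    stay_prob : HMM self-transition probability (fixed, not fitted).
    policy_temperature : softmax-search temperature in points (fixed).
    poly_degree : degree of the smoothing polynomial for the current-policy
        read-out.
    n_restarts : extra random optimisation starts per fit.
    random_state : seed for the optimiser's random starts.
    """

    def __init__(
        self,
        search: str = "softmax",
        stay_prob: float = 0.9,
        policy_temperature: float = 1.0,
        poly_degree: int = 5,
        n_restarts: int = 2,
        random_state: int = 0,
    ):
        self.search = search
        self.stay_prob = stay_prob
        self.policy_temperature = policy_temperature
        self.poly_degree = poly_degree
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _config(self) -> SearchConfig:
        return SearchConfig(
            stay_prob=self.stay_prob,
            policy_temperature=self.policy_temperature,
            poly_degree=self.poly_degree,
        )

    def fit(self, X, y=None) -> "PolicyExplorationModel":
        if self.search not in ("softmax", "hmm"):
            raise ValueError(f"search must be 'softmax' or 'hmm', got {self.search!r}")
        arrays = as_session_arrays(X)
        config = self._config()
        stage1 = inference.fit_per_policy(
            arrays, seed=self.random_state, n_restarts=self.n_restarts
        )
        self.alpha_ = np.array([a for a, _, _ in stage1])
        self.beta_ = np.array([b for _, b, _ in stage1])
        self.per_policy_log_likelihood_ = np.array([l for _, _, l in stage1])
        fit = inference.exploration_fit(
            arrays,
            search=self.search,
            config=config,
            seed=self.random_state,
            per_policy_params=stage1,
        )
        runs = [
            run_naive_rl(arrays, policy, LearningParams(a, b))
            for policy, a, b in zip(enumerate_policies(), self.alpha_, self.beta_)
        ]
        if self.search == "softmax":
            posterior = softmax_policy_posterior(arrays, runs, config)
        else:
            posterior, _ = hmm_policy_posterior(arrays, runs, config)
        schedule_result = inference.schedule_from_search(arrays, stage1, config)
        self.posterior_ = posterior
        self.entropy_ = schedule_result.entropy
        self.smoothed_posterior_ = schedule_result.smoothed
        self.current_policy_ = schedule_result.schedule
        self.transitions_ = schedule_result.transitions
        self.strategy_ = classify_strategy(schedule_result.schedule)
        self.log_likelihood_ = fit.log_likelihood
        self.k_ = fit.k
        self.n_trials_ = fit.n
        self.aic_ = fit.aic
        self.bic_ = fit.bic
        return self

    def predict(self, X) -> np.ndarray:
        """Per-trial current-policy ids for a session, using fitted parameters."""
        arrays = as_session_arrays(X)
        stage1 = [(a, b, 0.0) for a, b in zip(self.alpha_, self.beta_)]
        return inference.schedule_from_search(arrays, stage1, self._config()).schedule

    def predict_proba(self, X) -> np.ndarray:
        """Per-trial policy posterior for a session, using fitted parameters."""
        arrays = as_session_arrays(X)
        runs = [
            run_naive_rl(arrays, policy, LearningParams(a, b))
            for policy, a, b in zip(enumerate_policies(), self.alpha_, self.beta_)
        ]
        config = self._config()
        if self.search == "softmax":
            return softmax_policy_posterior(arrays, runs, config)
        return hmm_policy_posterior(arrays, runs, config)[0]

    def score(self, X, y=None) -> float:
        """Mixture log-likelihood of a session under the fitted parameters."""
        arrays = as_session_arrays(X)
        config = self._config()
        runs = [
            run_naive_rl(arrays, policy, LearningParams(a, b))
            for policy, a, b in zip(enumerate_policies(), self.alpha_, self.beta_)
        ]
        ap = action_prob_matrix(runs)
        if self.search == "softmax":
            posterior = softmax_policy_posterior(arrays, runs, config)
        else:
            _, posterior = hmm_policy_posterior(arrays, runs, config)
        return mixture_session_likelihood(posterior, ap, arrays)


class ValueTransferModel(BaseEstimator):
    """Single-active-policy learner with zero or inherited initialisation.

    If no schedule is supplied, the two-step procedure runs internally: the
    softmax-based search (with its own stage-1 fits) provides the per-trial
    policy schedule, which is then frozen while the shared (alpha, beta) are
    fitted by maximum likelihood (2 free parameters).
    """

    def __init__(
        self,
        init_rule: str = "inherited",
        schedule: Optional[Sequence[int]] = None,
        poly_degree: int = 5,
        policy_temperature: float = 1.0,
        n_restarts: int = 2,
        random_state: int = 0,
    ):
        self.init_rule = init_rule
        self.schedule = schedule
        self.poly_degree = poly_degree
        self.policy_temperature = policy_temperature
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None) -> "ValueTransferModel":
        arrays = as_session_arrays(X)
        config = SearchConfig(
            poly_degree=self.poly_degree, policy_temperature=self.policy_temperature
        )
        if self.schedule is None:
            stage1 = inference.fit_per_policy(
                arrays, seed=self.random_state, n_restarts=self.n_restarts
            )
            schedule_result = inference.schedule_from_search(arrays, stage1, config)
            schedule = schedule_result.schedule
            self.entropy_ = schedule_result.entropy
            self.transitions_ = schedule_result.transitions
        else:
            schedule = np.asarray(self.schedule, dtype=np.intp)
            self.transitions_ = None
        fit = inference.transfer_fit(
            arrays,
            schedule,
            init_rule=self.init_rule,
            seed=self.random_state,
            n_restarts=self.n_restarts,
        )
        self.schedule_ = schedule
        self.alpha_ = fit.params["alpha"]
        self.beta_ = fit.params["beta"]
        self.log_likelihood_ = fit.log_likelihood
        self.k_ = fit.k
        self.n_trials_ = fit.n
        self.aic_ = fit.aic
        self.bic_ = fit.bic
        trace = run_value_transfer(
            arrays,
            TransferModelSpec(
                init_rule=self.init_rule,
                params=LearningParams(self.alpha_, self.beta_),
                policy_schedule=schedule,
            ),
        )
        self.trace_ = trace
        self.value_signal_ = trace.chosen_q
        self.rpe_ = trace.rpe
        return self

    def predict_proba(self, X) -> np.ndarray:
        """(p_go, p_pass) per trial under the fitted parameters and schedule."""
        arrays = as_session_arrays(X)
        if len(arrays) != len(self.schedule_):
            raise ValueError("session length does not match the fitted schedule")
        trace = run_value_transfer(
            arrays,
            TransferModelSpec(
                init_rule=self.init_rule,
                params=LearningParams(self.alpha_, self.beta_),
                policy_schedule=self.schedule_,
            ),
        )
        return trace.choice_probs

    def score(self, X, y=None) -> float:
        arrays = as_session_arrays(X)
        trace = run_value_transfer(
            arrays,
            TransferModelSpec(
                init_rule=self.init_rule,
                params=LearningParams(self.alpha_, self.beta_),
                policy_schedule=self.schedule_,
            ),
        )
        return trace.log_likelihood


class PolicySevenNoiseModel(BaseEstimator):
    """Lapse baseline: naive learning on the full 3-d policy plus epsilon noise."""

    def __init__(self, n_restarts: int = 2, random_state: int = 0):
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None) -> "PolicySevenNoiseModel":
        arrays = as_session_arrays(X)
        fit = inference.policy7_noise_fit(
            arrays, seed=self.random_state, n_restarts=self.n_restarts
        )
        self.alpha_ = fit.params["alpha"]
        self.beta_ = fit.params["beta"]
        self.epsilon_ = fit.params["epsilon"]
        self.log_likelihood_ = fit.log_likelihood
        self.k_ = fit.k
        self.n_trials_ = fit.n
        self.aic_ = fit.aic
        self.bic_ = fit.bic
        return self

    def predict_proba(self, X) -> np.ndarray:
        arrays = as_session_arrays(X)
        result = run_policy7_noise(
            arrays,
            Policy7NoiseSpec(
                params=LearningParams(self.alpha_, self.beta_), epsilon=self.epsilon_
            ),
        )
        return result.choice_probs

    def score(self, X, y=None) -> float:
        arrays = as_session_arrays(X)
        return run_policy7_noise(
            arrays,
            Policy7NoiseSpec(
                params=LearningParams(self.alpha_, self.beta_), epsilon=self.epsilon_
            ),
        ).log_likelihood
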