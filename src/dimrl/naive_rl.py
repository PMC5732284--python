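"""Per-policy Rescorla-Wagner learning and softmax choice.

Each policy maintains a state x action table of Q-values (actions: go, pass),
initialised to zero and updated on every responded trial by the delta rule

    Q_new = Q_old + alpha * (R - Q_old)

applied to the chosen action's entry for the projected state.  Choice
probabilities come from a two-alternative softmax with inverse temperature
beta; the session log-likelihood is the sum of log probabilities of the
observed actions over responded trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp
from typing import Optional, Tuple

import numpy as np

from .policies import Policy, state_map
from .task import ACTION_GO, SessionArrays

#: probabilities are floored at this constant before taking logs
PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class LearningParams:
    """Free parameters of the delta-rule/softmax learner."""

    alpha: float  # learning rate, in [0, 1]
    beta: float  # inverse temperature, >= 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


def rw_update(q_old: float, reward: float, alpha: float) -> float:
    """Delta-rule value update toward the observed reward."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return q_old + alpha * (reward - q_old)


def softmax_choice_prob(q_go: float, q_pass: float, beta: float) -> Tuple[float, float]:
    """Two-alternative softmax, computed with max-subtraction for stability."""
    if beta < 0.0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    m = q_go if q_go > q_pass else q_pass
    e_go = exp(beta * (q_go - m))
    e_pass = exp(beta * (q_pass - m))
    z = e_go + e_pass
    return e_go / z, e_pass / z


@dataclass
class NaiveRLResult:
    """Trial-by-trial output of a single-policy delta-rule learner.

    ``choice_probs`` holds (p_go, p_pass) from the pre-update table,
    ``action_prob`` the probability of the action actually taken (NaN on
    missed trials), ``chosen_q`` the pre-update value of the taken action,
    and ``q_state`` the pre-update (q_go, q_pass) of the visited state.
    """

    policy: Policy
    params: LearningParams
    choice_probs: np.ndarray  # (T, 2)
    action_prob: np.ndarray  # (T,)
    chosen_q: np.ndarray  # (T,)
    q_state: np.ndarray  # (T, 2)
    q_final: np.ndarray  # (n_states, 2)
    q_trajectory: Optional[np.ndarray] = None  # (T, n_states, 2), pre-update


def run_naive_rl(
    arrays: SessionArrays,
    policy: Policy,
    params: LearningParams,
    record_q: bool = False,
) -> NaiveRLResult:
    """Run the delta-rule learner over a session under one policy.

    Q is initialised to zero; only the chosen action's entry updates, and only
    on responded trials.  Choice probabilities are computed from the table
    before the trial's update.
    """
    states = state_map(policy)[arrays.stim_index].tolist()
    actions = arrays.action.tolist()
    rewards = arrays.reward.tolist()
    alpha, beta = params.alpha, params.beta
    T = len(arrays)
    n_states = policy.n_states

    q = [[0.0, 0.0] for _ in range(n_states)]
    choice_probs = np.empty((T, 2))
    action_prob = np.full(T, np.nan)
    chosen_q = np.full(T, np.nan)
    q_state = np.empty((T, 2))
    traj = np.empty((T, n_states, 2)) if record_q else None

    for t in range(T):
        s = states[t]
        qs = q[s]
        q_go, q_pass = qs[0], qs[1]
        m = q_go if q_go > q_pass else q_pass
        e_go = exp(beta * (q_go - m))
        e_pass = exp(beta * (q_pass - m))
        p_go = e_go / (e_go + e_pass)
        choice_probs[t, 0] = p_go
        choice_probs[t, 1] = 1.0 - p_go
        q_state[t, 0] = q_go
        q_state[t, 1] = q_pass
        if traj is not None:
            traj[t] = q
        a = actions[t]
        if a >= 0:  # responded trial
            chosen_q[t] = qs[a]
            action_prob[t] = p_go if a == ACTION_GO else 1.0 - p_go
            qs[a] += alpha * (rewards[t] - qs[a])

    return NaiveRLResult(
        policy=policy,
        params=params,
        choice_probs=choice_probs,
        action_prob=action_prob,
        chosen_q=chosen_q,
        q_state=q_state,
        q_final=np.array(q),
        q_trajectory=traj,
    )


def session_log_likelihood(
    action_prob: np.ndarray, arrays: Optional[SessionArrays] = None
) -> float:
    """Sum of floored log choice probabilities over responded trials."""
    action_prob = np.asarray(action_prob, dtype=float)
    if arrays is not None:
        if len(action_prob) != len(arrays):
            raise ValueError("choice probabilities do not match the session length")
        valid = arrays.valid
    else:
        valid = ~np.isnan(action_prob)
    p = action_prob[valid]
    if p.size == 0:
        return 0.0
    if np.isnan(p).any():
        raise ValueError("NaN choice probability on a responded trial")
    return float(np.log(np.maximum(p, PROB_FLOOR)).sum())
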