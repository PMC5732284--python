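"""Single-active-policy learning with value transfer at policy transitions.

Once a per-trial policy schedule has been inferred, learning is modelled as a
single delta-rule learner that follows the schedule, re-initialising its
Q-table whenever the active policy changes.  Two initialisation rules are
compared:

* *zero*: the new table starts at zero, i.e. values are re-learned from
  scratch after every transition;
* *inherited*: each new state inherits from the old table.  When the feature
  set grows, every new state copies the action values of the unique old state
  it projects onto; when it shrinks or changes at equal dimensionality, each
  new state takes the unweighted mean over the old states consistent with its
  shared-feature levels (the full-table mean if no features are shared).

A third baseline, "policy 7 + epsilon", keeps the full three-dimensional
policy throughout but mixes its softmax choice probabilities with a uniform
lapse of rate epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp
import numpy as np

from .naive_rl import LearningParams, run_naive_rl, session_log_likelihood
from .policies import Policy, get_policy, state_map, state_preimage
from .task import ACTION_GO, SessionArrays

INIT_RULES = ("zero", "inherited")


def transfer_initialise(
    q_prev: np.ndarray,
    policy_prev: Policy,
    policy_curr: Policy,
    init_rule: str,
) -> np.ndarray:
    """Initial Q-table of the newly adopted policy.

    Both action columns transfer.  The inherited rule averages, for each new
    state, the old states returned by :func:`state_preimage`; for a growing
    feature set that preimage is a single state, so the mean reduces to a
    copy of its values.
    """
    q_prev = np.asarray(q_prev, dtype=float)
    if q_prev.shape != (policy_prev.n_states, 2):
        raise ValueError(
            f"previous table shape {q_prev.shape} does not match "
            f"policy {policy_prev.id} ({policy_prev.n_states} states)"
        )
    if init_rule == "zero":
        return np.zeros((policy_curr.n_states, 2))
    if init_rule != "inherited":
        raise ValueError(f"unknown init rule {init_rule!r}")
    q_new = np.empty((policy_curr.n_states, 2))
    for state in range(policy_curr.n_states):
        preimage = state_preimage(policy_prev, policy_curr, state)
        q_new[state] = q_prev[preimage].mean(axis=0)
    return q_new


@dataclass(frozen=True)
class TransferModelSpec:
    """A value-transfer model: init rule, shared (alpha, beta), and schedule."""

    init_rule: str
    params: LearningParams
    policy_schedule: np.ndarray  # per-trial policy ids

    def __post_init__(self) -> None:
        if self.init_rule not in INIT_RULES:
            raise ValueError(f"unknown init rule {self.init_rule!r}")
        object.__setattr__(
            self, "policy_schedule", np.asarray(self.policy_schedule, dtype=np.intp)
        )


@dataclass
class TransferResult:
    """Trial-by-trial trace of the value-transfer learner."""

    spec: TransferModelSpec
    choice_probs: np.ndarray  # (T, 2)
    action_prob: np.ndarray  # (T,)
    chosen_q: np.ndarray  # (T,) pre-update value of the taken action
    q_state: np.ndarray  # (T, 2) pre-update (q_go, q_pass) of the state
    rpe: np.ndarray  # (T,) reward prediction error, NaN on missed trials
    log_likelihood: float = np.nan


def run_value_transfer(
    arrays: SessionArrays, spec: TransferModelSpec
) -> TransferResult:
    """Play the value-transfer model through a session.

    At each trial where the schedule's policy differs from the previous one,
    the new policy's table is initialised (per ``spec.init_rule``) before the
    trial's choice probability is computed.  Within a policy, learning is the
    ordinary delta rule on responded trials.
    """
    schedule = spec.policy_schedule
    if len(schedule) != len(arrays):
        raise ValueError("policy schedule length does not match the session")
    alpha, beta = spec.params.alpha, spec.params.beta
    T = len(arrays)
    actions = arrays.action.tolist()
    rewards = arrays.reward.tolist()
    stim = arrays.stim_index.tolist()
    schedule_l = schedule.tolist()

    active_id = schedule_l[0]
    policy = get_policy(active_id)
    smap = state_map(policy).tolist()
    q = [[0.0, 0.0] for _ in range(policy.n_states)]

    choice_probs = np.empty((T, 2))
    action_prob = np.full(T, np.nan)
    chosen_q = np.full(T, np.nan)
    q_state = np.empty((T, 2))
    rpe = np.full(T, np.nan)

    for t in range(T):
        if schedule_l[t] != active_id:
            new_policy = get_policy(schedule_l[t])
            q = transfer_initialise(
                np.array(q), policy, new_policy, spec.init_rule
            ).tolist()
            policy = new_policy
            smap = state_map(policy).tolist()
            active_id = schedule_l[t]
        s = smap[stim[t]]
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
        a = actions[t]
        if a >= 0:
            chosen_q[t] = qs[a]
            action_prob[t] = p_go if a == ACTION_GO else 1.0 - p_go
            rpe[t] = rewards[t] - qs[a]
            qs[a] += alpha * (rewards[t] - qs[a])

    result = TransferResult(
        spec=spec,
        choice_probs=choice_probs,
        action_prob=action_prob,
        chosen_q=chosen_q,
        q_state=q_state,
        rpe=rpe,
    )
    result.log_likelihood = session_log_likelihood(action_prob, arrays)
    return result


@dataclass(frozen=True)
class Policy7NoiseSpec:
    """The lapse baseline: full 3-d policy with uniform-random lapses."""

    params: LearningParams
    epsilon: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must be in [0, 1], got {self.epsilon}")


@dataclass
class Policy7NoiseResult:
    spec: Policy7NoiseSpec
    choice_probs: np.ndarray
    action_prob: np.ndarray
    log_likelihood: float


def run_policy7_noise(
    arrays: SessionArrays, spec: Policy7NoiseSpec
) -> Policy7NoiseResult:
    """Naive learning on policy 7 with an epsilon share of coin-flip choices."""
    base = run_naive_rl(arrays, get_policy(7), spec.params)
    eps = spec.epsilon
    choice_probs = (1.0 - eps) * base.choice_probs + eps * 0.5
    action_prob = np.full(len(arrays), np.nan)
    valid = arrays.valid
    go = arrays.action == ACTION_GO
    action_prob[valid & go] = choice_probs[valid & go, 0]
    action_prob[valid & ~go] = choice_probs[valid & ~go, 1]
    return Policy7NoiseResult(
        spec=spec,
        choice_probs=choice_probs,
        action_prob=action_prob,
        log_likelihood=session_log_likelihood(action_prob, arrays),
    )
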