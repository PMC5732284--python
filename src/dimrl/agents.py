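"""Synthetic behavioural agents replacing the human cohort.

Three agent kinds generate sessions with the statistical structure the
analysis pipeline assumes:

* ``random`` — go/pass with probability 0.5 each, ignoring feedback (the
  null model behind the chance-level cutoff);
* ``fixed_policy`` — a delta-rule/softmax learner confined to one policy's
  state-space for the whole session;
* ``exploring_transfer`` — a learner that acts through one *active* policy
  but tracks all seven candidate policies in the background.  After any trial
  on which the entropy of its policy posterior exceeds a threshold, it
  switches, with a fixed probability, to a policy drawn in proportion to the
  posterior, initialising the new active table by the zero or inherited rule.
  The threshold-plus-probability switching law is this package's own
  generative construction: the empirical analyses establish that transitions
  co-occur with high entropy, not a mechanism, so the generator makes the
  simplest law with that signature (recorded per agent in the manifest).

Default learning parameters (alpha 0.25, beta 4.5) follow the fitted
transfer-model means of the behavioural cohort; the switching defaults
(threshold 0.65 ln 7 on a trailing-window mean entropy, probability 0.1 per
eligible trial, a 32-trial refractory/burn-in) produce a handful of
transitions per 256-trial session, concentrated while ambiguity is still
high, and let poorly-learning agents keep exploring while learners settle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .naive_rl import LearningParams
from .policies import N_POLICIES, enumerate_policies, get_policy, state_map
from .task import (
    ACTION_GO,
    GO,
    PASS,
    SessionArrays,
    StimulusFeatures,
    TaskConfig,
    TrialRecord,
    action_code,
    play_session,
)
from .value_transfer import transfer_initialise

AGENT_KINDS = ("random", "fixed_policy", "exploring_transfer")
DEFAULT_SWITCH_THRESHOLD = 0.65 * math.log(N_POLICIES)
DEFAULT_SWITCH_PROB = 0.1


@dataclass(frozen=True)
class AgentConfig:
    """Ground-truth description of one synthetic agent."""

    kind: str = "exploring_transfer"
    policy_id: int = 7  # acting policy (fixed) or starting policy (exploring)
    alpha: float = 0.25
    beta: float = 4.5
    switch_threshold: float = DEFAULT_SWITCH_THRESHOLD  # nats
    switch_prob: float = DEFAULT_SWITCH_PROB
    init_rule: str = "inherited"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in AGENT_KINDS:
            raise ValueError(f"unknown agent kind {self.kind!r}")
        if not 0.0 <= self.switch_threshold <= math.log(N_POLICIES) + 1e-12:
            raise ValueError("switch_threshold must be in [0, ln 7]")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch_prob must be in [0, 1]")


def _choice_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng([seed, 0])


def _switch_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng([seed, 1])


def _task_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng([seed, 2])


class RandomAgent:
    """Chooses go/pass with probability 0.5, ignoring all feedback."""

    def __init__(self, seed: int = 0):
        self._rng = _choice_rng(seed)

    def choose(self, stimulus: StimulusFeatures) -> str:
        return GO if self._rng.random() < 0.5 else PASS

    def observe(self, stimulus: StimulusFeatures, action: str, reward: int) -> None:
        pass


class FixedPolicyAgent:
    """Delta-rule/softmax learner on a single policy's state-space."""

    def __init__(self, policy_id: int, params: LearningParams, seed: int = 0):
        self.policy = get_policy(policy_id)
        self.params = params
        self._smap = state_map(self.policy)
        self._q = np.zeros((self.policy.n_states, 2))
        self._rng = _choice_rng(seed)

    def choose(self, stimulus: StimulusFeatures) -> str:
        q_go, q_pass = self._q[self._smap[stimulus.index]]
        beta = self.params.beta
        m = max(q_go, q_pass)
        p_go = math.exp(beta * (q_go - m)) / (
            math.exp(beta * (q_go - m)) + math.exp(beta * (q_pass - m))
        )
        return GO if self._rng.random() < p_go else PASS

    def observe(self, stimulus: StimulusFeatures, action: str, reward: int) -> None:
        s = self._smap[stimulus.index]
        a = action_code(action)
        self._q[s, a] += self.params.alpha * (reward - self._q[s, a])


class ExploringTransferAgent:
    """Learner that switches policies under high ambiguity, transferring values.

    Seven background Q-tables (one per candidate policy, all updated every
    trial) support a softmax policy posterior over the agent's own chosen
    actions, mirroring the analysis-side search on the raw value scale.
    Actions come from a separate *active* table, which is re-initialised by
    the configured rule at every policy switch.  Switching is gated on the
    trailing-window mean of the posterior entropy, observes a refractory
    period, and draws its destination in proportion to the value each
    candidate policy currently promises.  ``switch_prob=0`` reduces the
    agent to a fixed-policy learner on its starting policy (choice streams
    match because choice and switching draw from separate seeded
    generators).
    """

    GATE_WINDOW = 16  # trials; trailing window for the ambiguity gate
    REFRACTORY = 32  # minimum trials between switches (and before the first)
    DRAW_TEMPERATURE = 0.5  # points; softmax temperature of the destination draw

    def __init__(self, config: AgentConfig):
        if config.kind != "exploring_transfer":
            raise ValueError("config.kind must be 'exploring_transfer'")
        self.config = config
        self.params = LearningParams(config.alpha, config.beta)
        self.policies = enumerate_policies()
        self._smaps = [state_map(p) for p in self.policies]
        self._belief_q = [np.zeros((p.n_states, 2)) for p in self.policies]
        self.active_policy = get_policy(config.policy_id)
        self._active_q = np.zeros((self.active_policy.n_states, 2))
        self._rng_choice = _choice_rng(config.seed)
        self._rng_switch = _switch_rng(config.seed)
        self._trial = 0
        self._last_switch = 0  # doubles as a burn-in before the first switch
        self.true_transitions: List[Tuple[int, int, int]] = []  # (trial, from, to)
        self.entropy_trace: List[float] = []
        self.active_policy_trace: List[int] = []  # policy acting on each trial

    def choose(self, stimulus: StimulusFeatures) -> str:
        s = state_map(self.active_policy)[stimulus.index]
        q_go, q_pass = self._active_q[s]
        beta = self.params.beta
        m = max(q_go, q_pass)
        p_go = math.exp(beta * (q_go - m)) / (
            math.exp(beta * (q_go - m)) + math.exp(beta * (q_pass - m))
        )
        return GO if self._rng_choice.random() < p_go else PASS

    def observe(self, stimulus: StimulusFeatures, action: str, reward: int) -> None:
        self._trial += 1
        a = action_code(action)
        # Policy posterior mirroring the softmax-based search: softmax over
        # each policy's value advantage Q(a) - Q(other) for the agent's own
        # action, from the pre-update background tables.  The advantage is
        # used on the raw value scale (temperature 1 point) so that the
        # posterior, and hence the switching gate, stays soft while the
        # value gaps are still growing early in the session.
        scores = np.empty(N_POLICIES)
        for i in range(N_POLICIES):
            qs = self._belief_q[i][self._smaps[i][stimulus.index]]
            gap = qs[0] - qs[1]
            scores[i] = gap if a == 0 else -gap
        w = np.exp(scores - scores.max())
        posterior = w / w.sum()
        entropy = float(-(posterior * np.log(posterior)).sum())
        self.entropy_trace.append(entropy)
        self.active_policy_trace.append(self.active_policy.id)
        # Ambiguity gating uses the mean entropy over a trailing window of
        # trials: exploration is driven by a sustained state of ambiguity,
        # not by a single ambiguous stimulus (individual random-reward
        # stimuli stay ambiguous for the whole session by design).
        recent = self.entropy_trace[-self.GATE_WINDOW:]
        gate_entropy = sum(recent) / len(recent)
        # delta-rule updates: all background tables and the active table
        alpha = self.params.alpha
        for i in range(N_POLICIES):
            s = self._smaps[i][stimulus.index]
            self._belief_q[i][s, a] += alpha * (reward - self._belief_q[i][s, a])
        s_active = state_map(self.active_policy)[stimulus.index]
        self._active_q[s_active, a] += alpha * (reward - self._active_q[s_active, a])
        # Ambiguity-gated policy switch.  A refractory period enforces a
        # minimum commitment to the newly adopted policy: the agent gathers
        # experience under it before it may switch again.
        if (
            gate_entropy > self.config.switch_threshold
            and self._trial - self._last_switch >= self.REFRACTORY
            and self._rng_switch.random() < self.config.switch_prob
        ):
            # The destination is drawn prospectively: in proportion to the
            # value each candidate policy currently promises (mean over its
            # states of the better action's believed value).  Drawing from
            # the retrospective posterior instead would mostly re-select
            # whatever policy explains the agent's own recent actions.
            prospects = np.array(
                [self._belief_q[i].max(axis=1).mean() for i in range(N_POLICIES)]
            )
            w_draw = np.exp(
                (prospects - prospects.max()) / self.DRAW_TEMPERATURE
            )
            w_draw /= w_draw.sum()
            new_id = int(self._rng_switch.choice(N_POLICIES, p=w_draw)) + 1
            if new_id != self.active_policy.id:
                new_policy = get_policy(new_id)
                self._active_q = transfer_initialise(
                    self._active_q,
                    self.active_policy,
                    new_policy,
                    self.config.init_rule,
                )
                self.true_transitions.append(
                    (self._trial + 1, self.active_policy.id, new_id)
                )
                self.active_policy = new_policy
                self._last_switch = self._trial


def random_agent(seed: int = 0) -> RandomAgent:
    return RandomAgent(seed=seed)


def fixed_policy_agent(config: AgentConfig) -> FixedPolicyAgent:
    return FixedPolicyAgent(
        config.policy_id, LearningParams(config.alpha, config.beta), seed=config.seed
    )


def exploring_transfer_agent(config: AgentConfig) -> ExploringTransferAgent:
    return ExploringTransferAgent(config)


def make_agent(config: AgentConfig):
    if config.kind == "random":
        return random_agent(config.seed)
    if config.kind == "fixed_policy":
        return fixed_policy_agent(config)
    return exploring_transfer_agent(config)


def simulate_session(
    config: AgentConfig, task_config: TaskConfig
) -> Tuple[List[TrialRecord], int, object]:
    """One agent, one session; the task stream is derived from the agent seed."""
    agent = make_agent(config)
    records, score = play_session(agent, task_config, rng=_task_rng(config.seed))
    return records, score, agent


def reference_cohort_configs(
    seed: int = 0,
    n_exploring_increase: int = 15,
    n_exploring_decrease: int = 4,
    n_fixed_3d: int = 4,
    n_fixed_2d: int = 2,
    n_random: int = 4,
) -> List[AgentConfig]:
    """A mixed cohort mirroring the behavioural study's group structure.

    Exploring agents that increase dimensionality start from a 2-d policy;
    the decreasing-like group starts from the 3-d policy.
    """
    configs: List[AgentConfig] = []
    start_2d = (5, 6, 4)
    next_seed = seed
    for i in range(n_exploring_increase):
        configs.append(
            AgentConfig(
                kind="exploring_transfer",
                policy_id=start_2d[i % 3],
                seed=next_seed,
            )
        )
        next_seed += 1
    for _ in range(n_exploring_decrease):
        configs.append(
            AgentConfig(kind="exploring_transfer", policy_id=7, seed=next_seed)
        )
        next_seed += 1
    for _ in range(n_fixed_3d):
        configs.append(AgentConfig(kind="fixed_policy", policy_id=7, seed=next_seed))
        next_seed += 1
    for i in range(n_fixed_2d):
        configs.append(
            AgentConfig(kind="fixed_policy", policy_id=start_2d[i % 3], seed=next_seed)
        )
        next_seed += 1
    for _ in range(n_random):
        configs.append(AgentConfig(kind="random", seed=next_seed))
        next_seed += 1
    return configs


MANIFEST_COLUMNS = (
    "agent_id",
    "kind",
    "policy",
    "alpha",
    "beta",
    "init_rule",
    "switch_threshold",
    "switch_prob",
    "seed",
    "final_score",
)


def simulate_cohort(
    configs: Sequence[AgentConfig],
    task_config: TaskConfig,
    out_dir: Optional[str] = None,
) -> pd.DataFrame:
    """Simulate a cohort; optionally write one session file per agent.

    The returned manifest records every generator parameter, which is
    sufficient to reproduce each session bit-exactly.  Duplicate agent seeds
    are rejected because they would produce duplicated sessions.
    """
    seeds = [c.seed for c in configs]
    if len(set(seeds)) != len(seeds):
        raise ValueError("agent seeds must be distinct")
    from .io import write_session  # local import: io depends on task only

    rows = []
    for i, config in enumerate(configs):
        records, score, _ = simulate_session(config, task_config)
        agent_id = f"agent_{i:03d}"
        if out_dir is not None:
            path = Path(out_dir) / f"{agent_id}.tsv"
            path.parent.mkdir(parents=True, exist_ok=True)
            write_session(records, path)
        rows.append(
            {
                "agent_id": agent_id,
                "kind": config.kind,
                "policy": config.policy_id,
                "alpha": config.alpha,
                "beta": config.beta,
                "init_rule": config.init_rule,
                "switch_threshold": config.switch_threshold,
                "switch_prob": config.switch_prob,
                "seed": config.seed,
                "final_score": score,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.tsv", sep="\t", index=False)
    return manifest
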