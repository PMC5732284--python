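"""Multi-dimensional go/pass reward-learning task.

The task presents one of eight visual stimuli per trial, each a combination of
three binary feature dimensions (shape, colour, pattern).  The player chooses
``go`` (commit to the stimulus) or ``pass`` (decline, always 0 points).  A
fixed, uninstructed rule maps stimuli to outcomes:

* the two *all-match* stimuli (blue-square-vertical, yellow-circle-horizontal)
  pay +10 points on ``go``;
* the two stimuli that differ from an all-match stimulus only in one named
  dimension (the rule variant's *penalised non-match* pair) pay -10;
* the remaining four stimuli pay +-10 points with probability 0.5 each.

A session is a balanced, shuffled sequence of ``n_stages * trials_per_stage``
trials (256 in the main design, 320 in the three-rule variant experiment), in
which every stimulus appears equally often.  Because the optimal strategy must
distinguish all eight stimuli, the task rewards discovering and integrating
all three feature dimensions.

This module defines the stimuli, the reward rule and its variants, session
play-out against an agent object, and the coin-flip null model used to derive
a chance-level performance cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

# Fixed global feature order; binary levels are encoded 0/1 with this mapping.
FEATURES: Tuple[str, ...] = ("shape", "colour", "pattern")
FEATURE_LEVELS = {
    "shape": ("square", "circle"),
    "colour": ("blue", "yellow"),
    "pattern": ("vertical", "horizontal"),
}
RULE_VARIANTS = ("pattern_nonmatch", "shape_nonmatch", "colour_nonmatch")
CATEGORIES = (
    "all_match",
    "penalised_nonmatch",
    "random_nonmatch_A",
    "random_nonmatch_B",
)

GO, PASS, MISSED = "go", "pass", "missed"
ACTIONS = (GO, PASS, MISSED)
#: integer action codes used throughout the numerical layer
ACTION_GO, ACTION_PASS, ACTION_MISSED = 0, 1, -1
_ACTION_CODE = {GO: ACTION_GO, PASS: ACTION_PASS, MISSED: ACTION_MISSED}
_ACTION_LABEL = {v: k for k, v in _ACTION_CODE.items()}


@dataclass(frozen=True)
class StimulusFeatures:
    """One of the eight stimuli, as binary feature levels.

    Levels follow the fixed encoding square=0/circle=1, blue=0/yellow=1,
    vertical=0/horizontal=1.  ``category`` is the stimulus's reward category
    under a given rule variant; it is populated by :func:`enumerate_stimuli`
    and is ``None`` for stimuli constructed in isolation.
    """

    shape: int
    colour: int
    pattern: int
    category: Optional[str] = None

    def __post_init__(self) -> None:
        for name in FEATURES:
            level = getattr(self, name)
            if level not in (0, 1):
                raise ValueError(f"{name} level must be 0 or 1, got {level!r}")
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def levels(self) -> Tuple[int, int, int]:
        return (self.shape, self.colour, self.pattern)

    @property
    def index(self) -> int:
        """Binary encoding in the global (shape, colour, pattern) order."""
        return self.shape * 4 + self.colour * 2 + self.pattern

    @property
    def label(self) -> str:
        """Human-readable colour-shape-pattern label, e.g. 'blue-square-vertical'."""
        return "-".join(
            (
                FEATURE_LEVELS["colour"][self.colour],
                FEATURE_LEVELS["shape"][self.shape],
                FEATURE_LEVELS["pattern"][self.pattern],
            )
        )

    @classmethod
    def from_labels(
        cls, shape: str, colour: str, pattern: str, category: Optional[str] = None
    ) -> "StimulusFeatures":
        try:
            return cls(
                shape=FEATURE_LEVELS["shape"].index(shape),
                colour=FEATURE_LEVELS["colour"].index(colour),
                pattern=FEATURE_LEVELS["pattern"].index(pattern),
                category=category,
            )
        except ValueError as exc:
            raise ValueError(
                f"invalid feature labels ({shape!r}, {colour!r}, {pattern!r})"
            ) from exc


def _odd_feature(levels: Tuple[int, int, int]) -> Optional[str]:
    """Name of the single dimension whose level disagrees with the other two.

    Returns ``None`` for the two all-match stimuli (all levels equal).  Every
    other stimulus has exactly one disagreeing dimension, which determines its
    non-match type.
    """
    s, c, p = levels
    if s == c == p:
        return None
    if s == c:
        return "pattern"
    if s == p:
        return "colour"
    return "shape"


def categorise(stimulus: StimulusFeatures, rule_variant: str) -> str:
    """Reward category of ``stimulus`` under a rule variant.

    The category is a pure function of the three binary levels and the
    variant's penalised dimension.
    """
    if rule_variant not in RULE_VARIANTS:
        raise ValueError(f"unknown rule variant {rule_variant!r}")
    odd = _odd_feature(stimulus.levels)
    if odd is None:
        return "all_match"
    penalised_dim = rule_variant.split("_")[0]
    if odd == penalised_dim:
        return "penalised_nonmatch"
    others = [f for f in FEATURES if f != penalised_dim]
    return "random_nonmatch_A" if odd == others[0] else "random_nonmatch_B"


def enumerate_stimuli(rule_variant: str) -> List[StimulusFeatures]:
    """All eight stimuli, categorised under ``rule_variant``, in index order."""
    stimuli = []
    for idx in range(8):
        levels = ((idx >> 2) & 1, (idx >> 1) & 1, idx & 1)
        stim = StimulusFeatures(*levels)
        stimuli.append(
            StimulusFeatures(*levels, category=categorise(stim, rule_variant))
        )
    return stimuli


@dataclass(frozen=True)
class TaskConfig:
    """Session-level task parameters.

    Defaults give the main design: 8 stages of 32 trials (256 trials), reward
    magnitude 10 points, 50% win probability on the random non-match stimuli.
    The variant experiment uses 10 stages (320 trials) and a penalised
    dimension other than pattern for two of its three groups.
    """

    rule_variant: str = "pattern_nonmatch"
    n_stages: int = 8
    trials_per_stage: int = 32
    reward_magnitude: int = 10
    random_reward_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rule_variant not in RULE_VARIANTS:
            raise ValueError(f"unknown rule variant {self.rule_variant!r}")
        if self.n_stages < 1 or self.trials_per_stage < 1:
            raise ValueError("n_stages and trials_per_stage must be positive")
        if not 0.0 <= self.random_reward_prob <= 1.0:
            raise ValueError("random_reward_prob must be in [0, 1]")

    @property
    def n_trials(self) -> int:
        return self.n_stages * self.trials_per_stage


def main_task(seed: int = 0) -> TaskConfig:
    """The 256-trial main design (pattern non-match rule)."""
    return TaskConfig(seed=seed)


def variant_task(rule_variant: str, seed: int = 0) -> TaskConfig:
    """The 320-trial variant design with a chosen penalised dimension."""
    return TaskConfig(rule_variant=rule_variant, n_stages=10, seed=seed)


@dataclass(frozen=True)
class TrialRecord:
    """One trial of a behavioural session.

    ``reward`` is 0 on pass and missed trials and +-magnitude on go trials.
    Missed trials (no response within the deadline) are representable for
    real data but are excluded from all model likelihoods.
    """

    trial_index: int  # 1-based
    stage: int
    stimulus: StimulusFeatures
    action: str
    reward: int
    response_time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.action in (PASS, MISSED) and self.reward != 0:
            raise ValueError(f"{self.action} trial must have reward 0")


def sample_reward(
    stimulus: StimulusFeatures,
    action: str,
    config: TaskConfig,
    rng: np.random.Generator,
) -> int:
    """Outcome of one choice under the task's reward rule."""
    if action == MISSED:
        raise ValueError("missed trials have no sampled reward")
    if action == PASS:
        return 0
    if action != GO:
        raise ValueError(f"unknown action {action!r}")
    category = stimulus.category or categorise(stimulus, config.rule_variant)
    magnitude = config.reward_magnitude
    if category == "all_match":
        return magnitude
    if category == "penalised_nonmatch":
        return -magnitude
    return magnitude if rng.random() < config.random_reward_prob else -magnitude


def generate_trial_sequence(
    config: TaskConfig, rng: Optional[np.random.Generator] = None
) -> List[StimulusFeatures]:
    """Balanced shuffled stimulus sequence: each stimulus appears n/8 times."""
    n = config.n_trials
    if n % 8:
        raise ValueError(f"session length {n} is not divisible by 8 stimuli")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    stimuli = enumerate_stimuli(config.rule_variant)
    order = rng.permutation(np.repeat(np.arange(8), n // 8))
    return [stimuli[i] for i in order]


def play_session(
    agent, config: TaskConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[List[TrialRecord], int]:
    """Play one full session; returns trial records and the final score.

    ``agent`` must expose ``choose(stimulus) -> 'go'|'pass'`` and
    ``observe(stimulus, action, reward)``.  The provided (or config-seeded)
    ``rng`` drives both the stimulus shuffle and the random-stimulus outcomes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sequence = generate_trial_sequence(config, rng)
    records: List[TrialRecord] = []
    score = 0
    for t, stimulus in enumerate(sequence):
        action = agent.choose(stimulus)
        if action not in (GO, PASS):
            raise ValueError(f"agent returned invalid action {action!r}")
        reward = sample_reward(stimulus, action, config, rng)
        agent.observe(stimulus, action, reward)
        score += reward
        records.append(
            TrialRecord(
                trial_index=t + 1,
                stage=t // config.trials_per_stage + 1,
                stimulus=stimulus,
                action=action,
                reward=reward,
            )
        )
    return records, score


def simulate_null_scores(
    config: TaskConfig, n_sims: int, rng: np.random.Generator
) -> np.ndarray:
    """Final scores of ``n_sims`` sessions played by a go/pass coin-flipper.

    Because a session exposes fixed per-category trial counts and the null
    agent's choices are i.i.d., the score distribution does not depend on the
    stimulus order, so the simulation draws per-category go counts directly;
    this is distributionally identical to playing out each session trial by
    trial (checked against :func:`play_session` in the test suite).
    """
    reps = config.n_trials // 8
    n_det = 2 * reps  # trials in each deterministic category
    n_rand = 4 * reps  # trials paying +-magnitude at random
    go_plus = rng.binomial(n_det, 0.5, size=n_sims)
    go_minus = rng.binomial(n_det, 0.5, size=n_sims)
    go_rand = rng.binomial(n_rand, 0.5, size=n_sims)
    wins = rng.binomial(go_rand, config.random_reward_prob)
    return config.reward_magnitude * (go_plus - go_minus + 2 * wins - go_rand)


def chance_level_cutoff(
    config: TaskConfig,
    n_sims: int = 100_000,
    quantile: float = 0.95,
    seed: int = 0,
) -> float:
    """Empirical score quantile of the random go/pass null model.

    The 95th percentile over 100,000 simulated sessions is the chance-level
    performance cutoff used to screen learners.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    if config.n_trials % 8:
        raise ValueError("session length must be divisible by 8")
    rng = np.random.default_rng(seed)
    scores = simulate_null_scores(config, n_sims, rng)
    return float(np.quantile(scores, quantile))


@dataclass
class SessionArrays:
    """Column-oriented view of a session used by the numerical layer.

    ``stim_index`` is the full three-feature binary encoding (0..7);
    ``action`` uses the integer codes 0=go, 1=pass, -1=missed; ``valid``
    marks responded (non-missed) trials, the only ones entering likelihoods.
    """

    stim_index: np.ndarray
    action: np.ndarray
    reward: np.ndarray
    valid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.stim_index = np.asarray(self.stim_index, dtype=np.intp)
        self.action = np.asarray(self.action, dtype=np.intp)
        self.reward = np.asarray(self.reward, dtype=float)
        if not (len(self.stim_index) == len(self.action) == len(self.reward)):
            raise ValueError("session arrays must have equal length")
        self.valid = self.action != ACTION_MISSED

    def __len__(self) -> int:
        return len(self.action)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @classmethod
    def from_records(cls, records: Sequence[TrialRecord]) -> "SessionArrays":
        return cls(
            stim_index=[r.stimulus.index for r in records],
            action=[_ACTION_CODE[r.action] for r in records],
            reward=[r.reward for r in records],
        )


def action_code(label: str) -> int:
    return _ACTION_CODE[label]


def action_label(code: int) -> str:
    return _ACTION_LABEL[code]
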