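"""The seven feature-combination policies and their state-spaces.

A policy is a non-empty subset of the three stimulus dimensions; it sees two
stimuli as the same state whenever they agree on its features.  The canonical
ordering is pi_1..pi_3 the single dimensions (shape, colour, pattern), pi_4..
pi_6 the pairs ({shape,colour}, {shape,pattern}, {colour,pattern}), and pi_7
the full three-dimensional policy.  State indices are the binary encoding of
the policy's feature levels in the fixed global feature order, which makes the
value-transfer mappings between policies reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Tuple

import numpy as np

from .task import FEATURES, StimulusFeatures


@dataclass(frozen=True)
class Policy:
    """A feature subset defining a state-space over the eight stimuli."""

    id: int
    features: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.features or any(f not in FEATURES for f in self.features):
            raise ValueError(f"invalid feature subset {self.features!r}")

    @property
    def dimensionality(self) -> int:
        return len(self.features)

    @property
    def n_states(self) -> int:
        return 2 ** self.dimensionality


_POLICIES: Tuple[Policy, ...] = (
    Policy(1, ("shape",)),
    Policy(2, ("colour",)),
    Policy(3, ("pattern",)),
    Policy(4, ("shape", "colour")),
    Policy(5, ("shape", "pattern")),
    Policy(6, ("colour", "pattern")),
    Policy(7, ("shape", "colour", "pattern")),
)
N_POLICIES = len(_POLICIES)
POLICY_DIMENSIONALITY: Dict[int, int] = {p.id: p.dimensionality for p in _POLICIES}


def enumerate_policies() -> List[Policy]:
    """The seven policies in canonical order."""
    return list(_POLICIES)


def get_policy(policy_id: int) -> Policy:
    if not 1 <= policy_id <= 7:
        raise ValueError(f"policy id must be 1..7, got {policy_id}")
    return _POLICIES[policy_id - 1]


def project_state(stimulus: StimulusFeatures, policy: Policy) -> int:
    """State index of ``stimulus`` in ``policy``'s state-space."""
    state = 0
    for feature in policy.features:
        state = (state << 1) | getattr(stimulus, feature)
    return state


@lru_cache(maxsize=None)
def state_map(policy: Policy) -> np.ndarray:
    """Length-8 lookup from full stimulus index to ``policy`` state index."""
    table = np.empty(8, dtype=np.intp)
    for idx in range(8):
        levels = ((idx >> 2) & 1, (idx >> 1) & 1, idx & 1)
        state = 0
        for feature in policy.features:
            state = (state << 1) | levels[FEATURES.index(feature)]
        table[idx] = state
    return table


def state_levels(policy: Policy, state: int) -> Dict[str, int]:
    """Feature levels encoded by a state index (inverse of project_state)."""
    if not 0 <= state < policy.n_states:
        raise ValueError(f"state {state} out of range for {policy}")
    levels = {}
    for pos, feature in enumerate(policy.features):
        shift = policy.dimensionality - 1 - pos
        levels[feature] = (state >> shift) & 1
    return levels


def state_preimage(policy_from: Policy, policy_to: Policy, state_to: int) -> List[int]:
    """From-states whose shared-feature levels are consistent with ``state_to``.

    When the two policies share no features every from-state is returned, so
    a transfer degenerates to the grand mean over the old table.
    """
    shared = [f for f in policy_from.features if f in policy_to.features]
    target = state_levels(policy_to, state_to)
    states = []
    for state in range(policy_from.n_states):
        levels = state_levels(policy_from, state)
        if all(levels[f] == target[f] for f in shared):
            states.append(state)
    return states
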