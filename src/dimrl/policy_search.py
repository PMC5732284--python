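"""Trial-by-trial inference of the policy in use.

Two search models estimate, per trial, a probability distribution over the
seven candidate policies from the per-policy delta-rule outputs:

* the *softmax-based* search treats trials as temporally independent and
  weights each policy by the value it assigns to the action actually taken,
  P_t(pi_i) proportional to exp(Q_i(s_t, a_t) / temperature);
* the *HMM-based* search forward-filters a 7-state hidden Markov chain with a
  sticky transition matrix, using each policy's softmax probability of the
  observed action as the emission.

The per-policy probability series are smoothed by an ordinary least-squares
polynomial (degree 5 by default) before the per-trial argmax defines the
*current policy*; changes of the current policy are *transition events*.  The
Shannon entropy of the (unsmoothed) posterior quantifies cognitive ambiguity
about which policy is in use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .naive_rl import NaiveRLResult, PROB_FLOOR
from .policies import N_POLICIES, POLICY_DIMENSIONALITY
from .task import SessionArrays

STRATEGY_CLASSES = ("2d_to_3d", "3d_to_2d", "only_2d", "only_3d", "one_dim", "other")


@dataclass(frozen=True)
class SearchConfig:
    """Fixed (non-fitted) parameters of the two policy searches."""

    stay_prob: float = 0.9  # HMM self-transition probability
    policy_temperature: float = 1.0  # softmax-search temperature (points)
    poly_degree: int = 5  # smoothing polynomial degree
    floor: float = PROB_FLOOR

    def __post_init__(self) -> None:
        if not 1.0 / N_POLICIES < self.stay_prob < 1.0:
            raise ValueError("stay_prob must be in (1/7, 1)")
        if self.policy_temperature <= 0:
            raise ValueError("policy_temperature must be positive")
        if self.poly_degree < 1:
            raise ValueError("poly_degree must be >= 1")


@dataclass(frozen=True)
class TransitionEvent:
    """A change of the current policy between consecutive trials."""

    trial_index: int  # 1-based index of the trial with the new policy, >= 2
    from_policy: int
    to_policy: int

    def __post_init__(self) -> None:
        if self.from_policy == self.to_policy:
            raise ValueError("transition requires distinct policies")
        if self.trial_index < 2:
            raise ValueError("transitions start at trial 2")


def action_prob_matrix(runs: Sequence[NaiveRLResult]) -> np.ndarray:
    """(T, 7) matrix of each policy's probability of the observed action."""
    if len(runs) != N_POLICIES:
        raise ValueError(f"expected {N_POLICIES} per-policy runs, got {len(runs)}")
    return np.column_stack([r.action_prob for r in runs])


def chosen_q_matrix(runs: Sequence[NaiveRLResult]) -> np.ndarray:
    """(T, 7) matrix of each policy's pre-update value of the observed action."""
    if len(runs) != N_POLICIES:
        raise ValueError(f"expected {N_POLICIES} per-policy runs, got {len(runs)}")
    return np.column_stack([r.chosen_q for r in runs])


def _advantage_scores(arrays: SessionArrays, runs: Sequence[NaiveRLResult]) -> np.ndarray:
    """(T, 7) softmax advantage of the observed action under each policy.

    The score is beta_i * (Q_i(s_t, a_t) - Q_i(s_t, a_other)), i.e. the logit
    of policy i's choice probability for the action actually taken, computed
    from the pre-update table.  It pools each policy's learned values through
    its own fitted inverse temperature, so scores are comparable across
    policies, and it is discriminative on both go and pass trials (a policy
    that has learned to avoid a state assigns a large advantage to passing
    on it).
    """
    if len(runs) != N_POLICIES:
        raise ValueError(f"expected {N_POLICIES} per-policy runs, got {len(runs)}")
    go = (arrays.action == 0)[:, None]
    scores = np.empty((len(arrays), N_POLICIES))
    for i, run in enumerate(runs):
        gap = run.q_state[:, 0] - run.q_state[:, 1]
        scores[:, i] = run.params.beta * np.where(go[:, 0], gap, -gap)
    return scores


def softmax_policy_posterior(
    arrays: SessionArrays,
    runs: Sequence[NaiveRLResult],
    config: SearchConfig = SearchConfig(),
) -> np.ndarray:
    """Temporally independent policy posterior from chosen-action advantages.

    P_t(pi_i) is the softmax (at ``policy_temperature``) of each policy's
    advantage score for the action actually taken; each trial is inferred
    from the learned values alone, with no carry-over from the previous
    trial's probabilities.  Missed trials carry the previous posterior
    forward (uniform if the session starts with a miss).
    """
    scores = _advantage_scores(arrays, runs)
    T = scores.shape[0]
    posterior = np.empty((T, N_POLICIES))
    uniform = np.full(N_POLICIES, 1.0 / N_POLICIES)
    valid = arrays.valid
    for t in range(T):
        if not valid[t]:
            posterior[t] = posterior[t - 1] if t > 0 else uniform
            continue
        z = scores[t] / config.policy_temperature
        z -= z.max()
        w = np.exp(z)
        posterior[t] = w / w.sum()
    return posterior


def _transition_matrix(stay_prob: float) -> np.ndarray:
    off = (1.0 - stay_prob) / (N_POLICIES - 1)
    mat = np.full((N_POLICIES, N_POLICIES), off)
    np.fill_diagonal(mat, stay_prob)
    return mat


def hmm_policy_posterior(
    arrays: SessionArrays,
    runs: Sequence[NaiveRLResult],
    config: SearchConfig = SearchConfig(),
) -> Tuple[np.ndarray, np.ndarray]:
    """Forward-filtered policy posterior under a sticky 7-state HMM.

    Returns ``(filtered, predicted)``: ``filtered[t]`` is the posterior given
    choices up to and including trial t; ``predicted[t]`` is the one-step
    ahead distribution before trial t's choice is observed (uniform at t=0).
    The product of ``predicted[t] . emission[t]`` over trials is the exact
    session likelihood of the chain, which is what the mixture likelihood
    uses for this model.  Missed trials carry both distributions forward.
    """
    emissions = np.maximum(action_prob_matrix(runs), config.floor)
    T = emissions.shape[0]
    trans = _transition_matrix(config.stay_prob)
    filtered = np.empty((T, N_POLICIES))
    predicted = np.empty((T, N_POLICIES))
    uniform = np.full(N_POLICIES, 1.0 / N_POLICIES)
    valid = arrays.valid
    current = uniform
    seen_valid = False
    for t in range(T):
        if not valid[t]:
            predicted[t] = predicted[t - 1] if t > 0 else uniform
            filtered[t] = current
            continue
        pred = trans.T @ current if seen_valid else uniform
        seen_valid = True
        predicted[t] = pred
        weighted = pred * emissions[t]
        total = weighted.sum()
        if total <= 0.0:
            raise ValueError(f"zero emission mass at trial {t + 1}")
        current = weighted / total
        filtered[t] = current
    return filtered, predicted


def policy_entropy(posterior: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) of policy probability vectors, 0*log 0 = 0."""
    p = np.asarray(posterior, dtype=float)
    if np.any(p < -1e-12) or not np.allclose(p.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("posterior rows must be probability vectors")
    terms = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    h = -terms.sum(axis=-1)
    return h if h.ndim else float(h)


def smoothed_policy_entropy(
    smoothed: np.ndarray, floor: float = PROB_FLOOR
) -> np.ndarray:
    """Entropy (nats) of the polynomial-fitted policy probabilities.

    The fitted curves are clipped at ``floor`` and renormalised per trial
    before the entropy is taken.  This is the ambiguity series used by the
    transition analyses: the raw posterior's per-trial entropy is nearly
    bimodal (a single trial's evidence is either flat or decisive), whereas
    the fitted curves track the evolving ambiguity of the inferred policy
    and are maximally uncertain exactly where the current policy is about
    to change.
    """
    p = np.clip(np.asarray(smoothed, dtype=float), floor, None)
    p = p / p.sum(axis=1, keepdims=True)
    return -(p * np.log(p)).sum(axis=1)


def smooth_posterior(
    posterior: np.ndarray, config: SearchConfig = SearchConfig()
) -> np.ndarray:
    """Per-policy OLS polynomial fit of the probability series.

    The trial index is rescaled to [0, 1] for conditioning.  The fitted
    curves are used only for the argmax, so they are neither renormalised nor
    clipped.
    """
    posterior = np.asarray(posterior, dtype=float)
    T = posterior.shape[0]
    if T < config.poly_degree + 1:
        raise ValueError(
            f"need at least {config.poly_degree + 1} trials to fit "
            f"a degree-{config.poly_degree} polynomial, got {T}"
        )
    x = np.arange(T) / max(T - 1, 1)
    coeffs = np.polynomial.polynomial.polyfit(x, posterior, config.poly_degree)
    return np.polynomial.polynomial.polyval(x, coeffs).T


def current_policy(smoothed: np.ndarray) -> np.ndarray:
    """Per-trial argmax policy id; ties break to lower dimensionality, then id."""
    smoothed = np.asarray(smoothed, dtype=float)
    T = smoothed.shape[0]
    ids = np.empty(T, dtype=np.intp)
    # preference order for exact ties: (dimensionality, id)
    order = sorted(range(N_POLICIES), key=lambda i: (POLICY_DIMENSIONALITY[i + 1], i))
    for t in range(T):
        row = smoothed[t]
        top = row.max()
        ids[t] = next(i for i in order if row[i] == top) + 1
    return ids


def detect_transitions(series: Sequence[int]) -> List[TransitionEvent]:
    """Transition events wherever the current policy differs from the last trial."""
    series = np.asarray(series)
    if len(series) < 2:
        raise ValueError("need at least two trials to detect transitions")
    events = []
    for t in range(1, len(series)):
        if series[t] != series[t - 1]:
            events.append(
                TransitionEvent(
                    trial_index=t + 1,
                    from_policy=int(series[t - 1]),
                    to_policy=int(series[t]),
                )
            )
    return events


def classify_strategy(series: Sequence[int]) -> str:
    """Strategy class from modal policy dimensionality, first vs last quarter.

    A modal dimensionality of 1 in either quarter marks a one-dimensional
    (non-learner-like) session; otherwise the (first, last) pair maps onto
    the four classes (2d_to_3d, 3d_to_2d, only_2d, only_3d).
    """
    series = np.asarray(series)
    if series.size == 0:
        raise ValueError("empty policy series")
    quarter = max(1, len(series) // 4)

    def modal_dim(chunk: np.ndarray) -> int:
        dims = np.array([POLICY_DIMENSIONALITY[int(pid)] for pid in chunk])
        values, counts = np.unique(dims, return_counts=True)
        return int(values[counts.argmax()])  # tie breaks to the smaller dim

    d_first = modal_dim(series[:quarter])
    d_last = modal_dim(series[-quarter:])
    if d_first == 1 or d_last == 1:
        return "one_dim"
    return {
        (2, 3): "2d_to_3d",
        (3, 2): "3d_to_2d",
        (2, 2): "only_2d",
        (3, 3): "only_3d",
    }.get((d_first, d_last), "other")


def mixture_session_likelihood(
    posterior: np.ndarray,
    action_probs: np.ndarray,
    arrays: SessionArrays,
    floor: float = PROB_FLOOR,
) -> float:
    """Log-likelihood of the observed choices under a policy mixture.

    Per trial, p(C_t) = sum_i P_t(pi_i) * pi_i(C_t); responded trials only.
    """
    posterior = np.asarray(posterior, dtype=float)
    action_probs = np.asarray(action_probs, dtype=float)
    if posterior.shape != action_probs.shape or posterior.shape[0] != len(arrays):
        raise ValueError("posterior/action-probability shapes do not match session")
    valid = arrays.valid
    p = (posterior[valid] * action_probs[valid]).sum(axis=1)
    if p.size == 0:
        return 0.0
    return float(np.log(np.maximum(p, floor)).sum())
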