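"""Maximum-likelihood fitting, information criteria and cohort statistics.

Five behavioural models are fitted per session:

=====================  ==  ==========================================
model id                k  free parameters
=====================  ==  ==========================================
naive_softmax_search   14  (alpha_i, beta_i) per policy, i = 1..7
naive_hmm_search       14  (alpha_i, beta_i) per policy, i = 1..7
transfer_zero           2  shared (alpha, beta)
transfer_inherited      2  shared (alpha, beta)
policy7_noise           3  (alpha, beta, epsilon)
=====================  ==  ==========================================

Estimation follows the two-step procedure: stage 1 fits the seven per-policy
learners independently by maximum likelihood; stage 2 derives the softmax
search posterior and the per-trial policy schedule from those fits; stage 3
fits the transfer/baseline models with the schedule frozen.  Optimisation is
a coarse (alpha x log-beta) grid followed by bound-constrained local polish
(L-BFGS-B), deterministic given the seed.  AIC = 2k - 2 logL and
BIC = k ln n - 2 logL use n = responded-trial count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .naive_rl import LearningParams, run_naive_rl, session_log_likelihood
from .policies import N_POLICIES, enumerate_policies, get_policy
from .policy_search import (
    SearchConfig,
    TransitionEvent,
    action_prob_matrix,
    current_policy,
    detect_transitions,
    hmm_policy_posterior,
    mixture_session_likelihood,
    smooth_posterior,
    smoothed_policy_entropy,
    softmax_policy_posterior,
)
from .task import SessionArrays, TrialRecord
from .value_transfer import (
    Policy7NoiseSpec,
    TransferModelSpec,
    run_policy7_noise,
    run_value_transfer,
)

MODEL_IDS = (
    "naive_softmax_search",
    "naive_hmm_search",
    "transfer_zero",
    "transfer_inherited",
    "policy7_noise",
)

ALPHA_BOUNDS = (1e-6, 1.0)
BETA_BOUNDS = (1e-3, 50.0)
EPSILON_BOUNDS = (0.0, 1.0)
_ALPHA_GRID = np.linspace(0.05, 0.95, 5)
_BETA_GRID = np.geomspace(0.1, 32.0, 5)
_EPSILON_GRID = np.array([0.05, 0.35, 0.7])


def aic(log_likelihood: float, k: int) -> float:
    return 2.0 * k - 2.0 * log_likelihood


def bic(log_likelihood: float, k: int, n: int) -> float:
    if n < 1:
        raise ValueError("n must be >= 1")
    return k * float(np.log(n)) - 2.0 * log_likelihood


@dataclass(frozen=True)
class ModelFit:
    """A fitted model: parameters, likelihood and information criteria."""

    model: str
    params: Dict[str, float]
    log_likelihood: float
    k: int
    n: int
    aic: float
    bic: float


def _as_arrays(trials) -> SessionArrays:
    if isinstance(trials, SessionArrays):
        return trials
    if len(trials) and isinstance(trials[0], TrialRecord):
        return SessionArrays.from_records(trials)
    raise TypeError("trials must be a SessionArrays or a list of TrialRecord")


def _multistart_minimise(
    objective: Callable[[np.ndarray], float],
    grid: np.ndarray,
    bounds: Sequence[Tuple[float, float]],
    seed: int,
    n_restarts: int,
) -> Tuple[np.ndarray, float]:
    """Best of grid evaluation + local polish from the top grid points.

    ``n_restarts`` extra uniformly drawn starts (seeded) guard against a
    coarse grid; the returned optimum is deterministic given the seed.
    """
    grid = np.atleast_2d(grid)
    values = np.array([objective(x) for x in grid])
    order = np.argsort(values)
    starts = [grid[i] for i in order[:3]]
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        starts.extend(lo + rng.random((n_restarts, len(bounds))) * (hi - lo))
    best_x, best_f = grid[order[0]], values[order[0]]
    failures: List[str] = []
    for x0 in starts:
        try:
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B", bounds=bounds
            )
        except (ValueError, FloatingPointError) as exc:  # pragma: no cover
            failures.append(str(exc))
            continue
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f = res.x, res.fun
    if not np.isfinite(best_f):
        raise RuntimeError(
            "all optimisation starts failed: " + "; ".join(failures or ["no detail"])
        )
    return np.asarray(best_x, dtype=float), float(best_f)


def _alpha_beta_grid() -> np.ndarray:
    return np.array([(a, b) for a in _ALPHA_GRID for b in _BETA_GRID])


def fit_policy_params(
    arrays: SessionArrays,
    policy_id: int,
    seed: int = 0,
    n_restarts: int = 2,
) -> Tuple[float, float, float]:
    """MLE of (alpha, beta) for a single-policy delta-rule learner.

    Returns (alpha, beta, logL).
    """
    policy = get_policy(policy_id)

    def objective(x: np.ndarray) -> float:
        result = run_naive_rl(arrays, policy, LearningParams(float(x[0]), float(x[1])))
        return -session_log_likelihood(result.action_prob, arrays)

    x, f = _multistart_minimise(
        objective,
        _alpha_beta_grid(),
        [ALPHA_BOUNDS, BETA_BOUNDS],
        seed=seed,
        n_restarts=n_restarts,
    )
    return float(x[0]), float(x[1]), -f


def fit_per_policy(
    arrays: SessionArrays, seed: int = 0, n_restarts: int = 2
) -> List[Tuple[float, float, float]]:
    """Stage 1: independent (alpha_i, beta_i) fits for all seven policies."""
    return [
        fit_policy_params(arrays, policy.id, seed=seed + policy.id, n_restarts=n_restarts)
        for policy in enumerate_policies()
    ]


@dataclass
class ScheduleResult:
    """Stage 2 output: posterior, entropy, schedule and transitions.

    ``entropy`` is the ambiguity series of the smoothed (polynomial-fitted)
    policy probabilities, the series used by the transition analyses and the
    neuroimaging regressor export; the raw per-trial posterior is kept in
    ``posterior`` (its per-trial entropy is available via
    :func:`~dimrl.policy_search.policy_entropy`).
    """

    posterior: np.ndarray  # (T, 7) unsmoothed (softmax-search) posterior
    entropy: np.ndarray  # (T,) nats, from the smoothed probabilities
    smoothed: np.ndarray  # (T, 7) degree-5 polynomial fits
    schedule: np.ndarray  # (T,) current-policy ids
    transitions: List[TransitionEvent] = field(default_factory=list)


def schedule_from_search(
    arrays: SessionArrays,
    per_policy_params: Sequence[Tuple[float, float, float]],
    config: SearchConfig = SearchConfig(),
) -> ScheduleResult:
    """Derive the per-trial policy schedule from the softmax-based search."""
    runs = [
        run_naive_rl(arrays, policy, LearningParams(a, b))
        for policy, (a, b, _) in zip(enumerate_policies(), per_policy_params)
    ]
    posterior = softmax_policy_posterior(arrays, runs, config)
    smoothed = smooth_posterior(posterior, config)
    schedule = current_policy(smoothed)
    return ScheduleResult(
        posterior=posterior,
        entropy=smoothed_policy_entropy(smoothed),
        smoothed=smoothed,
        schedule=schedule,
        transitions=detect_transitions(schedule),
    )


def exploration_fit(
    arrays: SessionArrays,
    search: str = "softmax",
    config: SearchConfig = SearchConfig(),
    seed: int = 0,
    n_restarts: int = 2,
    per_policy_params: Optional[Sequence[Tuple[float, float, float]]] = None,
) -> ModelFit:
    """Fit a 14-parameter policy-exploration model (softmax or HMM search).

    The session likelihood mixes each policy's choice probability with the
    search model's per-trial policy distribution (the one-step predictive
    distribution for the HMM search).
    """
    if search not in ("softmax", "hmm"):
        raise ValueError(f"unknown search model {search!r}")
    if per_policy_params is None:
        per_policy_params = fit_per_policy(arrays, seed=seed, n_restarts=n_restarts)
    runs = [
        run_naive_rl(arrays, policy, LearningParams(a, b))
        for policy, (a, b, _) in zip(enumerate_policies(), per_policy_params)
    ]
    ap = action_prob_matrix(runs)
    if search == "softmax":
        posterior = softmax_policy_posterior(arrays, runs, config)
    else:
        _, posterior = hmm_policy_posterior(arrays, runs, config)
    log_l = mixture_session_likelihood(posterior, ap, arrays, floor=config.floor)
    n = arrays.n_valid
    k = 2 * N_POLICIES
    params: Dict[str, float] = {}
    for policy, (a, b, _) in zip(enumerate_policies(), per_policy_params):
        params[f"alpha_{policy.id}"] = a
        params[f"beta_{policy.id}"] = b
    return ModelFit(
        model=f"naive_{search}_search",
        params=params,
        log_likelihood=log_l,
        k=k,
        n=n,
        aic=aic(log_l, k),
        bic=bic(log_l, k, n),
    )


def transfer_fit(
    arrays: SessionArrays,
    schedule: np.ndarray,
    init_rule: str,
    seed: int = 0,
    n_restarts: int = 2,
) -> ModelFit:
    """Stage 3: fit the shared (alpha, beta) of a value-transfer model."""

    def objective(x: np.ndarray) -> float:
        spec = TransferModelSpec(
            init_rule=init_rule,
            params=LearningParams(float(x[0]), float(x[1])),
            policy_schedule=schedule,
        )
        return -run_value_transfer(arrays, spec).log_likelihood

    x, f = _multistart_minimise(
        objective,
        _alpha_beta_grid(),
        [ALPHA_BOUNDS, BETA_BOUNDS],
        seed=seed,
        n_restarts=n_restarts,
    )
    log_l = -f
    n = arrays.n_valid
    return ModelFit(
        model=f"transfer_{init_rule}",
        params={"alpha": float(x[0]), "beta": float(x[1])},
        log_likelihood=log_l,
        k=2,
        n=n,
        aic=aic(log_l, 2),
        bic=bic(log_l, 2, n),
    )


def policy7_noise_fit(
    arrays: SessionArrays, seed: int = 0, n_restarts: int = 2
) -> ModelFit:
    """Fit the (alpha, beta, epsilon) lapse baseline on policy 7.

    The fitted naive policy-7 solution (with epsilon = 0) seeds the
    multistart, so the baseline's likelihood never falls below its nested
    two-parameter special case.
    """
    a7, b7, _ = fit_policy_params(arrays, 7, seed=seed, n_restarts=n_restarts)

    def objective(x: np.ndarray) -> float:
        spec = Policy7NoiseSpec(
            params=LearningParams(float(x[0]), float(x[1])), epsilon=float(x[2])
        )
        return -run_policy7_noise(arrays, spec).log_likelihood

    grid = np.array(
        [(a, b, e) for a in _ALPHA_GRID for b in _BETA_GRID for e in _EPSILON_GRID]
        + [(a7, b7, 0.0)]
    )
    x, f = _multistart_minimise(
        objective,
        grid,
        [ALPHA_BOUNDS, BETA_BOUNDS, EPSILON_BOUNDS],
        seed=seed,
        n_restarts=n_restarts,
    )
    log_l = -f
    n = arrays.n_valid
    return ModelFit(
        model="policy7_noise",
        params={"alpha": float(x[0]), "beta": float(x[1]), "epsilon": float(x[2])},
        log_likelihood=log_l,
        k=3,
        n=n,
        aic=aic(log_l, 3),
        bic=bic(log_l, 3, n),
    )


def fit_model(
    trials,
    model_id: str,
    seed: int = 0,
    n_restarts: int = 2,
    config: SearchConfig = SearchConfig(),
) -> ModelFit:
    """Fit one of the five behavioural models to a session.

    For the transfer models the full two-step procedure runs internally:
    per-policy fits, softmax-search schedule, then the frozen-schedule
    (alpha, beta) fit.
    """
    arrays = _as_arrays(trials)
    if model_id in ("naive_softmax_search", "naive_hmm_search"):
        return exploration_fit(
            arrays,
            search=model_id.split("_")[1],
            config=config,
            seed=seed,
            n_restarts=n_restarts,
        )
    if model_id in ("transfer_zero", "transfer_inherited"):
        stage1 = fit_per_policy(arrays, seed=seed, n_restarts=n_restarts)
        schedule = schedule_from_search(arrays, stage1, config).schedule
        return transfer_fit(
            arrays,
            schedule,
            init_rule=model_id.split("_")[1],
            seed=seed,
            n_restarts=n_restarts,
        )
    if model_id == "policy7_noise":
        return policy7_noise_fit(arrays, seed=seed, n_restarts=n_restarts)
    raise ValueError(f"unknown model id {model_id!r}; expected one of {MODEL_IDS}")


@dataclass(frozen=True)
class PairedComparison:
    """Paired two-sided t-test on per-session criterion differences (A - B)."""

    criterion: str
    mean_difference: float
    t: float
    df: int
    p: float
    degenerate: bool = False


def compare_models(
    fits_a: Sequence[ModelFit],
    fits_b: Sequence[ModelFit],
    criterion: str = "aic",
) -> PairedComparison:
    """Paired comparison of two models across sessions; negative favours A."""
    if criterion not in ("aic", "bic", "log_likelihood"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if len(fits_a) != len(fits_b) or len(fits_a) < 2:
        raise ValueError("need the same >= 2 sessions in both fit sets")
    a = np.array([getattr(f, criterion) for f in fits_a])
    b = np.array([getattr(f, criterion) for f in fits_b])
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        mean = float(diff.mean())
        return PairedComparison(
            criterion=criterion,
            mean_difference=mean,
            t=np.nan,
            df=len(diff) - 1,
            p=1.0 if np.isclose(mean, 0.0) else np.nan,
            degenerate=True,
        )
    res = stats.ttest_rel(a, b)
    return PairedComparison(
        criterion=criterion,
        mean_difference=float(diff.mean()),
        t=float(res.statistic),
        df=len(diff) - 1,
        p=float(res.pvalue),
    )


@dataclass(frozen=True)
class TransitionEntropyResult:
    """Entropy at transition trials vs all trials, paired across sessions."""

    mean_difference: float
    t: float
    df: int
    p: float
    n_sessions: int
    n_excluded: int  # sessions without any transition


def transition_entropy_test(
    entropies: Sequence[np.ndarray],
    transitions: Sequence[Sequence[TransitionEvent]],
) -> TransitionEntropyResult:
    """Is the policy posterior more ambiguous when the policy changes?

    Per session, the difference between mean entropy at transition trials and
    mean entropy over all trials; one-sample t-test of the paired differences
    across sessions.  Sessions without transitions are excluded and counted.
    """
    if len(entropies) != len(transitions):
        raise ValueError("entropies and transitions must pair by session")
    diffs = []
    excluded = 0
    for entropy, events in zip(entropies, transitions):
        if not events:
            excluded += 1
            continue
        entropy = np.asarray(entropy, dtype=float)
        at_transition = np.array([entropy[e.trial_index - 1] for e in events])
        diffs.append(at_transition.mean() - entropy.mean())
    if len(diffs) < 2:
        raise ValueError(
            f"need >= 2 sessions with transitions, got {len(diffs)} "
            f"({excluded} excluded)"
        )
    diffs = np.array(diffs)
    res = stats.ttest_1samp(diffs, 0.0)
    return TransitionEntropyResult(
        mean_difference=float(diffs.mean()),
        t=float(res.statistic),
        df=len(diffs) - 1,
        p=float(res.pvalue),
        n_sessions=len(diffs),
        n_excluded=excluded,
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p: float


def transition_timing_regression(
    points: Sequence[Tuple[float, float]]
) -> RegressionResult:
    """OLS of entropy-at-transition on trial index, pooled across sessions.

    On exploring cohorts transitions concentrate in early, high-entropy
    trials, so the slope is expected to be negative.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 3:
        raise ValueError("need at least 3 pooled (trial_index, entropy) points")
    x, y = points[:, 0], points[:, 1]
    if np.allclose(x.std(), 0.0):
        raise ValueError("degenerate regression: no variance in trial index")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p=float(res.pvalue),
    )


def likelihood_performance_correlation(
    log_likelihoods: Sequence[float], final_scores: Sequence[float]
) -> RegressionResult:
    """OLS of final score on per-session model log-likelihood."""
    log_l = np.asarray(log_likelihoods, dtype=float)
    scores = np.asarray(final_scores, dtype=float)
    if log_l.shape != scores.shape:
        raise ValueError("log-likelihoods and scores must align by session")
    if np.allclose(scores.std(), 0.0) or np.allclose(log_l.std(), 0.0):
        return RegressionResult(slope=0.0, intercept=float(scores.mean()),
                                r_squared=0.0, p=1.0)
    res = stats.linregress(log_l, scores)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p=float(res.pvalue),
    )
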