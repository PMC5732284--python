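"""Session file I/O and regressor export.

Behavioural sessions are tab-separated files with a header row and columns
trial_index, stage, shape, colour, pattern, action, reward, response_time
(1-based trial indices; empty response_time for simulated agents).  Reading
validates every row and reports the offending row and column.  The regressor
export writes the four model-derived time series used downstream for
neuroimaging GLMs (value, reward prediction error, entropy, transition
indicator), unconvolved.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .task import (
    ACTION_GO,
    ACTIONS,
    FEATURE_LEVELS,
    GO,
    MISSED,
    PASS,
    SessionArrays,
    StimulusFeatures,
    TrialRecord,
)

SESSION_COLUMNS = (
    "trial_index",
    "stage",
    "shape",
    "colour",
    "pattern",
    "action",
    "reward",
    "response_time",
)

REGRESSOR_COLUMNS = (
    "trial_index",
    "onset_type",
    "value",
    "rpe",
    "entropy",
    "transition",
)


def write_session(records: Sequence[TrialRecord], path: Union[str, Path]) -> None:
    """Write a session TSV; byte-stable for a given record list."""
    lines = ["\t".join(SESSION_COLUMNS)]
    for r in records:
        rt = "" if r.response_time is None else f"{r.response_time:.3f}"
        lines.append(
            "\t".join(
                (
                    str(r.trial_index),
                    str(r.stage),
                    FEATURE_LEVELS["shape"][r.stimulus.shape],
                    FEATURE_LEVELS["colour"][r.stimulus.colour],
                    FEATURE_LEVELS["pattern"][r.stimulus.pattern],
                    r.action,
                    str(r.reward),
                    rt,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _row_error(row: int, column: str, message: str) -> ValueError:
    return ValueError(f"row {row}, column '{column}': {message}")


def read_session(path: Union[str, Path]) -> List[TrialRecord]:
    """Read and strictly validate a session TSV."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if tuple(frame.columns) != SESSION_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {list(SESSION_COLUMNS)}, "
            f"got {list(frame.columns)}"
        )
    records: List[TrialRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            trial_index = int(row.trial_index)
            stage = int(row.stage)
        except ValueError:
            raise _row_error(i, "trial_index", "non-integer index or stage")
        levels = {}
        for feature in ("shape", "colour", "pattern"):
            label = getattr(row, feature)
            if label not in FEATURE_LEVELS[feature]:
                raise _row_error(i, feature, f"unknown level {label!r}")
            levels[feature] = FEATURE_LEVELS[feature].index(label)
        action = row.action
        if action not in ACTIONS:
            raise _row_error(i, "action", f"unknown action {action!r}")
        try:
            reward = int(row.reward)
        except ValueError:
            raise _row_error(i, "reward", f"non-integer reward {row.reward!r}")
        if action in (PASS, MISSED) and reward != 0:
            raise _row_error(i, "reward", f"{action} trial must have reward 0")
        if action == GO and abs(reward) != 10:
            raise _row_error(i, "reward", f"go trial reward must be +-10, got {reward}")
        if row.response_time == "":
            response_time = None
        else:
            try:
                response_time = float(row.response_time)
            except ValueError:
                raise _row_error(i, "response_time", f"bad value {row.response_time!r}")
        records.append(
            TrialRecord(
                trial_index=trial_index,
                stage=stage,
                stimulus=StimulusFeatures(**levels),
                action=action,
                reward=reward,
                response_time=response_time,
            )
        )
    return records


def as_session_arrays(trials) -> SessionArrays:
    """Coerce records, a session file path, or arrays to SessionArrays."""
    if isinstance(trials, SessionArrays):
        return trials
    if isinstance(trials, (str, Path)):
        return SessionArrays.from_records(read_session(trials))
    return SessionArrays.from_records(list(trials))


def export_regressors(
    arrays: SessionArrays,
    value: np.ndarray,
    rpe: np.ndarray,
    entropy: np.ndarray,
    transition_trials: Sequence[int],
    path: Union[str, Path],
) -> None:
    """Write the four parametric regressor series, unconvolved.

    Two rows per trial: a stimulus-onset row carrying the value signal
    (pre-update chosen-action Q), the entropy signal and the transition
    indicator, and a feedback-onset row carrying the reward prediction error
    on go trials only.  Haemodynamic convolution is downstream and
    tool-specific.
    """
    T = len(arrays)
    value = np.asarray(value, dtype=float)
    rpe = np.asarray(rpe, dtype=float)
    entropy = np.asarray(entropy, dtype=float)
    if not (len(value) == len(rpe) == len(entropy) == T):
        raise ValueError("regressor series do not align with the session")
    transition_set = set(int(t) for t in transition_trials)
    if transition_set and (min(transition_set) < 2 or max(transition_set) > T):
        raise ValueError("transition trial index outside the session")
    go = arrays.action == ACTION_GO

    def fmt(x: float) -> str:
        return "" if np.isnan(x) else f"{x:.6f}"

    lines = ["\t".join(REGRESSOR_COLUMNS)]
    for t in range(T):
        idx = str(t + 1)
        lines.append(
            "\t".join(
                (
                    idx,
                    "stimulus",
                    fmt(value[t]),
                    "",
                    fmt(entropy[t]),
                    "1" if t + 1 in transition_set else "0",
                )
            )
        )
        lines.append(
            "\t".join(
                (idx, "feedback", "", fmt(rpe[t]) if go[t] else "", "", "")
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def posterior_table(
    posterior: np.ndarray,
    entropy: np.ndarray,
    schedule: np.ndarray,
    transition_trials: Sequence[int],
) -> pd.DataFrame:
    """Posterior export table: per-trial policy probabilities and labels."""
    T = posterior.shape[0]
    transition_set = set(int(t) for t in transition_trials)
    data = {"trial_index": np.arange(1, T + 1)}
    for i in range(posterior.shape[1]):
        data[f"p_pi{i + 1}"] = posterior[:, i]
    data["entropy"] = entropy
    data["current_policy"] = schedule
    data["is_transition"] = [int(t + 1 in transition_set) for t in range(T)]
    return pd.DataFrame(data)
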