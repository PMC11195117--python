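"""Trial-pair ensemble statistics.

Pairwise trial-to-trial activity-pattern correlations, the six-bin
movement-correlation binning (-0.2..1.0 in steps of 0.2; pairs below -0.2
excluded), and the activated-ensemble difference |a-b| / (0.5 (a+b)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .signals import EventTrain
from .trial_response import TrialTensor

__all__ = [
    "MOVEMENT_CORR_BINS",
    "activity_pattern_correlation",
    "bin_by_movement_correlation",
    "activated_count",
    "ensemble_difference",
    "trial_pair_table",
]

# bin edges for movement-trajectory correlation; half-open [lo, hi),
# last bin closed at 1.0
MOVEMENT_CORR_BINS = np.array([-0.2, 0.0, 0.2, 0.4, 0.6, 0.8, 1.0])


def activity_pattern_correlation(
    tensor: TrialTensor, trial_i: int, trial_j: int
) -> float:
    """Pearson correlation between two trials' bouton x time patterns."""
    a = tensor.activity[:, trial_i, :].ravel()
    b = tensor.activity[:, trial_j, :].ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("undefined correlation: zero-variance trial pattern")
    return float(_stats.pearsonr(a, b)[0])


def bin_by_movement_correlation(
    pairs: pd.DataFrame,
    value_col: str,
    bins: np.ndarray = MOVEMENT_CORR_BINS,
) -> pd.Series:
    """Mean of ``value_col`` per movement-correlation bin.

    ``pairs`` must have a ``movement_r`` column. Pairs with movement_r below
    the first edge are excluded; bins are half-open [lo, hi) with the last
    bin closed. Empty bins are NaN.
    """
    r = pairs["movement_r"].to_numpy()
    v = pairs[value_col].to_numpy()
    out = {}
    for lo, hi in zip(bins[:-1], bins[1:]):
        last = hi == bins[-1]
        mask = (r >= lo) & ((r <= hi) if last else (r < hi))
        out[(float(lo), float(hi))] = float(np.mean(v[mask])) if mask.any() else np.nan
    return pd.Series(out, name=value_col)


def activated_count(
    events: dict[int, EventTrain] | list[EventTrain],
    responsive_set: set[int] | list[int],
    onset: float,
    window: tuple[float, float] = (-0.33, 0.67),
) -> int:
    """Number of responsive boutons with >= 1 event in the trial window.

    The window around the movement onset reuses the outcome-association
    window (330 ms before to 670 ms after onset).
    """
    if isinstance(events, list):
        events = dict(enumerate(events))
    lo, hi = onset + window[0], onset + window[1]
    return sum(
        1
        for b in responsive_set
        if b in events and np.any((events[b].times >= lo) & (events[b].times <= hi))
    )


def ensemble_difference(a: int, b: int) -> float:
    """Fraction of activated-ensemble difference: |a-b| / (0.5 (a+b)).

    Symmetric in (a, b), zero iff a == b, bounded by 2. Undefined when both
    counts are zero.
    """
    if a < 0 or b < 0:
        raise ValueError("counts must be nonnegative")
    if a + b == 0:
        raise ValueError("undefined ensemble difference: both counts zero")
    return abs(a - b) / (0.5 * (a + b))


def trial_pair_table(
    tensor: TrialTensor,
    movement_trajectories: np.ndarray,
    events: dict[int, EventTrain],
    responsive_set: set[int],
    onsets: np.ndarray,
) -> pd.DataFrame:
    """All-pairs table of movement_r, activity_pattern_r and ensemble_diff.

    ``movement_trajectories`` is trials x samples (aligned lever snippets).
    Pairs whose ensemble difference is undefined (no activated boutons in
    either trial) get NaN there and are logged via the ``n_undefined``
    attribute on the returned frame.
    """
    n_trials = tensor.activity.shape[1]
    counts = [
        activated_count(events, responsive_set, float(t)) for t in onsets
    ]
    rows = []
    n_undefined = 0
    for i in range(n_trials):
        for j in range(i + 1, n_trials):
            try:
                move_r = float(
                    _stats.pearsonr(
                        movement_trajectories[i], movement_trajectories[j]
                    )[0]
                )
                act_r = activity_pattern_correlation(tensor, i, j)
            except ValueError:
                continue
            try:
                diff = ensemble_difference(counts[i], counts[j])
            except ValueError:
                diff = np.nan
                n_undefined += 1
            rows.append((i, j, move_r, act_r, diff))
    df = pd.DataFrame(
        rows,
        columns=["trial_i", "trial_j", "movement_r", "activity_pattern_r",
                 "ensemble_diff"],
    )
    df.attrs["n_undefined"] = n_undefined
    return df
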