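"""Lever-movement behavior analysis.

Detects movement bouts from a continuously sampled lever-position trace,
labels each bout as a rewarded movement (RM: a push that crosses the
displacement threshold inside a cue-initiated task period) or an un-rewarded
movement (UM: a sub-threshold push inside the task period, or any push during
the inter-trial interval), applies the clean-baseline exclusion, and computes
session-level behavioral metrics and pairwise movement-trajectory
correlations.

Time convention: seconds throughout; bout intervals are half-open
``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as _stats

__all__ = [
    "LeverSession",
    "MovementBout",
    "detect_bouts",
    "label_bouts",
    "filter_clean_baseline",
    "rest_threshold_from_trace",
    "extract_trajectory",
    "movement_correlation",
    "behavior_metrics",
]


@dataclass
class LeverSession:
    """A single behavioral session of the cued lever-pushing task.

    Parameters
    ----------
    positions
        Lever displacement in mm, sampled at ``sample_rate`` Hz.
    sample_rate
        Sampling rate in Hz.
    cue_onsets
        Cue (tone) onset times in seconds, strictly increasing.
    task_period
        Length of the response window after each cue, in seconds.
    push_threshold
        Displacement (mm) a push must reach during the task period to be
        rewarded.
    """

    positions: np.ndarray
    sample_rate: float
    cue_onsets: np.ndarray
    task_period: float = 10.0
    push_threshold: float = 1.5

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.cue_onsets = np.asarray(self.cue_onsets, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("lever positions must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.cue_onsets.size and (
            np.any(np.diff(self.cue_onsets) <= 0)
            or self.cue_onsets[-1] >= self.duration
        ):
            raise ValueError(
                "cue_onsets must be strictly increasing and within the session"
            )

    @property
    def duration(self) -> float:
        """Session length in seconds."""
        return len(self.positions) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.positions)) / self.sample_rate

    def in_task_period(self, t: float) -> bool:
        """True if time ``t`` falls inside any cue-initiated task period."""
        if self.cue_onsets.size == 0:
            return False
        i = np.searchsorted(self.cue_onsets, t, side="right") - 1
        if i < 0:
            return False
        return t < self.cue_onsets[i] + self.task_period


@dataclass
class MovementBout:
    """One detected lever-movement bout."""

    onset: float
    offset: float
    peak: float = np.nan
    label: str | None = None  # "RM" | "UM" once labeled
    clean_baseline: bool = True
    trajectory: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError("bout onset must precede offset")


def rest_threshold_from_trace(
    positions: np.ndarray, rest_mask: np.ndarray | None = None, k: float = 2.0
) -> float:
    """Displacement threshold separating rest from movement.

    mean + ``k``·sd of the lever position during rest. When no explicit rest
    annotation is given the full trace is used, which is adequate for traces
    dominated by rest.
    """
    positions = np.asarray(positions, dtype=float)
    rest = positions if rest_mask is None else positions[np.asarray(rest_mask)]
    return float(np.mean(rest) + k * np.std(rest))


def detect_bouts(
    session: LeverSession,
    rest_threshold: float,
    merge_gap: float = 0.5,
) -> list[MovementBout]:
    """Detect movement bouts as excursions above ``rest_threshold``.

    Onsets/offsets are the threshold crossings; bouts separated by less than
    ``merge_gap`` seconds are considered continuous and combined. A trace that
    never crosses the threshold yields an empty list.
    """
    if rest_threshold <= 0:
        raise ValueError("rest_threshold must be positive")
    above = session.positions > rest_threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(above)]
    fs = session.sample_rate
    merged: list[list[float]] = []
    for s, e in zip(starts, ends):
        onset, offset = s / fs, e / fs
        if merged and onset - merged[-1][1] < merge_gap:
            merged[-1][1] = offset
        else:
            merged.append([onset, offset])
    bouts = []
    for onset, offset in merged:
        i0, i1 = int(round(onset * fs)), int(round(offset * fs))
        peak = float(np.max(session.positions[i0:i1]))
        bouts.append(MovementBout(onset=onset, offset=offset, peak=peak))
    return bouts


def label_bouts(
    bouts: list[MovementBout], session: LeverSession
) -> list[MovementBout]:
    """Assign RM/UM labels.

    A bout is RM iff its peak displacement reaches the session's push
    threshold *and* its onset falls inside a cue-initiated task period;
    every other bout (sub-threshold in the task period, or any push during
    the ITI) is UM.
    """
    labeled = []
    for b in bouts:
        is_rm = b.peak >= session.push_threshold and session.in_task_period(
            b.onset
        )
        labeled.append(replace(b, label="RM" if is_rm else "UM"))
    return labeled


def filter_clean_baseline(
    bouts: list[MovementBout], window: float = 3.0
) -> list[MovementBout]:
    """Clean-baseline exclusion.

    A bout is kept only if no other bout ends within the ``window`` seconds
    preceding its onset, so that the pre-movement baseline is movement-free.
    The full input list is returned with ``clean_baseline`` set; callers that
    want the subset can filter on the flag.
    """
    bouts = sorted(bouts, key=lambda b: b.onset)
    out = []
    for i, b in enumerate(bouts):
        clean = all(
            not (b.onset - window <= other.offset <= b.onset)
            for j, other in enumerate(bouts)
            if j != i
        )
        out.append(replace(b, clean_baseline=clean))
    return out


def extract_trajectory(
    session: LeverSession,
    bout: MovementBout,
    window: tuple[float, float] = (-0.5, 1.5),
    n_samples: int = 64,
) -> np.ndarray:
    """Lever trajectory around a bout onset, resampled to a fixed length.

    The window is relative to onset; samples outside the session are held at
    the nearest edge value.
    """
    t = bout.onset + np.linspace(window[0], window[1], n_samples)
    return np.interp(t, session.times, session.positions)


def movement_correlation(traj_i: np.ndarray, traj_j: np.ndarray) -> float:
    """Pearson correlation of two aligned movement trajectories."""
    traj_i = np.asarray(traj_i, dtype=float)
    traj_j = np.asarray(traj_j, dtype=float)
    if traj_i.shape != traj_j.shape:
        raise ValueError("trajectories must share the alignment window")
    if np.std(traj_i) == 0 or np.std(traj_j) == 0:
        raise ValueError("undefined correlation: zero-variance trajectory")
    return float(_stats.pearsonr(traj_i, traj_j)[0])


def behavior_metrics(
    session: LeverSession, bouts: list[MovementBout]
) -> dict[str, float]:
    """Session-level metrics: success rate, reaction time, ITI pushes.

    success_rate
        Fraction of cued trials with a rewarded push.
    reaction_time
        Median cue-to-threshold-crossing latency over rewarded trials (s).
    iti_push_count
        Number of UM bouts whose onset falls outside every task period.
    """
    if session.cue_onsets.size == 0:
        raise ValueError("undefined success rate: session has no cued trials")
    if any(b.label is None for b in bouts):
        raise ValueError("bouts must be labeled first")
    rm = [b for b in bouts if b.label == "RM"]
    rewarded_cues = 0
    latencies = []
    fs = session.sample_rate
    for cue in session.cue_onsets:
        trial_rms = [b for b in rm if cue <= b.onset < cue + session.task_period]
        if not trial_rms:
            continue
        rewarded_cues += 1
        b = min(trial_rms, key=lambda b: b.onset)
        i0 = int(round(b.onset * fs))
        i1 = int(round(b.offset * fs))
        seg = session.positions[i0:i1]
        cross = np.flatnonzero(seg >= session.push_threshold)
        t_cross = (i0 + cross[0]) / fs if cross.size else b.onset
        latencies.append(t_cross - cue)
    iti_pushes = sum(
        1
        for b in bouts
        if b.label == "UM" and not session.in_task_period(b.onset)
    )
    return {
        "success_rate": rewarded_cues / session.cue_onsets.size,
        "reaction_time": float(np.median(latencies)) if latencies else np.nan,
        "iti_push_count": float(iti_pushes),
    }
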