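"""Trial-aligned responses and RM/UM classification.

Bouton activity is aligned to movement onsets over a -1 s (baseline) to +3 s
window. A bouton is responsive to a trial type when, on the trial-averaged
trace, the peak (searched -0.2..+3 s relative to onset) minus the 5th
percentile of the averaged trace exceeds 90% of the reference standard
deviation. Axons use the same rule with a threshold derived from the
histograms of peak values (0.1-sd bins; threshold = mean of the RM and UM
mode-bin centers, capped at 1 sd). The two responsiveness booleans define
four classes: RM_only, UM_only, both, none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrialTensor",
    "ResponseClass",
    "align_trials",
    "peak_minus_p5",
    "classify_bouton",
    "axon_response_threshold",
    "classify_axon",
    "class_fractions",
    "class_transition_matrix",
    "CLASS_ORDER",
]

CLASS_ORDER = ("RM_only", "UM_only", "both", "none")


@dataclass
class TrialTensor:
    """Per-trial activity snippets aligned to movement onsets.

    ``activity`` is boutons x trials x time (dF/F); ``time`` is the axis in
    seconds relative to onset; ``labels`` holds the RM/UM label per trial.
    """

    activity: np.ndarray
    time: np.ndarray
    labels: np.ndarray
    dropped_trials: int = 0

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.activity.shape[2] != self.time.size:
            raise ValueError("time axis does not match activity")
        if self.activity.shape[1] != self.labels.size:
            raise ValueError("labels do not match trials")

    @property
    def n_boutons(self) -> int:
        return self.activity.shape[0]

    def subset(self, label: str) -> np.ndarray:
        """Activity of trials with the given label."""
        return self.activity[:, self.labels == label, :]

    def trial_average(self, label: str) -> np.ndarray:
        """Boutons x time average over trials with the given label."""
        sub = self.subset(label)
        if sub.shape[1] == 0:
            raise ValueError(f"no {label} trials")
        return sub.mean(axis=1)


@dataclass
class ResponseClass:
    """Classification result for one bouton or axon."""

    cls: str
    peak_rm: float = np.nan
    peak_um: float = np.nan
    threshold: float = np.nan
    insufficient_data: bool = False

    @property
    def rm_responsive(self) -> bool:
        """RM grouping used in summary figures: RM_only together with both."""
        return self.cls in ("RM_only", "both")

    @property
    def um_responsive(self) -> bool:
        return self.cls in ("UM_only", "both")


def align_trials(
    dff: np.ndarray,
    onsets: np.ndarray,
    labels: np.ndarray,
    frame_rate: float,
    window: tuple[float, float] = (-1.0, 3.0),
) -> TrialTensor:
    """Align dF/F to movement onsets on the native frame grid.

    Trials whose window extends past either segment edge are dropped and
    counted in ``dropped_trials``.
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    onsets = np.asarray(onsets, dtype=float)
    labels = np.asarray(labels)
    if onsets.size != labels.size:
        raise ValueError("one label per onset required")
    pre = int(round(-window[0] * frame_rate))
    post = int(round(window[1] * frame_rate))
    n_frames = dff.shape[1]
    snippets, kept = [], []
    for k, t in enumerate(onsets):
        i = int(round(t * frame_rate))
        if i - pre < 0 or i + post + 1 > n_frames:
            continue
        snippets.append(dff[:, i - pre : i + post + 1])
        kept.append(k)
    if not snippets:
        raise ValueError("no trials survive the alignment window")
    activity = np.stack(snippets, axis=1)
    time = np.arange(-pre, post + 1) / frame_rate
    return TrialTensor(
        activity=activity,
        time=time,
        labels=labels[kept],
        dropped_trials=onsets.size - len(kept),
    )


def peak_minus_p5(
    trial_avg: np.ndarray,
    time: np.ndarray,
    peak_window: tuple[float, float] = (-0.2, 3.0),
) -> float:
    """Peak (within the search window) minus the 5th percentile of the
    full averaged trace."""
    trial_avg = np.asarray(trial_avg, dtype=float)
    mask = (time >= peak_window[0]) & (time <= peak_window[1])
    return float(np.max(trial_avg[mask]) - np.percentile(trial_avg, 5))


def _classify(
    resp_rm: bool, resp_um: bool
) -> str:
    if resp_rm and resp_um:
        return "both"
    if resp_rm:
        return "RM_only"
    if resp_um:
        return "UM_only"
    return "none"


def classify_bouton(
    trial_avg_rm: np.ndarray,
    trial_avg_um: np.ndarray,
    time: np.ndarray,
    session_sd: float,
    sd_factor: float = 0.9,
    n_trials_rm: int | None = None,
    n_trials_um: int | None = None,
    min_trials: int = 5,
) -> ResponseClass:
    """Classify one bouton from its RM and UM trial averages.

    Responsive to a trial type iff peak - p5 strictly exceeds
    ``sd_factor`` x ``session_sd`` (the bouton's dF/F sd over the full
    imaged segment). With fewer than ``min_trials`` trials of either type
    the bouton is flagged and classed ``none``.
    """
    if session_sd <= 0:
        raise ValueError("session_sd must be positive")
    if (n_trials_rm is not None and n_trials_rm < min_trials) or (
        n_trials_um is not None and n_trials_um < min_trials
    ):
        return ResponseClass(cls="none", insufficient_data=True,
                             threshold=sd_factor * session_sd)
    thr = sd_factor * session_sd
    peak_rm = peak_minus_p5(trial_avg_rm, time)
    peak_um = peak_minus_p5(trial_avg_um, time)
    return ResponseClass(
        cls=_classify(peak_rm > thr, peak_um > thr),
        peak_rm=peak_rm,
        peak_um=peak_um,
        threshold=thr,
    )


def axon_response_threshold(
    peaks_rm: np.ndarray,
    peaks_um: np.ndarray,
    bin_width: float = 0.1,
    cap: float = 1.0,
) -> float:
    """Histogram-derived responsiveness threshold for axons, in sd units.

    Peak values (already normalized by the reference sd) are histogrammed
    with ``bin_width``-sd bins from 0; the threshold is the mean of the RM
    and UM mode-bin centers, capped at ``cap`` sd. Mode ties break toward
    the lower bin.
    """
    peaks_rm = np.asarray(peaks_rm, dtype=float)
    peaks_um = np.asarray(peaks_um, dtype=float)
    if peaks_rm.size == 0 or peaks_um.size == 0:
        raise ValueError("need at least one peak value per distribution")

    def mode_center(vals: np.ndarray) -> float:
        hi = max(vals.max(), bin_width)
        edges = np.arange(0, hi + bin_width, bin_width)
        counts, edges = np.histogram(vals, bins=edges)
        i = int(np.argmax(counts))  # argmax takes the first (lower) tie
        return (edges[i] + edges[i + 1]) / 2

    thr = (mode_center(peaks_rm) + mode_center(peaks_um)) / 2
    return float(min(thr, cap))


def classify_axon(
    trial_avg_rm: np.ndarray,
    trial_avg_um: np.ndarray,
    time: np.ndarray,
    session_sd: float,
    threshold_sd: float,
) -> ResponseClass:
    """Classify one axon with the histogram-derived threshold (in sd)."""
    if session_sd <= 0:
        raise ValueError("session_sd must be positive")
    thr = threshold_sd * session_sd
    peak_rm = peak_minus_p5(trial_avg_rm, time)
    peak_um = peak_minus_p5(trial_avg_um, time)
    return ResponseClass(
        cls=_classify(peak_rm > thr, peak_um > thr),
        peak_rm=peak_rm,
        peak_um=peak_um,
        threshold=thr,
    )


def class_fractions(classes: list[ResponseClass] | list[str]) -> pd.Series:
    """Fractions of RM_only/UM_only/both/none over classified units."""
    names = [c.cls if isinstance(c, ResponseClass) else c for c in classes]
    if not names:
        raise ValueError("no classified units")
    counts = pd.Series(names).value_counts().reindex(CLASS_ORDER, fill_value=0)
    return counts / counts.sum()


def class_transition_matrix(
    early: list[ResponseClass] | list[str],
    late: list[ResponseClass] | list[str],
) -> pd.DataFrame:
    """Row-stochastic 4x4 matrix of class transitions (early -> late).

    Requires the same boutons in the same order at both stages. Rows with no
    early members are NaN.
    """
    e = [c.cls if isinstance(c, ResponseClass) else c for c in early]
    l = [c.cls if isinstance(c, ResponseClass) else c for c in late]
    if len(e) != len(l):
        raise ValueError("early and late stages must track the same boutons")
    mat = pd.DataFrame(
        0.0, index=list(CLASS_ORDER), columns=list(CLASS_ORDER)
    )
    for a, b in zip(e, l):
        mat.loc[a, b] += 1
    sums = mat.sum(axis=1)
    return mat.div(sums.where(sums > 0), axis=0)
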