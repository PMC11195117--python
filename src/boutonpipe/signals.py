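"""Fluorescence trace processing and Ca2+ event detection.

dF/F uses a sliding-percentile baseline: F0 at each frame is the 30th
percentile of raw fluorescence inside a 30-s window centered on the frame
(the window shrinks at segment edges), and dF/F = (F - F0) / F0. Events are
local maxima of dF/F that satisfy BOTH detection criteria: z-scored dF/F
above 1 sd and raw dF/F above an 8% change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import find_peaks

__all__ = [
    "FluorescenceSet",
    "EventTrain",
    "compute_dff",
    "zscore_trace",
    "detect_events",
]


@dataclass
class FluorescenceSet:
    """Raw fluorescence for one continuously imaged segment.

    ``raw`` is boutons x frames in arbitrary units (strictly positive);
    ``axon_of`` maps each bouton index to its parent axon id.
    """

    raw: np.ndarray
    frame_rate: float
    axon_of: np.ndarray
    bouton_ids: np.ndarray | None = None
    day: int = 0

    def __post_init__(self) -> None:
        self.raw = np.atleast_2d(np.asarray(self.raw, dtype=float))
        self.axon_of = np.asarray(self.axon_of)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.axon_of.shape[0] != self.raw.shape[0]:
            raise ValueError("axon_of must have one entry per bouton")
        if self.bouton_ids is None:
            self.bouton_ids = np.arange(self.raw.shape[0])

    @property
    def n_boutons(self) -> int:
        return self.raw.shape[0]

    @property
    def n_frames(self) -> int:
        return self.raw.shape[1]


@dataclass
class EventTrain:
    """Detected Ca2+ peaks for one bouton: times (s), dF/F amplitudes, z."""

    times: np.ndarray
    amplitudes: np.ndarray = field(default_factory=lambda: np.array([]))
    z: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def _sliding_percentile(
    trace: np.ndarray, window_frames: int, percentile: float
) -> np.ndarray:
    """Centered sliding percentile with truncated (shrinking) edge windows."""
    n = trace.size
    half = window_frames // 2
    out = np.empty(n)
    if n >= window_frames:
        # interior: full windows, vectorized; the linear-interpolation
        # percentile needs only two order statistics, so partition instead
        # of a full per-window sort
        windows = sliding_window_view(trace, window_frames)
        q = percentile / 100 * (window_frames - 1)
        k0 = int(np.floor(q))
        frac = q - k0
        k1 = min(k0 + 1, window_frames - 1)
        part = np.partition(windows, (k0, k1), axis=1)
        full = part[:, k0] * (1 - frac) + part[:, k1] * frac
        # frame t uses window [t-half, t-half+window_frames)
        lo, hi = half, half + windows.shape[0]
        out[lo:hi] = full
        edge_idx = list(range(lo)) + list(range(hi, n))
    else:
        edge_idx = list(range(n))
    for t in edge_idx:
        a, b = max(0, t - half), min(n, t - half + window_frames)
        out[t] = np.percentile(trace[a:b], percentile)
    return out


def compute_dff(
    raw_trace: np.ndarray,
    frame_rate: float,
    window: float = 30.0,
    percentile: float = 30.0,
) -> np.ndarray:
    """dF/F with a sliding-percentile baseline.

    F0 at each frame is the ``percentile``-th percentile (linear
    interpolation between order statistics) of the raw trace within a
    ``window``-second window centered on the frame; the window truncates at
    segment edges. dF/F = (F - F0) / F0, exactly invariant under positive
    rescaling of the raw fluorescence.
    """
    raw_trace = np.asarray(raw_trace, dtype=float)
    if raw_trace.ndim == 2:
        return np.vstack(
            [compute_dff(r, frame_rate, window, percentile) for r in raw_trace]
        )
    window_frames = int(round(window * frame_rate))
    if window_frames < 2:
        raise ValueError("baseline window must span at least 2 frames")
    f0 = _sliding_percentile(raw_trace, window_frames, percentile)
    if np.any(f0 <= 0):
        raise ValueError("degenerate baseline: nonpositive F0")
    return (raw_trace - f0) / f0


def zscore_trace(dff_trace: np.ndarray) -> np.ndarray:
    """z-score over the whole imaged segment: (x - mean) / sd."""
    dff_trace = np.asarray(dff_trace, dtype=float)
    sd = np.std(dff_trace, axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot z-score a zero-variance trace")
    return (dff_trace - np.mean(dff_trace, axis=-1, keepdims=True)) / sd


def detect_events(
    dff_trace: np.ndarray,
    z_trace: np.ndarray,
    frame_rate: float,
    z_thresh: float = 1.0,
    raw_thresh: float = 0.08,
    min_separation_frames: int = 3,
) -> EventTrain:
    """Dual-criterion Ca2+ event detection.

    Local maxima of the dF/F trace (minimum peak separation
    ``min_separation_frames``) are kept as events only when the peak's
    z-scored value exceeds ``z_thresh`` AND its raw dF/F value exceeds
    ``raw_thresh``. Event time = peak frame / frame rate.
    """
    dff_trace = np.asarray(dff_trace, dtype=float)
    z_trace = np.asarray(z_trace, dtype=float)
    if dff_trace.shape != z_trace.shape:
        raise ValueError("dff and z traces must have the same length")
    peaks, _ = find_peaks(dff_trace, distance=min_separation_frames)
    keep = (z_trace[peaks] > z_thresh) & (dff_trace[peaks] > raw_thresh)
    peaks = peaks[keep]
    return EventTrain(
        times=peaks / frame_rate,
        amplitudes=dff_trace[peaks],
        z=z_trace[peaks],
    )
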