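"""Synthetic sessions with full ground truth.

Generates the three kinds of raw material the pipeline consumes, with a known
generative record for every emitted feature, so each downstream stage can be
validated without real data:

- behavior: a lever-position trace for the cued pushing task, with cued
  rewarded pushes, sub-threshold failed pushes and un-cued ITI pushes;
- fluorescence: GCaMP6s-like bouton traces in which each axon carries a
  shared event train, individual boutons realize shared events with
  probability ``p_shared`` and add bouton-unique events, and outcome-tuned
  boutons respond at RM/UM onsets;
- structure: per-axon bouton inventories over imaging days with programmed
  formation and elimination rates and optional spatial clustering of newly
  formed boutons.

A single global seed is expanded into independent substreams (behavior,
fluorescence, structure) so stages can be regenerated independently;
identical (config, seed) gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .behavior import LeverSession
from .signals import FluorescenceSet
from .structure import BoutonTrack

__all__ = [
    "BehaviorSpec",
    "StructureSpec",
    "SimConfig",
    "GroundTruth",
    "transient_kernel",
    "simulate_behavior",
    "simulate_fluorescence",
    "simulate_structure",
]

_STREAMS = {"behavior": 1, "fluorescence": 2, "structure": 3}

CLASSES = ("RM_only", "UM_only", "both", "none")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


@dataclass
class BehaviorSpec:
    """Parameters of the cued lever-pushing task simulation."""

    task_period: float = 10.0  # s, response window after the cue
    iti: float = 4.0  # s, inter-trial interval
    p_success: float = 0.7  # probability a cued trial is rewarded
    p_fail_push: float = 0.5  # failed trial still has a sub-threshold push
    p_iti_push: float = 0.3  # probability of an un-cued push per ITI
    push_threshold_mm: float = 1.5
    push_duration: float = 0.6  # s, half-sine push width
    latency_range: tuple[float, float] = (0.3, 1.5)  # s after cue
    rewarded_amp_mm: tuple[float, float] = (1.8, 2.6)
    failed_amp_mm: tuple[float, float] = (0.5, 1.2)
    lever_noise_mm: float = 0.02


@dataclass
class StructureSpec:
    """Parameters of the structural (bouton turnover) simulation."""

    days: tuple[int, ...] = (0, 2, 4, 6, 8, 10)
    axon_length_um: float = 100.0
    boutons_per_10um: float = 1.0  # baseline density
    formation_rate: float = 0.08  # per inter-session interval
    elimination_rate: float = 0.06  # per inter-session interval
    cluster_scale_um: float | None = None  # None = uniform placement


@dataclass
class SimConfig:
    """Study conditions for the synthetic sessions.

    Defaults follow the task and imaging parameters of the experiments the
    pipeline targets (15 Hz frame rate, 4000-frame segments, 1.5 mm push
    threshold, 10 s task period, GCaMP6s-like ~0.2 s rise / ~1 s decay);
    quantities the experiments do not pin down (noise level, event rates,
    transient amplitudes) use values chosen to look like realistic striatal
    axonal-bouton imaging and are free parameters.
    """

    n_axons: int = 10
    boutons_per_axon: int = 5
    frame_rate: float = 15.0
    n_frames: int = 4000
    n_segments: int = 1
    transient_rise: float = 0.2  # s
    transient_decay: float = 1.0  # s
    noise_sd: float = 0.05  # dF/F units
    p_shared: float = 0.9  # axon event realized in a given bouton
    shared_event_rate: float = 0.05  # Hz, axon-level spontaneous events
    unique_event_rate: float = 0.02  # Hz per bouton, local additions
    frac_rm_only: float = 0.3
    frac_um_only: float = 0.2
    frac_both: float = 0.2
    response_gain: float = 1.0  # dF/F peak for the preferred outcome
    min_event_spacing: float = 1.0  # s, refractory gap within a train
    spont_amp: tuple[float, float] = (0.5, 1.0)  # dF/F spontaneous peaks
    baseline_range: tuple[float, float] = (100.0, 200.0)  # raw a.u.
    behavior: BehaviorSpec = field(default_factory=BehaviorSpec)
    structure: StructureSpec = field(default_factory=StructureSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.n_frames <= 0 or self.n_axons <= 0:
            raise ValueError("counts and rates must be positive")
        fracs = (self.frac_rm_only, self.frac_um_only, self.frac_both)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1 + 1e-12:
            raise ValueError("class fractions must be in [0,1] and sum <= 1")
        for p in (self.p_shared, self.behavior.p_success,
                  self.behavior.p_iti_push, self.behavior.p_fail_push,
                  self.structure.formation_rate,
                  self.structure.elimination_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.shared_event_rate < 0 or self.unique_event_rate < 0:
            raise ValueError("event rates must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return self.n_frames / self.frame_rate

    @property
    def n_boutons(self) -> int:
        return self.n_axons * self.boutons_per_axon

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Generative record of a synthetic session.

    ``bouts``: (onset, offset, label, peak_mm) for every simulated push.
    ``bouton_classes``: (bouton_id, axon_id, cls) programmed tuning.
    ``events``: one row per emitted transient (bouton_id, time_s — the
    observable kernel-peak time, origin in {shared, unique, response},
    amplitude, axon_event_id for shared events).
    ``structural_events``: (bouton_id, axon_id, day, kind) log of every
    formation/elimination.
    """

    bouts: pd.DataFrame | None = None
    bouton_classes: pd.DataFrame | None = None
    events: pd.DataFrame | None = None
    structural_events: pd.DataFrame | None = None


def transient_kernel(
    frame_rate: float, rise: float = 0.2, decay: float = 1.0
) -> np.ndarray:
    """Difference-of-exponentials Ca2+ transient kernel, unit peak.

    k(t) = exp(-t/decay) - exp(-t/rise), truncated at 8 decay constants.
    """
    if not 0 < rise < decay:
        raise ValueError("require 0 < rise < decay")
    t = np.arange(0, 8 * decay, 1 / frame_rate)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    return k / k.max()


def kernel_peak_offset(frame_rate: float, rise: float, decay: float) -> int:
    """Frame offset of the kernel maximum relative to the impulse frame."""
    return int(np.argmax(transient_kernel(frame_rate, rise, decay)))


# ---------------------------------------------------------------------------
# behavior


def _half_sine(amp: float, duration: float, fs: float) -> np.ndarray:
    n = max(2, int(round(duration * fs)))
    return amp * np.sin(np.pi * np.arange(n) / (n - 1))


def simulate_behavior(
    config: SimConfig, seed: int | None = None
) -> tuple[LeverSession, pd.DataFrame]:
    """Simulate one behavioral session.

    Returns the lever session and a ground-truth bout table (onset, offset,
    label, peak_mm). Pushes are half-sine displacement bumps; rewarded pushes
    cross the threshold within the task period, failed pushes stay below it,
    and ITI pushes occur between trials. Successive pushes are separated by
    more than 0.5 s by construction.
    """
    if seed is None:
        seed = config.seed
    rng = _rng(seed, "behavior")
    spec = config.behavior
    fs = config.frame_rate
    duration = config.duration * config.n_segments
    n = int(round(duration * fs))
    positions = (
        rng.normal(0, spec.lever_noise_mm, n) if spec.lever_noise_mm > 0
        else np.zeros(n)
    )
    trial_len = spec.task_period + spec.iti
    cues = np.arange(2.0, duration - trial_len, trial_len)
    rows = []

    def add_push(onset: float, amp: float) -> tuple[float, float]:
        # the emitted push is quantized to the sample grid; ground truth
        # records the realized onset/offset, not the continuous draw
        bump = _half_sine(amp, spec.push_duration, fs)
        i0 = int(round(onset * fs))
        i1 = min(i0 + bump.size, n)
        positions[i0:i1] += bump[: i1 - i0]
        return i0 / fs, i1 / fs

    for cue in cues:
        u = rng.random()
        if u < spec.p_success:
            amp = rng.uniform(*spec.rewarded_amp_mm)
            onset, offset = add_push(
                cue + rng.uniform(*spec.latency_range), amp
            )
            rows.append((onset, offset, "RM", amp))
        elif rng.random() < spec.p_fail_push:
            amp = rng.uniform(*spec.failed_amp_mm)
            onset, offset = add_push(
                cue + rng.uniform(*spec.latency_range), amp
            )
            rows.append((onset, offset, "UM", amp))
        if rng.random() < spec.p_iti_push:
            lo = cue + spec.task_period + 0.5
            hi = cue + trial_len - spec.push_duration - 0.2
            if hi > lo:
                amp = rng.uniform(*spec.rewarded_amp_mm)
                onset, offset = add_push(rng.uniform(lo, hi), amp)
                rows.append((onset, offset, "UM", amp))
    bouts = pd.DataFrame(
        rows, columns=["onset", "offset", "label", "peak_mm"]
    ).sort_values("onset", ignore_index=True)
    session = LeverSession(
        positions=positions,
        sample_rate=fs,
        cue_onsets=cues,
        task_period=spec.task_period,
        push_threshold=spec.push_threshold_mm,
    )
    return session, bouts


# ---------------------------------------------------------------------------
# fluorescence


def _gap_train(
    rng: np.random.Generator, rate: float, duration: float, min_gap: float
) -> np.ndarray:
    """Event times with exponential gaps plus a refractory minimum gap."""
    if rate <= 0:
        return np.array([])
    times = []
    t = rng.exponential(1 / rate)
    while t < duration:
        times.append(t)
        t += min_gap + rng.exponential(1 / rate)
    return np.asarray(times)


def assign_classes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Programmed outcome tuning per bouton."""
    probs = [
        config.frac_rm_only,
        config.frac_um_only,
        config.frac_both,
        1 - config.frac_rm_only - config.frac_um_only - config.frac_both,
    ]
    cls = rng.choice(CLASSES, size=config.n_boutons, p=probs)
    return pd.DataFrame(
        {
            "bouton_id": np.arange(config.n_boutons),
            "axon_id": np.repeat(
                np.arange(config.n_axons), config.boutons_per_axon
            ),
            "cls": cls,
        }
    )


def simulate_fluorescence(
    config: SimConfig,
    behavior: LeverSession,
    truth_bouts: pd.DataFrame,
    seed: int | None = None,
) -> tuple[FluorescenceSet, GroundTruth]:
    """Simulate bouton fluorescence given a behavioral session.

    Each axon carries a shared spontaneous event train; each bouton realizes
    a shared event with probability ``p_shared`` and adds unique events at
    ``unique_event_rate``. Boutons tuned to RM (UM, both) additionally emit a
    transient of amplitude ``response_gain`` shortly after each RM (UM)
    onset. Transients are impulse trains convolved with the
    difference-of-exponentials kernel; raw fluorescence is a per-bouton
    positive baseline times (1 + signal + Gaussian noise).
    """
    if seed is None:
        seed = config.seed
    rng = _rng(seed, "fluorescence")
    fs = config.frame_rate
    n_frames = config.n_frames * config.n_segments
    duration = n_frames / fs
    if abs(behavior.duration - duration) > 1.5 / fs:
        raise ValueError(
            "behavior and fluorescence configs disagree on duration"
        )
    kernel = transient_kernel(fs, config.transient_rise, config.transient_decay)
    peak_off = int(np.argmax(kernel))

    classes = assign_classes(config, rng)
    # axon-level shared trains, amplitudes common to all realizing boutons
    shared_times = []
    shared_amps = []
    for _ in range(config.n_axons):
        t = _gap_train(
            rng, config.shared_event_rate, duration, config.min_event_spacing
        )
        shared_times.append(t)
        shared_amps.append(rng.uniform(*config.spont_amp, size=t.size))

    raw = np.empty((config.n_boutons, n_frames))
    event_rows = []
    rm_onsets = truth_bouts.loc[truth_bouts.label == "RM", "onset"].to_numpy()
    um_onsets = truth_bouts.loc[truth_bouts.label == "UM", "onset"].to_numpy()

    for b in range(config.n_boutons):
        axon = b // config.boutons_per_axon
        cls = classes.loc[b, "cls"]
        impulses: list[tuple[float, float, str, float]] = []
        st, sa = shared_times[axon], shared_amps[axon]
        keep = rng.random(st.size) < config.p_shared
        for k in np.flatnonzero(keep):
            impulses.append((st[k], sa[k], "shared", k))
        for t in _gap_train(
            rng, config.unique_event_rate, duration, config.min_event_spacing
        ):
            impulses.append((t, rng.uniform(*config.spont_amp), "unique", -1))
        pref = {"RM_only": rm_onsets, "UM_only": um_onsets,
                "both": np.concatenate([rm_onsets, um_onsets])}.get(cls)
        if pref is not None:
            for onset in pref:
                impulses.append(
                    (onset + rng.uniform(0.05, 0.2), config.response_gain,
                     "response", -1)
                )
        # refractory spacing across the bouton's combined impulse train:
        # impulses closer than min_event_spacing to an earlier kept impulse
        # are dropped (and not recorded), so every ground-truth event is a
        # separable transient
        impulses.sort(key=lambda e: e[0])
        kept, last_t = [], -np.inf
        for imp in impulses:
            if imp[0] - last_t >= config.min_event_spacing:
                kept.append(imp)
                last_t = imp[0]
        signal = np.zeros(n_frames)
        for t, amp, origin, axon_event in kept:
            i = int(round(t * fs))
            if i >= n_frames:
                continue
            j = min(i + kernel.size, n_frames)
            signal[i:j] += amp * kernel[: j - i]
            event_rows.append(
                (b, axon, (i + peak_off) / fs, origin, amp, axon_event)
            )
        noise = (
            rng.normal(0, config.noise_sd, n_frames)
            if config.noise_sd > 0 else 0.0
        )
        f0 = rng.uniform(*config.baseline_range)
        raw[b] = np.maximum(f0 * (1 + signal + noise), 1e-6)

    events = pd.DataFrame(
        event_rows,
        columns=["bouton_id", "axon_id", "time_s", "origin", "amplitude",
                 "axon_event_id"],
    ).sort_values(["bouton_id", "time_s"], ignore_index=True)
    fset = FluorescenceSet(
        raw=raw,
        frame_rate=fs,
        axon_of=classes["axon_id"].to_numpy(),
        bouton_ids=classes["bouton_id"].to_numpy(),
    )
    truth = GroundTruth(
        bouts=truth_bouts, bouton_classes=classes, events=events
    )
    return fset, truth


# ---------------------------------------------------------------------------
# structure


def simulate_structure(
    config: SimConfig,
    seed: int | None = None,
    formation_rate_per_axon: np.ndarray | None = None,
    elimination_rate_per_axon: np.ndarray | None = None,
    group: str = "training",
) -> tuple[BoutonTrack, GroundTruth]:
    """Simulate longitudinal bouton inventories.

    Starting from a baseline density, each inter-session interval eliminates
    present boutons independently with ``elimination_rate`` and forms
    Binomial(n_present, ``formation_rate``) new ones. New-bouton positions
    are uniform along the axon, or, when ``cluster_scale_um`` is set, drawn
    as Gaussian displacements from a randomly chosen existing or co-formed
    bouton. Per-axon rate overrides allow coupling structural dynamics to
    functional class.
    """
    if seed is None:
        seed = config.seed
    rng = _rng(seed, "structure")
    spec = config.structure
    if len(spec.days) < 2:
        raise ValueError("at least two imaging sessions are required")
    if spec.axon_length_um <= 0:
        raise ValueError("axon length must be positive")
    form = (
        np.full(config.n_axons, spec.formation_rate)
        if formation_rate_per_axon is None
        else np.asarray(formation_rate_per_axon, dtype=float)
    )
    elim = (
        np.full(config.n_axons, spec.elimination_rate)
        if elimination_rate_per_axon is None
        else np.asarray(elimination_rate_per_axon, dtype=float)
    )
    L = spec.axon_length_um
    n0 = max(1, int(round(L * spec.boutons_per_10um / 10)))
    days = list(spec.days)

    bouton_axon: list[int] = []
    bouton_pos: list[float] = []
    presence_rows: list[dict[int, bool]] = []
    log = []

    # state per axon: dict bouton_index -> currently present
    current: dict[int, list[int]] = {a: [] for a in range(config.n_axons)}
    for a in range(config.n_axons):
        for _ in range(n0):
            bid = len(bouton_axon)
            bouton_axon.append(a)
            bouton_pos.append(float(rng.uniform(0, L)))
            presence_rows.append({days[0]: True})
            current[a].append(bid)

    for d0, d1 in zip(days[:-1], days[1:]):
        for a in range(config.n_axons):
            present = list(current[a])
            survivors = []
            for bid in present:
                if rng.random() < elim[a]:
                    presence_rows[bid][d1] = False
                    log.append((bid, a, d1, "eliminated"))
                else:
                    presence_rows[bid][d1] = True
                    survivors.append(bid)
            n_new = rng.binomial(len(present), form[a]) if present else 0
            anchors = [bouton_pos[b] for b in present]
            new_ids = []
            for _ in range(n_new):
                if spec.cluster_scale_um is not None and anchors:
                    anchor = anchors[rng.integers(len(anchors))]
                    pos = float(
                        np.clip(
                            anchor + rng.normal(0, spec.cluster_scale_um),
                            0, L,
                        )
                    )
                else:
                    pos = float(rng.uniform(0, L))
                bid = len(bouton_axon)
                bouton_axon.append(a)
                bouton_pos.append(pos)
                anchors.append(pos)  # co-formed boutons can seed clusters
                presence_rows.append({d: False for d in days if d <= d0})
                presence_rows[bid][d1] = True
                log.append((bid, a, d1, "formed"))
                new_ids.append(bid)
            current[a] = survivors + new_ids

    n_total = len(bouton_axon)
    presence = pd.DataFrame(
        [[presence_rows[b].get(d, False) for d in days] for b in range(n_total)],
        columns=days,
        index=pd.Index(np.arange(n_total), name="bouton_id"),
    )
    boutons = pd.DataFrame(
        {
            "bouton_id": np.arange(n_total),
            "axon_id": bouton_axon,
            "position_um": bouton_pos,
        }
    )
    track = BoutonTrack(
        boutons=boutons,
        presence=presence,
        axon_length_um=pd.Series(
            L, index=pd.Index(np.arange(config.n_axons), name="axon_id"),
            dtype=float,
        ),
        group=group,
    )
    truth = GroundTruth(
        structural_events=pd.DataFrame(
            log, columns=["bouton_id", "axon_id", "day", "kind"]
        )
    )
    return track, truth
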