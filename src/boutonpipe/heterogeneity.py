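"""Same-axon bouton activity heterogeneity.

Ca2+ peaks of two boutons on the same axon are matched one-to-one when they
occur within 670 ms of each other ("same peaks"); unmatched peaks are
"unique peaks". Peaks falling 330 ms before to 670 ms after an RM or UM
onset are outcome-related. The same-peak fraction per bouton pair is
averaged bouton -> axon -> mouse. Axon heterogeneity is the minority
fraction of RM- vs UM-selective boutons along one axon (0 = uniform,
0.5 = maximally mixed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signals import EventTrain

__all__ = [
    "PeakMatchResult",
    "match_peaks",
    "same_peak_fraction",
    "aggregate_same_fraction",
    "label_peak_outcome",
    "outcome_peak_fractions",
    "axon_heterogeneity",
    "MATCH_TOL",
    "OUTCOME_WINDOW",
]

MATCH_TOL = 0.670  # s, two peaks within this window are the same peak
OUTCOME_WINDOW = (-0.33, 0.67)  # s around a movement onset


@dataclass
class PeakMatchResult:
    """One-to-one matching of two boutons' event trains."""

    matched: list[tuple[float, float]]
    unique_i: np.ndarray
    unique_j: np.ndarray
    n_i: int
    n_j: int

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def match_peaks(
    train_i: EventTrain | np.ndarray,
    train_j: EventTrain | np.ndarray,
    tol: float = MATCH_TOL,
) -> PeakMatchResult:
    """Greedy one-to-one peak matching.

    Events are visited in global time order; each unmatched event is paired
    with its nearest unmatched partner in the other train, provided
    |t_i - t_j| <= tol. On trains whose within-train spacing exceeds 2 tol
    this equals maximum-cardinality bipartite matching.
    """
    t_i = np.asarray(
        train_i.times if isinstance(train_i, EventTrain) else train_i,
        dtype=float,
    )
    t_j = np.asarray(
        train_j.times if isinstance(train_j, EventTrain) else train_j,
        dtype=float,
    )
    used_i = np.zeros(t_i.size, dtype=bool)
    used_j = np.zeros(t_j.size, dtype=bool)
    events = sorted(
        [(t, 0, k) for k, t in enumerate(t_i)]
        + [(t, 1, k) for k, t in enumerate(t_j)]
    )
    matched: list[tuple[float, float]] = []
    for t, side, k in events:
        used_self, used_other, t_other = (
            (used_i, used_j, t_j) if side == 0 else (used_j, used_i, t_i)
        )
        if used_self[k]:
            continue
        cand = np.flatnonzero(~used_other & (np.abs(t_other - t) <= tol))
        if cand.size == 0:
            continue
        partner = cand[np.argmin(np.abs(t_other[cand] - t))]
        used_self[k] = True
        used_other[partner] = True
        pair = (t, t_other[partner]) if side == 0 else (t_other[partner], t)
        matched.append(pair)
    return PeakMatchResult(
        matched=matched,
        unique_i=t_i[~used_i],
        unique_j=t_j[~used_j],
        n_i=t_i.size,
        n_j=t_j.size,
    )


def same_peak_fraction(
    match: PeakMatchResult, convention: str = "per_bouton"
) -> float:
    """Fraction of same peaks for one bouton pair.

    With the default ``per_bouton`` convention a matched pair counts once in
    each bouton's tally: 2 |matched| / (n_i + n_j). The alternative ``max``
    convention reads the ratio as |matched| / max(n_i, n_j). Undefined when
    both trains are empty.
    """
    total = match.n_i + match.n_j
    if total == 0:
        raise ValueError("undefined same-peak fraction: both trains empty")
    if convention == "per_bouton":
        return 2 * match.n_matched / total
    if convention == "max":
        return match.n_matched / max(match.n_i, match.n_j)
    raise ValueError(f"unknown convention: {convention!r}")


def aggregate_same_fraction(
    pair_fractions: pd.DataFrame,
) -> float:
    """Hierarchical mouse-level mean of per-pair same-peak fractions.

    ``pair_fractions`` has columns (axon_id, bouton_i, bouton_j, fraction).
    Per-bouton mean over its pairs, then per-axon mean over boutons, then
    mean over axons. Axons contributing fewer than one pair are absent from
    the table and hence excluded.
    """
    if pair_fractions.empty:
        raise ValueError("no same-axon bouton pairs")
    axon_means = []
    for _, grp in pair_fractions.groupby("axon_id"):
        per_bouton: dict[int, list[float]] = {}
        for _, row in grp.iterrows():
            per_bouton.setdefault(row["bouton_i"], []).append(row["fraction"])
            per_bouton.setdefault(row["bouton_j"], []).append(row["fraction"])
        axon_means.append(
            float(np.mean([np.mean(v) for v in per_bouton.values()]))
        )
    return float(np.mean(axon_means))


def label_peak_outcome(
    peak_time: float,
    bout_onsets: np.ndarray,
    bout_labels: np.ndarray,
    window: tuple[float, float] = OUTCOME_WINDOW,
) -> str:
    """Outcome association of one peak: 'RM', 'UM' or 'none'.

    The peak is outcome-related when it falls within [onset + window[0],
    onset + window[1]] of any labeled movement onset; overlapping RM and UM
    windows resolve to the nearest onset.
    """
    bout_onsets = np.asarray(bout_onsets, dtype=float)
    bout_labels = np.asarray(bout_labels)
    rel = peak_time - bout_onsets
    hit = (rel >= window[0]) & (rel <= window[1])
    if not hit.any():
        return "none"
    nearest = np.flatnonzero(hit)[np.argmin(np.abs(rel[hit]))]
    return str(bout_labels[nearest])


def outcome_peak_fractions(
    matches: list[PeakMatchResult],
    bout_onsets: np.ndarray,
    bout_labels: np.ndarray,
    window: tuple[float, float] = OUTCOME_WINDOW,
) -> pd.Series:
    """Same- vs unique-peak fractions among outcome-related peaks.

    Pools peaks over all same-axon bouton pairs. For each outcome (RM, UM)
    the same and unique fractions sum to 1; outcomes with zero related peaks
    are reported NaN.
    """
    counts = {("RM", "same"): 0, ("RM", "unique"): 0,
              ("UM", "same"): 0, ("UM", "unique"): 0}
    for m in matches:
        for t_i, t_j in m.matched:
            lab = label_peak_outcome((t_i + t_j) / 2, bout_onsets,
                                     bout_labels, window)
            if lab != "none":
                counts[(lab, "same")] += 1
        for t in np.concatenate([m.unique_i, m.unique_j]):
            lab = label_peak_outcome(float(t), bout_onsets, bout_labels,
                                     window)
            if lab != "none":
                counts[(lab, "unique")] += 1
    out = {}
    for outcome in ("RM", "UM"):
        tot = counts[(outcome, "same")] + counts[(outcome, "unique")]
        for kind in ("same", "unique"):
            out[f"{outcome}_{kind}"] = (
                counts[(outcome, kind)] / tot if tot else np.nan
            )
    return pd.Series(out)


def axon_heterogeneity(bouton_classes: list[str]) -> float:
    """Minority fraction of RM- vs UM-selective boutons on one axon.

    Only RM_only and UM_only boutons count ("both" and "none" are excluded);
    requires at least two selective boutons. 0 means a uniform axon, 0.5 a
    maximally mixed one.
    """
    n_rm = sum(1 for c in bouton_classes if c == "RM_only")
    n_um = sum(1 for c in bouton_classes if c == "UM_only")
    if n_rm + n_um < 2:
        raise ValueError("need at least two RM/UM-selective boutons")
    return min(n_rm, n_um) / (n_rm + n_um)
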