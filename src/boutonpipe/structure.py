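"""Longitudinal structural analysis of axonal boutons.

Boutons are identified along axons and tracked across imaging sessions held
every other day. Between two adjacent sessions a bouton is persistent
(present -> present), eliminated (present -> absent), formed
(absent -> present), or absent. Derived quantities: per-axon density time
courses, formation/elimination percentages, survival of newly formed boutons,
pairwise distances among co-formed boutons, day-to-day density correlation,
and joins of structural rates with functional (RM/UM) axon classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "BoutonTrack",
    "annotate_dynamics",
    "density_timecourse",
    "turnover_rates",
    "survival_curve",
    "new_bouton_pair_distances",
    "ecdf",
    "density_day_correlation",
    "function_structure_join",
]

STATES = ("persistent", "formed", "eliminated", "absent")


@dataclass
class BoutonTrack:
    """Per-axon longitudinal inventory of boutons.

    ``boutons``: DataFrame with columns (bouton_id, axon_id, position_um).
    ``presence``: boolean DataFrame indexed by bouton_id with one column per
    imaged day.
    ``axon_length_um``: Series indexed by axon_id.
    """

    boutons: pd.DataFrame
    presence: pd.DataFrame
    axon_length_um: pd.Series
    group: str = "training"

    def __post_init__(self) -> None:
        self.boutons = self.boutons.set_index("bouton_id", drop=False) \
            if self.boutons.index.name != "bouton_id" else self.boutons
        if (self.axon_length_um <= 0).any():
            raise ValueError("axon lengths must be positive")
        pos = self.boutons["position_um"].to_numpy()
        lengths = self.axon_length_um.loc[
            self.boutons["axon_id"]
        ].to_numpy()
        if np.any(pos < 0) or np.any(pos > lengths):
            raise ValueError("bouton positions must lie within the axon")
        if not self.presence.index.equals(self.boutons.index):
            self.presence = self.presence.loc[self.boutons.index]

    @property
    def days(self) -> list[int]:
        return list(self.presence.columns)

    def present_on(self, day: int) -> pd.Index:
        return self.presence.index[self.presence[day]]


def annotate_dynamics(track: BoutonTrack) -> pd.DataFrame:
    """State of every bouton at every adjacent-session pair.

    Returns a long DataFrame (bouton_id, axon_id, day_from, day_to, state)
    with exactly one state per bouton and pair. Re-appearance
    (present, absent, present) is annotated independently per transition,
    i.e. as an elimination followed by a formation.
    """
    days = track.days
    if len(days) < 2:
        raise ValueError("at least two imaged sessions are required")
    rows = []
    pres = track.presence
    for d0, d1 in zip(days[:-1], days[1:]):
        before = pres[d0].to_numpy()
        after = pres[d1].to_numpy()
        state = np.where(
            before & after,
            "persistent",
            np.where(
                before & ~after,
                "eliminated",
                np.where(~before & after, "formed", "absent"),
            ),
        )
        rows.append(
            pd.DataFrame(
                {
                    "bouton_id": pres.index,
                    "axon_id": track.boutons["axon_id"].to_numpy(),
                    "day_from": d0,
                    "day_to": d1,
                    "state": state,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def density_timecourse(track: BoutonTrack) -> pd.DataFrame:
    """Per-axon bouton density (per um) and density normalized to day 0.

    Axons with zero boutons on the first imaged day have undefined
    normalized density (NaN).
    """
    days = track.days
    counts = (
        track.presence.groupby(track.boutons["axon_id"]).sum().reindex(
            track.axon_length_um.index, fill_value=0
        )
    )
    density = counts.div(track.axon_length_um, axis=0)
    d0 = density[days[0]]
    normalized = density.div(d0.where(d0 > 0), axis=0)
    out = density.copy()
    out.columns = pd.MultiIndex.from_product([["density"], days])
    for d in days:
        out[("normalized", d)] = normalized[d]
    out.index.name = "axon_id"
    return out


def turnover_rates(
    track: BoutonTrack, per_axon: bool = False
) -> pd.DataFrame:
    """Formation and elimination percentages per inter-session interval.

    Formation% at day d = formed(d-2 -> d) / present(d-2) * 100, normalized
    to the bouton count of the earlier session; elimination% analogous. By
    default rates are pooled over axons; with ``per_axon`` a per-axon table
    is returned (NaN where the earlier session had no boutons).
    """
    ann = annotate_dynamics(track)
    group_keys = ["day_from", "day_to"] + (["axon_id"] if per_axon else [])
    counts = (
        ann.groupby(group_keys + ["state"]).size().unstack("state")
        .reindex(columns=STATES, fill_value=0).fillna(0)
    )
    present_before = counts["persistent"] + counts["eliminated"]
    out = pd.DataFrame(
        {
            "formation_pct": 100 * counts["formed"] / present_before.where(
                present_before > 0
            ),
            "elimination_pct": 100
            * counts["eliminated"]
            / present_before.where(present_before > 0),
            "present_before": present_before,
            "formed": counts["formed"],
            "eliminated": counts["eliminated"],
        }
    )
    return out.reset_index()


def survival_curve(
    track: BoutonTrack,
    formation_day: int = 4,
    check_days: tuple[int, ...] = (6, 8, 10),
) -> pd.Series:
    """Survival of boutons formed on ``formation_day``.

    A bouton "formed on day d" was absent at the previous imaged session and
    present on day d. The curve gives, for each later check day, the fraction
    of those boutons still present.
    """
    days = track.days
    if formation_day not in days or any(d not in days for d in check_days):
        raise ValueError("formation and check days must all be imaged")
    prev = days[days.index(formation_day) - 1]
    formed = track.presence.index[
        ~track.presence[prev] & track.presence[formation_day]
    ]
    if formed.empty:
        raise ValueError("no boutons formed on the formation day")
    return pd.Series(
        {d: float(track.presence.loc[formed, d].mean()) for d in check_days},
        name="survival_fraction",
    )


def new_bouton_pair_distances(track: BoutonTrack, day: int) -> np.ndarray:
    """Pairwise along-axon distances (um) among same-axon co-formed boutons.

    Considers boutons formed on ``day`` (absent at the previous session);
    distances are taken along the 1-D axon coordinate. Axons with fewer than
    two co-formed boutons contribute no pairs.
    """
    days = track.days
    prev = days[days.index(day) - 1]
    formed = track.presence.index[~track.presence[prev] & track.presence[day]]
    dists: list[float] = []
    for _, grp in track.boutons.loc[formed].groupby("axon_id"):
        pos = np.sort(grp["position_um"].to_numpy())
        if pos.size < 2:
            continue
        i, j = np.triu_indices(pos.size, k=1)
        dists.extend(np.abs(pos[i] - pos[j]))
    return np.asarray(dists)


def ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF: sorted values and cumulative fractions."""
    x = np.sort(np.asarray(values, dtype=float))
    return x, np.arange(1, x.size + 1) / x.size


def density_day_correlation(
    densities: pd.DataFrame, day_a: int, day_b: int
) -> tuple[float, float]:
    """Pearson correlation (r, p) of per-axon densities between two days."""
    a = densities[("density", day_a)].to_numpy()
    b = densities[("density", day_b)].to_numpy()
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need at least 3 axons with defined densities")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("undefined correlation: zero variance across axons")
    r, p = _stats.pearsonr(a, b)
    return float(r), float(p)


def function_structure_join(
    track: BoutonTrack, axon_classes: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Stratify structural dynamics by functional axon class.

    ``axon_classes`` has columns (axon_id, early_class, late_class) with
    classes in {RM, UM, none}; RM groups RM-only with RM-UM-both axons, as in
    the functional classification. Returns:

    - ``formation_by_late_class``: mean per-axon formation % by late class
    - ``elimination_by_early_class``: mean per-axon elimination % by early
      class
    - ``density_change_by_path``: mean final/initial density ratio by
      (early_class, late_class) path

    Axons missing from either record are excluded.
    """
    classes = axon_classes.set_index("axon_id")
    shared = classes.index.intersection(track.axon_length_um.index)
    classes = classes.loc[shared]
    rates = turnover_rates(track, per_axon=True)
    rates = rates[rates["axon_id"].isin(shared)]
    per_axon = rates.groupby("axon_id")[
        ["formation_pct", "elimination_pct"]
    ].mean()
    per_axon = per_axon.join(classes)

    formation = (
        per_axon.groupby("late_class")["formation_pct"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
    elimination = (
        per_axon.groupby("early_class")["elimination_pct"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )

    dens = density_timecourse(track)
    days = track.days
    ratio = dens[("normalized", days[-1])].rename("density_ratio")
    path = classes.join(ratio, how="inner")
    density_change = (
        path.groupby(["early_class", "late_class"])["density_ratio"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
    return {
        "formation_by_late_class": formation,
        "elimination_by_early_class": elimination,
        "density_change_by_path": density_change,
    }
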