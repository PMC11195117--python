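"""File formats and configuration.

Tabular outputs are TSV (UTF-8, LF, '.' decimal) with explicit headers;
fluorescence arrays go to an HDF5 container; configuration is YAML.
Re-reading a written table reproduces the values exactly (round-trip via
full-precision repr).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .behavior import LeverSession
from .signals import EventTrain, FluorescenceSet
from .structure import BoutonTrack
from .synthetic import BehaviorSpec, SimConfig, StructureSpec

__all__ = [
    "write_table",
    "read_table",
    "save_lever_session",
    "load_lever_session",
    "save_fluorescence",
    "load_fluorescence",
    "events_to_frame",
    "frame_to_events",
    "track_to_frame",
    "frame_to_track",
    "load_sim_config",
    "dump_sim_config",
]


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g",
              lineterminator="\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    # round_trip parsing: written values must re-read bit-exactly
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def save_lever_session(
    session: LeverSession, path: str | Path
) -> Path:
    """Lever trace as a two-column TSV plus a JSON sidecar with task meta."""
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": session.times, "position_mm": session.positions}
    )
    write_table(df, path)
    meta = {
        "sample_rate": session.sample_rate,
        "cue_onsets": session.cue_onsets.tolist(),
        "task_period": session.task_period,
        "push_threshold": session.push_threshold,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta))
    return path


def load_lever_session(path: str | Path) -> LeverSession:
    path = Path(path)
    df = read_table(path)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    return LeverSession(
        positions=df["position_mm"].to_numpy(),
        sample_rate=meta["sample_rate"],
        cue_onsets=np.asarray(meta["cue_onsets"]),
        task_period=meta["task_period"],
        push_threshold=meta["push_threshold"],
    )


def save_fluorescence(fset: FluorescenceSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("raw", data=fset.raw, compression="gzip")
        f.create_dataset("axon_of", data=np.asarray(fset.axon_of))
        f.create_dataset("bouton_ids", data=np.asarray(fset.bouton_ids))
        f.attrs["frame_rate"] = fset.frame_rate
        f.attrs["day"] = fset.day
    return path


def load_fluorescence(path: str | Path) -> FluorescenceSet:
    with h5py.File(path, "r") as f:
        return FluorescenceSet(
            raw=f["raw"][()],
            frame_rate=float(f.attrs["frame_rate"]),
            axon_of=f["axon_of"][()],
            bouton_ids=f["bouton_ids"][()],
            day=int(f.attrs["day"]),
        )


def events_to_frame(events: dict[int, EventTrain]) -> pd.DataFrame:
    rows = []
    for bouton_id, train in events.items():
        for t, a, z in zip(train.times, train.amplitudes, train.z):
            rows.append((bouton_id, t, a, z))
    return pd.DataFrame(
        rows, columns=["bouton_id", "time_s", "amplitude_dff", "z"]
    )


def frame_to_events(df: pd.DataFrame) -> dict[int, EventTrain]:
    out = {}
    for bouton_id, grp in df.groupby("bouton_id"):
        grp = grp.sort_values("time_s")
        out[int(bouton_id)] = EventTrain(
            times=grp["time_s"].to_numpy(),
            amplitudes=grp["amplitude_dff"].to_numpy(),
            z=grp["z"].to_numpy(),
        )
    return out


def track_to_frame(track: BoutonTrack) -> pd.DataFrame:
    """Long-format bouton track (axon_id, bouton_id, position_um, day,
    present, axon_length_um, group)."""
    rows = []
    for bid, row in track.boutons.iterrows():
        for day in track.days:
            rows.append(
                (
                    row["axon_id"],
                    bid,
                    row["position_um"],
                    day,
                    bool(track.presence.loc[bid, day]),
                    float(track.axon_length_um.loc[row["axon_id"]]),
                    track.group,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["axon_id", "bouton_id", "position_um", "day", "present",
                 "axon_length_um", "group"],
    )


def frame_to_track(df: pd.DataFrame) -> BoutonTrack:
    boutons = (
        df[["bouton_id", "axon_id", "position_um"]]
        .drop_duplicates("bouton_id")
        .reset_index(drop=True)
    )
    presence = (
        df.pivot(index="bouton_id", columns="day", values="present")
        .astype(bool)
        .loc[boutons["bouton_id"]]
    )
    lengths = (
        df[["axon_id", "axon_length_um"]]
        .drop_duplicates("axon_id")
        .set_index("axon_id")["axon_length_um"]
    )
    group = df["group"].iloc[0] if "group" in df else "training"
    return BoutonTrack(
        boutons=boutons, presence=presence, axon_length_um=lengths,
        group=str(group),
    )


def dump_sim_config(config: SimConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return path


def load_sim_config(path: str | Path) -> SimConfig:
    data = yaml.safe_load(Path(path).read_text())
    return sim_config_from_dict(data)


def sim_config_from_dict(data: dict) -> SimConfig:
    data = dict(data)
    if isinstance(data.get("behavior"), dict):
        data["behavior"] = BehaviorSpec(**_tuplify(data["behavior"]))
    if isinstance(data.get("structure"), dict):
        data["structure"] = StructureSpec(**_tuplify(data["structure"]))
    return SimConfig(**_tuplify(data))


def _tuplify(d: dict) -> dict:
    defaults = {
        f.name: f for cls in (SimConfig, BehaviorSpec, StructureSpec)
        for f in dataclasses.fields(cls)
    }
    out = {}
    for k, v in d.items():
        if isinstance(v, list) and k in defaults:
            v = tuple(v)
        out[k] = v
    return out
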