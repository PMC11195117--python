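"""End-to-end orchestration.

Runs the stages in dependency order on synthetic cohorts: simulate ->
behavior -> dff -> detect -> classify -> ensembles -> pca -> heterogeneity
-> structure -> report. Each stage writes TSV tables into the run directory;
a provenance record (package version, config hash, seed) accompanies every
run. Stages are deterministic in (config, seed), so re-running a subset
refreshes exactly those outputs.

The early/late stage parameter sets emulate motor learning: late sessions
have a higher task success rate, a larger fraction of RM-tuned boutons, and
a higher shared-event probability (less same-axon heterogeneity), mirroring
the direction of the experimental effects.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import (
    LeverSession,
    behavior_metrics,
    detect_bouts,
    extract_trajectory,
    filter_clean_baseline,
    label_bouts,
    rest_threshold_from_trace,
)
from .ensembles import bin_by_movement_correlation, trial_pair_table
from .heterogeneity import (
    aggregate_same_fraction,
    axon_heterogeneity,
    match_peaks,
    outcome_peak_fractions,
    same_peak_fraction,
)
from .io import (
    dump_sim_config,
    events_to_frame,
    save_fluorescence,
    save_lever_session,
    track_to_frame,
    write_table,
)
from .pca_embedding import (
    build_concat_matrix,
    embed_boutons,
    extract_trajectories,
    segment_pca,
    selectivity_index,
)
from .signals import EventTrain, compute_dff, detect_events, zscore_trace
from .structure import (
    density_day_correlation,
    density_timecourse,
    function_structure_join,
    new_bouton_pair_distances,
    survival_curve,
    turnover_rates,
)
from .synthetic import (
    SimConfig,
    simulate_behavior,
    simulate_fluorescence,
    simulate_structure,
)
from .trial_response import (
    align_trials,
    axon_response_threshold,
    class_fractions,
    class_transition_matrix,
    classify_axon,
    classify_bouton,
    peak_minus_p5,
)

STAGES = (
    "simulate", "behavior", "dff", "detect", "classify", "ensembles",
    "pca", "heterogeneity", "structure", "report",
)

# learning-stage parameter sets (see docs/methods.md)
EARLY_OVERRIDES = {
    "p_success": 0.4, "frac_rm_only": 0.15, "frac_um_only": 0.30,
    "p_shared": 0.65,
}
LATE_OVERRIDES = {
    "p_success": 0.75, "frac_rm_only": 0.35, "frac_um_only": 0.15,
    "p_shared": 0.85,
}
CONTROL_STRUCTURE = {"formation_rate": 0.05, "elimination_rate": 0.05,
                     "cluster_scale_um": None}
TRAINING_STRUCTURE = {"cluster_scale_um": 5.0}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: Path
    seed: int = 0
    n_mice: int = 4
    n_control_mice: int = 4
    base: SimConfig = field(default_factory=SimConfig)
    stages: tuple[str, ...] = STAGES

    def stage_config(self, stage: str) -> SimConfig:
        over = EARLY_OVERRIDES if stage == "early" else LATE_OVERRIDES
        beh = replace(self.base.behavior, p_success=over["p_success"])
        return replace(
            self.base,
            behavior=beh,
            frac_rm_only=over["frac_rm_only"],
            frac_um_only=over["frac_um_only"],
            p_shared=over["p_shared"],
        )


def derive_seed(seed: int, *keys: int) -> int:
    """Stable sub-seed below 2**31 from a base seed and integer keys."""
    return int(
        np.random.SeedSequence(entropy=seed, spawn_key=tuple(keys))
        .generate_state(1)[0] % (2**31)
    )


@dataclass
class SessionResult:
    """In-memory results for one (mouse, stage) imaging session."""

    session: LeverSession
    truth_bouts: pd.DataFrame
    bouts: list
    clean: list
    metrics: dict
    dff: np.ndarray
    events: dict[int, EventTrain]
    tensor: object
    bouton_classes: list
    axon_classes: dict
    axon_threshold_sd: float
    pair_table: pd.DataFrame
    selectivity: pd.DataFrame
    same_peak_pairs: pd.DataFrame
    same_peak_fraction: float
    outcome_fractions: pd.Series
    axon_het: dict
    truth: object


def analyze_session(config: SimConfig, seed: int) -> SessionResult:
    """Simulate and fully analyze one imaging session."""
    session, truth_bouts = simulate_behavior(config, seed)
    fset, truth = simulate_fluorescence(config, session, truth_bouts, seed)

    # robust rest annotation: MAD-based sigma is insensitive to the sparse
    # push bumps; k=5 keeps the threshold above extreme noise excursions
    # while staying far below the smallest simulated push amplitude
    pos = session.positions
    sigma = 1.4826 * np.median(np.abs(pos - np.median(pos))) + 1e-12
    rest_mask = np.abs(pos - np.median(pos)) < 3 * sigma
    thr = rest_threshold_from_trace(pos, rest_mask, k=5.0)
    bouts = label_bouts(detect_bouts(session, thr), session)
    bouts = filter_clean_baseline(bouts)
    clean = [b for b in bouts if b.clean_baseline]
    metrics = behavior_metrics(session, bouts)

    dff = compute_dff(fset.raw, fset.frame_rate)
    z = zscore_trace(dff)
    events = {
        int(fset.bouton_ids[b]): detect_events(dff[b], z[b], fset.frame_rate)
        for b in range(fset.n_boutons)
    }

    onsets = np.array([b.onset for b in clean])
    labels = np.array([b.label for b in clean])
    tensor = align_trials(dff, onsets, labels, fset.frame_rate)

    session_sd = dff.std(axis=1)
    n_rm = int((tensor.labels == "RM").sum())
    n_um = int((tensor.labels == "UM").sum())
    have_both = n_rm > 0 and n_um > 0
    bouton_classes = []
    if have_both:
        avg_rm = tensor.trial_average("RM")
        avg_um = tensor.trial_average("UM")
        for b in range(fset.n_boutons):
            bouton_classes.append(
                classify_bouton(
                    avg_rm[b], avg_um[b], tensor.time, session_sd[b],
                    n_trials_rm=n_rm, n_trials_um=n_um,
                )
            )
    # axon-level classification with the histogram-derived threshold
    axon_classes: dict = {}
    thr_sd = np.nan
    if have_both:
        axon_ids = np.unique(fset.axon_of)
        peaks_rm, peaks_um, axon_traces = [], [], {}
        for a in axon_ids:
            members = np.flatnonzero(fset.axon_of == a)
            at = dff[members].mean(axis=0)
            asd = at.std()
            t_ax = align_trials(at, onsets, labels, fset.frame_rate)
            pr = peak_minus_p5(t_ax.trial_average("RM")[0], t_ax.time)
            pu = peak_minus_p5(t_ax.trial_average("UM")[0], t_ax.time)
            peaks_rm.append(pr / asd)
            peaks_um.append(pu / asd)
            axon_traces[a] = (t_ax, asd)
        thr_sd = axon_response_threshold(
            np.asarray(peaks_rm), np.asarray(peaks_um)
        )
        for a in axon_ids:
            t_ax, asd = axon_traces[a]
            axon_classes[int(a)] = classify_axon(
                t_ax.trial_average("RM")[0], t_ax.trial_average("UM")[0],
                t_ax.time, asd, thr_sd,
            )

    # ensembles: trial-pair statistics over clean bouts
    move_trajs = np.array(
        [extract_trajectory(session, b) for b in clean]
    )
    responsive = {
        int(fset.bouton_ids[b])
        for b, c in enumerate(bouton_classes)
        if c.rm_responsive
    }
    pair_table = trial_pair_table(tensor, move_trajs, events, responsive,
                                  onsets)

    # pca trajectories and selectivity
    pcs, _ = segment_pca(dff)
    sel_rows = []
    try:
        tset = extract_trajectories(pcs, onsets, labels, fset.frame_rate)
        if tset.mean_rm is not None and tset.mean_um is not None:
            for k, lab in enumerate(tset.labels):
                _, mean_idx = selectivity_index(
                    tset.trajectories[k], tset.mean_rm, tset.mean_um,
                    str(lab),
                )
                sel_rows.append((k, str(lab), mean_idx))
    except ValueError:
        pass
    selectivity = pd.DataFrame(
        sel_rows, columns=["trial", "label", "selectivity"]
    )

    # same-axon heterogeneity
    pair_rows, matches = [], []
    bout_onsets = np.array([b.onset for b in bouts])
    bout_labels = np.array([b.label for b in bouts])
    for a in np.unique(fset.axon_of):
        members = [int(i) for i in np.flatnonzero(fset.axon_of == a)]
        for ii in range(len(members)):
            for jj in range(ii + 1, len(members)):
                bi, bj = members[ii], members[jj]
                m = match_peaks(events[bi], events[bj])
                matches.append(m)
                if m.n_i + m.n_j > 0:
                    pair_rows.append(
                        (int(a), bi, bj, same_peak_fraction(m))
                    )
    same_pairs = pd.DataFrame(
        pair_rows, columns=["axon_id", "bouton_i", "bouton_j", "fraction"]
    )
    spf = aggregate_same_fraction(same_pairs) if not same_pairs.empty else np.nan
    outcome = outcome_peak_fractions(matches, bout_onsets, bout_labels)

    axon_het = {}
    for a in np.unique(fset.axon_of):
        members = np.flatnonzero(fset.axon_of == a)
        cls = [bouton_classes[b].cls for b in members] if bouton_classes else []
        try:
            axon_het[int(a)] = axon_heterogeneity(cls)
        except ValueError:
            pass

    return SessionResult(
        session=session, truth_bouts=truth_bouts, bouts=bouts, clean=clean,
        metrics=metrics, dff=dff, events=events, tensor=tensor,
        bouton_classes=bouton_classes, axon_classes=axon_classes,
        axon_threshold_sd=float(thr_sd), pair_table=pair_table,
        selectivity=selectivity, same_peak_pairs=same_pairs,
        same_peak_fraction=spf, outcome_fractions=outcome,
        axon_het=axon_het, truth=truth,
    )


def _bout_frame(bouts: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (b.onset, b.offset, b.label, b.peak, b.clean_baseline)
            for b in bouts
        ],
        columns=["onset", "offset", "label", "peak_mm", "clean_baseline"],
    )


def _class_frame(result: SessionResult, mouse: int, stage: str) -> pd.DataFrame:
    rows = []
    for b, c in enumerate(result.bouton_classes):
        rows.append((mouse, stage, "bouton", b, c.cls, c.peak_rm, c.peak_um,
                     c.threshold))
    for a, c in result.axon_classes.items():
        rows.append((mouse, stage, "axon", a, c.cls, c.peak_rm, c.peak_um,
                     c.threshold))
    return pd.DataFrame(
        rows,
        columns=["mouse", "stage", "level", "unit_id", "cls", "peak_rm",
                 "peak_um", "threshold"],
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute the pipeline and write all stage outputs.

    Returns the run directory. Idempotent for identical config and seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_yaml = yaml.safe_dump(
        {
            "seed": config.seed,
            "n_mice": config.n_mice,
            "n_control_mice": config.n_control_mice,
            "base": config.base.to_dict(),
            "stages": list(config.stages),
        },
        sort_keys=True,
    )
    (outdir / "run_config.yaml").write_text(cfg_yaml)
    (outdir / "run_meta.json").write_text(
        json.dumps(
            {
                "package_version": __version__,
                "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
                "seed": config.seed,
            },
            indent=2,
        )
    )
    dump_sim_config(config.base, outdir / "sim_config.yaml")
    want = set(config.stages)

    summary_rows = []
    class_frames = []
    results: dict[tuple[int, str], SessionResult] = {}
    for mouse in range(config.n_mice):
        for s_idx, stage in enumerate(("early", "late")):
            cfg = config.stage_config(stage)
            seed = derive_seed(config.seed, mouse, s_idx)
            res = analyze_session(cfg, seed)
            results[(mouse, stage)] = res
            tag = f"m{mouse}_{stage}"
            if "simulate" in want:
                save_lever_session(res.session, outdir / f"lever_{tag}.tsv")
                write_table(res.truth_bouts, outdir / f"truth_bouts_{tag}.tsv")
                write_table(
                    res.truth.bouton_classes,
                    outdir / f"truth_classes_{tag}.tsv",
                )
            if "behavior" in want:
                write_table(_bout_frame(res.bouts), outdir / f"bouts_{tag}.tsv")
            if "dff" in want:
                from .signals import FluorescenceSet

                save_fluorescence(
                    FluorescenceSet(
                        raw=res.dff, frame_rate=config.base.frame_rate,
                        axon_of=res.truth.bouton_classes["axon_id"]
                        .to_numpy(),
                    ),
                    outdir / f"dff_{tag}.h5",
                )
            if "detect" in want:
                write_table(
                    events_to_frame(res.events), outdir / f"events_{tag}.tsv"
                )
            if "classify" in want:
                class_frames.append(_class_frame(res, mouse, stage))
            if "ensembles" in want:
                write_table(res.pair_table, outdir / f"trial_pairs_{tag}.tsv")
                binned = bin_by_movement_correlation(
                    res.pair_table.dropna(subset=["ensemble_diff"]),
                    "ensemble_diff",
                )
                binned_df = pd.DataFrame(
                    {
                        "bin_lo": [k[0] for k in binned.index],
                        "bin_hi": [k[1] for k in binned.index],
                        "ensemble_diff": binned.to_numpy(),
                    }
                )
                write_table(binned_df, outdir / f"ensemble_binned_{tag}.tsv")
            if "pca" in want:
                write_table(res.selectivity, outdir / f"selectivity_{tag}.tsv")
                labels_present = set(res.tensor.labels)
                if {"RM", "UM"} <= labels_present:
                    cm = build_concat_matrix(res.tensor)
                    scores, evr = embed_boutons(cm)
                    emb = pd.DataFrame(
                        scores, columns=[f"pc{k + 1}" for k in
                                         range(scores.shape[1])]
                    )
                    emb.insert(0, "bouton_id", cm.bouton_ids)
                    emb.attrs["explained_variance_ratio"] = list(evr)
                    write_table(emb, outdir / f"embedding_{tag}.tsv")
            if "heterogeneity" in want:
                write_table(
                    res.same_peak_pairs, outdir / f"same_peaks_{tag}.tsv"
                )
            sel_rm = res.selectivity.query("label == 'RM'")["selectivity"]
            fr = (
                class_fractions(res.bouton_classes)
                if res.bouton_classes else pd.Series(dtype=float)
            )
            summary_rows.append(
                {
                    "mouse": mouse,
                    "stage": stage,
                    **res.metrics,
                    "frac_rm_only": fr.get("RM_only", np.nan),
                    "frac_um_only": fr.get("UM_only", np.nan),
                    "frac_both": fr.get("both", np.nan),
                    "same_peak_fraction": res.same_peak_fraction,
                    "rm_same_fraction": res.outcome_fractions.get("RM_same"),
                    "selectivity_rm": sel_rm.mean() if len(sel_rm) else np.nan,
                    "axon_heterogeneity": (
                        float(np.mean(list(res.axon_het.values())))
                        if res.axon_het else np.nan
                    ),
                }
            )
    summary = pd.DataFrame(summary_rows)
    write_table(summary, outdir / "mouse_summary.tsv")
    class_frames = [f for f in class_frames if not f.empty]
    if "classify" in want and class_frames:
        write_table(pd.concat(class_frames), outdir / "classes.tsv")
        trans_rows = []
        for mouse in range(config.n_mice):
            early = results[(mouse, "early")].bouton_classes
            late = results[(mouse, "late")].bouton_classes
            if early and late and len(early) == len(late):
                mat = class_transition_matrix(early, late)
                mat = mat.rename_axis("early").reset_index().assign(mouse=mouse)
                trans_rows.append(mat)
        if trans_rows:
            write_table(pd.concat(trans_rows), outdir / "transitions.tsv")

    if "structure" in want:
        _run_structure(config, results, outdir)

    if "report" in want:
        from .report import summary_report

        summary_report(outdir)
    return outdir


def _run_structure(
    config: RunConfig, results: dict, outdir: Path
) -> None:
    dist_rows, turnover_frames, density_frames, survival_rows = [], [], [], []
    join_frames = []
    for group, n, over in (
        ("training", config.n_mice, TRAINING_STRUCTURE),
        ("control", config.n_control_mice, CONTROL_STRUCTURE),
    ):
        for mouse in range(n):
            cfg = replace(
                config.base,
                structure=replace(config.base.structure, **over),
            )
            seed = derive_seed(config.seed, 100 + mouse, 0 if group ==
                               "training" else 1)
            track, truth = simulate_structure(cfg, seed, group=group)
            tag = f"{group}_m{mouse}"
            write_table(track_to_frame(track), outdir / f"track_{tag}.tsv")
            tr = turnover_rates(track).assign(mouse=mouse, group=group)
            turnover_frames.append(tr)
            dens = density_timecourse(track)
            dens.columns = [f"{a}_{b}" for a, b in dens.columns]
            density_frames.append(
                dens.reset_index().assign(mouse=mouse, group=group)
            )
            try:
                surv = survival_curve(track)
                survival_rows.append(
                    {"mouse": mouse, "group": group,
                     **{f"day{d}": v for d, v in surv.items()}}
                )
            except ValueError:
                pass
            for d in track.days[1:]:
                for dist in new_bouton_pair_distances(track, d):
                    dist_rows.append((group, mouse, d, dist))
            if group == "training" and (mouse, "late") in results:
                res_e = results[(mouse, "early")]
                res_l = results[(mouse, "late")]
                shared = set(res_e.axon_classes) & set(res_l.axon_classes)
                ac = pd.DataFrame(
                    {
                        "axon_id": sorted(shared),
                        "early_class": [
                            "RM" if res_e.axon_classes[a].rm_responsive
                            else ("UM" if res_e.axon_classes[a].um_responsive
                                  else "none")
                            for a in sorted(shared)
                        ],
                        "late_class": [
                            "RM" if res_l.axon_classes[a].rm_responsive
                            else ("UM" if res_l.axon_classes[a].um_responsive
                                  else "none")
                            for a in sorted(shared)
                        ],
                    }
                )
                join = function_structure_join(track, ac)
                for name, df in join.items():
                    join_frames.append(df.assign(table=name, mouse=mouse))
    write_table(pd.concat(turnover_frames), outdir / "turnover.tsv")
    density = pd.concat(density_frames)
    write_table(density, outdir / "densities.tsv")
    if survival_rows:
        write_table(pd.DataFrame(survival_rows), outdir / "survival.tsv")
    write_table(
        pd.DataFrame(
            dist_rows, columns=["group", "mouse", "day", "distance_um"]
        ),
        outdir / "new_bouton_distances.tsv",
    )
    if join_frames:
        write_table(
            pd.concat(join_frames), outdir / "function_structure.tsv"
        )
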