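"""Summary statistics report.

Early-vs-late comparisons use the two-sided Wilcoxon rank-sum test on
per-mouse values; correlations use Pearson's r; distribution comparisons
(new-bouton pair distances, training vs control) use the two-sided
Kolmogorov-Smirnov test. Values are reported as mean +/- SEM. No
multiple-testing correction is applied; raw p-values are listed with the
conventional thresholds (* p < 0.05, ** p < 0.01, *** p < 0.001).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .io import read_table, write_table

__all__ = ["summary_report", "stars"]

COMPARED_METRICS = (
    "success_rate",
    "reaction_time",
    "iti_push_count",
    "frac_rm_only",
    "frac_um_only",
    "frac_both",
    "same_peak_fraction",
    "rm_same_fraction",
    "selectivity_rm",
    "axon_heterogeneity",
)

MIN_REPLICATES = 3


def stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    x = x[np.isfinite(x)]
    if x.size == 0:
        return np.nan, np.nan
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan
    return float(np.mean(x)), sem


def summary_report(run_dir: str | Path) -> pd.DataFrame:
    """Headline statistics of a finished run directory.

    Writes ``report.tsv`` and returns it. Tests with fewer than three
    replicates per group are skipped with a notice row.
    """
    run_dir = Path(run_dir)
    summary_path = run_dir / "mouse_summary.tsv"
    if not summary_path.exists():
        raise FileNotFoundError(
            "missing upstream output: mouse_summary.tsv (run the classify "
            "and heterogeneity stages first)"
        )
    summary = read_table(summary_path)
    rows = []
    for metric in COMPARED_METRICS:
        if metric not in summary:
            continue
        early = summary.loc[summary.stage == "early", metric].to_numpy(float)
        late = summary.loc[summary.stage == "late", metric].to_numpy(float)
        early = early[np.isfinite(early)]
        late = late[np.isfinite(late)]
        m_e, s_e = _mean_sem(early)
        m_l, s_l = _mean_sem(late)
        if early.size < MIN_REPLICATES or late.size < MIN_REPLICATES:
            rows.append(
                (metric, "ranksum_early_vs_late", m_e, s_e, m_l, s_l,
                 np.nan, "skipped: <3 replicates")
            )
            continue
        stat, p = _stats.ranksums(early, late)
        rows.append(
            (metric, "ranksum_early_vs_late", m_e, s_e, m_l, s_l, p, stars(p))
        )

    dist_path = run_dir / "new_bouton_distances.tsv"
    if dist_path.exists():
        dist = read_table(dist_path)
        train = dist.loc[dist.group == "training", "distance_um"].to_numpy()
        ctrl = dist.loc[dist.group == "control", "distance_um"].to_numpy()
        if train.size >= MIN_REPLICATES and ctrl.size >= MIN_REPLICATES:
            _, p = _stats.ks_2samp(train, ctrl)
            m_t, s_t = _mean_sem(train)
            m_c, s_c = _mean_sem(ctrl)
            rows.append(
                ("new_bouton_pair_distance", "ks_training_vs_control",
                 m_t, s_t, m_c, s_c, p, stars(p))
            )

    dens_path = run_dir / "densities.tsv"
    if dens_path.exists():
        dens = read_table(dens_path)
        train = dens[dens.group == "training"]
        for day in (4, 8):
            a = train.get(f"density_{day}")
            b = train.get("density_10")
            if a is None or b is None or len(train) < MIN_REPLICATES:
                continue
            a, b = a.to_numpy(float), b.to_numpy(float)
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < MIN_REPLICATES or np.std(a[ok]) == 0:
                continue
            r, p = _stats.pearsonr(a[ok], b[ok])
            rows.append(
                (f"density_day10_vs_day{day}", "pearson", r, np.nan,
                 np.nan, np.nan, p, stars(p))
            )

    report = pd.DataFrame(
        rows,
        columns=["metric", "test", "group1_mean", "group1_sem",
                 "group2_mean", "group2_sem", "p_value", "significance"],
    )
    write_table(report, run_dir / "report.tsv")
    return report
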