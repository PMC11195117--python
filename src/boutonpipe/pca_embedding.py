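"""PCA embeddings and trajectory selectivity.

Two uses of PCA:

1. Bouton embedding: each bouton's trial-averaged RM and UM activity is
   concatenated into a 2M-vector (M = frames per trial window); PCA across
   time points places each bouton as a dot in a 3-D PC space where RM-only
   and UM-only boutons separate.
2. Population trajectories: PCA on a continuous imaged segment
   (boutons x frames) yields the first three population PC time courses;
   aligning them from -1 s to +3 s around each movement onset gives
   single-trial neural trajectories.

The trajectory selectivity index for an RM trial is
(d_UM - d_RM) / (d_RM + d_UM), computed frame by frame, where d_X is the
Euclidean distance from the single-trial trajectory to the mean trajectory
of type X; for UM trials the roles swap. +1 means the trial sits exactly on
its own type's mean trajectory, -1 exactly on the opposite type's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "ConcatMatrix",
    "TrajectorySet",
    "build_concat_matrix",
    "embed_boutons",
    "segment_pca",
    "extract_trajectories",
    "selectivity_index",
]


@dataclass
class ConcatMatrix:
    """2M x N matrix of concatenated trial-averaged RM then UM activity."""

    matrix: np.ndarray  # (2M, N)
    n_window_frames: int  # M
    bouton_ids: np.ndarray
    excluded: list[int] = field(default_factory=list)


@dataclass
class TrajectorySet:
    """Single-trial PC trajectories plus the two mean trajectories."""

    trajectories: np.ndarray  # (trials, frames, k)
    labels: np.ndarray
    time: np.ndarray
    mean_rm: np.ndarray | None  # (frames, k)
    mean_um: np.ndarray | None


def build_concat_matrix(tensor) -> ConcatMatrix:
    """Stack per-bouton RM and UM trial averages into a 2M x N matrix.

    Boutons are columns; the first M rows are the RM average, the last M the
    UM average. Boutons missing a trial type are excluded (recorded in
    ``excluded``).
    """
    has_rm = np.any(tensor.labels == "RM")
    has_um = np.any(tensor.labels == "UM")
    if not (has_rm and has_um):
        raise ValueError("both RM and UM trials are required")
    avg_rm = tensor.trial_average("RM")  # boutons x M
    avg_um = tensor.trial_average("UM")
    mat = np.concatenate([avg_rm, avg_um], axis=1).T  # 2M x N
    return ConcatMatrix(
        matrix=mat,
        n_window_frames=avg_rm.shape[1],
        bouton_ids=np.arange(mat.shape[1]),
    )


def _fix_signs(components: np.ndarray, scores: np.ndarray):
    """Fix each PC's sign so its largest-|loading| element is positive."""
    for k in range(components.shape[0]):
        i = np.argmax(np.abs(components[k]))
        if components[k, i] < 0:
            components[k] *= -1
            scores[:, k] *= -1
    return components, scores


def embed_boutons(
    concat: ConcatMatrix, k: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Embed boutons in k-dimensional PC space.

    PCA is run across the time points of the concatenated matrix (boutons as
    samples, 2M time-point features) after mean-centering each bouton
    column; no variance scaling. Returns (scores: N x k, explained-variance
    ratios, non-increasing).
    """
    X = concat.matrix  # 2M x N
    n = X.shape[1]
    if n < k:
        raise ValueError(f"need at least {k} boutons")
    Xc = X - X.mean(axis=0, keepdims=True)  # center each bouton column
    rank = np.linalg.matrix_rank(Xc)
    k_eff = min(k, rank)
    if k_eff < k:
        warnings.warn(
            f"rank-deficient input: returning {k_eff} components", stacklevel=2
        )
    pca = PCA(n_components=k_eff)
    scores = pca.fit_transform(Xc.T)  # boutons as samples
    _, scores = _fix_signs(pca.components_.copy(), scores)
    return scores, pca.explained_variance_ratio_


def segment_pca(
    dff_segment: np.ndarray, k: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Population PC time courses over one continuous imaged segment.

    ``dff_segment`` is boutons x frames. Frames are the samples, boutons the
    features. Returns (pc time courses: frames x k, explained-variance
    ratios). If the segment has fewer boutons than k, k is reduced with a
    warning.
    """
    X = np.atleast_2d(np.asarray(dff_segment, dtype=float))
    n_boutons, n_frames = X.shape
    if n_frames < k:
        raise ValueError("segment too short for requested components")
    k_eff = min(k, n_boutons)
    if k_eff < k:
        warnings.warn(
            f"only {n_boutons} boutons: returning {k_eff} components",
            stacklevel=2,
        )
    pca = PCA(n_components=k_eff)
    pcs = pca.fit_transform(X.T)  # frames x k
    _, pcs = _fix_signs(pca.components_.copy(), pcs)
    return pcs, pca.explained_variance_ratio_


def extract_trajectories(
    pcs: np.ndarray,
    onsets: np.ndarray,
    labels: np.ndarray,
    frame_rate: float,
    window: tuple[float, float] = (-1.0, 3.0),
) -> TrajectorySet:
    """Slice PC time courses into per-trial trajectories and type means.

    Trials whose window leaves the segment are dropped. A label with zero
    surviving trials yields a None mean trajectory (selectivity is then
    unavailable for this segment).
    """
    pcs = np.asarray(pcs, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    labels = np.asarray(labels)
    pre = int(round(-window[0] * frame_rate))
    post = int(round(window[1] * frame_rate))
    trajs, kept = [], []
    for k_i, t in enumerate(onsets):
        i = int(round(t * frame_rate))
        if i - pre < 0 or i + post + 1 > pcs.shape[0]:
            continue
        trajs.append(pcs[i - pre : i + post + 1])
        kept.append(k_i)
    if not trajs:
        raise ValueError("no trials survive the alignment window")
    trajectories = np.stack(trajs)
    labels = labels[kept]
    time = np.arange(-pre, post + 1) / frame_rate

    def mean_of(label: str):
        sub = trajectories[labels == label]
        return sub.mean(axis=0) if sub.shape[0] else None

    return TrajectorySet(
        trajectories=trajectories,
        labels=labels,
        time=time,
        mean_rm=mean_of("RM"),
        mean_um=mean_of("UM"),
    )


def selectivity_index(
    trial_traj: np.ndarray,
    mean_rm: np.ndarray,
    mean_um: np.ndarray,
    label: str,
) -> tuple[np.ndarray, float]:
    """Per-frame trajectory selectivity index and its trial mean.

    For an RM trial: (d_UM - d_RM) / (d_RM + d_UM) per frame, where d_X is
    the frame-wise Euclidean distance to the mean trajectory of type X. For
    a UM trial the distances swap so that +1 always means "on the own-type
    mean". Frames where both distances are zero are undefined (NaN) and
    excluded from the trial mean.
    """
    trial_traj = np.asarray(trial_traj, dtype=float)
    if label not in ("RM", "UM"):
        raise ValueError("label must be RM or UM")
    if not (trial_traj.shape == mean_rm.shape == mean_um.shape):
        raise ValueError("trajectories must share frame count and dimension")
    d_rm = np.linalg.norm(trial_traj - mean_rm, axis=1)
    d_um = np.linalg.norm(trial_traj - mean_um, axis=1)
    own, other = (d_rm, d_um) if label == "RM" else (d_um, d_rm)
    denom = own + other
    with np.errstate(invalid="ignore", divide="ignore"):
        index = np.where(denom > 0, (other - own) / denom, np.nan)
    defined = np.isfinite(index)
    if not defined.any():
        raise ValueError("selectivity undefined at every frame")
    return index, float(np.mean(index[defined]))
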