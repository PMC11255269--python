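"""Population-trajectory geometry in principal-component space.

Trial-averaged, z-scored responses (window -0.5 to 1 s around stimulus
onset) are stacked time x condition and embedded with one shared PCA so
trajectories from different conditions and sessions live in a common space.
Trajectory length is the summed Euclidean step length in PC1-3 over the 1-s
stimulus window; the distance between two trajectories is the summed
pointwise Euclidean distance over the same window.  Sampling variability is
assessed with a bootstrap over random 40-neuron subsets (5,000 iterations,
PCA re-fit per draw).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from ._rng import as_generator
from .config import frame_times


@dataclass
class TrajectoryResult:
    scores: dict  # condition -> (time, components)
    explained_variance: np.ndarray
    times: np.ndarray
    path_length: dict = field(default_factory=dict)
    pairwise_distance: dict = field(default_factory=dict)
    bootstrap_samples: np.ndarray | None = None


def build_condition_matrix(
    zscored: np.ndarray,
    trials: pd.DataFrame,
    conditions: dict,
    frame_rate: float,
    t0_frame: int,
    window=(-0.5, 1.0),
):
    """Stack trial-averaged responses: rows = time points of each condition.

    ``conditions`` maps a name to a boolean trial mask.  Returns (matrix,
    times, n_frames_per_condition); the matrix is column-centered.
    """
    t = frame_times(zscored.shape[2], frame_rate, t0_frame)
    fmask = (t >= window[0]) & (t < window[1])
    blocks = []
    for name, sel in conditions.items():
        sel = np.asarray(sel)
        if sel.sum() == 0:
            raise ValueError(f"condition {name!r} has no trials")
        with np.errstate(invalid="ignore"):
            avg = np.nanmean(zscored[:, sel][:, :, fmask], axis=1)  # neurons x time
        blocks.append(avg.T)
    mat = np.vstack(blocks)
    mat = mat - mat.mean(axis=0, keepdims=True)
    return mat, t[fmask], int(fmask.sum())


def embed_trajectories(matrix: np.ndarray, condition_names, times, n_components: int = 3) -> TrajectoryResult:
    """PCA (SVD, column-centered input) shared across all conditions."""
    k = min(n_components, *matrix.shape)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(matrix)
    n_time = len(times)
    per_cond = {
        name: scores[i * n_time : (i + 1) * n_time] for i, name in enumerate(condition_names)
    }
    return TrajectoryResult(
        scores=per_cond,
        explained_variance=pca.explained_variance_ratio_,
        times=np.asarray(times),
    )


def trajectory_length(scores: np.ndarray, times: np.ndarray, window=(0.0, 1.0)) -> float:
    """Sum of Euclidean distances between consecutive in-window time points."""
    sel = (times >= window[0]) & (times < window[1])
    pts = np.asarray(scores)[sel]
    if len(pts) < 2:
        raise ValueError("need >= 2 time points in the window")
    return float(np.sqrt(((np.diff(pts, axis=0)) ** 2).sum(axis=1)).sum())


def trajectory_distance(scores_a, scores_b, times, window=(0.0, 1.0)) -> float:
    """Sum of pointwise Euclidean distances between two trajectories."""
    a, b = np.asarray(scores_a), np.asarray(scores_b)
    if a.shape != b.shape:
        raise ValueError("trajectories must share one time grid")
    sel = (times >= window[0]) & (times < window[1])
    return float(np.sqrt(((a[sel] - b[sel]) ** 2).sum(axis=1)).sum())


def compute_geometry(
    zscored, trials, conditions, frame_rate, t0_frame, window=(-0.5, 1.0), metric_window=(0.0, 1.0)
) -> TrajectoryResult:
    """Embed and measure all condition trajectories in one shared space."""
    mat, times, _ = build_condition_matrix(zscored, trials, conditions, frame_rate, t0_frame, window)
    res = embed_trajectories(mat, list(conditions), times)
    names = list(conditions)
    for name in names:
        res.path_length[name] = trajectory_length(res.scores[name], times, metric_window)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res.pairwise_distance[(a, b)] = trajectory_distance(
                res.scores[a], res.scores[b], times, metric_window
            )
    return res


def bootstrap_trajectory_metric(
    zscored,
    trials,
    conditions,
    frame_rate,
    t0_frame,
    metric: str = "distance",
    n_iter: int = 5000,
    subset_size: int = 40,
    seed=None,
    replace: bool = False,
    window=(-0.5, 1.0),
    metric_window=(0.0, 1.0),
) -> np.ndarray:
    """Bootstrap a trajectory metric over random neuron subsets.

    Per iteration: draw ``subset_size`` neurons (without replacement by
    default), rebuild the condition matrix, re-fit the PCA, recompute the
    metric.  ``metric`` is "length" (first condition) or "distance" (first
    condition pair).  Returns all samples.
    """
    rng = as_generator(seed)
    n_neurons = zscored.shape[0]
    if n_neurons < subset_size and not replace:
        raise ValueError(f"population ({n_neurons}) smaller than subset_size ({subset_size})")
    names = list(conditions)
    out = np.empty(n_iter)
    for k in range(n_iter):
        idx = rng.choice(n_neurons, size=subset_size, replace=replace)
        sub = zscored[idx]
        mat, times, _ = build_condition_matrix(sub, trials, conditions, frame_rate, t0_frame, window)
        res = embed_trajectories(mat, names, times)
        if metric == "length":
            out[k] = trajectory_length(res.scores[names[0]], times, metric_window)
        elif metric == "distance":
            out[k] = trajectory_distance(
                res.scores[names[0]], res.scores[names[1]], times, metric_window
            )
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return out


def population_correlation(window_means: dict) -> pd.DataFrame:
    """Pearson correlation between neuron-indexed mean-response vectors.

    ``window_means`` maps a group label (phase or session) to a vector of
    per-neuron trial-averaged window responses over one shared neuron set.
    Zero-variance vectors give NaN entries with a warning.
    """
    import warnings

    names = list(window_means)
    n = len(names)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            a = np.asarray(window_means[names[i]], dtype=float)
            b = np.asarray(window_means[names[j]], dtype=float)
            if a.std() == 0 or b.std() == 0:
                warnings.warn("zero-variance group in population correlation", stacklevel=2)
                continue
            mat[i, j] = np.corrcoef(a, b)[0, 1]
    return pd.DataFrame(mat, index=names, columns=names)
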