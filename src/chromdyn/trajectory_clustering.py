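"""Time-course accessibility trajectories: k-means and trend calling.

Per-peak stage means on normalized counts are z-scored (mean 0, sd 1 per
row), clustered with k-means (k = 4 by default, matching the four element
clusters of the time-course analysis), and each cluster's mean trajectory
is called opening / closing / non-monotone by Spearman correlation with
the ordinal time index (|rho| >= 0.8 by default — time is treated as an
ordinal index because the sampling days are unevenly spaced).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from ._errors import ArgumentError
from .coverage_peaks import CountMatrix
from .differential_accessibility import normalize_libsize

TRENDS = ("opening", "closing", "non-monotone")


@dataclass
class TrajectoryMatrix:
    """Per-peak stage-mean accessibility and its z-scored copy."""

    peak_ids: list[str]
    timepoints: list[str]
    means: pd.DataFrame          # peaks x timepoints, normalized stage means
    zscores: pd.DataFrame        # same shape, per-row mean 0 / sd 1
    excluded_constant: list[str] = field(default_factory=list)


@dataclass
class TrajectoryClustering:
    labels: pd.Series            # peak -> cluster label in 1..k
    k: int
    cluster_means: pd.DataFrame  # k x timepoints mean z-trajectory
    trends: dict[int, str] = field(default_factory=dict)


def build_trajectories(cm: CountMatrix, stage_order: list[str]) -> TrajectoryMatrix:
    """Stage-mean normalized counts per peak, z-scored per row.

    Rows constant across stages cannot be z-scored; they are excluded and
    reported in ``excluded_constant``.
    """
    if len(stage_order) < 3:
        raise ArgumentError("need >= 3 timepoints for a trajectory")
    stages = cm.stages()
    missing = [s for s in stage_order if s not in set(stages)]
    if missing:
        raise ArgumentError(f"stages missing from matrix: {missing}")
    norm, _ = normalize_libsize(cm, method="median_of_ratios")
    means = pd.DataFrame(
        {s: norm[stages.index[stages == s]].mean(axis=1) for s in stage_order}
    )
    sd = means.std(axis=1, ddof=0)
    constant = sd == 0
    kept = means.loc[~constant]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[~constant], axis=0)
    return TrajectoryMatrix(
        peak_ids=list(kept.index),
        timepoints=list(stage_order),
        means=kept,
        zscores=z,
        excluded_constant=list(means.index[constant]),
    )


def kmeans_cluster(tm: TrajectoryMatrix, k: int = 4, seed: int = 0,
                   n_init: int = 20) -> TrajectoryClustering:
    """Lloyd's k-means on z-rows, best of ``n_init`` restarts by WCSS."""
    n = len(tm.peak_ids)
    if k < 2:
        raise ArgumentError("k must be >= 2")
    if k > n:
        raise ArgumentError(f"k={k} exceeds number of rows ({n})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(tm.zscores.values)
    labels = pd.Series(raw + 1, index=tm.peak_ids, name="cluster")
    cluster_means = pd.DataFrame(
        {c: tm.zscores.values[raw == c - 1].mean(axis=0) for c in range(1, k + 1)},
        index=tm.timepoints,
    ).T
    return TrajectoryClustering(labels=labels, k=k, cluster_means=cluster_means)


def call_trends(tc: TrajectoryClustering, rho_thresh: float = 0.8
                ) -> TrajectoryClustering:
    """Classify each cluster-mean trajectory as opening/closing/non-monotone.

    Spearman rank correlation of the mean z-trajectory against the time
    index: >= +rho_thresh is opening, <= -rho_thresh closing, else
    non-monotone.
    """
    t_index = np.arange(tc.cluster_means.shape[1])
    trends = {}
    for c in range(1, tc.k + 1):
        traj = tc.cluster_means.loc[c].values
        rho = stats.spearmanr(traj, t_index).statistic
        if np.isnan(rho):
            trends[c] = "non-monotone"
        elif rho >= rho_thresh:
            trends[c] = "opening"
        elif rho <= -rho_thresh:
            trends[c] = "closing"
        else:
            trends[c] = "non-monotone"
    tc.trends = trends
    return tc


def wcss(tm: TrajectoryMatrix, tc: TrajectoryClustering) -> float:
    """Within-cluster sum of squares of a clustering on its matrix."""
    total = 0.0
    z = tm.zscores.values
    lab = tc.labels.values
    for c in range(1, tc.k + 1):
        pts = z[lab == c]
        if len(pts):
            total += ((pts - pts.mean(axis=0)) ** 2).sum()
    return float(total)


def plot_heatmap(tm: TrajectoryMatrix, tc: TrajectoryClustering, path) -> None:
    """Cluster-ordered z-score heatmap (optional figure output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = tc.labels.sort_values().index
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(tm.zscores.loc[order].values, aspect="auto", cmap="RdBu_r",
                   interpolation="nearest")
    ax.set_xticks(range(len(tm.timepoints)), tm.timepoints)
    ax.set_ylabel(f"{len(order)} elements in {tc.k} clusters")
    fig.colorbar(im, label="z-scored accessibility")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
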