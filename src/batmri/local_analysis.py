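"""Voxel-wise ΔFF/ΔT2* analysis: joint histograms and k-means clustering
with the explained-variance elbow rule.

Thermoneutral maps and ROI are pulled to the post-cooling grid, both time
points are smoothed with the in-plane neighborhood mean, and paired
per-voxel values are tabulated.  Cluster structure in the (FF, ΔFF, ΔT2*)
distributions is summarized by k-means; the number of clusters is the
smallest k whose explained variance (between-cluster sum of squares over
total sum of squares) reaches a cutoff, 95% by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import DeformationField, QuantitativeMaps, RoiMask
from .roi_transform import neighborhood_mean, transform_mask, transform_volume

__all__ = ["voxel_deltas", "joint_histogram", "cluster_elbow", "ClusterResult"]


def voxel_deltas(maps_pre: QuantitativeMaps, maps_post: QuantitativeMaps,
                 roi: RoiMask, field: DeformationField | None = None,
                 smoothing_k: int = 3, roi_threshold: float = 0.5) -> pd.DataFrame:
    """Paired per-voxel FF/T2* table on the post-cooling grid.

    ``roi`` is the thermoneutral depot ROI; ``field`` the deformation
    pulling thermoneutral data to post-cooling coordinates (``None`` for
    already co-registered grids).  Both stacks are smoothed with the
    ``smoothing_k`` × ``smoothing_k`` in-plane neighborhood mean before
    differencing.  Rows are voxels whose transformed ROI weight is at
    least ``roi_threshold`` at both time points.
    """
    if field is None:
        zeros = np.zeros((*maps_post.ff.shape, 3))
        field = DeformationField(displacements=zeros, affine=maps_post.affine.copy())
    ff_pre = transform_volume(np.nan_to_num(maps_pre.ff), maps_pre.affine, field)
    t2_pre = transform_volume(np.nan_to_num(maps_pre.t2star), maps_pre.affine, field)
    roi_t = transform_mask(roi, field)

    ff_pre_s = neighborhood_mean(ff_pre, smoothing_k)
    ff_post_s = neighborhood_mean(np.nan_to_num(maps_post.ff), smoothing_k)
    t2_pre_s = neighborhood_mean(t2_pre, smoothing_k)
    t2_post_s = neighborhood_mean(np.nan_to_num(maps_post.t2star), smoothing_k)

    sel = roi_t.values >= roi_threshold
    if not sel.any():
        raise ValueError("empty intersection ROI after transformation")
    idx = np.argwhere(sel)
    return pd.DataFrame({
        "x": idx[:, 0], "y": idx[:, 1], "z": idx[:, 2],
        "ff_pre": ff_pre_s[sel], "ff_post": ff_post_s[sel],
        "dff": ff_post_s[sel] - ff_pre_s[sel],
        "t2_pre": t2_pre_s[sel], "t2_post": t2_post_s[sel],
        "dt2": t2_post_s[sel] - t2_pre_s[sel],
        "roi_weight": roi_t.values[sel],
    })


def joint_histogram(x, y, x_bins, y_bins) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D joint histogram of paired per-voxel values.

    ``x_bins``/``y_bins`` are bin edges or counts (as for
    ``numpy.histogram2d``); bins are half-open with the last closed, so
    marginal sums conserve the total voxel count exactly.
    Returns ``(counts, x_edges, y_edges)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    counts, xe, ye = np.histogram2d(x, y, bins=[x_bins, y_bins])
    return counts, xe, ye


@dataclass
class ClusterResult:
    """k-means clustering with elbow (explained-variance) model selection."""

    k_selected: int
    labels: np.ndarray
    centroids: np.ndarray  # on the original (unstandardized) scale
    explained_variance_curve: np.ndarray  # index k-1 → EV at k clusters
    summaries: pd.DataFrame  # per-cluster mean ± SD of each variable
    columns: list[str]


def cluster_elbow(table: pd.DataFrame, columns: list[str] | None = None,
                  k_max: int = 8, variance_cutoff: float = 0.95,
                  seed: int = 0, n_restarts: int = 10,
                  standardize: bool = True) -> ClusterResult:
    """Select and fit the k-means clustering of selected table columns.

    Runs k-means for k = 1..``k_max`` with ``n_restarts`` seeded restarts
    each (plus a warm start that splits the previous k's worst-fit point,
    which keeps the explained-variance curve non-decreasing).  Explained
    variance is the between-cluster sum of squares divided by the total
    sum of squares; ``k_selected`` is the smallest k reaching
    ``variance_cutoff``, or ``k_max`` if none does.

    Variables are z-scored before clustering by default — FF (fraction)
    and T2* (ms) live on incommensurate scales.
    """
    if k_max < 2:
        raise ValueError("k_max must be at least 2")
    if not 0 < variance_cutoff <= 1:
        raise ValueError("variance_cutoff must be in (0, 1]")
    if columns is None:
        columns = [c for c in ("ff_pre", "dff", "dt2") if c in table.columns]
    x = table[columns].to_numpy(dtype=float)
    n = x.shape[0]
    if n < k_max:
        raise ValueError(f"fewer points ({n}) than k_max ({k_max})")

    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - mu) / sd if standardize else x

    tss = float(((z - z.mean(axis=0)) ** 2).sum())
    rng = np.random.default_rng(seed)
    ev = np.empty(k_max)
    fits = []
    prev = None
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts,
                    random_state=int(rng.integers(0, 2 ** 31 - 1))).fit(z)
        best = km
        if prev is not None:
            # warm start: previous centroids plus the worst-fit point
            d2 = ((z - prev.cluster_centers_[prev.labels_]) ** 2).sum(axis=1)
            init = np.vstack([prev.cluster_centers_, z[int(np.argmax(d2))]])
            km_w = KMeans(n_clusters=k, init=init, n_init=1).fit(z)
            if km_w.inertia_ < best.inertia_:
                best = km_w
        ev[k - 1] = 1.0 - best.inertia_ / tss if tss > 0 else 1.0
        fits.append(best)
        prev = best
    ev = np.maximum.accumulate(ev)  # guard against numerical ties

    reaching = np.flatnonzero(ev >= variance_cutoff)
    k_selected = int(reaching[0]) + 1 if reaching.size else k_max
    best = fits[k_selected - 1]
    labels = best.labels_
    centroids = best.cluster_centers_ * sd + mu if standardize else best.cluster_centers_

    rows = []
    for c in range(k_selected):
        m = labels == c
        row = {"cluster": c, "n": int(m.sum())}
        for j, col in enumerate(columns):
            row[f"{col}_mean"] = float(x[m, j].mean())
            row[f"{col}_sd"] = float(x[m, j].std(ddof=1)) if m.sum() > 1 else 0.0
        rows.append(row)
    return ClusterResult(k_selected=k_selected, labels=labels, centroids=centroids,
                         explained_variance_curve=ev,
                         summaries=pd.DataFrame(rows), columns=list(columns))
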