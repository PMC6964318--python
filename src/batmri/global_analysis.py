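"""Threshold-dependent global analysis of the supraclavicular depot.

Quantifies estimated BAT volume (Vol_BAT), global fat fraction (FF_Glob)
and T2* (T2*_Glob) inside FF threshold ranges, volume histograms, per-bin
cold-induced volume changes, and the full sweep over all (lower, upper)
threshold pairs.

Selection semantics follow the joint-exclusion rule: voxels below the
lower FF threshold are excluded *in both* the thermoneutral and
post-cooling ROIs for paired FF/T2* analyses, while volume analyses select
each time point independently (the voxel counts may differ).  Transformed
ROIs contribute fractional (floating-point) voxel weights by default; for
a voxel present in both time points the joint weight is the minimum of the
two.

The threshold sweep aggregates each subject once into FF-bin tables at the
sweep step and evaluates every (lower, upper) pair from cumulative sums,
which is exact for thresholds on the bin lattice (the only ones the sweep
visits) and turns the sweep into an O(bins²) operation per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import RoiMask, ThresholdRange

__all__ = [
    "SubjectData", "SegmentResult", "DepotSummary", "ThresholdGrid",
    "PairedTestResult", "segment_joint", "estimated_volume",
    "volume_histogram", "depot_summary", "binned_volume_change",
    "threshold_sweep", "paired_stats",
]

# default metabolizable-energy densities, kcal per μL of tissue compartment
_FAT_ENERGY = 9.4e-3
_LEAN_ENERGY = 1.0e-3


@dataclass
class SubjectData:
    """One subject's co-registered pre/post maps and ROIs.

    FF maps are fractions in [0, 1]; both time points must live on the
    same (post-cooling) grid, the thermoneutral maps having been pulled
    there by the registration deformation field.
    """

    ff_pre: np.ndarray
    ff_post: np.ndarray
    t2_pre: np.ndarray
    t2_post: np.ndarray
    roi_pre: RoiMask
    roi_post: RoiMask

    @property
    def voxel_volume(self) -> float:
        return self.roi_pre.voxel_volume

    @classmethod
    def from_truth_pair(cls, pre, post, which_roi: str = "roi") -> "SubjectData":
        """Build from a (thermoneutral, post-cooling) phantom-truth pair.

        Truth maps share one grid, so the identity registration applies.
        ``which_roi`` selects ``roi`` (depot) or ``sat_roi`` (control).
        """
        roi = getattr(pre, which_roi).astype(float)
        label = "supraclavicular" if which_roi == "roi" else "deltoid SAT"
        mk = lambda: RoiMask(values=roi, voxel_volume=pre.voxel_volume, label=label)
        return cls(ff_pre=pre.ff_true, ff_post=post.ff_true,
                   t2_pre=pre.t2s_true, t2_post=post.t2s_true,
                   roi_pre=mk(), roi_post=mk())


@dataclass
class SegmentResult:
    """Voxel selections for one threshold range.

    ``pre_weights``/``post_weights`` are per-timepoint fractional selection
    weights (zero outside the selection); ``joint_weights`` keeps only
    voxels passing the threshold at both time points.
    """

    range: ThresholdRange
    pre_weights: np.ndarray
    post_weights: np.ndarray
    joint_weights: np.ndarray

    @property
    def pre_mask(self) -> np.ndarray:
        return self.pre_weights > 0

    @property
    def post_mask(self) -> np.ndarray:
        return self.post_weights > 0

    @property
    def joint_mask(self) -> np.ndarray:
        return self.joint_weights > 0


@dataclass
class DepotSummary:
    """Vol_BAT / FF_Glob / T2*_Glob of one depot, range and time point."""

    vol_bat: float  # mL
    ff_glob: float  # percent
    t2_glob: float  # ms
    n_voxels: float  # weighted voxel count
    range: ThresholdRange
    timepoint: str
    label: str = "supraclavicular"


@dataclass
class ThresholdGrid:
    """Cohort-mean post-minus-pre change over all (lower, upper) pairs."""

    quantity: str
    lowers: np.ndarray  # percent
    uppers: np.ndarray  # percent
    delta: np.ndarray  # (n_lower, n_upper), nan where invalid
    valid: np.ndarray  # bool

    def extremum(self, sign: str = "min") -> tuple[float, float, float]:
        """(lower, upper, delta) of the most negative ('min') or most
        positive ('max') valid entry."""
        d = np.where(self.valid, self.delta, np.nan)
        idx = np.nanargmin(d) if sign == "min" else np.nanargmax(d)
        i, j = np.unravel_index(idx, d.shape)
        return float(self.lowers[i]), float(self.uppers[j]), float(d[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.delta, index=pd.Index(self.lowers, name="lower"),
                            columns=pd.Index(self.uppers, name="upper"))


@dataclass
class PairedTestResult:
    """Two-sided paired t-test report with a Shapiro-Wilk normality check.

    Significance is judged at p < 0.05, uncorrected.  Zero-variance
    differences are flagged ``degenerate`` (p = 1 when all differences are
    exactly zero, NA otherwise) rather than reported as spuriously small.
    """

    n: int
    mean_pre: float
    sem_pre: float
    mean_post: float
    sem_post: float
    mean_diff: float
    sem_diff: float
    shapiro_p: float
    t: float
    p: float
    significant: bool
    degenerate: bool = False


def estimated_volume(n_voxels: float, voxel_volume: float) -> float:
    """Estimated tissue volume in mL from a (possibly fractional) voxel
    count and the per-voxel volume in μL."""
    if n_voxels < 0:
        raise ValueError("n_voxels must be non-negative")
    return n_voxels * voxel_volume / 1000.0


def segment_joint(ff_pre: np.ndarray, ff_post: np.ndarray,
                  roi_pre: RoiMask, roi_post: RoiMask,
                  range: ThresholdRange) -> SegmentResult:
    """Select voxels inside an inclusive FF range, per time point and jointly.

    FF maps are fractions; the range is in percent.  Per-timepoint
    selections are independent (for volume analysis); the joint selection
    keeps voxels passing at both time points (for paired FF/T2* analysis),
    weighted by the smaller of the two fractional ROI weights.
    """
    if ff_pre.shape != ff_post.shape:
        raise ValueError("pre/post FF maps must share a grid")
    sel_pre = range.contains(ff_pre * 100.0) & (roi_pre.values > 0)
    sel_post = range.contains(ff_post * 100.0) & (roi_post.values > 0)
    w_pre = np.where(sel_pre, roi_pre.values, 0.0)
    w_post = np.where(sel_post, roi_post.values, 0.0)
    w_joint = np.minimum(w_pre, w_post)
    return SegmentResult(range=range, pre_weights=w_pre, post_weights=w_post,
                         joint_weights=w_joint)


def depot_summary(ff: np.ndarray, t2: np.ndarray, roi: RoiMask,
                  range: ThresholdRange, timepoint: str) -> DepotSummary:
    """Vol_BAT, FF_Glob and T2*_Glob of one map inside a threshold range."""
    sel = range.contains(ff * 100.0) & (roi.values > 0)
    w = np.where(sel, roi.values, 0.0)
    n = float(w.sum())
    if n > 0:
        ff_glob = float((w * ff).sum() / n) * 100.0
        t2_glob = float((w * t2).sum() / n)
    else:
        ff_glob = np.nan
        t2_glob = np.nan
    return DepotSummary(vol_bat=estimated_volume(n, roi.voxel_volume),
                        ff_glob=ff_glob, t2_glob=t2_glob, n_voxels=n,
                        range=range, timepoint=timepoint, label=roi.label)


def volume_histogram(ff: np.ndarray, roi: RoiMask, bin_width: float = 0.5,
                     ff_range: tuple[float, float] = (0.0, 100.0),
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Volume histogram over FF.

    Returns ``(edges, volumes_ml)`` with half-open bins ``[b, b + w)`` (the
    last bin closed, so FF = 100% is counted); bar height is the weighted
    voxel count times the voxel volume.  The bars over any sub-range sum to
    the estimated volume of that segmentation exactly.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = ff_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    inside = roi.values > 0
    ffp = ff[inside] * 100.0
    w = roi.values[inside]
    keep = (ffp >= lo) & (ffp <= hi)
    counts, _ = np.histogram(ffp[keep], bins=edges, weights=w[keep])
    return edges, counts * roi.voxel_volume / 1000.0


def paired_stats(pre, post) -> PairedTestResult:
    """Paired comparison of per-subject values (Shapiro-Wilk + paired t)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    n = len(pre)
    if n < 2:
        raise ValueError("at least 2 subjects required for a paired test")
    diff = post - pre
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan
    scale = max(float(np.max(np.abs(diff))), 1.0)
    degenerate = bool(np.std(diff, ddof=1) <= 1e-12 * scale)
    if degenerate:
        p = 1.0 if np.allclose(diff, 0) else np.nan
        t = 0.0 if np.allclose(diff, 0) else np.nan
        shapiro_p = np.nan
    else:
        shapiro_p = float(stats.shapiro(diff).pvalue) if n >= 3 else np.nan
        t, p = stats.ttest_rel(post, pre)
        t, p = float(t), float(p)
    return PairedTestResult(
        n=n, mean_pre=float(pre.mean()), sem_pre=sem(pre),
        mean_post=float(post.mean()), sem_post=sem(post),
        mean_diff=float(diff.mean()), sem_diff=sem(diff),
        shapiro_p=shapiro_p, t=t, p=p,
        significant=bool(p < 0.05) if np.isfinite(p) else False,
        degenerate=degenerate,
    )


def binned_volume_change(subjects: list[SubjectData], bin_width: float = 10.0,
                         ff_range: tuple[float, float] = (30.0, 100.0),
                         ) -> pd.DataFrame:
    """Per-FF-interval cold-induced volume change across the cohort.

    For each FF interval (default 10% bins over 30-100%), computes the
    per-subject post-minus-pre estimated volume and a paired t-test across
    subjects.  With fewer than 2 subjects only descriptive columns are
    returned.
    """
    lo, hi = ff_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    rows = []
    deltas = np.empty((len(subjects), len(edges) - 1))
    for i, s in enumerate(subjects):
        _, v_pre = volume_histogram(s.ff_pre, s.roi_pre, bin_width, ff_range)
        _, v_post = volume_histogram(s.ff_post, s.roi_post, bin_width, ff_range)
        deltas[i] = v_post - v_pre
    for b in range(len(edges) - 1):
        row = {
            "ff_lower": edges[b], "ff_upper": edges[b + 1],
            "mean_delta_ml": float(deltas[:, b].mean()),
        }
        if len(subjects) >= 2:
            res = paired_stats(np.zeros(len(subjects)), deltas[:, b])
            row.update(sem_delta_ml=res.sem_diff, shapiro_p=res.shapiro_p,
                       t=res.t, p=res.p, significant=res.significant,
                       degenerate=res.degenerate)
        rows.append(row)
    if len(subjects) < 2:
        import warnings
        warnings.warn("fewer than 2 subjects: descriptive output only, test omitted")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# threshold sweep via per-subject bin aggregates


def _bin_index(ff: np.ndarray, step: float, n_bins: int) -> np.ndarray:
    """FF (fraction) to bin index at percent step; top edge closed."""
    return np.clip(np.floor(ff * 100.0 / step).astype(int), 0, n_bins - 1)


@dataclass
class _SubjectAggregates:
    """Bin-level sufficient statistics for one subject at the sweep step.

    1-D marginals per time point support volume, energy and the default
    independent-selection FF/T2* means; the 2-D (pre-bin, post-bin) joint
    tables support the optional joint-selection mode.
    """

    step: float
    w_pre: np.ndarray  # (B,) per-timepoint selection weights per FF bin
    w_post: np.ndarray
    e_pre: np.ndarray  # (B,) energy kcal per bin, per timepoint
    e_post: np.ndarray
    ff_pre: np.ndarray  # (B,) weighted FF sums per bin
    ff_post: np.ndarray
    t2_pre: np.ndarray
    t2_post: np.ndarray
    jw: np.ndarray  # (B, B) joint weights over (pre bin, post bin)
    jff_pre: np.ndarray
    jff_post: np.ndarray
    jt2_pre: np.ndarray
    jt2_post: np.ndarray
    voxel_volume: float


def _aggregate_subject(s: SubjectData, step: float,
                       fat_energy: float = _FAT_ENERGY,
                       lean_energy: float = _LEAN_ENERGY) -> _SubjectAggregates:
    n_bins = int(round(100.0 / step))
    inside = (s.roi_pre.values > 0) | (s.roi_post.values > 0)
    ff_pre = s.ff_pre[inside]
    ff_post = s.ff_post[inside]
    t2_pre = s.t2_pre[inside]
    t2_post = s.t2_post[inside]
    wp = s.roi_pre.values[inside] * (s.roi_pre.values[inside] > 0)
    wq = s.roi_post.values[inside] * (s.roi_post.values[inside] > 0)
    bp = _bin_index(ff_pre, step, n_bins)
    bq = _bin_index(ff_post, step, n_bins)
    v = s.voxel_volume

    def marg(b, w):
        return np.bincount(b, weights=w, minlength=n_bins)

    energy_pre = wp * v * (ff_pre * fat_energy + (1 - ff_pre) * lean_energy)
    energy_post = wq * v * (ff_post * fat_energy + (1 - ff_post) * lean_energy)
    wj = np.minimum(wp, wq)
    flat = bp * n_bins + bq

    def joint(w):
        return np.bincount(flat, weights=w, minlength=n_bins * n_bins).reshape(n_bins, n_bins)

    return _SubjectAggregates(
        step=step,
        w_pre=marg(bp, wp), w_post=marg(bq, wq),
        e_pre=marg(bp, energy_pre), e_post=marg(bq, energy_post),
        ff_pre=marg(bp, wp * ff_pre), ff_post=marg(bq, wq * ff_post),
        t2_pre=marg(bp, wp * t2_pre), t2_post=marg(bq, wq * t2_post),
        jw=joint(wj), jff_pre=joint(wj * ff_pre), jff_post=joint(wj * ff_post),
        jt2_pre=joint(wj * t2_pre), jt2_post=joint(wj * t2_post),
        voxel_volume=v,
    )


def _range_sum_1d(cum: np.ndarray, i0: int, i1: int) -> float:
    """Sum of bins [i0, i1) from a prepended-zero cumulative sum."""
    return cum[i1] - cum[i0]


def threshold_sweep(subjects: list[SubjectData], quantity: str = "volume",
                    step: float = 1.0, lower_min: float = 30.0,
                    selection: str = "independent",
                    fat_energy: float = _FAT_ENERGY,
                    lean_energy: float = _LEAN_ENERGY) -> ThresholdGrid:
    """Cohort-mean post-minus-pre change for every (lower, upper) FF pair.

    ``quantity`` is one of ``volume`` (mL), ``ff`` (percent points),
    ``t2star`` (ms) or ``energy`` (kcal).  With the default
    ``selection="independent"`` each time point's voxel set is thresholded
    on its own map — voxels whose FF drops below the lower threshold leave
    the post-cooling set but remain in the thermoneutral one, which is
    what compresses the apparent FF change at high lower thresholds.
    ``selection="joint"`` restricts FF/T2* means to voxels passing at both
    time points (volume and energy always use independent sets; their
    voxel counts may differ by design).  Pairs with ``lower >= upper`` or
    ``lower < lower_min`` are invalid (NaN).
    """
    if quantity not in {"volume", "ff", "t2star", "energy"}:
        raise ValueError(f"unknown quantity {quantity!r}")
    if selection not in {"independent", "joint"}:
        raise ValueError(f"unknown selection mode {selection!r}")
    if 100.0 % step:
        raise ValueError("step must divide the FF range")
    lowers = np.arange(lower_min, 100.0, step)
    uppers = np.arange(lower_min + step, 100.0 + step / 2, step)
    delta = np.full((len(lowers), len(uppers)), np.nan)
    valid = np.zeros(delta.shape, dtype=bool)

    aggs = [_aggregate_subject(s, step, fat_energy, lean_energy) for s in subjects]
    joint_mode = quantity in ("ff", "t2star") and selection == "joint"
    per_subject = np.zeros(len(subjects))
    cum = lambda a: np.concatenate([[0.0], np.cumsum(a)])
    pre_tables, post_tables, wpre_tables, wpost_tables = [], [], [], []
    for agg in aggs:
        if joint_mode:
            ii = lambda m: np.pad(m, ((1, 0), (1, 0))).cumsum(0).cumsum(1)
            wpre_tables.append(ii(agg.jw))
            src_pre = agg.jff_pre if quantity == "ff" else agg.jt2_pre
            src_post = agg.jff_post if quantity == "ff" else agg.jt2_post
            pre_tables.append(ii(src_pre))
            post_tables.append(ii(src_post))
        else:
            names = {"volume": ("w_pre", "w_post"), "energy": ("e_pre", "e_post"),
                     "ff": ("ff_pre", "ff_post"), "t2star": ("t2_pre", "t2_post")}
            a, b = names[quantity]
            pre_tables.append(cum(getattr(agg, a)))
            post_tables.append(cum(getattr(agg, b)))
            wpre_tables.append(cum(agg.w_pre))
            wpost_tables.append(cum(agg.w_post))

    def box(ii_mat, i0, i1):
        return ii_mat[i1, i1] - ii_mat[i0, i1] - ii_mat[i1, i0] + ii_mat[i0, i0]

    for i, lo in enumerate(lowers):
        i0 = int(round(lo / step))
        for j, up in enumerate(uppers):
            if lo >= up:
                continue
            i1 = int(round(up / step))
            for k, agg in enumerate(aggs):
                if joint_mode:
                    w = box(wpre_tables[k], i0, i1)
                    if w > 0:
                        d = (box(post_tables[k], i0, i1)
                             - box(pre_tables[k], i0, i1)) / w
                    else:
                        d = np.nan
                elif quantity in ("volume", "energy"):
                    d = _range_sum_1d(post_tables[k], i0, i1) \
                        - _range_sum_1d(pre_tables[k], i0, i1)
                    if quantity == "volume":
                        d *= agg.voxel_volume / 1000.0
                else:
                    wp = _range_sum_1d(wpre_tables[k], i0, i1)
                    wq = _range_sum_1d(wpost_tables[k], i0, i1)
                    if wp > 0 and wq > 0:
                        d = _range_sum_1d(post_tables[k], i0, i1) / wq \
                            - _range_sum_1d(pre_tables[k], i0, i1) / wp
                    else:
                        d = np.nan
                if quantity == "ff" and np.isfinite(d):
                    d *= 100.0
                per_subject[k] = d
            delta[i, j] = np.nanmean(per_subject) if np.isfinite(per_subject).any() else np.nan
            valid[i, j] = True

    return ThresholdGrid(quantity=quantity, lowers=lowers, uppers=uppers,
                         delta=delta, valid=valid & np.isfinite(delta))
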