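"""Threshold segmentation, volume accounting, sweeps and paired statistics."""

import numpy as np
import pandas as pd
import pytest

from batmri.core import RoiMask, ThresholdRange
from batmri.global_analysis import (SubjectData, binned_volume_change,
                                    depot_summary, estimated_volume,
                                    paired_stats, segment_joint,
                                    threshold_sweep, volume_histogram)

from conftest import box_roi


def random_subject(rng, shape=(16, 16, 16), voxel_volume=1.0):
    roi = RoiMask(values=np.ones(shape), voxel_volume=voxel_volume)
    return SubjectData(ff_pre=rng.random(shape), ff_post=rng.random(shape),
                       t2_pre=10 + 10 * rng.random(shape),
                       t2_post=10 + 10 * rng.random(shape),
                       roi_pre=roi, roi_post=roi)


class TestSegmentJoint:
    def test_vacuous_threshold_selects_all(self, rng):
        shape = (8, 8, 4)
        roi = box_roi(shape)
        ff = 0.005 + 0.99 * rng.random(shape)
        seg = segment_joint(ff, ff, roi, roi, ThresholdRange(0, 100))
        assert np.array_equal(seg.pre_mask, roi.values > 0)
        assert np.array_equal(seg.joint_mask, roi.values > 0)

    def test_direct_threshold_rule(self):
        ff = np.array([[[0.20, 0.40, 0.80]]])
        roi = RoiMask(values=np.ones((1, 1, 3)), voxel_volume=1.0)
        seg = segment_joint(ff, ff, roi, roi, ThresholdRange(30, 100))
        assert list(seg.pre_mask[0, 0]) == [False, True, True]

    def test_matches_brute_force_loop(self, rng):
        shape = (16, 16, 16)
        ff_pre, ff_post = rng.random(shape), rng.random(shape)
        w = rng.random(shape)
        roi = RoiMask(values=w, voxel_volume=1.0)
        r = ThresholdRange(30, 80)
        seg = segment_joint(ff_pre, ff_post, roi, roi, r)
        for _ in range(200):
            i, j, k = rng.integers(0, 16, 3)
            in_pre = w[i, j, k] > 0 and 30 <= ff_pre[i, j, k] * 100 <= 80
            in_post = w[i, j, k] > 0 and 30 <= ff_post[i, j, k] * 100 <= 80
            assert seg.pre_mask[i, j, k] == in_pre
            assert seg.joint_mask[i, j, k] == (in_pre and in_post)
            if in_pre and in_post:
                assert seg.joint_weights[i, j, k] == w[i, j, k]

    def test_inclusive_bounds(self):
        ff = np.array([[[0.30, 0.999999, 1.0]]])
        roi = RoiMask(values=np.ones((1, 1, 3)), voxel_volume=1.0)
        seg = segment_joint(ff, ff, roi, roi, ThresholdRange(30, 100))
        assert seg.pre_mask.all()

    def test_nested_monotonicity(self, rng):
        shape = (12, 12, 6)
        ff = rng.random(shape)
        roi = RoiMask(values=np.ones(shape), voxel_volume=1.0)
        prev = -1.0
        for lo in (70, 50, 30, 10):
            seg = segment_joint(ff, ff, roi, roi, ThresholdRange(lo, 100))
            n = seg.pre_weights.sum()
            assert n >= prev
            prev = n


class TestEstimatedVolume:
    def test_worked_example(self):
        assert round(estimated_volume(93275, 0.548)) == 51

    @pytest.mark.parametrize("n,v,expected", [(0, 0.548, 0.0), (1000, 1.0, 1.0)])
    def test_unit_conversion(self, n, v, expected):
        assert estimated_volume(n, v) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            estimated_volume(-1, 1.0)


class TestVolumeHistogram:
    def test_delta_distribution(self):
        shape = (5, 5, 4)
        roi = RoiMask(values=np.ones(shape), voxel_volume=1.0)
        ff = np.full(shape, 0.55)
        edges, vols = volume_histogram(ff, roi, bin_width=0.5)
        nz = np.flatnonzero(vols)
        assert len(nz) == 1
        assert edges[nz[0]] == 55.0
        assert vols[nz[0]] == 100 * 1.0 / 1000.0

    def test_single_bin_conserves_total(self, rng):
        shape = (6, 6, 3)
        roi = RoiMask(values=np.ones(shape), voxel_volume=0.548)
        ff = rng.random(shape)
        _, vols = volume_histogram(ff, roi, bin_width=100.0)
        assert len(vols) == 1
        assert np.isclose(vols[0], estimated_volume(ff.size, 0.548))

    def test_matches_brute_force(self, rng):
        shape = (16, 16, 16)
        w = rng.random(shape)
        roi = RoiMask(values=w, voxel_volume=1.0)
        ff = rng.random(shape)
        edges, vols = volume_histogram(ff, roi, bin_width=0.5)
        for b in rng.integers(0, len(vols), 15):
            lo, hi = edges[b] / 100, edges[b + 1] / 100
            sel = (ff >= lo) & ((ff < hi) if b < len(vols) - 1 else (ff <= hi))
            expected = w[sel & (w > 0)].sum() / 1000.0
            assert np.isclose(vols[b], expected)

    def test_bars_sum_to_segmented_volume(self, rng):
        shape = (12, 12, 6)
        w = rng.random(shape)
        roi = RoiMask(values=w, voxel_volume=0.548)
        ff = rng.random(shape)
        _, vols = volume_histogram(ff, roi, 0.5, ff_range=(30, 100))
        seg = segment_joint(ff, ff, roi, roi, ThresholdRange(30, 100))
        assert np.isclose(vols.sum(), estimated_volume(seg.pre_weights.sum(), 0.548))


class TestPairedStats:
    def test_identical_pairs(self):
        r = paired_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.mean_diff == 0 and r.p == 1.0 and r.degenerate

    def test_three_pair_closed_form(self):
        # d = [1, 3, 2]: mean 2, sd 1, t = 2 / (1/sqrt(3)) = 2*sqrt(3)
        pre = np.array([10.0, 11.0, 12.0])
        post = pre + np.array([1.0, 3.0, 2.0])
        r = paired_stats(pre, post)
        assert np.isclose(r.t, 2 * np.sqrt(3))
        assert np.isclose(r.mean_diff, 2.0)

    def test_constant_shift_equivariance(self, rng):
        pre = rng.random(6)
        r = paired_stats(pre, pre + 1.0)
        assert np.isclose(r.mean_diff, 1.0)
        assert r.degenerate  # zero-variance differences flagged, not p=0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_stats([1, 2], [1, 2, 3])


class TestBinnedVolumeChange:
    def test_null_cohort(self, rng):
        subjects = [random_subject(rng) for _ in range(3)]
        subjects = [SubjectData(s.ff_pre, s.ff_pre, s.t2_pre, s.t2_pre,
                                s.roi_pre, s.roi_pre) for s in subjects]
        df = binned_volume_change(subjects)
        assert np.allclose(df.mean_delta_ml, 0)
        assert (df.p == 1.0).all() and df.degenerate.all()

    def test_single_subject_descriptive_only(self, rng):
        with pytest.warns(UserWarning, match="fewer than 2"):
            df = binned_volume_change([random_subject(rng)])
        assert "p" not in df.columns


class TestThresholdSweep:
    def test_identical_inputs_zero_grid(self, rng):
        s = random_subject(rng)
        null = SubjectData(s.ff_pre, s.ff_pre, s.t2_pre, s.t2_pre, s.roi_pre, s.roi_pre)
        for qty in ("volume", "ff", "t2star", "energy"):
            grid = threshold_sweep([null], qty, step=5.0)
            assert np.nanmax(np.abs(grid.delta[grid.valid])) == 0

    def test_invalid_pairs_flagged(self, rng):
        grid = threshold_sweep([random_subject(rng)], "volume", step=10.0)
        for i, lo in enumerate(grid.lowers):
            for j, up in enumerate(grid.uppers):
                assert grid.valid[i, j] == (lo < up)
        assert grid.lowers.min() == 30.0

    def test_matches_brute_force_loops(self, rng):
        s = random_subject(rng)
        grid_v = threshold_sweep([s], "volume", step=10.0)
        grid_f = threshold_sweep([s], "ff", step=10.0)
        for lo, up in ((30, 100), (50, 90), (70, 80)):
            i = list(grid_v.lowers).index(lo)
            j = list(grid_v.uppers).index(up)
            # brute force: bins are [lo, up) except up=100 which is closed
            inc = (lambda f: (f * 100 >= lo) & ((f * 100 < up) if up < 100
                                                else (f * 100 <= up)))
            d_vol = (inc(s.ff_post).sum() - inc(s.ff_pre).sum()) / 1000.0
            assert np.isclose(grid_v.delta[i, j], d_vol)
            d_ff = (s.ff_post[inc(s.ff_post)].mean()
                    - s.ff_pre[inc(s.ff_pre)].mean()) * 100
            assert np.isclose(grid_f.delta[i, j], d_ff)

    def test_joint_selection_mode(self, rng):
        s = random_subject(rng)
        grid = threshold_sweep([s], "ff", step=10.0, selection="joint")
        i = list(grid.lowers).index(30)
        j = list(grid.uppers).index(100)
        sel_pre = s.ff_pre * 100 >= 30
        sel_post = s.ff_post * 100 >= 30
        joint = sel_pre & sel_post
        expected = (s.ff_post[joint].mean() - s.ff_pre[joint].mean()) * 100
        assert np.isclose(grid.delta[i, j], expected)

    def test_extremum_reporting(self, rng):
        grid = threshold_sweep([random_subject(rng)], "volume", step=10.0)
        lo, up, val = grid.extremum("min")
        assert val == np.nanmin(grid.delta[grid.valid])
        assert grid.valid[list(grid.lowers).index(lo), list(grid.uppers).index(up)]


def test_depot_summary_volume_identity(rng):
    shape = (10, 10, 5)
    w = rng.random(shape)
    roi = RoiMask(values=w, voxel_volume=0.548)
    ff = rng.random(shape)
    t2 = 15 + rng.random(shape)
    summ = depot_summary(ff, t2, roi, ThresholdRange(30, 100), "thermoneutral")
    assert np.isclose(summ.vol_bat, summ.n_voxels * 0.548 / 1000)
    assert 0 <= summ.ff_glob <= 100
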