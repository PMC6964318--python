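"""FF → fat/lean volume, mass, and metabolizable energy conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from batmri.core import RoiMask, ThresholdRange
from batmri.global_analysis import SubjectData
from batmri.mass_energy import (CompositionConstants, depot_totals,
                                energy_threshold_grid, mass_volume_r2,
                                voxel_composition)


class TestVoxelComposition:
    def test_half_fat_voxel_partitions_evenly(self):
        c = voxel_composition(0.5, 1.0)
        assert c.fat_volume == 0.5 and c.lean_volume == 0.5

    def test_pure_fat_mass_and_energy(self):
        c = voxel_composition(1.0, 1.0)
        assert np.isclose(c.fat_mass, 0.92)
        assert np.isclose(c.fat_energy, 9.4e-3)
        assert c.lean_mass == 0 and c.lean_energy == 0

    def test_half_fat_masses_from_densities(self):
        c = voxel_composition(0.5, 1.0)
        assert np.isclose(c.fat_mass, 0.5 * 0.92)   # 0.46 mg
        assert np.isclose(c.lean_mass, 0.5 * 1.06)  # 0.53 mg

    def test_out_of_range_ff_rejected(self):
        with pytest.raises(ValueError):
            voxel_composition(1.2, 1.0)
        with pytest.raises(ValueError):
            voxel_composition(-0.1, 1.0)

    def test_constants_validated(self):
        with pytest.raises(ValueError):
            CompositionConstants(fat_density=0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(ff=st.floats(0, 1), v=st.floats(0.1, 10))
    def test_volume_partition_exact(self, ff, v):
        c = voxel_composition(ff, v)
        assert np.isclose(c.fat_volume + c.lean_volume, v, rtol=1e-12)


class TestDepotTotals:
    def test_pure_fat_depot(self):
        shape = (10, 10, 10)
        roi = RoiMask(values=np.ones(shape), voxel_volume=1.0)
        ff = np.ones(shape)
        tab = depot_totals(ff, roi, ThresholdRange(0, 100))
        total = tab.loc["total"]
        assert np.isclose(total.fat_mass_g, 0.92)  # 1000 voxels x 0.92 mg
        assert np.isclose(total.fat_energy_kcal, 9.4)
        assert np.isclose(total.total_energy_kcal, 9.4)

    def test_fat_free_depot_energy_is_lean_only(self):
        shape = (6, 6, 3)
        roi = RoiMask(values=np.ones(shape), voxel_volume=1.0)
        tab = depot_totals(np.zeros(shape), roi, ThresholdRange(0, 100))
        total = tab.loc["total"]
        assert total.fat_energy_kcal == 0
        assert np.isclose(total.total_energy_kcal, total.lean_energy_kcal)

    def test_matches_brute_force_sum(self, rng):
        shape = (16, 16, 16)
        w = rng.random(shape)
        roi = RoiMask(values=w, voxel_volume=0.548)
        ff = rng.random(shape)
        r = ThresholdRange(30, 100)
        tab = depot_totals(ff, roi, r)
        sel = (ff * 100 >= 30) & (ff * 100 <= 100) & (w > 0)
        fat_ul = (w[sel] * ff[sel] * 0.548).sum()
        lean_ul = (w[sel] * (1 - ff[sel]) * 0.548).sum()
        total = tab.loc["total"]
        assert np.isclose(total.fat_volume_ul, fat_ul)
        assert np.isclose(total.lean_volume_ul, lean_ul)
        assert np.isclose(total.fat_mass_g, fat_ul * 0.92 / 1000)
        assert np.isclose(total.total_energy_kcal,
                          fat_ul * 9.4e-3 + lean_ul * 1.0e-3)

    def test_bins_sum_to_total(self, rng):
        shape = (12, 12, 6)
        roi = RoiMask(values=np.ones(shape), voxel_volume=1.0)
        ff = rng.random(shape)
        tab = depot_totals(ff, roi, ThresholdRange(30, 100))
        bins = tab.drop(index="total")
        for col in ("fat_volume_ul", "lean_volume_ul", "total_energy_kcal"):
            assert np.isclose(bins[col].sum(), tab.loc["total", col])

    def test_volume_partition_invariant(self, rng):
        shape = (10, 10, 5)
        w = rng.random(shape)
        roi = RoiMask(values=w, voxel_volume=0.548)
        ff = rng.random(shape)
        r = ThresholdRange(40, 90)
        tab = depot_totals(ff, roi, r)
        sel = r.contains(ff * 100) & (w > 0)
        analyzed = (w[sel] * 0.548).sum()
        total = tab.loc["total"]
        assert np.isclose(total.fat_volume_ul + total.lean_volume_ul, analyzed)

    def test_empty_segmentation_warns(self):
        shape = (6, 6, 3)
        roi = RoiMask(values=np.ones(shape), voxel_volume=1.0)
        with pytest.warns(UserWarning, match="empty segmentation"):
            tab = depot_totals(np.zeros(shape), roi, ThresholdRange(90, 100))
        assert tab.loc["total", "total_energy_kcal"] == 0

    def test_fat_energy_dominance(self, rng):
        # fat carries 9.4x the energy density of lean tissue, so any depot
        # with mean FF >= 0.3 stores >= 80% of its energy as lipid
        shape = (8, 8, 4)
        roi = RoiMask(values=np.ones(shape), voxel_volume=1.0)
        for _ in range(5):
            ff = np.clip(0.3 + 0.7 * rng.random(shape), 0, 1)
            assert ff.mean() >= 0.3
            tab = depot_totals(ff, roi, ThresholdRange(0, 100))
            total = tab.loc["total"]
            assert total.fat_energy_kcal / total.total_energy_kcal >= 0.8


class TestEnergyThresholdGrid:
    def test_identical_inputs_zero_grid(self, rng):
        shape = (10, 10, 5)
        roi = RoiMask(values=np.ones(shape), voxel_volume=1.0)
        ff = rng.random(shape)
        s = SubjectData(ff, ff, ff, ff, roi, roi)
        grid = energy_threshold_grid([s], step=10.0)
        assert np.nanmax(np.abs(grid.delta[grid.valid])) == 0

    def test_grid_consistent_with_depot_totals(self, rng):
        shape = (12, 12, 6)
        roi = RoiMask(values=np.ones(shape), voxel_volume=0.548)
        ff_pre, ff_post = rng.random(shape), rng.random(shape)
        s = SubjectData(ff_pre, ff_post, ff_pre, ff_post, roi, roi)
        grid = energy_threshold_grid([s], step=10.0)
        i = list(grid.lowers).index(30)
        j = list(grid.uppers).index(100)
        r = ThresholdRange(30, 100)
        e_pre = depot_totals(ff_pre, roi, r).loc["total", "total_energy_kcal"]
        e_post = depot_totals(ff_post, roi, r).loc["total", "total_energy_kcal"]
        assert np.isclose(grid.delta[i, j], e_post - e_pre)

    def test_custom_constants_thread_through(self, rng):
        shape = (8, 8, 4)
        roi = RoiMask(values=np.ones(shape), voxel_volume=1.0)
        ff_pre, ff_post = rng.random(shape), rng.random(shape)
        s = SubjectData(ff_pre, ff_post, ff_pre, ff_post, roi, roi)
        doubled = CompositionConstants(fat_energy=2 * 9.4e-3, lean_energy=2e-3)
        g1 = energy_threshold_grid([s], step=10.0)
        g2 = energy_threshold_grid([s], step=10.0, constants=doubled)
        assert np.allclose(g2.delta[g2.valid], 2 * g1.delta[g1.valid])


class TestMassVolumeRegression:
    def test_collinear_points_r2_one(self):
        vol = np.array([10.0, 20, 30, 40])
        slope, intercept, r2 = mass_volume_r2(vol, 0.9 * vol + 1.0)
        assert np.isclose(slope, 0.9) and np.isclose(intercept, 1.0)
        assert np.isclose(r2, 1.0)

    def test_noise_only_r2_near_zero(self, rng):
        vol = np.linspace(10, 50, 40)
        mass = rng.standard_normal(40)
        *_, r2 = mass_volume_r2(vol, mass)
        assert r2 < 0.1

    def test_five_point_closed_form(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 2.8, 4.1, 4.9, 6.2])
        slope, intercept, r2 = mass_volume_r2(x, y)
        # closed-form OLS on the same numbers
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        syy = ((y - y.mean()) ** 2).sum()
        assert np.isclose(slope, sxy / sxx)
        assert np.isclose(intercept, y.mean() - slope * x.mean())
        assert np.isclose(r2, sxy ** 2 / (sxx * syy))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            mass_volume_r2([1, 2], [1, 2])
        with pytest.raises(ValueError):
            mass_volume_r2([3, 3, 3], [1, 2, 3])
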