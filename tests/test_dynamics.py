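"""Tumor volumetry, growth slopes, progression masks, radial profiles."""

import numpy as np
import pytest

from sonoquant.dynamics import (
    ProgressionProfile,
    TumorTrajectory,
    cohort_slope_comparison,
    growth_slope,
    infield_outfield_volumes,
    per_bin_cohort_test,
    progression_mask,
    radial_coverage_profile,
)
from sonoquant.geometry import (
    CylinderSpec,
    VoxelGrid,
    axial_distance_map,
    build_emitter_array,
    rasterize_cylinder_rois,
    tube_shell_masks,
)


@pytest.fixture(scope="module")
def field_setting(array):
    grid = VoxelGrid.isotropic((72, 72, 86), 1.0, (-35.63, -35.63, -0.87))
    margin_rois = rasterize_cylinder_rois(array, grid, CylinderSpec(margin_mm=5.0))
    brain = np.ones(grid.shape, dtype=bool)
    return grid, margin_rois, brain


class TestInfieldOutfield:
    def test_containment_extremes(self, field_setting):
        grid, rois, brain = field_setting
        inside = rois.mask(5) & (np.arange(grid.shape[2]) < 40)[None, None, :]
        vin, vout = infield_outfield_volumes(inside, rois, brain)
        assert vout == 0.0 and vin > 0
        outside = ~rois.any_mask
        outside[:, :, 40:] = False
        vin, vout = infield_outfield_volumes(outside, rois, brain)
        assert vin == 0.0 and vout > 0

    def test_sphere_straddling_boundary_conserves_volume(self, field_setting):
        grid, rois, brain = field_setting
        x = grid.voxel_centers()
        # 8 mL sphere centered on the edge of the field
        r = (3 * 8000 / (4 * np.pi)) ** (1 / 3)
        sphere = (((x - [29.3, 0, 40.0]) ** 2).sum(1) <= r * r).reshape(grid.shape)
        vin, vout = infield_outfield_volumes(sphere, rois, brain)
        total = sphere.sum() * grid.voxel_volume_mm3 / 1000.0
        assert vin + vout == pytest.approx(total, abs=1e-12)
        assert 0 < vin < total

    def test_random_masks_conserve_exactly(self, field_setting):
        grid, rois, brain = field_setting
        rng = np.random.default_rng(3)
        for _ in range(5):
            mask = rng.random(grid.shape) < 0.1
            vin, vout = infield_outfield_volumes(mask, rois, brain)
            assert vin + vout == pytest.approx(
                mask.sum() * grid.voxel_volume_mm3 / 1000.0, abs=1e-12
            )


def traj(times, infield, outfield=None, pid="p1", cohort="C"):
    infield = np.asarray(infield, float)
    if outfield is None:
        outfield = np.zeros_like(infield)
    return TumorTrajectory(
        patient_id=pid, cohort=cohort, times_months=np.asarray(times, float),
        infield_mL=infield, outfield_mL=np.asarray(outfield, float),
    )


class TestGrowthSlope:
    def test_exact_line(self):
        rate = growth_slope(traj([0, 1, 2, 3], [10, 12, 14, 16]))
        assert rate.slope_mL_per_month == pytest.approx(2.0)

    def test_constant_volumes(self):
        assert growth_slope(traj([0, 1, 2], [5, 5, 5])).slope_mL_per_month == pytest.approx(0.0, abs=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="2 time points"):
            growth_slope(traj([0.0], [5.0]))

    def test_ols_unbiased_under_symmetric_noise(self):
        rng = np.random.default_rng(0)
        slopes = []
        for _ in range(500):
            t = np.arange(5, dtype=float)
            v = np.maximum(5 + 2.31 * t + 0.3 * rng.standard_normal(5), 0)
            slopes.append(growth_slope(traj(t, v)).slope_mL_per_month)
        assert np.mean(slopes) == pytest.approx(2.31, abs=0.05)

    def test_shift_invariance_and_unit_scaling(self):
        t = [0, 1, 2, 4]
        v = np.array([3.0, 4.5, 5.1, 9.0])
        s0 = growth_slope(traj(t, v)).slope_mL_per_month
        s_shift = growth_slope(traj(t, v + 100.0)).slope_mL_per_month
        s_scale = growth_slope(traj(t, 2.5 * v)).slope_mL_per_month
        assert s_shift == pytest.approx(s0, abs=1e-9)
        assert s_scale == pytest.approx(2.5 * s0, rel=1e-12)


class TestCohortComparison:
    def test_identical_cohorts_p_one(self):
        out = cohort_slope_comparison(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert out["p_value"] == pytest.approx(1.0)

    def test_complete_separation_exact_p(self):
        # brute-force over C(6,3)=20 orderings: two extreme labelings
        out = cohort_slope_comparison(np.array([3.0, 4, 5]), np.array([0.0, 1, 2]))
        assert out["p_value"] == pytest.approx(2 / 20)
        assert out["median_C"] == 4.0 and out["median_D"] == 1.0

    def test_median_definition(self):
        out = cohort_slope_comparison(np.array([1.0, 2.31, 5.0]), np.array([1.0]))
        assert out["median_C"] == pytest.approx(2.31)


class TestProgressionMask:
    def test_identities(self):
        rng = np.random.default_rng(1)
        first = rng.random((20, 20, 20)) < 0.2
        assert not progression_mask(first, first).any()
        shell = rng.random((20, 20, 20)) < 0.1
        grown = first | shell
        np.testing.assert_array_equal(progression_mask(first, grown), shell & ~first)
        last = rng.random((20, 20, 20)) < 0.2
        mask = progression_mask(first, last)
        assert mask.sum() == last.sum() - (last & first).sum()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            progression_mask(np.zeros((4, 4, 4), bool), np.zeros((5, 4, 4), bool))


@pytest.fixture(scope="module")
def shells_setting(array):
    grid = VoxelGrid.isotropic((72, 72, 80), 1.0, (-35.63, -35.63, 0.13))
    dmap = axial_distance_map(array, grid, max_length_mm=75.0)
    edges = np.array([0.0, 2.5, 5.0, 7.5, 10.0])
    return dmap, tube_shell_masks(dmap, edges), edges


class TestRadialCoverage:
    def test_full_and_empty_masks(self, shells_setting):
        dmap, shells, edges = shells_setting
        full = radial_coverage_profile(
            np.ones(dmap.grid.shape, bool), shells, edges
        )
        np.testing.assert_allclose(full.coverage, 1.0)
        empty = radial_coverage_profile(
            np.zeros(dmap.grid.shape, bool), shells, edges
        )
        np.testing.assert_allclose(empty.coverage, 0.0)

    def test_inner_tube_fixture(self, shells_setting):
        dmap, shells, edges = shells_setting
        mask = dmap.radial_mm < 5.0
        prof = radial_coverage_profile(mask, shells, edges)
        np.testing.assert_allclose(prof.coverage[:2], 1.0)
        np.testing.assert_allclose(prof.coverage[2:], 0.0)

    def test_empty_shell_flagged_nan(self, shells_setting):
        dmap, _, _ = shells_setting
        edges = np.array([200.0, 300.0])
        shells = tube_shell_masks(dmap, edges)
        prof = radial_coverage_profile(
            np.zeros(dmap.grid.shape, bool), shells, edges
        )
        assert np.isnan(prof.coverage[0])


def profile(cov, edges, pid, cohort):
    return ProgressionProfile(
        patient_id=pid, cohort=cohort, bin_edges_mm=edges, coverage=np.asarray(cov)
    )


class TestPerBinTest:
    edges = np.array([0.0, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0])

    def test_identical_cohorts_all_p_one(self):
        profs = [profile([0.3] * 6, self.edges, f"p{i}", "C") for i in range(4)]
        profs_d = [profile([0.3] * 6, self.edges, f"q{i}", "D") for i in range(4)]
        out = per_bin_cohort_test(profs, profs_d)
        np.testing.assert_allclose(out["p_raw"], 1.0)

    def test_single_bin_complete_separation(self):
        edges = np.array([0.0, 5.0])
        c = [profile([v], edges, f"p{i}", "C") for i, v in enumerate((0.5, 0.6, 0.7))]
        d = [profile([v], edges, f"q{i}", "D") for i, v in enumerate((0.1, 0.2, 0.3))]
        out = per_bin_cohort_test(c, d)
        assert out["p_raw"][0] == pytest.approx(0.1)

    def test_near_axis_suppression_detected_in_near_bins_only(self):
        # generative model: cohort D coverage suppressed below 10 mm, the
        # cohorts identical in law beyond
        hits_near, hits_far = 0, 0
        n_seeds = 20
        for s in range(n_seeds):
            rng = np.random.default_rng(s)
            c = [
                profile(rng.uniform(0.2, 0.6, 6), self.edges, f"p{i}", "C")
                for i in range(14)
            ]
            d_cov = rng.uniform(0.2, 0.6, (12, 6))
            d_cov[:, :4] = rng.uniform(0.0, 0.08, (12, 4))  # bins below 10 mm
            d = [profile(d_cov[i], self.edges, f"q{i}", "D") for i in range(12)]
            out = per_bin_cohort_test(c, d)
            hits_near += (out["p_raw"][:4] < 0.05).all()
            hits_far += (out["p_raw"][4:] > 0.05).all()
        assert hits_near >= 0.9 * n_seeds
        assert hits_far >= 0.5 * n_seeds

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(5)
        c = [profile(rng.uniform(0, 1, 6), self.edges, f"p{i}", "C") for i in range(8)]
        d = [profile(rng.uniform(0, 1, 6), self.edges, f"q{i}", "D") for i in range(8)]
        out = per_bin_cohort_test(c, d, holm=True)
        assert np.all(out["p_holm"] >= out["p_raw"] - 1e-12)
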