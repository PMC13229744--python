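import numpy as np
import pytest

from dgcurve import (
    ROI,
    DoseGrid,
    PhantomSpec,
    compute_dvh,
    contour_volume_shoelace,
    dose_at_volume,
    gradient_index,
    make_sphere_phantom,
    paddick_ci,
    r50,
    structure_mask,
    summary_stats,
    volume_at_dose,
)
from dgcurve.dicom_io import Contour
from dgcurve.dvh import DVHCurve

from conftest import uniform_grid


def _grid_with(values: np.ndarray) -> DoseGrid:
    return DoseGrid(values=values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0))


def _square_roi(x0, x1, y0, y1, planes) -> ROI:
    verts = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)
    return ROI(name="sq", contours=[Contour(vertices=verts, z_mm=float(z)) for z in planes])


class TestStructureMask:
    def test_square_contour_counts_enclosed_centers(self):
        grid = uniform_grid(1.0, shape=(3, 20, 20))
        # voxel centres at integers 0..19; enclose centres 3..12 -> 10x10
        roi = _square_roi(2.5, 12.5, 2.5, 12.5, planes=[0.0])
        mask = structure_mask(grid, roi)
        assert mask[0].sum() == 100
        assert mask[1].sum() == 0

    def test_annulus_excludes_inner_region(self):
        grid = uniform_grid(1.0, shape=(1, 20, 20))
        outer = _square_roi(1.5, 16.5, 1.5, 16.5, planes=[0.0])
        inner = _square_roi(5.5, 10.5, 5.5, 10.5, planes=[0.0])
        roi = ROI(name="ann", contours=outer.contours + inner.contours)
        mask = structure_mask(grid, roi)
        assert mask.sum() == 15 * 15 - 5 * 5

    def test_sphere_roi_dice_against_analytic_occupancy(self):
        spec = PhantomSpec(spacing_mm=0.5, seed=7)
        bundle = make_sphere_phantom(spec)
        mask = structure_mask(bundle.dose, bundle.target)
        xs, ys, zs = bundle.dose.axis_coordinates()
        rr = np.sqrt(
            zs[:, None, None] ** 2 + ys[None, :, None] ** 2 + xs[None, None, :] ** 2
        )
        truth = rr <= spec.r0_mm
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.98

    def test_contour_far_from_any_slice_skipped(self, caplog):
        grid = uniform_grid(1.0, shape=(3, 10, 10))
        roi = _square_roi(1, 8, 1, 8, planes=[50.0])
        assert structure_mask(grid, roi).sum() == 0


class TestComputeDvh:
    def test_uniform_structure_is_step_function(self):
        grid = uniform_grid(10.0, shape=(4, 6, 6))
        mask = np.ones(grid.values.shape, dtype=bool)
        dvh = compute_dvh(grid, mask, name="u")
        pct_below, _ = volume_at_dose(dvh, 9.9)
        pct_above, _ = volume_at_dose(dvh, 10.1)
        assert pct_below == pytest.approx(100.0)
        assert pct_above == 0.0

    def test_curve_starts_at_total_volume(self):
        grid = uniform_grid(5.0, shape=(4, 4, 4))
        mask = np.ones(grid.values.shape, dtype=bool)
        dvh = compute_dvh(grid, mask)
        assert dvh.cumulative_mm3[0] == pytest.approx(64.0)
        assert (np.diff(dvh.cumulative_mm3) <= 0).all()

    def test_two_level_structure(self):
        values = np.full((2, 4, 4), 5.0)
        values[1] = 10.0
        grid = _grid_with(values)
        dvh = compute_dvh(grid, np.ones_like(values, dtype=bool))
        assert volume_at_dose(dvh, 4.0)[0] == pytest.approx(100.0)
        assert volume_at_dose(dvh, 7.5)[0] == pytest.approx(50.0, abs=0.1)

    def test_empty_mask_names_structure(self):
        grid = uniform_grid(5.0)
        with pytest.raises(ValueError, match="ghost"):
            compute_dvh(grid, np.zeros(grid.values.shape, bool), name="ghost")


class TestDoseAtVolume:
    def test_uniform_d95(self):
        grid = uniform_grid(10.0)
        dvh = compute_dvh(grid, np.ones(grid.values.shape, bool))
        assert dose_at_volume(dvh, 95.0) == pytest.approx(10.0, abs=0.02)

    def test_linear_ramp_d50_at_midpoint(self):
        values = np.linspace(0.0, 20.0, 4000).reshape((10, 20, 20))
        dvh = compute_dvh(_grid_with(values), np.ones(values.shape, bool))
        assert dose_at_volume(dvh, 50.0) == pytest.approx(10.0, abs=0.05)

    def test_two_level_d50_resolved_by_interpolation(self):
        # 50/50 at 5 and 10 Gy: the cumulative curve still shows 50% at the
        # 10 Gy bin edge, so D50 lands on 10 Gy
        values = np.full((2, 4, 4), 5.0)
        values[1] = 10.0
        dvh = compute_dvh(_grid_with(values), np.ones(values.shape, bool))
        assert dose_at_volume(dvh, 50.0) == pytest.approx(10.0, abs=0.02)

    def test_dx_vx_duality(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(2.0, 18.0, size=(8, 10, 10))
        dvh = compute_dvh(_grid_with(values), np.ones(values.shape, bool))
        for x in (10.0, 25.0, 50.0, 75.0, 90.0):
            d = dose_at_volume(dvh, x)
            back, _ = volume_at_dose(dvh, d)
            assert back == pytest.approx(x, abs=0.5)


class TestSummaryStats:
    def test_uniform(self):
        grid = uniform_grid(10.0)
        stats = summary_stats(compute_dvh(grid, np.ones(grid.values.shape, bool)))
        for key in ("mean_gy", "max_gy", "min_gy"):
            assert stats[key] == pytest.approx(10.0, abs=0.02)

    def test_ramp_mean_is_midpoint(self):
        values = np.linspace(0.0, 20.0, 4000).reshape((10, 20, 20))
        stats = summary_stats(compute_dvh(_grid_with(values), np.ones(values.shape, bool)))
        assert stats["mean_gy"] == pytest.approx(10.0, abs=0.05)

    def test_two_level_mean(self):
        values = np.full((2, 4, 4), 5.0)
        values[1] = 10.0
        stats = summary_stats(compute_dvh(_grid_with(values), np.ones(values.shape, bool)))
        assert stats["mean_gy"] == pytest.approx(7.5, abs=0.05)


class TestPaddickCI:
    def test_perfect_conformity(self):
        tv = np.zeros((6, 6, 6), bool)
        tv[1:5, 1:5, 1:5] = True
        assert paddick_ci(tv, tv, (1, 1, 1)) == pytest.approx(1.0)

    def test_piv_twice_tv(self):
        tv = np.zeros((6, 6, 8), bool)
        tv[1:5, 1:5, 1:3] = True
        piv = np.zeros_like(tv)
        piv[1:5, 1:5, 1:5] = True  # contains TV, twice the volume
        assert paddick_ci(tv, piv, (1, 1, 1)) == pytest.approx(0.5)

    def test_disjoint_masks_zero(self):
        tv = np.zeros((4, 4, 8), bool)
        piv = np.zeros_like(tv)
        tv[:, :, :3] = True
        piv[:, :, 5:] = True
        assert paddick_ci(tv, piv, (1, 1, 1)) == 0.0

    def test_empty_mask_errors(self):
        tv = np.zeros((3, 3, 3), bool)
        with pytest.raises(ValueError):
            paddick_ci(tv, np.ones_like(tv), (1, 1, 1))


class TestGradientIndexCubeLaw:
    @pytest.mark.parametrize("r0", [10.0, 20.0])
    def test_gi_matches_cube_law(self, r0):
        # fall-off chosen so the Rx -> 50% Rx distance is 3 mm
        spec = PhantomSpec(r0_mm=r0, d0_gy=20.0, g_gy_per_mm=20.0 / 6.0,
                           spacing_mm=0.5, low_frac=0.5, seed=7)
        dose = make_sphere_phantom(spec).dose
        gi = gradient_index(dose, 20.0)
        assert gi == pytest.approx((1 + 3.0 / r0) ** 3, rel=0.05)

    def test_degenerate_step_profile_gi_one(self):
        grid = uniform_grid(10.0)
        assert gradient_index(grid, 10.0) == 1.0

    def test_r50_uses_target_volume(self, sphere_bundle, sphere_spec):
        tv = contour_volume_shoelace(sphere_bundle.target)
        val = r50(sphere_bundle.dose, 13.0, tv)
        r_half = sphere_spec.isodose_radius(6.5)
        assert val == pytest.approx((r_half / sphere_spec.r0_mm) ** 3, rel=0.05)


class TestDvhConservation:
    def test_voxel_dvh_volume_matches_contour_volume(self):
        spec = PhantomSpec(spacing_mm=0.5, seed=7)
        bundle = make_sphere_phantom(spec)
        dvh = compute_dvh(bundle.dose, bundle.target)
        contour_vol = contour_volume_shoelace(bundle.target)
        assert dvh.volume_mm3 == pytest.approx(contour_vol, rel=0.02)


class TestClamping:
    def test_dx_beyond_support_clamps(self):
        dvh = DVHCurve(
            structure="s",
            bin_edges_cgy=np.array([0.0, 1.0, 2.0]),
            cumulative_mm3=np.array([100.0, 50.0, 0.0]),
        )
        assert dose_at_volume(dvh, 100.0) == 0.0  # full volume only at 0 dose
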