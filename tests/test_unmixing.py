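"""Per-pixel fits, saturation maps, ROI summaries and renders."""

import numpy as np
import pytest
from scipy import ndimage

from oximsi import (
    AcquisitionSpec,
    build_design,
    fit_pixel,
    make_phantom,
    reconstruct_rgb,
    register_bands,
    render_cube,
    render_sat_image,
    roi_summary,
    saturation_map,
    to_reflectance,
)
from oximsi.preprocess import ReflectanceCube
from oximsi.unmixing import MASK_GREY, UnmixingError, default_rgb_response


class TestFitPixel:
    def test_exact_linear_inversion(self, design):
        a = design.matrix @ np.array([0.6, 0.4, 0.0])
        fit = fit_pixel(a, design, nonneg=False)
        assert fit.c_oxy == pytest.approx(0.6, abs=1e-10)
        assert fit.c_deoxy == pytest.approx(0.4, abs=1e-10)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-10)

    def test_pure_oxyhemoglobin(self, design):
        a = design.matrix @ np.array([1.0, 0.0, 0.0])
        fit = fit_pixel(a, design)
        assert fit.c_oxy == pytest.approx(1.0, abs=1e-10)
        assert fit.c_deoxy == pytest.approx(0.0, abs=1e-10)

    def test_offset_column_absorbs_constants(self, design):
        base = design.matrix @ np.array([0.6, 0.4, 0.0])
        fit = fit_pixel(base + 0.2, design)
        assert fit.c_oxy == pytest.approx(0.6, abs=1e-10)
        assert fit.c_deoxy == pytest.approx(0.4, abs=1e-10)
        assert fit.offset == pytest.approx(0.2, abs=1e-10)

    def test_nonfinite_input_marked_invalid(self, design):
        a = np.full(design.matrix.shape[0], np.nan)
        assert not fit_pixel(a, design).valid

    def test_wrong_length_rejected(self, design):
        with pytest.raises(UnmixingError):
            fit_pixel(np.zeros(5), design)

    def test_matches_normal_equations_oracle_on_toy_problems(self):
        """Hand-computed normal-equations solution on ≤5-band toy designs."""
        from oximsi.spectra import WavelengthGrid, build_design

        rng = np.random.default_rng(42)
        for n_bands in (4, 5):
            g = WavelengthGrid(500.0 + 10.0 * np.arange(n_bands))
            oxy = rng.uniform(1.0, 5.0, n_bands)
            deoxy = rng.uniform(1.0, 5.0, n_bands)
            d = build_design(g, oxy=oxy, deoxy=deoxy)
            for _ in range(20):
                a = rng.normal(size=n_bands)
                x = d.matrix
                oracle = np.linalg.solve(x.T @ x, x.T @ a)
                fit = fit_pixel(a, d, nonneg=False)
                got = np.array([fit.c_oxy, fit.c_deoxy, fit.offset])
                np.testing.assert_allclose(got, oracle, atol=1e-10)

    def test_nonneg_matches_scipy_nnls(self, design):
        """Active-set enumeration agrees with scipy's NNLS when the offset is
        also constrained-free in both (offset happens to come out positive)."""
        from scipy.optimize import nnls

        rng = np.random.default_rng(3)
        for _ in range(50):
            # attenuations that push the unconstrained fit negative
            a = design.matrix @ np.array([0.02, -0.01, 0.3]) + rng.normal(
                0, 0.01, design.matrix.shape[0]
            )
            fit = fit_pixel(a, design)
            assert fit.c_oxy >= 0 and fit.c_deoxy >= 0
            ref, _ = nnls(design.matrix, a)
            if ref[2] > 1e-9:  # scipy constrains the offset too; only compare
                np.testing.assert_allclose(  # when that constraint is slack
                    [fit.c_oxy, fit.c_deoxy, fit.offset], ref, atol=1e-8
                )


class TestSaturationMap:
    def test_noiseless_forward_inverse_loop(self, truth, design, noiseless_cube):
        omap = saturation_map(noiseless_cube, design)
        err = np.abs(omap.sat - truth.sat_map)[omap.mask]
        assert err.max() < 1e-6

    def test_thb_recovered_and_scaled_equivariantly(self, design, grid):
        """Scaling THb by k scales fitted THb by k and leaves sat unchanged."""
        maps = []
        for k in (1.0, 3.0):
            # base THb kept low enough that 3x scaling stays above the
            # reflectance log floor
            t = make_phantom(
                (48, 48),
                {
                    "cornua_sat": 0.9,
                    "cornua_thb": 0.012 * k,
                    "background_thb": 0.004 * k,
                },
                seed=4,
            )
            acq = AcquisitionSpec(grid=grid, shot_noise=False, read_noise_sd=0.0)
            b = render_cube(t, design, acq)
            cube = to_reflectance(b.raw, b.white, b.dark, grid)
            maps.append(saturation_map(cube, design))
        m1, m3 = maps
        sel = m1.mask & m3.mask
        np.testing.assert_allclose(m3.thb[sel], 3.0 * m1.thb[sel], rtol=1e-6)
        np.testing.assert_allclose(m3.sat[sel], m1.sat[sel], atol=1e-9)

    def test_constant_attenuation_shift_leaves_sat_unchanged(
        self, design, noiseless_cube
    ):
        """Adding a constant to all bands lands in the offset column."""
        shifted = ReflectanceCube(
            noiseless_cube.grid,
            noiseless_cube.bands * 10 ** (-0.2),
            noiseless_cube.valid,
        )
        a = saturation_map(noiseless_cube, design)
        b = saturation_map(shifted, design)
        sel = a.mask & b.mask
        np.testing.assert_allclose(b.sat[sel], a.sat[sel], atol=1e-8)

    def test_bloodless_region_masked_not_nan_propagated(self, design, grid):
        t = make_phantom(
            (48, 48),
            {"cornua_thb": 0.04, "background_thb": 0.0, "thb_texture_rel": 0.0,
             "edge_smooth_px": 0.0},
            seed=0,
        )
        acq = AcquisitionSpec(grid=grid, shot_noise=False, read_noise_sd=0.0)
        b = render_cube(t, design, acq)
        cube = to_reflectance(b.raw, b.white, b.dark, grid)
        omap = saturation_map(cube, design)
        background = t.regions["background"]
        interior = ndimage.binary_erosion(background, iterations=2)
        assert not omap.mask[interior].any()
        assert np.isfinite(omap.sat[omap.mask]).all()

    def test_nonneg_saturation_always_in_unit_interval(self, design, grid, truth):
        acq = AcquisitionSpec(grid=grid, exposure_proxy=500.0, seed=8)
        b = render_cube(truth, design, acq)
        cube = to_reflectance(b.raw, b.white, b.dark, grid)
        omap = saturation_map(cube, design, nonneg=True)
        s = omap.sat[omap.mask]
        assert np.all((s >= 0) & (s <= 1))

    def test_unconstrained_out_of_range_pixels_masked_and_counted(
        self, design, grid, truth
    ):
        acq = AcquisitionSpec(grid=grid, exposure_proxy=200.0, seed=8)
        b = render_cube(truth, design, acq)
        cube = to_reflectance(b.raw, b.white, b.dark, grid)
        omap = saturation_map(cube, design, nonneg=False)
        assert omap.n_out_of_range > 0
        s = omap.sat[omap.mask]
        assert np.all((s >= 0) & (s <= 1))


class TestRoiSummary:
    def test_uniform_region_mean(self, design, grid):
        t = make_phantom(
            (48, 48), {"cornua_sat": 0.5, "sat_texture_sd": 0.0,
                       "edge_smooth_px": 0.0}, seed=0
        )
        acq = AcquisitionSpec(grid=grid, shot_noise=False, read_noise_sd=0.0)
        b = render_cube(t, design, acq)
        cube = to_reflectance(b.raw, b.white, b.dark, grid)
        omap = saturation_map(cube, design)
        s = roi_summary(omap, t.regions, select=["left_medial"])
        assert s.loc[0, "mean_sat"] == pytest.approx(0.5, abs=1e-9)

    def test_fully_masked_roi_flagged_undefined(self, truth, design, noiseless_cube):
        omap = saturation_map(noiseless_cube, design)
        empty = {"nowhere": np.zeros_like(truth.tissue_mask)}
        s = roi_summary(omap, empty)
        assert not s.loc[0, "defined"]
        assert np.isnan(s.loc[0, "mean_sat"])

    def test_unknown_label_lists_available(self, truth, design, noiseless_cube):
        omap = saturation_map(noiseless_cube, design)
        with pytest.raises(KeyError, match="left_medial"):
            roi_summary(omap, truth.regions, select=["no_such_site"])


class TestRenders:
    def test_flat_white_cube_maps_to_white(self, grid):
        n = len(grid)
        cube = ReflectanceCube(grid, np.ones((n, 8, 8)), np.ones((8, 8), bool))
        np.testing.assert_allclose(reconstruct_rgb(cube), 1.0)

    def test_black_cube_maps_to_black(self, grid):
        n = len(grid)
        cube = ReflectanceCube(grid, np.zeros((n, 8, 8)), np.ones((8, 8), bool))
        np.testing.assert_allclose(reconstruct_rgb(cube), 0.0)

    def test_monochromatic_response_selects_single_band(self, grid):
        n = len(grid)
        rng = np.random.default_rng(1)
        cube = ReflectanceCube(
            grid, rng.random((n, 8, 8)), np.ones((8, 8), bool)
        )
        resp = np.zeros((3, n))
        resp[:, list(grid.centers).index(620.0)] = 1.0
        img = reconstruct_rgb(cube, resp)
        np.testing.assert_allclose(img[..., 0], cube.bands[-1])

    def test_zero_response_rejected(self, grid):
        n = len(grid)
        cube = ReflectanceCube(grid, np.ones((n, 8, 8)), np.ones((8, 8), bool))
        with pytest.raises(UnmixingError):
            reconstruct_rgb(cube, np.zeros((3, n)))

    def test_default_response_covers_grid(self, grid):
        assert (default_rgb_response(grid).sum(axis=1) > 0).all()

    def test_saturation_color_scale_extremes_and_mask(self, design, noiseless_cube):
        from oximsi.unmixing import OxygenationMap

        sat = np.array([[0.0, 1.0], [0.5, np.nan]])
        mask = np.array([[True, True], [True, False]])
        omap = OxygenationMap(
            sat=sat, thb=np.ones((2, 2)), residual=np.zeros((2, 2)),
            mask=mask, thb_floor=0.0,
        )
        img = render_sat_image(omap)
        blue, red = img[0, 0], img[0, 1]
        assert blue[2] > blue[0]  # saturation 0 → blue end
        assert red[0] > red[2]    # saturation 1 → red end
        np.testing.assert_allclose(img[1, 1], MASK_GREY)
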