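"""Generator tests: hook response, rendering photometry, series designs,
paired S/NSB arms, photobleaching stacks, determinism."""

import numpy as np
import pytest

from lfaquant import (
    BindingModel,
    DomainError,
    GeometryError,
    OpticsConfig,
    SeriesDesign,
    SpotGeometry,
    hook_response,
    render_image,
    simulate_bleach_stack,
    simulate_dose_series,
    simulate_snsb_pair,
)
from lfaquant.dose_response import fit_linear


class TestHookResponse:
    def test_zero_concentration_gives_zero(self):
        binding = BindingModel(alpha=2.0, b=0.75, k_hook=100.0)
        assert hook_response(0.0, binding) == 0.0

    def test_negative_concentration_rejected(self):
        binding = BindingModel(alpha=1.0, b=1.0, k_hook=10.0)
        with pytest.raises(DomainError):
            hook_response(-1.0, binding)

    def test_low_dose_limit_is_power_law(self):
        binding = BindingModel(alpha=3.0, b=0.8, k_hook=1000.0)
        # where (c/k)^(2b) < 0.01 the hook correction is below 1%
        c = np.array([0.1, 1.0, 10.0])
        assert np.all((c / binding.k_hook) ** (2 * binding.b) < 0.01)
        np.testing.assert_allclose(
            hook_response(c, binding), binding.alpha * c**binding.b, rtol=0.01
        )

    def test_peak_at_hook_concentration_by_grid_search(self):
        # brute-force grid maximization oracle
        binding = BindingModel(alpha=1.0, b=1.0, k_hook=100.0)
        grid = np.linspace(0.0, 500.0, 50001)  # step 0.01, includes 100.0
        amps = hook_response(grid, binding)
        assert grid[np.argmax(amps)] == pytest.approx(100.0, abs=1e-9)

    def test_unimodal_rising_then_falling(self):
        binding = BindingModel(alpha=0.9, b=0.75, k_hook=6000.0)
        below = np.geomspace(1.0, 6000.0, 200)
        above = np.geomspace(6000.0, 1e6, 200)
        assert np.all(np.diff(hook_response(below, binding)) > 0)
        assert np.all(np.diff(hook_response(above, binding)) < 0)


class TestRenderImage:
    def test_blank_noiseless_is_exactly_background(self, noiseless_optics, disk_geometry):
        img = render_image(disk_geometry, 0.0, noiseless_optics, "fluorescence", seed=0)
        assert np.all(img.pixels == 20)

    def test_huge_amplitude_saturates_zone(self, noiseless_optics, disk_geometry):
        img = render_image(disk_geometry, 1e6, noiseless_optics, "fluorescence", seed=0)
        mask = disk_geometry.mask(noiseless_optics.height_px, noiseless_optics.width_px)
        assert np.all(img.pixels[:, :, 0][mask] == 255)

    @pytest.mark.parametrize("amplitude", [7.0, 50.0, 120.0])
    def test_photometric_conservation_noiseless_disk(
        self, noiseless_optics, disk_geometry, amplitude
    ):
        # total above-background DN equals amplitude x mask area (integer
        # amplitudes render exactly)
        img = render_image(disk_geometry, amplitude, noiseless_optics, "fluorescence")
        mask = disk_geometry.mask(noiseless_optics.height_px, noiseless_optics.width_px)
        total = float((img.pixels[:, :, 0].astype(float) - 20.0).sum())
        assert total == pytest.approx(amplitude * mask.sum(), abs=1e-9)

    def test_exposure_linearity_noiseless(self, noiseless_optics, disk_geometry):
        ref = noiseless_optics.reference_exposure_s
        img1 = render_image(disk_geometry, 40.0, noiseless_optics, "fluorescence", ref)
        img2 = render_image(disk_geometry, 40.0, noiseless_optics, "fluorescence", 2 * ref)
        above1 = (img1.pixels[:, :, 0].astype(float) - 20.0).sum()
        above2 = (img2.pixels[:, :, 0].astype(float) - 20.0).sum()
        assert above2 == pytest.approx(2.0 * above1, rel=1e-12)

    def test_other_channels_background_only(self, noiseless_optics, disk_geometry):
        img = render_image(disk_geometry, 50.0, noiseless_optics, "fluorescence")
        assert np.all(img.pixels[:, :, 1] == 20)
        assert np.all(img.pixels[:, :, 2] == 20)

    def test_absorbance_darkens_green_multiplicatively(self, noiseless_optics, disk_geometry):
        optics = OpticsConfig(
            width_px=96, height_px=64, background_dn=(30.0, 200.0, 30.0),
            read_noise_dn=0.0, reference_exposure_s=1.0 / 15.0,
        )
        img = render_image(disk_geometry, 0.5, optics, "absorbance")
        mask = disk_geometry.mask(64, 96)
        expected = np.rint(200.0 * 10.0**-0.5)
        assert np.all(img.pixels[:, :, 1][mask] == expected)
        assert np.all(img.pixels[:, :, 1][~mask] == 200)

    def test_absorbance_deficit_bounded_by_background(self, disk_geometry):
        # the generative basis of the compressed gold dynamic range:
        # no amplitude can remove more light than the background provides
        optics = OpticsConfig(
            width_px=96, height_px=64, background_dn=(30.0, 180.0, 30.0),
            read_noise_dn=0.0, reference_exposure_s=1.0 / 15.0,
        )
        mask = disk_geometry.mask(64, 96)
        for amplitude in [0.1, 1.0, 10.0, 1e4]:
            img = render_image(disk_geometry, amplitude, optics, "absorbance")
            deficit = (180.0 - img.pixels[:, :, 1].astype(float))[mask].sum()
            assert deficit <= 180.0 * mask.sum() + 1e-9

    def test_determinism_bit_identical(self, noisy_optics, disk_geometry):
        a = render_image(disk_geometry, 30.0, noisy_optics, "fluorescence", seed=42)
        b = render_image(disk_geometry, 30.0, noisy_optics, "fluorescence", seed=42)
        c = render_image(disk_geometry, 30.0, noisy_optics, "fluorescence", seed=43)
        assert np.array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_zone_outside_image_rejected(self, noiseless_optics):
        geom = SpotGeometry(center=(5, 5), radius_px=10.0)
        with pytest.raises(GeometryError):
            render_image(geom, 10.0, noiseless_optics, "fluorescence")

    def test_crescent_is_leading_edge_subset_of_disk(
        self, disk_geometry, crescent_geometry
    ):
        disk = disk_geometry.mask(64, 96)
        crescent = crescent_geometry.mask(64, 96)
        assert crescent.sum() < disk.sum()
        assert np.all(disk[crescent])  # subset
        # signal sits on the upstream (low-column) side
        cols = np.nonzero(crescent)[1]
        assert cols.max() <= crescent_geometry.center[1]


class TestDoseSeries:
    def test_four_fold_series_spans_printed_range(self):
        design = SeriesDesign(c_min=0.063, fold=4.0, n_points=10)
        concs = design.concentrations
        assert concs[0] == pytest.approx(0.063)
        assert concs[-1] == pytest.approx(0.063 * 4**9)  # 16,515.072 ng/mL
        assert concs[-1] == pytest.approx(16515.072)

    def test_two_fold_series_spans_printed_range(self):
        design = SeriesDesign(c_min=630.0, fold=2.0, n_points=7)
        concs = design.concentrations
        assert concs[-1] == pytest.approx(630.0 * 2**6)  # 40,320 ng/mL

    def test_image_and_truth_counts(self, noisy_optics, disk_geometry):
        design = SeriesDesign(c_min=1.0, fold=4.0, n_points=10, n_replicates=3,
                              exposure_s="auto")
        binding = BindingModel(alpha=0.9, b=0.75, k_hook=6000.0)
        images, truth = simulate_dose_series(
            design, binding, disk_geometry, noisy_optics, seed=7
        )
        assert len(images) == 30
        assert len(truth.per_image_amplitude) == 30

    def test_replicate_noise_is_mean_one(self, noisy_optics, disk_geometry):
        design = SeriesDesign(c_min=100.0, fold=2.0, n_points=3, n_replicates=400,
                              exposure_s=1.0 / 15.0)
        binding = BindingModel(alpha=1.0, b=1.0, k_hook=1e9)
        _, truth = simulate_dose_series(
            design, binding, disk_geometry, noisy_optics, seed=3, replicate_cv=0.10
        )
        amps = np.array(truth.per_image_amplitude).reshape(3, 400)
        means = amps.mean(axis=1)
        np.testing.assert_allclose(means, design.concentrations, rtol=0.03)

    def test_stack_determinism(self, noisy_optics, disk_geometry):
        design = SeriesDesign(c_min=10.0, fold=2.0, n_points=4, n_replicates=2,
                              exposure_s="auto")
        binding = BindingModel(alpha=1.0, b=0.75, k_hook=1e6)
        im1, t1 = simulate_dose_series(design, binding, disk_geometry, noisy_optics, seed=5)
        im2, t2 = simulate_dose_series(design, binding, disk_geometry, noisy_optics, seed=5)
        assert t1.per_image_amplitude == t2.per_image_amplitude
        for a, b in zip(im1, im2):
            assert np.array_equal(a.pixels, b.pixels)


class TestSnsbPair:
    def test_equal_slopes_give_equal_per_pixel_amplitude(
        self, noiseless_optics, disk_geometry
    ):
        design = SeriesDesign(c_min=630.0, fold=2.0, n_points=7, n_replicates=1,
                              exposure_s=1.0 / 15.0)
        spot, strip, truth = simulate_snsb_pair(
            design, true_snsb=1.0, nsb_slope=1e-4, geometry=disk_geometry,
            optics=noiseless_optics, seed=0, replicate_cv=0.0,
        )
        n = len(design.concentrations)
        spot_amps = truth.per_image_amplitude[:n]
        strip_amps = truth.per_image_amplitude[n:]
        np.testing.assert_allclose(spot_amps, strip_amps, rtol=1e-12)

    def test_generative_slope_ratio_recovered_from_truth_by_ols(
        self, noiseless_optics, disk_geometry
    ):
        # closed-form OLS on the noiseless generated truth amplitudes
        design = SeriesDesign(c_min=630.0, fold=2.0, n_points=7, n_replicates=1,
                              exposure_s=1.0 / 15.0)
        _, _, truth = simulate_snsb_pair(
            design, true_snsb=2.0, nsb_slope=1e-4, geometry=disk_geometry,
            optics=noiseless_optics, seed=0, replicate_cv=0.0,
        )
        c = np.asarray(truth.concentrations)
        n = c.size
        s_spot = fit_linear(c, np.asarray(truth.per_image_amplitude[:n])).slope
        s_strip = fit_linear(c, np.asarray(truth.per_image_amplitude[n:])).slope
        assert s_spot / s_strip == pytest.approx(2.0, rel=1e-12)

    def test_arm_sizes_match_design(self, noisy_optics, disk_geometry):
        design = SeriesDesign(c_min=630.0, fold=2.0, n_points=7, n_replicates=3,
                              exposure_s="auto")
        spot, strip, truth = simulate_snsb_pair(
            design, true_snsb=50.0, nsb_slope=5e-5, geometry=disk_geometry,
            optics=noisy_optics, seed=1,
        )
        assert len(spot) == len(strip) == 21
        assert len(truth.concentrations) == 7
        assert truth.true_snsb == 50.0

    def test_strip_arm_is_uniform_over_footprint(self, noiseless_optics, disk_geometry):
        from lfaquant.simulate import strip_footprint

        design = SeriesDesign(c_min=1000.0, fold=2.0, n_points=3, n_replicates=1,
                              exposure_s=1.0 / 15.0)
        _, strip, _ = simulate_snsb_pair(
            design, true_snsb=1.0, nsb_slope=0.05, geometry=disk_geometry,
            optics=noiseless_optics, seed=0, replicate_cv=0.0,
        )
        r0, r1, c0, c1 = strip_footprint(noiseless_optics)
        red = strip[0].pixels[:, :, 0].astype(float)
        inside = red[r0:r1, c0:c1]
        assert inside.std() == 0.0  # uniform elevation
        assert inside[0, 0] > 20.0
        assert red[0, 0] == 20.0  # off-strip margin stays at background


class TestBleachStack:
    def test_amplitude_halves_at_half_life(self, noiseless_optics, disk_geometry):
        _, truth = simulate_bleach_stack(
            100.0, 2000.0, [0.0, 2000.0], disk_geometry, noiseless_optics
        )
        assert truth.per_image_amplitude[1] == pytest.approx(50.0, rel=1e-12)

    def test_three_half_lives_is_one_eighth(self, noiseless_optics, disk_geometry):
        # t = 6,000 s at a 2,000 s half-life
        _, truth = simulate_bleach_stack(
            160.0, 2000.0, [0.0, 6000.0], disk_geometry, noiseless_optics
        )
        assert truth.per_image_amplitude[1] == pytest.approx(20.0, rel=1e-12)

    def test_zero_amplitude_gives_pure_background(self, noiseless_optics, disk_geometry):
        images, _ = simulate_bleach_stack(
            0.0, 1000.0, [0.0, 10.0, 20.0], disk_geometry, noiseless_optics
        )
        for img in images:
            assert np.all(img.pixels == 20)

    def test_invalid_inputs_rejected(self, noiseless_optics, disk_geometry):
        with pytest.raises(DomainError):
            simulate_bleach_stack(10.0, -5.0, [0.0, 1.0], disk_geometry, noiseless_optics)
        with pytest.raises(DomainError):
            simulate_bleach_stack(10.0, 5.0, [1.0, 1.0], disk_geometry, noiseless_optics)
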