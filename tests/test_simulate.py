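"""Scene generation, forward model and noise injection."""

from dataclasses import replace

import numpy as np
import pytest

from phasestain.qpi import OpticalConfig
from phasestain.simulate import (NoiseSpec, SceneSpec, TimeLapseSpec,
                                 add_phase_noise, chimerize, generate_scene,
                                 generate_timelapse, render_brightfield_stack,
                                 render_fluorescence)


class TestSceneSpec:
    def test_overlapping_phase_intervals_rejected(self):
        with pytest.raises(ValueError, match="strictly above"):
            SceneSpec(cell_phase_range_rad=(0.3, 1.5),
                      aggregate_phase_range_rad=(1.2, 2.0))

    def test_subpixel_aggregates_rejected(self):
        with pytest.raises(ValueError, match="3 pixels"):
            SceneSpec(aggregate_area_range_um2=(0.01, 30.0))

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(phase_noise_variance_rad2=-0.1)


class TestGenerateScene:
    def test_deterministic_given_seed(self):
        spec = SceneSpec(seed=7)
        a, b = generate_scene(spec), generate_scene(spec)
        np.testing.assert_array_equal(a.phase_map, b.phase_map)
        np.testing.assert_array_equal(a.aggregate_mask, b.aggregate_mask)
        np.testing.assert_array_equal(a.fluor_density, b.fluor_density)

    def test_different_seed_different_scene(self):
        a = generate_scene(SceneSpec(seed=1))
        b = generate_scene(SceneSpec(seed=2))
        assert not np.array_equal(a.phase_map, b.phase_map)

    def test_no_aggregates_flat_fluorescence(self):
        scene = generate_scene(SceneSpec(n_aggregates=0, seed=3))
        assert not scene.aggregate_mask.any()
        assert np.all(scene.fluor_density == scene.spec.diffuse_floor)

    def test_requested_counts_present(self, default_scene):
        assert len(default_scene.per_aggregate_truth) == default_scene.spec.n_aggregates

    def test_exact_area_control(self):
        """Fixed-area request lands within one pixel-area of the target."""
        spec = SceneSpec(aggregate_area_range_um2=(5.0, 5.0), n_aggregates=2,
                         seed=11)
        scene = generate_scene(spec)
        pa = spec.pixel_area_um2
        for truth in scene.per_aggregate_truth:
            # oracle: count mask pixels near the recorded centroid
            assert truth.area_um2 == pytest.approx(5.0, abs=pa)
        # truth areas must equal the mask pixel count exactly
        assert sum(t.area_um2 for t in scene.per_aggregate_truth) == pytest.approx(
            scene.aggregate_mask.sum() * pa, rel=1e-12)

    def test_truth_areas_within_requested_range(self, default_scene):
        lo, hi = default_scene.spec.aggregate_area_range_um2
        pa = default_scene.spec.pixel_area_um2
        for t in default_scene.per_aggregate_truth:
            assert lo - pa <= t.area_um2 <= hi + pa

    def test_infeasible_packing_raises(self):
        spec = SceneSpec(field_size_px=(64, 64), n_cells=1, n_aggregates=30,
                         aggregate_area_range_um2=(8.0, 8.0), seed=0)
        with pytest.raises(ValueError, match="infeasible packing"):
            generate_scene(spec)

    def test_fluorescence_higher_inside_aggregates(self, default_scene):
        inside = default_scene.fluor_density[default_scene.aggregate_mask]
        outside = default_scene.fluor_density[~default_scene.aggregate_mask]
        assert inside.min() > outside.max()
        assert outside.min() > 0  # diffuse pool everywhere

    def test_diffuse_fraction_honored(self, default_scene):
        f = default_scene.spec.diffuse_fluor_fraction
        mask = default_scene.aggregate_mask
        total = default_scene.fluor_density.sum()
        outside = default_scene.fluor_density[~mask].sum()
        assert outside / total == pytest.approx(f, rel=1e-6)

    def test_phase_bookkeeping_closes(self, default_scene):
        """Total phase = cell contribution + per-aggregate contributions.

        Gaussian smoothing redistributes but conserves the integral.
        """
        pa = default_scene.spec.pixel_area_um2
        agg = sum(t.mean_phase_rad * t.area_um2 / pa
                  for t in default_scene.per_aggregate_truth)
        expected = default_scene.cell_phase_integral + agg
        assert default_scene.phase_map.sum() == pytest.approx(expected, rel=1e-6)

    def test_core_shell_profile_two_levels(self):
        spec = SceneSpec(core_shell=True, boundary_sigma_px=0.0, seed=5,
                         n_aggregates=1)
        scene = generate_scene(spec)
        vals = np.unique(np.round(scene.phase_map[scene.aggregate_mask], 9))
        assert len(vals) == 2  # shell level and elevated core level


class TestTimelapse:
    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match=">= 3 frames"):
            TimeLapseSpec(n_frames=2)

    def test_pre_onset_frames_empty(self):
        spec = SceneSpec(seed=2, aggregate_area_range_um2=(3.0, 25.0))
        tl = TimeLapseSpec(n_frames=30, onset_frame=8, final_area_um2=20.0)
        frames = generate_timelapse(spec, tl)
        for i in range(tl.onset_frame):
            assert not frames[i].aggregate_mask.any()
            assert np.all(frames[i].fluor_density == spec.diffuse_floor)

    def test_area_follows_logistic_to_plateau(self):
        spec = SceneSpec(seed=2, aggregate_area_range_um2=(3.0, 25.0))
        tl = TimeLapseSpec(n_frames=60, onset_frame=10, growth_rate=0.15,
                           final_area_um2=20.0)
        frames = generate_timelapse(spec, tl)
        areas = [f.per_aggregate_truth[0].area_um2 if f.per_aggregate_truth else 0.0
                 for f in frames]
        # oracle: evaluate the logistic at the last frame time
        t_mid = 0.5 * (tl.onset_frame + tl.n_frames - 1) * tl.frame_interval_min
        t_end = (tl.n_frames - 1) * tl.frame_interval_min
        expected_end = tl.final_area_um2 / (
            1 + np.exp(-tl.growth_rate * (t_end - t_mid)))
        assert areas[-1] == pytest.approx(expected_end, rel=0.02)
        assert areas[-1] == pytest.approx(tl.final_area_um2, rel=0.05)
        assert np.all(np.diff(areas) >= 0)

    def test_final_area_outside_range_rejected(self):
        spec = SceneSpec(seed=2)  # default range (3, 30)
        with pytest.raises(ValueError, match="within the spec"):
            generate_timelapse(spec, TimeLapseSpec(final_area_um2=50.0))


class TestChimerize:
    def test_zero_fraction_is_identity(self, default_scene):
        donor = generate_scene(replace(default_scene.spec, seed=77))
        out = chimerize(default_scene, donor, fraction=0.0, seed=1)
        np.testing.assert_array_equal(out.phase_map, default_scene.phase_map)
        np.testing.assert_array_equal(out.aggregate_mask,
                                      default_scene.aggregate_mask)

    def test_half_fraction_halves_area(self, default_scene):
        donor = generate_scene(replace(default_scene.spec, seed=77))
        out = chimerize(default_scene, donor, fraction=0.5, seed=1)
        before = int(default_scene.aggregate_mask.sum())
        after = int(out.aggregate_mask.sum())
        assert after == pytest.approx(before / 2, abs=len(
            default_scene.per_aggregate_truth))

    def test_sector_removal_lowers_circularity(self, default_scene):
        from phasestain.quantify import aggregate_records
        donor = generate_scene(replace(default_scene.spec, seed=77))
        out = chimerize(default_scene, donor, fraction=0.4, seed=1)
        optics = OpticalConfig()
        before = aggregate_records(default_scene.aggregate_mask, optics=optics,
                                   min_area_um2=1.0)
        after = aggregate_records(out.aggregate_mask, optics=optics,
                                  min_area_um2=1.0)
        assert np.mean([r.circularity for r in after]) < np.mean(
            [r.circularity for r in before])

    def test_no_donor_aggregate_pixels_imported(self, default_scene):
        donor = generate_scene(replace(default_scene.spec, seed=77))
        out = chimerize(default_scene, donor, fraction=0.5, seed=1)
        removed = default_scene.aggregate_mask & ~out.aggregate_mask
        # spliced phase must come from donor background (below cell max)
        assert out.phase_map[removed].max() < \
            default_scene.spec.aggregate_phase_range_rad[0]


class TestRenderFluorescence:
    def test_zero_density_zero_image(self):
        scene = generate_scene(SceneSpec(n_aggregates=0, seed=3,
                                         diffuse_floor=0.0))
        img = render_fluorescence(scene, NoiseSpec(seed=0))
        assert np.all(img == 0)

    def test_high_photon_limit_converges(self, default_scene):
        img = render_fluorescence(default_scene,
                                  NoiseSpec(fluor_photon_scale=1e7, seed=0))
        np.testing.assert_allclose(img, default_scene.fluor_density, atol=5e-3)

    def test_pixel_mean_matches_expectation(self, default_scene):
        """Monte-Carlo oracle: sample mean within 3 standard errors."""
        y, x = np.argwhere(default_scene.aggregate_mask)[0]
        expected = default_scene.fluor_density[y, x]
        scale = 200.0
        draws = np.array([
            render_fluorescence(default_scene,
                                NoiseSpec(fluor_photon_scale=scale, seed=s))[y, x]
            for s in range(1000)])
        se = np.sqrt(expected / scale / len(draws))
        assert abs(draws.mean() - expected) < 3 * se

    def test_deterministic_given_seed(self, default_scene):
        a = render_fluorescence(default_scene, NoiseSpec(seed=5))
        b = render_fluorescence(default_scene, NoiseSpec(seed=5))
        np.testing.assert_array_equal(a, b)


class TestRenderBrightfield:
    def test_zero_phase_uniform_planes(self):
        scene = generate_scene(SceneSpec(n_cells=0, n_aggregates=0,
                                         cell_phase_range_rad=(0.0, 0.0), seed=0))
        stack = render_brightfield_stack(scene)
        np.testing.assert_allclose(stack.planes, 1.0, atol=1e-10)

    def test_energy_conserved_across_planes(self, default_scene):
        stack = render_brightfield_stack(default_scene)
        means = stack.planes.mean(axis=(1, 2))
        assert np.ptp(means) / means.mean() < 1e-6

    def test_focus_has_least_contrast(self, weak_phase_spec):
        from phasestain.simulate import generate_scene as gen
        scene = gen(weak_phase_spec)
        stack = render_brightfield_stack(scene)
        stds = stack.planes.std(axis=(1, 2))
        # central planes (closest to focus) show the least contrast
        assert min(stds[3], stds[4]) < stds[0]
        assert min(stds[3], stds[4]) < stds[7]

    def test_matches_independent_fresnel_propagator(self):
        """Oracle: an independently coded single-FFT Fresnel propagator."""
        h = w = 256
        px, lam = 0.111, 0.550
        yy, xx = np.mgrid[0:h, 0:w]
        from scipy.ndimage import gaussian_filter
        phase = gaussian_filter(
            0.1 * (((xx - 128) ** 2 + (yy - 128) ** 2) < 20 ** 2).astype(float), 12.0)
        spec = SceneSpec(field_size_px=(h, w), n_cells=0, n_aggregates=0,
                         cell_phase_range_rad=(0.0, 0.0), seed=0)
        scene = generate_scene(spec)
        scene.phase_map[:] = phase
        optics = OpticalConfig(n_planes=8)
        stack = render_brightfield_stack(scene, optics)

        fy = np.fft.fftfreq(h, px)[:, None]
        fx = np.fft.fftfreq(w, px)[None, :]
        f2 = fy ** 2 + fx ** 2
        spectrum = np.fft.fft2(np.exp(1j * phase))
        zs = (np.arange(8) - 3.5) * 0.350
        for j, z in enumerate(zs):
            fresnel = np.exp(1j * 2 * np.pi * z / lam) * np.exp(
                -1j * np.pi * lam * z * f2)
            ref = np.abs(np.fft.ifft2(spectrum * fresnel)) ** 2
            rms = np.sqrt(np.mean((stack.planes[j] - ref) ** 2))
            assert rms < 1e-6

    def test_nonpositive_plane_spacing_rejected(self, default_scene):
        with pytest.raises(ValueError):
            render_brightfield_stack(
                default_scene, OpticalConfig(plane_spacing_um=-0.1))


class TestAddPhaseNoise:
    def test_zero_variance_is_identity(self, default_scene):
        out = add_phase_noise(default_scene.phase_map,
                              NoiseSpec(phase_noise_variance_rad2=0.0))
        np.testing.assert_array_equal(out, default_scene.phase_map)

    def test_sample_variance_at_stress_level(self):
        """The 0.48 rad^2 stress level is realized within 2%."""
        base = np.zeros((512, 512))
        noisy = add_phase_noise(base, NoiseSpec(
            phase_noise_variance_rad2=0.48, seed=3))
        assert np.var(noisy) == pytest.approx(0.48, rel=0.02)

    def test_aggregate_only_leaves_outside_untouched(self, default_scene):
        out = add_phase_noise(
            default_scene.phase_map,
            NoiseSpec(phase_noise_variance_rad2=0.2, region="aggregate_only",
                      seed=1),
            aggregate_mask=default_scene.aggregate_mask)
        outside = ~default_scene.aggregate_mask
        np.testing.assert_array_equal(out[outside],
                                      default_scene.phase_map[outside])
        assert not np.array_equal(out[default_scene.aggregate_mask],
                                  default_scene.phase_map[default_scene.aggregate_mask])

    def test_aggregate_only_without_mask_rejected(self, default_scene):
        with pytest.raises(ValueError, match="mask"):
            add_phase_noise(default_scene.phase_map,
                            NoiseSpec(phase_noise_variance_rad2=0.2,
                                      region="aggregate_only"))
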