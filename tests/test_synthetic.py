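import numpy as np
import pytest

from nanofoci import (
    PlacementError,
    SceneParams,
    generate_scene,
    mask_area,
    render_frames,
    sample_localizations,
)


def _params(**kw):
    base = dict(seed=1)
    base.update(kw)
    return SceneParams(**base)


class TestGenerateScene:
    def test_empty_scene(self):
        scene = generate_scene(_params(n_foci=0, background_density_ch1=0.0))
        assert len(scene.positions_ch1) == 0

    def test_count_conservation_two_foci(self):
        scene = generate_scene(
            _params(n_foci=2, events_per_focus_ch1=300, background_density_ch1=0.0)
        )
        assert len(scene.positions_ch1) == 600
        assert scene.nucleus_mask.contains(
            scene.positions_ch1[:, 0], scene.positions_ch1[:, 1]
        ).all()

    def test_background_count_matches_poisson_oracle(self):
        # oracle: Poisson with mean density * mask area; 200 seeds
        counts = []
        area = None
        for seed in range(200):
            scene = generate_scene(
                _params(n_foci=0, background_density_ch1=50.0, seed=seed)
            )
            counts.append(len(scene.positions_ch1))
            area = mask_area(scene.nucleus_mask)
        expected = 50.0 * area
        tol = 3.0 * np.sqrt(expected) / np.sqrt(200)
        assert abs(np.mean(counts) - expected) <= tol

    def test_focus_positions_inside_nucleus_and_foci_mask_subset(self):
        scene = generate_scene(_params())
        focus_pts = scene.positions_ch1[scene.labels_ch1 >= 0]
        assert scene.nucleus_mask.contains(focus_pts[:, 0], focus_pts[:, 1]).all()
        assert not (scene.foci_mask.grid & ~scene.nucleus_mask.grid).any()

    def test_focus_separation_at_least_4_sigma(self):
        for seed in range(20):
            scene = generate_scene(_params(seed=seed))
            d = np.hypot(*(scene.focus_centers[0] - scene.focus_centers[1]))
            assert d >= 4 * scene.params.focus_sigma_nm

    def test_placement_failure_raises(self):
        with pytest.raises(PlacementError):
            generate_scene(
                _params(nucleus_radius_nm=100.0, focus_sigma_nm=80.0, n_foci=2)
            )

    def test_reproducible_bit_identical(self):
        a = generate_scene(_params(seed=99))
        b = generate_scene(_params(seed=99))
        np.testing.assert_array_equal(a.positions_ch1, b.positions_ch1)
        np.testing.assert_array_equal(a.positions_ch2, b.positions_ch2)
        np.testing.assert_array_equal(a.nucleus_mask.grid, b.nucleus_mask.grid)

    def test_foci_mask_covers_about_six_percent_of_nucleus(self):
        # default calibration: two macro-focus discs over a ~30 um^2 nucleus
        fracs = [
            mask_area(generate_scene(_params(seed=s)).foci_mask)
            / mask_area(generate_scene(_params(seed=s)).nucleus_mask)
            for s in range(5)
        ]
        assert 0.03 <= np.mean(fracs) <= 0.09

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            generate_scene(_params(coloc_fraction=1.5))
        with pytest.raises(ValueError):
            generate_scene(_params(focus_sigma_nm=-1.0))


class TestSampleLocalizations:
    def test_zero_noise_identity(self):
        params = _params(loc_error_ch1_nm=0.0, background_density_ch1=0.0)
        scene = generate_scene(params)
        orte = sample_localizations(scene, 1, mean_blinks_per_emitter=1.0)
        np.testing.assert_allclose(orte.xy, scene.positions_ch1)

    def test_rms_noise_matches_gaussian_oracle(self):
        params = _params(
            n_foci=1, events_per_focus_ch2=10_000, background_density_ch2=0.0,
            loc_error_ch2_nm=15.0,
        )
        scene = generate_scene(params)
        orte = sample_localizations(scene, 2)
        resid = orte.xy - scene.positions_ch2[orte.data["emitter"]]
        rms = np.sqrt(np.mean(resid**2, axis=0))
        np.testing.assert_allclose(rms, 15.0, rtol=0.02)

    def test_loc_error_column_constant_17_for_channel1(self):
        scene = generate_scene(_params())
        orte = sample_localizations(scene, 1)
        assert (orte.data["loc_error_nm"] == 17.0).all()

    def test_blink_count_conservation(self):
        scene = generate_scene(_params(n_foci=1, background_density_ch1=0.0))
        orte = sample_localizations(scene, 1, mean_blinks_per_emitter=3.0)
        counts = orte.data["emitter"].value_counts()
        assert len(orte) == counts.sum()
        assert counts.min() >= 1  # geometric support

    def test_poisson_blinks_option(self):
        scene = generate_scene(_params(n_foci=1, background_density_ch1=0.0))
        orte = sample_localizations(
            scene, 1, mean_blinks_per_emitter=2.0, blink_distribution="poisson"
        )
        assert len(orte) > 0

    def test_focus_sigma_recovered_by_mle(self):
        params = _params(n_foci=1, events_per_focus_ch1=10_000,
                         background_density_ch1=0.0, loc_error_ch1_nm=0.0)
        scene = generate_scene(params)
        r = np.linalg.norm(scene.positions_ch1 - scene.focus_centers[0], axis=1)
        sigma_hat = np.sqrt(np.mean(r**2) / 2.0)  # ML estimate for 2D isotropic
        assert abs(sigma_hat - params.focus_sigma_nm) / params.focus_sigma_nm < 0.05


class TestRenderFrames:
    def test_zero_emitters_background_only(self, small_scene_params):
        scene = generate_scene(small_scene_params)
        stack = render_frames(
            scene, n_frames=20, background_photons=50.0, seed=3,
            positions=np.zeros((0, 2)), fov_nm=2000.0,
        )
        mean = stack.frames.mean()
        se = np.sqrt(50.0 / stack.frames.size)
        assert abs(mean - 50.0) <= 3 * se

    def test_peak_at_emitter(self, small_scene_params):
        scene = generate_scene(small_scene_params)
        pos = np.array([[950.0, 1250.0]])
        stack = render_frames(
            scene, n_frames=1, pixel_size_nm=100.0, photons_per_blink=1e6,
            background_photons=0.0, seed=1, positions=pos, poisson_noise=False,
            fov_nm=2000.0,
        )
        row, col = np.unravel_index(np.argmax(stack.frames[0]), stack.frames[0].shape)
        assert (row, col) == (12, 9)  # floor(1250/100), floor(950/100)

    def test_blink_allocation_bookkeeping(self, small_scene_params, rng):
        scene = generate_scene(small_scene_params)
        pos = 500 + 1000 * rng.random((100, 2))
        stack = render_frames(scene, n_frames=2000, seed=9, positions=pos, fov_nm=2000.0)
        gt = stack.ground_truth
        assert len(gt) == 100
        assert gt["frame"].between(0, 1999).all()

    def test_out_of_fov_clipped_with_warning(self, small_scene_params, caplog):
        scene = generate_scene(small_scene_params)
        pos = np.array([[50_000.0, 50_000.0], [500.0, 500.0]])
        with caplog.at_level("WARNING"):
            render_frames(scene, n_frames=5, seed=2, positions=pos, fov_nm=2000.0)
        assert any("clipped" in r.message for r in caplog.records)
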