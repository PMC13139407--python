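"""Phantom generators and the acquisition (noise + background) model."""

import numpy as np
import pytest
from skimage.measure import label
from skimage.morphology import skeletonize

from clid3s.simulate import (
    AcquisitionConfig,
    DataError,
    SimulationParameterError,
    generate_bead_pair,
    generate_line_pair,
    generate_random_walk_structure,
    inject_noise,
    make_fixed_pattern_background,
    normalize_and_quantize,
    simulate_switching_series,
)
from clid3s.psf import bessel_psf


class TestRandomWalk:
    def test_zero_filaments_gives_empty_scene(self):
        gt = generate_random_walk_structure((64, 64), 0, seed=0)
        assert not gt.pixels.any()

    def test_determinism_under_seed(self):
        a = generate_random_walk_structure((96, 96), 4, seed=11)
        b = generate_random_walk_structure((96, 96), 4, seed=11)
        assert np.array_equal(a.pixels, b.pixels)
        c = generate_random_walk_structure((96, 96), 4, seed=12)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_component_count_and_curvature_bound(self):
        max_turn = 0.3
        gt = generate_random_walk_structure((256, 256), 5, max_turn_rad=max_turn, seed=5)
        assert gt.meta["n_placed"] == 5
        skel = skeletonize(gt.pixels > 0.05 * gt.pixels.max())
        assert label(skel, connectivity=2).max() == 5
        # independent path-walking oracle: per-step heading change
        for path in gt.meta["paths_px"]:
            steps = np.diff(np.asarray(path), axis=0)
            headings = np.arctan2(steps[:, 0], steps[:, 1])
            turns = np.diff(headings)
            turns = (turns + np.pi) % (2 * np.pi) - np.pi
            assert np.abs(turns).max() <= max_turn + 1e-9

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(shape=(0, 64)),
            dict(shape=(64, 64), pixel_nm=-1.0),
            dict(shape=(64, 64), max_turn_rad=0.0),
            dict(shape=(64, 64), n_filaments=-1),
        ],
    )
    def test_invalid_parameters(self, kwargs):
        kwargs.setdefault("n_filaments", 1)
        with pytest.raises(SimulationParameterError):
            generate_random_walk_structure(**kwargs)


class TestLinePair:
    def test_one_pixel_spacing_on_grid(self):
        gt = generate_line_pair(65.0, 2600.0, "vertical", 65.0, (64, 64))
        cols = np.where(gt.pixels.any(axis=0))[0]
        assert len(cols) == 2 and cols[1] - cols[0] == 1

    def test_zero_spacing_single_line_doubled(self):
        pair = generate_line_pair(0.0, 2600.0, "vertical", 65.0, (64, 64))
        single = generate_line_pair(130.0, 2600.0, "vertical", 65.0, (64, 64))
        assert pair.pixels.max() == pytest.approx(2.0 * single.pixels.max())

    @pytest.mark.parametrize("spacing", [130.0, 97.5, 60.0])
    def test_centre_of_mass_separation(self, spacing):
        # first-moment oracle on the raster, perpendicular to the lines
        gt = generate_line_pair(spacing, 2600.0, "vertical", 65.0, (64, 64))
        col = gt.pixels.sum(axis=0)
        x = (np.arange(64) + 0.5) * 65.0
        mid = (col * x).sum() / col.sum()
        left, right = col.copy(), col.copy()
        left[x >= mid] = 0
        right[x < mid] = 0
        sep = (right * x).sum() / right.sum() - (left * x).sum() / left.sum()
        assert sep == pytest.approx(spacing, abs=32.5)

    def test_spacing_exceeding_fov_rejected(self):
        with pytest.raises(SimulationParameterError):
            generate_line_pair(65.0 * 70, 2600.0, "vertical", 65.0, (64, 64))

    def test_horizontal_orientation(self):
        gt = generate_line_pair(195.0, 2600.0, "horizontal", 65.0, (64, 64))
        rows = np.where(gt.pixels.any(axis=1))[0]
        assert len(rows) == 2 and rows[1] - rows[0] == 3


class TestBeadPair:
    def test_out_of_fov_rejected(self):
        with pytest.raises(SimulationParameterError):
            generate_bead_pair(100.0, 65.0 * 100, 65.0, (64, 64))

    def test_fig_configuration_centroid_distance(self):
        # 100 nm beads, 126 nm apart: centroid distance within half a pixel
        gt = generate_bead_pair(100.0, 126.0, 65.0, (64, 64))
        x = (np.arange(64) + 0.5) * 65.0
        col = gt.pixels.sum(axis=0)
        mid = (col * x).sum() / col.sum()
        left, right = col.copy(), col.copy()
        left[x >= mid] = 0
        right[x < mid] = 0
        sep = (right * x).sum() / right.sum() - (left * x).sum() / left.sum()
        assert sep == pytest.approx(126.0, abs=32.5)

    def test_single_bead_centroid_at_centre(self):
        gt = generate_bead_pair(200.0, 300.0, 65.0, (64, 64), diameter2_nm=0.0)
        ys, xs = np.mgrid[0:64, 0:64]
        cx = (gt.pixels * xs).sum() / gt.pixels.sum()
        expected = (64 * 65.0 / 2 - 150.0) / 65.0 - 0.5  # first bead centre, px idx
        assert cx == pytest.approx(expected, abs=0.5)

    def test_flux_proportional_to_area(self):
        small = generate_bead_pair(100.0, 600.0, 65.0, (64, 64))
        big = generate_bead_pair(200.0, 600.0, 65.0, (64, 64))
        assert big.pixels.sum() / small.pixels.sum() == pytest.approx(4.0, rel=0.05)


class TestNormalizeQuantize:
    def test_linear_ramp_maps_to_range(self):
        ramp = np.linspace(0, 1, 256).reshape(16, 16)
        out = normalize_and_quantize(ramp)
        assert out.min() == 0.0 and out.max() == 255.0
        assert np.all(np.diff(out.ravel()) >= 0)

    def test_constant_maps_to_range_min(self):
        out = normalize_and_quantize(np.full((8, 8), 7.3), (0.0, 255.0))
        assert np.all(out == 0.0)

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        img = rng.random((32, 32)) * 90
        once = normalize_and_quantize(img)
        twice = normalize_and_quantize(once)
        assert np.array_equal(once, twice)

    def test_nan_rejected(self):
        img = np.ones((4, 4))
        img[0, 0] = np.nan
        with pytest.raises(DataError):
            normalize_and_quantize(img)


class TestInjectNoise:
    def test_noise_free_passthrough(self):
        cfg = AcquisitionConfig(poisson_lam=0.0, gaussian_std=0.0, seed=0)
        img = np.linspace(0, 255, 64).reshape(8, 8)
        out = inject_noise(img, cfg)
        step = cfg.quantization_step
        assert np.abs(out - img).max() <= step / 2 + 1e-12

    def test_determinism_under_seed(self):
        cfg = AcquisitionConfig(seed=9)
        img = np.full((64, 64), 100.0)
        assert np.array_equal(inject_noise(img, cfg), inject_noise(img, cfg))

    def test_noise_law_sqrt_lam_plus_var(self):
        # var(Poisson(5) + N(0,5)) = 5 + 25, so std = sqrt(30) ~ 5.477
        cfg = AcquisitionConfig(poisson_lam=5.0, gaussian_std=5.0, seed=1)
        img = np.full((1024, 1024), 128.0)
        out = inject_noise(img, cfg)
        assert out.std() == pytest.approx(np.sqrt(30.0), rel=0.05)

    def test_negative_parameters_rejected(self):
        with pytest.raises(SimulationParameterError):
            AcquisitionConfig(poisson_lam=-1.0)
        with pytest.raises(SimulationParameterError):
            AcquisitionConfig(gaussian_std=-0.1)


class TestSwitchingSeries:
    def test_frame_counts(self, psf65, filament_series):
        _gt, cfg, series = filament_series
        assert series.on_frames.shape[0] == cfg.frames_per_state == 50
        assert series.off_frames.shape == series.on_frames.shape
        assert series.on_frames.min() >= 0

    def test_mean_difference_recovers_blur_with_averaging_law(self, psf65):
        from clid3s.simulate import blur_structure, generate_line_pair

        gt = generate_line_pair(130.0, 2600.0, "vertical", 65.0, (64, 64))
        N = 50
        # constant background keeps both states away from the zero-clip
        cfg = AcquisitionConfig(
            seed=3, frames_per_state=N, background=np.full((64, 64), 100.0)
        )
        series = simulate_switching_series(gt, psf65, cfg)
        signal = blur_structure(gt, psf65, cfg)
        residual = series.on_frames.mean(axis=0) - series.off_frames.mean(axis=0) - signal
        expected = np.sqrt(30.0) * np.sqrt(2.0 / N)
        assert residual.std() == pytest.approx(expected, rel=0.10)

    def test_zero_structure_on_off_indistinguishable(self, psf65):
        from clid3s.simulate import StructureImage

        gt = StructureImage(np.zeros((48, 48)), 65.0)
        cfg = AcquisitionConfig(seed=4, frames_per_state=30)
        series = simulate_switching_series(gt, psf65, cfg)
        diff = series.on_frames.mean() - series.off_frames.mean()
        # two-sample mean comparison at ~5 sigma of the mean difference
        se = np.sqrt(2 * 30.0 / (30 * 48 * 48))
        assert abs(diff) < 5 * se

    def test_fixed_pattern_constant_across_frames(self, psf65):
        from clid3s.simulate import StructureImage

        bg = make_fixed_pattern_background((48, 48), seed=5)
        gt = StructureImage(np.zeros((48, 48)), 65.0)
        cfg = AcquisitionConfig(
            poisson_lam=0.0, gaussian_std=0.0, background=bg, seed=6, frames_per_state=5
        )
        series = simulate_switching_series(gt, psf65, cfg)
        assert series.on_frames.std(axis=0).max() == pytest.approx(0.0, abs=1e-12)

    def test_pitch_mismatch_rejected(self, psf65):
        from clid3s.simulate import StructureImage

        gt = StructureImage(np.zeros((48, 48)), 80.0)
        with pytest.raises(SimulationParameterError):
            simulate_switching_series(gt, psf65, AcquisitionConfig(seed=0))
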