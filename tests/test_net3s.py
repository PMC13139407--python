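"""Hybrid-loss denoiser: training-set construction, loss, training, inference."""

import math

import numpy as np
import pytest

from clid3s.denoise3s import s3_denoise
from clid3s.metrics import psnr
from clid3s.net3s import (
    Acquisition,
    NetworkSpec,
    TrainedDenoiser,
    TrainingSetSpec,
    UNet,
    build_noise_level_sets,
    denoise_frame,
    hybrid_loss,
    make_acquisition,
    sample_training_pair,
    select_lambda,
    train_denoiser,
)


class TestTrainingSetSpec:
    def test_k_exceeding_frames_rejected(self):
        with pytest.raises(ValueError):
            TrainingSetSpec(n_frames=10, k_levels=(1, 16))

    def test_selections_exceeding_combinations_rejected(self):
        # C(4, 2) = 6 < 50
        with pytest.raises(ValueError):
            TrainingSetSpec(n_frames=4, k_levels=(2,), selections_per_level=50)

    def test_default_grid_is_combinatorially_feasible(self):
        spec = TrainingSetSpec()
        for k in spec.k_levels:
            assert math.comb(spec.n_frames, k) >= spec.selections_per_level


class TestNoiseLevelSets:
    def test_k1_images_are_original_frames(self):
        rng = np.random.default_rng(0)
        stack = rng.random((10, 8, 8))
        spec = TrainingSetSpec(n_frames=10, k_levels=(1,), selections_per_level=5, seed=1)
        sets = build_noise_level_sets(stack, spec)
        for img, subset in zip(sets[1]["images"], sets[1]["subsets"]):
            assert len(subset) == 1
            assert np.array_equal(img, stack[subset[0]])

    def test_subsets_distinct_and_counts_match(self):
        rng = np.random.default_rng(1)
        stack = rng.random((12, 4, 4))
        spec = TrainingSetSpec(n_frames=12, k_levels=(2, 4), selections_per_level=20, seed=2)
        sets = build_noise_level_sets(stack, spec)
        for k in (2, 4):
            subsets = sets[k]["subsets"]
            assert len(subsets) == 20
            assert len(set(subsets)) == 20
            assert sets[k]["images"].shape == (20, 4, 4)

    def test_noise_scales_as_inverse_sqrt_k(self):
        # averaging variance law on a pure-noise stack
        rng = np.random.default_rng(2)
        sigma = 8.0
        stack = rng.normal(100.0, sigma, (50, 128, 128))
        spec = TrainingSetSpec(seed=3)
        sets = build_noise_level_sets(stack, spec)
        for k in spec.k_levels:
            measured = (sets[k]["images"] - 100.0).std()
            assert measured == pytest.approx(sigma / np.sqrt(k), rel=0.10)


class TestSampling:
    def test_pair_distinct_same_level_deterministic(self):
        rng = np.random.default_rng(3)
        stack = rng.random((10, 6, 6))
        spec = TrainingSetSpec(n_frames=10, k_levels=(2,), selections_per_level=8, seed=4)
        sets = build_noise_level_sets(stack, spec)
        gt = np.zeros((6, 6))
        p1 = sample_training_pair(sets, 2, gt, rng=5)
        p2 = sample_training_pair(sets, 2, gt, rng=5)
        assert not np.array_equal(p1.x, p1.y)
        assert p1.level == 2
        assert np.array_equal(p1.x, p2.x) and np.array_equal(p1.y, p2.y)

    def test_missing_level_and_short_level_rejected(self):
        sets = {2: {"images": np.zeros((1, 4, 4)), "subsets": [(0, 1)]}}
        with pytest.raises(ValueError):
            sample_training_pair(sets, 4, np.zeros((4, 4)))
        with pytest.raises(ValueError):
            sample_training_pair(sets, 2, np.zeros((4, 4)))


class TestHybridLoss:
    def test_zero_when_output_matches_everything(self):
        img = np.random.default_rng(4).random((8, 8))
        for lam in (0.0, 1.0, 7.0, float("inf")):
            assert hybrid_loss(img, img, img, lam) == pytest.approx(0.0)

    def test_lambda_zero_is_self_supervised_only(self):
        rng = np.random.default_rng(5)
        x_hat, y, gt = rng.random((8, 8)), rng.random((8, 8)), rng.random((8, 8))
        assert hybrid_loss(x_hat, y, gt, 0.0) == pytest.approx(np.mean((x_hat - y) ** 2))

    def test_lambda_inf_is_supervised_only(self):
        rng = np.random.default_rng(6)
        x_hat, y, gt = rng.random((8, 8)), rng.random((8, 8)), rng.random((8, 8))
        assert hybrid_loss(x_hat, y, gt, float("inf")) == pytest.approx(
            np.mean((x_hat - gt) ** 2)
        )

    def test_weighted_combination_arithmetic(self):
        # MSE(x,y)=4, MSE(x,gt)=1, lambda=1 -> (4 + 1)/2 = 2.5
        x_hat = np.zeros((2, 2))
        y = np.full((2, 2), 2.0)
        gt = np.full((2, 2), 1.0)
        assert hybrid_loss(x_hat, y, gt, 1.0) == pytest.approx(2.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hybrid_loss(np.zeros((2, 2)), np.zeros((2, 3)), np.zeros((2, 2)), 1.0)


def tiny_acquisition(seed=0, n_frames=6, size=32):
    rng = np.random.default_rng(seed)
    signal = rng.random((size, size)) * 100
    stack = signal + rng.normal(0, 5, (n_frames, size, size))
    spec = TrainingSetSpec(n_frames=n_frames, k_levels=(1, 2), selections_per_level=4, seed=seed)
    return make_acquisition(stack, signal, spec)


class TestTraining:
    def test_zero_epochs_returns_seeded_initial_network(self):
        acq = tiny_acquisition()
        spec = NetworkSpec(base_channels=4, n_scales=1)
        m = train_denoiser([acq], spec, lam=1.0, epochs=0, seed=9)
        ref = UNet(spec, seed=10)  # train_denoiser seeds the net with seed+1
        for a, b in zip(m.network.get_params(), ref.get_params()):
            assert np.array_equal(a, b)

    def test_identity_task_loss_collapses(self):
        # noise-free x = y = gt: the residual head can be driven to zero
        rng = np.random.default_rng(7)
        signal = rng.random((32, 32)) * 100
        stack = np.stack([signal] * 6)
        spec = TrainingSetSpec(n_frames=6, k_levels=(1, 2), selections_per_level=4, seed=0)
        acq = make_acquisition(stack, signal, spec)
        m = train_denoiser(
            [acq], NetworkSpec(4, 1), lam=1.0, epochs=8, seed=1,
            steps_per_epoch=25, patch=32, batch=2, lr=2e-3,
        )
        curve = m.training_record["loss_curve"]
        assert curve[-1] < 1e-2 * curve[0]

    def test_training_improves_heldout_psnr(self, filament_series, quick_denoiser):
        from clid3s.simulate import blur_structure

        gt, cfg, series = filament_series
        from clid3s.psf import bessel_psf

        signal = blur_structure(gt, bessel_psf(488.0, 1.49, 65.0), cfg)
        raw = series.on_frames[1]
        den = quick_denoiser.denoise(raw)
        assert psnr(den, signal) > psnr(raw, signal) + 3.0

    def test_lambda_positive_requires_ground_truth(self):
        acq = tiny_acquisition()
        broken = Acquisition(acq.sets, None)
        with pytest.raises(ValueError):
            train_denoiser([broken], NetworkSpec(4, 1), lam=1.0, epochs=1)


class TestSelectLambda:
    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_lambda([], [tiny_acquisition()], [])

    def test_stubbed_evaluator_argmax(self):
        table = {0.0: 20.0, 1.0: 25.0, 4.0: 23.0}
        acq = tiny_acquisition()

        def stub(model, frames):
            return table[model.training_record["lambda"]]

        best, scored, model = select_lambda(
            list(table), [acq], [], NetworkSpec(4, 1), seed=0, epochs=0, evaluator=stub
        )
        assert best == 1.0
        assert scored == table
        assert model.training_record["lambda"] == 1.0

    def test_exact_tie_returns_smallest_lambda(self):
        acq = tiny_acquisition()
        best, _, _ = select_lambda(
            [4.0, 0.0, 16.0], [acq], [], NetworkSpec(4, 1), seed=0, epochs=0,
            evaluator=lambda m, f: 30.0,
        )
        assert best == 0.0

    def test_single_candidate_returned_with_score(self):
        acq = tiny_acquisition()
        best, table, _ = select_lambda(
            [2.0], [acq], [], NetworkSpec(4, 1), seed=0, epochs=0,
            evaluator=lambda m, f: 17.5,
        )
        assert best == 2.0 and table == {2.0: 17.5}


class TestInference:
    def test_deterministic_nonnegative_same_shape(self, quick_denoiser):
        rng = np.random.default_rng(8)
        frame = rng.random((64, 64)) * 255
        a = quick_denoiser.denoise(frame)
        b = quick_denoiser.denoise(frame)
        assert np.array_equal(a, b)
        assert a.min() >= 0
        assert a.shape == frame.shape

    def test_frame_below_minimum_tile_rejected(self, quick_denoiser):
        with pytest.raises(ValueError):
            quick_denoiser.denoise(np.ones((2, 2)))

    def test_tiled_inference_matches_whole_frame(self, quick_denoiser):
        rng = np.random.default_rng(9)
        frame = rng.random((96, 96)) * 255
        whole = quick_denoiser.denoise(frame)
        tiled_model = TrainedDenoiser(
            quick_denoiser.network,
            quick_denoiser.normalization,
            quick_denoiser.training_record,
            tile_size=64,
            tile_overlap=32,
        )
        tiled = tiled_model.denoise(frame)
        # interior agreement; tile borders may differ by padding effects
        diff = np.abs(whole - tiled)[8:-8, 8:-8]
        assert diff.max() < 0.05 * whole.max()

    def test_denoise_frame_wraps_clear_image(self, quick_denoiser):
        frame = np.random.default_rng(10).random((64, 64)) * 255
        clear = denoise_frame(quick_denoiser, frame, pixel_nm=65.0)
        assert clear.pixel_nm == 65.0
        assert clear.provenance["reducer"] == "3Snet"

    def test_save_load_round_trip(self, quick_denoiser, tmp_path):
        path = tmp_path / "model.npz"
        quick_denoiser.save(str(path))
        loaded = TrainedDenoiser.load(str(path))
        frame = np.random.default_rng(11).random((64, 64)) * 255
        assert np.allclose(quick_denoiser.denoise(frame), loaded.denoise(frame))


class TestCrossStructureGeneralization:
    def test_filament_trained_model_improves_line_phantom(self, quick_denoiser):
        # structure-agnostic denoising: trained on filaments, still
        # improves pSNR on a line-pair field it never saw
        from clid3s.psf import bessel_psf
        from clid3s.simulate import (
            AcquisitionConfig,
            blur_structure,
            generate_line_pair,
            inject_noise,
            make_fixed_pattern_background,
        )

        psf = bessel_psf(488.0, 1.49, 65.0)
        gt = generate_line_pair(260.0, 3000.0, "vertical", 65.0, (64, 64))
        cfg = AcquisitionConfig(
            background=make_fixed_pattern_background((64, 64), seed=43), seed=50
        )
        signal = blur_structure(gt, psf, cfg)
        frame = inject_noise(signal, cfg)
        den = quick_denoiser.denoise(frame)
        assert psnr(den, signal) > psnr(frame, signal)


class TestDistributionPreservation:
    def test_denoised_intensity_regression_on_reference(self, filament_series, quick_denoiser):
        # per-pixel regression of denoised vs noise-free signal: slope ~1,
        # intercept small relative to the dynamic range
        from clid3s.psf import bessel_psf
        from clid3s.simulate import blur_structure

        gt, cfg, series = filament_series
        signal = blur_structure(gt, bessel_psf(488.0, 1.49, 65.0), cfg)
        den = quick_denoiser.denoise(series.on_frames[2])
        x = signal.ravel()
        y = den.ravel()
        slope, intercept = np.polyfit(x, y, 1)
        assert 0.9 <= slope <= 1.1
        assert abs(intercept) <= 0.05 * 255.0
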