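import numpy as np
import pytest

from clid3s.net3s import NetworkSpec, TrainingSetSpec, make_acquisition, train_denoiser
from clid3s.psf import bessel_psf
from clid3s.simulate import (
    AcquisitionConfig,
    generate_random_walk_structure,
    make_fixed_pattern_background,
    simulate_switching_series,
)
from clid3s.denoise3s import s3_denoise


@pytest.fixture(scope="session")
def psf65():
    """Reference Airy PSF: 488 nm emission, NA 1.49, 65 nm pitch."""
    return bessel_psf(488.0, 1.49, 65.0)


@pytest.fixture(scope="session")
def filament_series(psf65):
    """One simulated filament switching acquisition (64x64, 50 cycles)."""
    shape = (64, 64)
    gt = generate_random_walk_structure(shape, 5, seed=42, length_nm=3000.0)
    cfg = AcquisitionConfig(
        background=make_fixed_pattern_background(shape, seed=43),
        seed=42,
        frames_per_state=50,
    )
    return gt, cfg, simulate_switching_series(gt, psf65, cfg)


@pytest.fixture(scope="session")
def filament_bench():
    """The seed-0 filament study (reducers + CLID comparisons), shared
    between the property-suite and cross-agreement tests."""
    from clid3s.validation import filament_benchmark

    return filament_benchmark(seed=0)


@pytest.fixture(scope="session")
def quick_denoiser(filament_series):
    """A small denoiser trained briefly on one acquisition (supervised)."""
    _gt, _cfg, series = filament_series
    spec = TrainingSetSpec(n_frames=50, seed=7)
    acq = make_acquisition(series.on_frames, s3_denoise(series), spec)
    return train_denoiser(
        [acq],
        NetworkSpec(base_channels=8, n_scales=2),
        lam=float("inf"),
        epochs=10,
        seed=7,
        steps_per_epoch=40,
        patch=48,
        batch=4,
        lr=2e-3,
    )
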