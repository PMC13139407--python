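"""Clear-image deconvolution (CLID): upsampling + Richardson-Lucy.

The reconstruction core upsamples a denoised ("clear") image onto a finer
computational grid — by default 3x Lanczos — and then sharpens it with
Richardson-Lucy (RL) deconvolution against the Airy PSF regenerated
analytically at the upsampled pitch. The finer grid does not add signal
content; it stabilizes RL's large gain near the optical cutoff.

RL iterates the multiplicative Poisson maximum-likelihood update

    e_{k+1} = e_k * [ PSF* (x) ( d / (PSF (x) e_k + eps) ) ]

(PSF* is the mirrored kernel, (x) convolution). Two update schedules are
provided: the plain update above, which conserves total flux at every
iteration, and Biggs-Andrews vector extrapolation (the default, and the
default of the standard MATLAB deconvlucy implementation), which reaches a
given contrast in several-fold fewer iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy.signal import fftconvolve

from clid3s.denoise3s import ClearImage
from clid3s.psf import PSFModel, resample_psf

Interpolator = Literal["lanczos", "linear", "bicubic", "fourier"]


@dataclass(frozen=True)
class CLIDConfig:
    """Reconstruction parameters with the study defaults."""

    upsample_factor: int = 3
    interpolator: Interpolator = "lanczos"
    lanczos_a: int = 3
    rl_iterations: int = 1000
    epsilon: float | None = None  # default: 1e-12 * image max
    boundary: str = "reflect"
    accelerated: bool = True

    def __post_init__(self) -> None:
        if self.upsample_factor < 1:
            raise ValueError("upsample_factor must be >= 1")
        if self.rl_iterations < 0:
            raise ValueError("rl_iterations must be >= 0")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


# ---------------------------------------------------------------------------
# upsampling
# ---------------------------------------------------------------------------


def lanczos_kernel(x: np.ndarray, a: int = 3) -> np.ndarray:
    """Windowed sinc: sinc(x) sinc(x/a) on |x| < a, else 0."""
    x = np.asarray(x, dtype=float)
    out = np.sinc(x) * np.sinc(x / a)
    out[np.abs(x) >= a] = 0.0
    return out


def _linear_kernel(x: np.ndarray) -> np.ndarray:
    return np.clip(1.0 - np.abs(x), 0.0, None)


def _bicubic_kernel(x: np.ndarray, a: float = -0.5) -> np.ndarray:
    # Keys' cubic (Catmull-Rom for a = -0.5)
    ax = np.abs(np.asarray(x, dtype=float))
    out = np.zeros_like(ax)
    m1 = ax <= 1
    m2 = (ax > 1) & (ax < 2)
    out[m1] = (a + 2) * ax[m1] ** 3 - (a + 3) * ax[m1] ** 2 + 1
    out[m2] = a * (ax[m2] ** 3 - 5 * ax[m2] ** 2 + 8 * ax[m2] - 4)
    return out


def _resample_matrix(n_in: int, factor: int, kernel: Callable[[np.ndarray], np.ndarray], support: int) -> np.ndarray:
    """Dense 1-D interpolation matrix mapping n_in -> n_in * factor samples.

    Output pixel centres sit at (j + 0.5)/factor - 0.5 in input pixel
    coordinates. Rows are normalized to unit sum so constants are
    preserved; source indices are clamped at the borders (edge
    replication).
    """
    n_out = n_in * factor
    pos = (np.arange(n_out) + 0.5) / factor - 0.5
    W = np.zeros((n_out, n_in))
    for o, p in enumerate(pos):
        i0 = int(np.floor(p)) - support + 1
        idx = np.arange(i0, i0 + 2 * support)
        w = kernel(p - idx)
        idx = np.clip(idx, 0, n_in - 1)
        for i, wi in zip(idx, w):
            W[o, i] += wi
    W /= W.sum(axis=1, keepdims=True)
    return W


def _fourier_upsample(image: np.ndarray, factor: int) -> np.ndarray:
    """Zero-pad the discrete spectrum (periodic sinc interpolation)."""
    H, W = image.shape
    F = np.fft.fftshift(np.fft.fft2(image))
    H2, W2 = H * factor, W * factor
    out = np.zeros((H2, W2), dtype=complex)
    y0, x0 = (H2 - H) // 2, (W2 - W) // 2
    out[y0 : y0 + H, x0 : x0 + W] = F
    up = np.fft.ifft2(np.fft.ifftshift(out)).real * factor**2
    return up


def upsample(
    image: np.ndarray,
    factor: int,
    interpolator: Interpolator = "lanczos",
    lanczos_a: int = 3,
) -> np.ndarray:
    """Resample onto a ``factor``-times finer grid."""
    image = np.asarray(image, dtype=float)
    if factor < 1 or factor != int(factor):
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return image.copy()
    if interpolator == "fourier":
        return _fourier_upsample(image, factor)
    if interpolator == "lanczos":
        kernel, support = (lambda x: lanczos_kernel(x, lanczos_a)), lanczos_a
    elif interpolator == "linear":
        kernel, support = _linear_kernel, 1
    elif interpolator == "bicubic":
        kernel, support = _bicubic_kernel, 2
    else:
        raise ValueError(f"unknown interpolator {interpolator!r}")
    Wr = _resample_matrix(image.shape[0], factor, kernel, support)
    Wc = _resample_matrix(image.shape[1], factor, kernel, support)
    return Wr @ image @ Wc.T


# ---------------------------------------------------------------------------
# Richardson-Lucy
# ---------------------------------------------------------------------------


def _conv_same(image: np.ndarray, kernel: np.ndarray, boundary: str) -> np.ndarray:
    """FFT convolution with boundary padding by one kernel radius."""
    r = kernel.shape[0] // 2
    if boundary == "none" or r == 0:
        return fftconvolve(image, kernel, mode="same")
    padded = np.pad(image, r, mode=boundary)
    return fftconvolve(padded, kernel, mode="same")[r:-r, r:-r]


def rl_deconvolve(
    image: np.ndarray,
    psf: PSFModel,
    iterations: int = 1000,
    epsilon: float | None = None,
    boundary: str = "reflect",
    accelerated: bool = True,
    pixel_nm: float | None = None,
) -> np.ndarray:
    """Richardson-Lucy deconvolution of a nonnegative image.

    ``iterations = 0`` returns the input. ``pixel_nm``, when given, is
    checked against the PSF grid pitch. With ``accelerated=False`` the
    plain multiplicative update is used, which conserves total flux
    exactly (to FFT round-off) for a unit-sum PSF and an object supported
    away from the borders.
    """
    image = np.asarray(image, dtype=float)
    if image.min() < -1e-9 * max(abs(image).max(), 1.0):
        raise ValueError("RL requires a nonnegative input image")
    image = np.clip(image, 0.0, None)  # tolerate FFT round-off dust
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if pixel_nm is not None and not np.isclose(pixel_nm, psf.pixel_nm, rtol=1e-6):
        raise ValueError(f"image pitch {pixel_nm} nm != PSF pitch {psf.pixel_nm} nm")
    if iterations == 0 or image.max() == 0:
        return image.copy()
    kernel = psf.kernel
    kernel_m = kernel[::-1, ::-1]
    eps = epsilon if epsilon is not None else 1e-12 * image.max()

    def update(est: np.ndarray) -> np.ndarray:
        conv = _conv_same(est, kernel, boundary)
        out = est * _conv_same(image / (conv + eps), kernel_m, boundary)
        np.clip(out, 0.0, None, out=out)
        return out

    if not accelerated:
        est = image.copy()
        for _ in range(iterations):
            est = update(est)
        return est

    # Biggs-Andrews vector extrapolation: predict y_k = x_k + alpha (x_k -
    # x_{k-1}) with alpha from the correlation of successive update steps,
    # then apply the plain update at the predicted point.
    x = image.copy()
    x_prev: np.ndarray | None = None
    g: np.ndarray | None = None
    g_prev: np.ndarray | None = None
    for _ in range(iterations):
        if x_prev is not None and g_prev is not None:
            den = float((g_prev * g_prev).sum())
            alpha = float((g * g_prev).sum()) / den if den > 0 else 0.0
            alpha = min(max(alpha, 0.0), 1.0 - 1e-6)
            y = np.clip(x + alpha * (x - x_prev), 0.0, None)
        else:
            y = x
        x_new = update(y)
        g_prev = g
        g = x_new - y
        x_prev, x = x, x_new
    return x


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def clid_pipeline(
    image: ClearImage | np.ndarray,
    psf: PSFModel,
    config: CLIDConfig = CLIDConfig(),
    denoiser: Callable[[np.ndarray], np.ndarray] | None = None,
    return_stages: bool = False,
) -> np.ndarray | tuple[np.ndarray, dict]:
    """Denoise (optional) -> upsample -> RL deconvolve.

    With a ``denoiser`` the input is a raw single frame that is first
    mapped to a clear image; otherwise the input is an already denoised
    :class:`ClearImage` (or plain array). The PSF must live on the input
    grid; it is regenerated analytically at the upsampled pitch before
    deconvolution.
    """
    if isinstance(image, ClearImage):
        pixels = image.pixels
        pixel_nm = image.pixel_nm
    else:
        pixels = np.asarray(image, dtype=float)
        pixel_nm = psf.pixel_nm
    stages: dict = {}
    if denoiser is not None:
        pixels = np.asarray(denoiser(pixels), dtype=float)
        stages["denoised"] = pixels
    pixels = np.clip(pixels, 0.0, None)
    up = upsample(pixels, config.upsample_factor, config.interpolator, config.lanczos_a)
    up = np.clip(up, 0.0, None)
    stages["upsampled"] = up
    psf_fine = resample_psf(psf, config.upsample_factor)
    sr = rl_deconvolve(
        up,
        psf_fine,
        iterations=config.rl_iterations,
        epsilon=config.epsilon,
        boundary=config.boundary,
        accelerated=config.accelerated,
        pixel_nm=pixel_nm / config.upsample_factor if pixel_nm else None,
    )
    stages["deconvolved"] = sr
    if return_stages:
        return sr, stages
    return sr
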