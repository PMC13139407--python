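"""Quantitative evaluation: pSNR, SSIM, uncertainty STD, FWHM, two-peak
distances and Fourier ring correlation.

Conventions
-----------
* pSNR uses the *theoretical* peak of the normalized scale (255 by
  default), not the empirical maximum; pass ``peak`` to override.
* SSIM is the standard windowed form (uniform 7x7 window, covariance in
  the numerator, C1 = (0.01 L)^2, C2 = (0.03 L)^2). A literal variant that
  replaces the covariance with the product of the window standard
  deviations is available via ``as_printed=True``.
* The uncertainty STD is reported in two forms: a mean-absolute-deviation
  style sum, sum |D - <D>| / (n - 1), and the conventional sample standard
  deviation; the two coincide only up to a distribution-dependent factor.
* FRC reads resolution at the first crossing of the 1/7 threshold, rings
  one frequency bin wide, no curve smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from skimage.metrics import structural_similarity
from scipy.ndimage import uniform_filter


@dataclass
class MetricsReport:
    """All metrics for one reconstruction against one reference."""

    psnr_db: float
    ssim: float
    uncertainty_std: float
    uncertainty_std_as_printed: float
    fwhm_nm: float | None = None
    peak_distance_nm: float | None = None
    frc_resolution_nm: float | None = None
    psnr_infinite: bool = False
    provenance: dict | None = None


def psnr(recon: np.ndarray, gt: np.ndarray, peak: float = 255.0) -> float:
    """10 log10(peak^2 / MSE) in dB; returns inf for identical images."""
    recon = np.asarray(recon, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if recon.shape != gt.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((gt - recon) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak**2 / mse)


def ssim(
    a: np.ndarray,
    b: np.ndarray,
    data_range: float | None = None,
    win_size: int = 7,
    as_printed: bool = False,
) -> float:
    """Windowed structural similarity averaged over the image."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if min(a.shape) < win_size:
        raise ValueError(f"image smaller than the {win_size}x{win_size} SSIM window")
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = hi - lo if hi > lo else 1.0
    if not as_printed:
        return float(
            structural_similarity(
                a, b, data_range=data_range, win_size=win_size, gaussian_weights=False
            )
        )
    # literal variant: product of window stds instead of the covariance
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mu_a = uniform_filter(a, win_size)
    mu_b = uniform_filter(b, win_size)
    var_a = np.clip(uniform_filter(a * a, win_size) - mu_a**2, 0.0, None)
    var_b = np.clip(uniform_filter(b * b, win_size) - mu_b**2, 0.0, None)
    sig_a, sig_b = np.sqrt(var_a), np.sqrt(var_b)
    smap = ((2 * mu_a * mu_b + c1) * (2 * sig_a * sig_b + c2)) / (
        (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    )
    r = win_size // 2
    return float(smap[r:-r, r:-r].mean())


class UncertaintySTD(NamedTuple):
    conventional: float
    as_printed: float


def uncertainty_std(noisy: np.ndarray, gt: np.ndarray) -> UncertaintySTD:
    """Spread of the difference image D = noisy - gt, in two conventions.

    ``as_printed`` is sum_xy |D - <D>| / (n - 1) (the square root applied
    inside the sum); ``conventional`` is the sample standard deviation
    sqrt(sum (D - <D>)^2 / (n - 1)). Both are invariant to adding a
    constant to either image.
    """
    noisy = np.asarray(noisy, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if noisy.shape != gt.shape:
        raise ValueError("shape mismatch")
    d = noisy - gt
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 pixels")
    centred = d - d.mean()
    as_printed = float(np.abs(centred).sum() / (n - 1))
    conventional = float(np.sqrt((centred**2).sum() / (n - 1)))
    return UncertaintySTD(conventional, as_printed)


def _gauss(x, amp, x0, sigma, off):
    return amp * np.exp(-((x - x0) ** 2) / (2.0 * sigma**2)) + off


_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


def fit_gaussian_fwhm(profile: np.ndarray, coordinates_nm: np.ndarray) -> float:
    """FWHM (nm) from a least-squares Gaussian fit to a 1-D profile.

    FWHM = 2 sqrt(2 ln 2) sigma. Raises for flat or non-convergent
    profiles.
    """
    profile = np.asarray(profile, dtype=float)
    x = np.asarray(coordinates_nm, dtype=float)
    if profile.size < 5:
        raise ValueError("need at least 5 samples")
    if np.ptp(profile) == 0:
        raise RuntimeError("flat profile: Gaussian fit is degenerate")
    p0 = (
        profile.max() - profile.min(),
        float(x[np.argmax(profile)]),
        max(np.ptp(x) / 6.0, 1e-6),
        profile.min(),
    )
    try:
        popt, _ = curve_fit(_gauss, x, profile, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"Gaussian fit did not converge: {err}") from err
    return _FWHM_FACTOR * abs(float(popt[2]))


def _two_gauss(x, a1, x1, s1, a2, x2, s2, off):
    return (
        a1 * np.exp(-((x - x1) ** 2) / (2 * s1**2))
        + a2 * np.exp(-((x - x2) ** 2) / (2 * s2**2))
        + off
    )


def two_peak_distance(
    profile: np.ndarray,
    coordinates_nm: np.ndarray,
    min_prominence: float = 0.02,
    min_height: float = 0.25,
) -> float | None:
    """Peak-to-peak distance (nm) from a two-Gaussian fit, or None.

    The profile is declared *resolved* when it contains two local maxima
    (each above ``min_height`` of the profile maximum, with relative
    prominence above ``min_prominence``) separated by an interior minimum;
    the distance is then |x01 - x02| of a sum-of-two-Gaussians fit seeded
    at the detected maxima. Returns ``None`` when unresolved — that is a
    measurement outcome, distinct from a RuntimeError for a fit that does
    not converge.
    """
    profile = np.asarray(profile, dtype=float)
    x = np.asarray(coordinates_nm, dtype=float)
    top = profile.max()
    if top <= 0 or np.ptp(profile) == 0:
        return None
    peaks, _props = find_peaks(
        profile, height=min_height * top, prominence=min_prominence * top
    )
    if len(peaks) < 2:
        return None
    # two strongest detected maxima and the valley between them
    order = np.argsort(profile[peaks])[::-1]
    p1, p2 = sorted(peaks[order[:2]])
    interior = profile[p1 + 1 : p2]
    if interior.size == 0 or interior.min() >= min(profile[p1], profile[p2]):
        return None
    sigma0 = max((x[p2] - x[p1]) / 4.0, abs(x[1] - x[0]))
    p0 = (profile[p1], x[p1], sigma0, profile[p2], x[p2], sigma0, profile.min())
    try:
        popt, _ = curve_fit(_two_gauss, x, profile, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"two-Gaussian fit did not converge: {err}") from err
    return abs(float(popt[4] - popt[1]))


@dataclass
class FRCResult:
    """FRC curve plus the 1/7-threshold resolution readout."""

    resolution_nm: float | None
    spatial_freq_per_nm: np.ndarray
    curve: np.ndarray
    at_nyquist_bound: bool


def frc_resolution(image1: np.ndarray, image2: np.ndarray, pixel_nm: float) -> FRCResult:
    """Fourier ring correlation between two independent images of one field.

    Rings are one frequency bin wide; the resolution is 1/f at the first
    crossing of the 1/7 threshold, located by linear interpolation between
    ring centres. If the curve never falls below 1/7 up to Nyquist the
    result is flagged ``at_nyquist_bound`` with ``resolution_nm = None``.
    """
    a = np.asarray(image1, dtype=float)
    b = np.asarray(image2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    F1 = np.fft.fftshift(np.fft.fft2(a - a.mean()))
    F2 = np.fft.fftshift(np.fft.fft2(b - b.mean()))
    H, W = a.shape
    fy = np.fft.fftshift(np.fft.fftfreq(H, d=pixel_nm))
    fx = np.fft.fftshift(np.fft.fftfreq(W, d=pixel_nm))
    FY, FX = np.meshgrid(fy, fx, indexing="ij")
    fr = np.hypot(FY, FX)
    df = 1.0 / (min(H, W) * pixel_nm)  # one-bin ring width
    ring = np.round(fr / df).astype(int)
    n_rings = int(ring.max()) + 1
    num = np.bincount(ring.ravel(), weights=(F1 * np.conj(F2)).real.ravel(), minlength=n_rings)
    d1 = np.bincount(ring.ravel(), weights=(np.abs(F1) ** 2).ravel(), minlength=n_rings)
    d2 = np.bincount(ring.ravel(), weights=(np.abs(F2) ** 2).ravel(), minlength=n_rings)
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = num / np.sqrt(d1 * d2)
    curve = np.nan_to_num(curve, nan=0.0)
    freqs = np.arange(n_rings) * df
    nyquist = 0.5 / pixel_nm
    valid = freqs <= nyquist
    freqs, curve = freqs[valid], curve[valid]
    threshold = 1.0 / 7.0
    below = np.where(curve < threshold)[0]
    below = below[below > 0]  # ignore the DC ring
    if below.size == 0:
        return FRCResult(None, freqs, curve, True)
    i = below[0]
    f0, f1 = freqs[i - 1], freqs[i]
    c0, c1 = curve[i - 1], curve[i]
    f_cross = f0 + (c0 - threshold) * (f1 - f0) / (c0 - c1) if c0 != c1 else f1
    return FRCResult(1.0 / f_cross, freqs, curve, False)


def metrics_report(
    recon: np.ndarray,
    gt: np.ndarray,
    peak: float = 255.0,
    provenance: dict | None = None,
) -> MetricsReport:
    """Bundle pSNR, SSIM and uncertainty STD for one image pair."""
    p = psnr(recon, gt, peak)
    u = uncertainty_std(recon, gt)
    return MetricsReport(
        psnr_db=p if np.isfinite(p) else float("inf"),
        ssim=ssim(recon, gt),
        uncertainty_std=u.conventional,
        uncertainty_std_as_printed=u.as_printed,
        psnr_infinite=not np.isfinite(p),
        provenance=provenance,
    )
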