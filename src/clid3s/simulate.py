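"""Synthetic phantoms and acquisition emulation.

The simulator mirrors how a switchable-fluorophore acquisition is formed:
a nonnegative structure (filaments, line pairs, bead pairs) is blurred by
the microscope PSF, normalized to a 0-255 working range, quantized at the
camera bit depth, and contaminated per frame with additive Poisson
(lam = 5) and Gaussian (std = 5) noise on top of a fixed-pattern
background field. ON frames carry the blurred signal; OFF frames carry
only background (plus an optional residual fluorescence fraction). A
series of N ON and N OFF frames emulates N switching cycles.

Structures whose nominal geometry is sub-pixel (e.g. line pairs spaced
below the 65-nm camera pitch) can be rasterized on a finer grid and
mean-binned to the camera grid through ``AcquisitionConfig.detector_bin``,
which models the camera pixel aperture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from clid3s.psf import PSFModel


class SimulationParameterError(ValueError):
    """Raised for out-of-range generator or acquisition parameters."""


class DataError(ValueError):
    """Raised for non-finite image data."""


@dataclass(frozen=True)
class StructureImage:
    """Noise-free ground-truth intensity grid with a physical pixel pitch."""

    pixels: np.ndarray
    pixel_nm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise SimulationParameterError("pixels must be 2-D")
        if np.any(px < 0):
            raise SimulationParameterError("structure intensities must be nonnegative")
        if self.pixel_nm <= 0:
            raise SimulationParameterError("pixel_nm must be positive")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera / noise model parameters.

    ``poisson_lam`` is the expected count of an additive Poisson draw per
    pixel and ``gaussian_std`` the standard deviation of additive Gaussian
    noise, both on the normalized 0-255 scale. ``detector_bin`` > 1 means
    the structure and PSF live on a grid ``detector_bin`` times finer than
    the camera and each camera pixel averages a bin x bin block.
    """

    poisson_lam: float = 5.0
    gaussian_std: float = 5.0
    background: np.ndarray | None = None
    frames_per_state: int = 50
    bit_depth: int = 16
    value_range: tuple[float, float] = (0.0, 255.0)
    seed: int | None = None
    poisson_signal_dependent: bool = False
    off_residual_fraction: float = 0.0
    detector_bin: int = 1

    def __post_init__(self) -> None:
        if self.poisson_lam < 0 or self.gaussian_std < 0:
            raise SimulationParameterError("noise parameters must be nonnegative")
        if self.frames_per_state < 1:
            raise SimulationParameterError("frames_per_state must be >= 1")
        if not self.value_range[0] < self.value_range[1]:
            raise SimulationParameterError("value_range min must be < max")
        if self.detector_bin < 1 or self.detector_bin != int(self.detector_bin):
            raise SimulationParameterError("detector_bin must be a positive integer")
        if not 0.0 <= self.off_residual_fraction <= 1.0:
            raise SimulationParameterError("off_residual_fraction must be in [0, 1]")

    @property
    def quantization_step(self) -> float:
        lo, hi = self.value_range
        return (hi - lo) / (2**self.bit_depth - 1)


@dataclass(frozen=True)
class SwitchingSeries:
    """Paired ON/OFF frame stacks from one (simulated or real) acquisition."""

    on_frames: np.ndarray
    off_frames: np.ndarray
    pixel_nm: float
    config: AcquisitionConfig | None = None

    def __post_init__(self) -> None:
        on = np.asarray(self.on_frames, dtype=float)
        off = np.asarray(self.off_frames, dtype=float)
        if on.ndim != 3 or off.ndim != 3:
            raise SimulationParameterError("frame stacks must be 3-D (frame, row, col)")
        if on.shape != off.shape:
            raise SimulationParameterError(
                f"ON and OFF stacks must match in count and shape, got {on.shape} vs {off.shape}"
            )
        object.__setattr__(self, "on_frames", on)
        object.__setattr__(self, "off_frames", off)


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------


def _splat_path(image: np.ndarray, path_px: np.ndarray, intensity: float, ds_px: float) -> None:
    """Deposit ``intensity`` per pixel of arc length along a polyline, with
    bilinear (area-weighted) sub-pixel splatting."""
    H, W = image.shape
    for a, b in zip(path_px[:-1], path_px[1:]):
        seg = b - a
        L = float(np.hypot(*seg))
        n_sub = max(int(np.ceil(L / ds_px)), 1)
        ts = (np.arange(n_sub) + 0.5) / n_sub
        pts = a[None, :] + ts[:, None] * seg[None, :]
        w = intensity * L / n_sub
        for y, x in pts:
            iy, ix = int(np.floor(y)), int(np.floor(x))
            fy, fx = y - iy, x - ix
            for dy, wy in ((0, 1 - fy), (1, fy)):
                for dx, wx in ((0, 1 - fx), (1, fx)):
                    yy, xx = iy + dy, ix + dx
                    if 0 <= yy < H and 0 <= xx < W:
                        image[yy, xx] += w * wy * wx


def generate_random_walk_structure(
    shape: tuple[int, int],
    n_filaments: int,
    step_nm: float = 65.0,
    max_turn_rad: float = 0.3,
    intensity: float = 1.0,
    pixel_nm: float = 65.0,
    seed: int | None = None,
    *,
    length_nm: float = 6500.0,
    margin_px: int = 6,
    avoid_crossing: bool = True,
    max_retries: int = 25,
) -> StructureImage:
    """Microtubule-like curvilinear filaments from a bounded random walk.

    Each filament is a random walk of fixed step length whose heading
    change per step is uniform on [-max_turn_rad, +max_turn_rad], so the
    curvature is bounded by construction. Filaments are rasterized with
    area-weighted anti-aliasing. With ``avoid_crossing`` (default) each
    filament is re-drawn (up to ``max_retries`` times) until it keeps a
    small clearance from previously placed ones, so the skeleton of the
    scene has exactly ``n_filaments`` connected components.
    """
    if len(shape) != 2 or shape[0] <= 0 or shape[1] <= 0:
        raise SimulationParameterError("shape must be two positive integers")
    if pixel_nm <= 0:
        raise SimulationParameterError("pixel_nm must be positive")
    if n_filaments < 0:
        raise SimulationParameterError("n_filaments must be >= 0")
    if not 0.0 < max_turn_rad <= np.pi:
        raise SimulationParameterError("max_turn_rad must lie in (0, pi]")

    rng = np.random.default_rng(seed)
    H, W = shape
    image = np.zeros(shape)
    occupied = np.zeros(shape, dtype=bool)
    step_px = step_nm / pixel_nm
    n_steps = max(int(round(length_nm / step_nm)), 1)
    paths: list[np.ndarray] = []

    def walk() -> np.ndarray:
        pos = np.array(
            [
                rng.uniform(margin_px, H - 1 - margin_px),
                rng.uniform(margin_px, W - 1 - margin_px),
            ]
        )
        heading = rng.uniform(0.0, 2.0 * np.pi)
        pts = [pos.copy()]
        for _ in range(n_steps):
            heading += rng.uniform(-max_turn_rad, max_turn_rad)
            nxt = pos + step_px * np.array([np.sin(heading), np.cos(heading)])
            if not (margin_px <= nxt[0] <= H - 1 - margin_px and margin_px <= nxt[1] <= W - 1 - margin_px):
                break
            pos = nxt
            pts.append(pos.copy())
        return np.array(pts)

    def footprint(path: np.ndarray) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        tmp = np.zeros(shape)
        _splat_path(tmp, path, 1.0, ds_px=0.25)
        m[tmp > 1e-6] = True
        return m

    for _ in range(n_filaments):
        placed = False
        for _attempt in range(max_retries):
            path = walk()
            if path.shape[0] < 3:
                continue
            fp = footprint(path)
            if avoid_crossing:
                # 2-px clearance between filaments keeps skeletons disjoint
                grown = gaussian_filter(fp.astype(float), 1.0) > 1e-3
                if np.any(grown & occupied):
                    continue
                occupied |= grown
            placed = True
            break
        if not placed:
            continue
        _splat_path(image, path, intensity, ds_px=0.25)
        paths.append(path)

    meta = {
        "generator": "random_walk",
        "n_filaments": n_filaments,
        "n_placed": len(paths),
        "step_nm": step_nm,
        "max_turn_rad": max_turn_rad,
        "intensity": intensity,
        "seed": seed,
        "paths_px": paths,
    }
    return StructureImage(image, pixel_nm, meta)


def generate_line_pair(
    spacing_nm: float,
    length_nm: float,
    orientation: Literal["vertical", "horizontal"] = "vertical",
    pixel_nm: float = 65.0,
    shape: tuple[int, int] = (96, 96),
) -> StructureImage:
    """Two parallel 1-pixel-wide lines at a centre-to-centre distance.

    Positions are defined in physical (nm) coordinates with pixel centres
    at (index + 0.5) * pixel_nm; sub-pixel line positions are drawn with
    linear (area-weighted) anti-aliasing, so the perpendicular intensity
    first moment reproduces the nominal spacing exactly. ``spacing_nm = 0``
    collapses to a single line of doubled intensity.
    """
    if spacing_nm < 0:
        raise SimulationParameterError("spacing_nm must be >= 0")
    if pixel_nm <= 0:
        raise SimulationParameterError("pixel_nm must be positive")
    H, W = shape
    image = np.zeros(shape)
    n_perp = W if orientation == "vertical" else H
    n_along = H if orientation == "vertical" else W
    if orientation not in ("vertical", "horizontal"):
        raise SimulationParameterError(f"unknown orientation {orientation!r}")
    centre_nm = n_perp * pixel_nm / 2.0
    positions = [centre_nm - spacing_nm / 2.0, centre_nm + spacing_nm / 2.0]
    if positions[0] < 0 or positions[1] > n_perp * pixel_nm:
        raise SimulationParameterError("spacing exceeds the field of view")
    n_line = int(round(length_nm / pixel_nm))
    if n_line > n_along:
        raise SimulationParameterError("line length exceeds the field of view")
    a0 = (n_along - n_line) // 2
    a1 = a0 + n_line
    for pos in positions:
        c = pos / pixel_nm - 0.5  # pixel-centre coordinate
        i = int(np.floor(c))
        f = c - i
        for idx, wgt in ((i, 1.0 - f), (i + 1, f)):
            if wgt <= 0 or not 0 <= idx < n_perp:
                continue
            if orientation == "vertical":
                image[a0:a1, idx] += wgt
            else:
                image[idx, a0:a1] += wgt
    meta = {
        "generator": "line_pair",
        "spacing_nm": spacing_nm,
        "length_nm": length_nm,
        "orientation": orientation,
    }
    return StructureImage(image, pixel_nm, meta)


def generate_bead_pair(
    diameter_nm: float,
    separation_nm: float,
    pixel_nm: float = 65.0,
    shape: tuple[int, int] = (96, 96),
    diameter2_nm: float | None = None,
    oversample: int = 8,
) -> StructureImage:
    """Two filled disks (beads) at a given centre separation along x.

    Disk edges are anti-aliased by ``oversample**2`` coverage sampling per
    pixel, so total flux is proportional to disk area and centroids sit at
    the nominal positions to sub-pixel accuracy. ``diameter2_nm = 0``
    leaves a single bead.
    """
    if diameter_nm < 0 or (diameter2_nm is not None and diameter2_nm < 0):
        raise SimulationParameterError("bead diameters must be >= 0")
    if separation_nm < 0:
        raise SimulationParameterError("separation_nm must be >= 0")
    d2 = diameter_nm if diameter2_nm is None else diameter2_nm
    H, W = shape
    cy_nm = H * pixel_nm / 2.0
    cx_nm = W * pixel_nm / 2.0
    centres = [
        (cy_nm, cx_nm - separation_nm / 2.0, diameter_nm / 2.0),
        (cy_nm, cx_nm + separation_nm / 2.0, d2 / 2.0),
    ]
    for cy, cx, r in centres:
        if r > 0 and (cx - r < 0 or cx + r > W * pixel_nm or cy - r < 0 or cy + r > H * pixel_nm):
            raise SimulationParameterError("bead extends outside the field of view")
    image = np.zeros(shape)
    sub = (np.arange(oversample) + 0.5) / oversample
    for cy, cx, r in centres:
        if r <= 0:
            continue
        lo_y = max(int((cy - r) / pixel_nm) - 1, 0)
        hi_y = min(int((cy + r) / pixel_nm) + 2, H)
        lo_x = max(int((cx - r) / pixel_nm) - 1, 0)
        hi_x = min(int((cx + r) / pixel_nm) + 2, W)
        for iy in range(lo_y, hi_y):
            for ix in range(lo_x, hi_x):
                ys = (iy + sub[:, None]) * pixel_nm - cy
                xs = (ix + sub[None, :]) * pixel_nm - cx
                cover = (ys**2 + xs**2) <= r**2
                image[iy, ix] += cover.mean()
    meta = {
        "generator": "bead_pair",
        "diameter_nm": diameter_nm,
        "diameter2_nm": d2,
        "separation_nm": separation_nm,
    }
    return StructureImage(image, pixel_nm, meta)


# ---------------------------------------------------------------------------
# acquisition
# ---------------------------------------------------------------------------


def normalize_and_quantize(
    image: np.ndarray,
    value_range: tuple[float, float] = (0.0, 255.0),
    bit_depth: int = 16,
) -> np.ndarray:
    """Min-max map onto ``value_range`` then round at the camera bit depth.

    The quantization step is span / (2**bit_depth - 1). A constant image
    maps to the range minimum (min-max scaling is otherwise undefined).
    Idempotent on already-normalized input.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise DataError("image contains NaN or Inf")
    lo, hi = value_range
    if not lo < hi:
        raise SimulationParameterError("value_range min must be < max")
    mn, mx = img.min(), img.max()
    if mx == mn:
        return np.full_like(img, lo)
    scaled = lo + (img - mn) * (hi - lo) / (mx - mn)
    step = (hi - lo) / (2**bit_depth - 1)
    return np.round(scaled / step) * step


def make_fixed_pattern_background(
    shape: tuple[int, int],
    seed: int | None = None,
    mean: float = 20.0,
    smooth_std: float = 5.0,
    smooth_sigma_px: float = 8.0,
    pixel_std: float = 2.0,
) -> np.ndarray:
    """Synthetic fixed-pattern background on the 0-255 scale.

    A smooth low-frequency random field (vignetting / stray light) plus a
    per-pixel offset pattern (sensor nonuniformity), clipped at zero. The
    field is a pure function of (shape, seed) and is meant to be reused
    across every frame of a series — that is what makes it fixed-pattern.
    """
    rng = np.random.default_rng(seed)
    smooth = gaussian_filter(rng.normal(0.0, 1.0, shape), smooth_sigma_px)
    smooth = (smooth - smooth.mean()) / max(smooth.std(), 1e-12)
    field = mean + smooth_std * smooth + rng.normal(0.0, pixel_std, shape)
    return np.clip(field, 0.0, None)


def inject_noise(
    image: np.ndarray,
    config: AcquisitionConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One noisy camera frame from a normalized-scale image.

    output = image + background + Poisson(lam) + N(0, std), clipped at 0
    and quantized at the camera step. With
    ``config.poisson_signal_dependent`` the Poisson draw has expectation
    image + lam (shot noise) instead of a signal-independent lam offset.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise DataError("image contains NaN or Inf")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = img.copy()
    if config.background is not None:
        bg = np.asarray(config.background, dtype=float)
        if bg.shape != img.shape:
            raise SimulationParameterError("background shape must match the image")
        out = out + bg
    if config.poisson_signal_dependent:
        out = rng.poisson(np.clip(out, 0.0, None) + config.poisson_lam).astype(float)
    elif config.poisson_lam > 0:
        out = out + rng.poisson(config.poisson_lam, img.shape)
    if config.gaussian_std > 0:
        out = out + rng.normal(0.0, config.gaussian_std, img.shape)
    out = np.clip(out, 0.0, None)
    step = config.quantization_step
    return np.round(out / step) * step


def _bin_mean(image: np.ndarray, b: int) -> np.ndarray:
    H, W = image.shape
    if H % b or W % b:
        raise SimulationParameterError("image shape must be divisible by detector_bin")
    return image.reshape(H // b, b, W // b, b).mean(axis=(1, 3))


def blur_structure(gt: StructureImage, psf: PSFModel, config: AcquisitionConfig) -> np.ndarray:
    """Noise-free blurred signal on the camera grid, normalized 0-255."""
    if not np.isclose(gt.pixel_nm, psf.pixel_nm, rtol=1e-6):
        raise SimulationParameterError(
            f"structure pitch {gt.pixel_nm} nm != PSF pitch {psf.pixel_nm} nm"
        )
    blurred = fftconvolve(gt.pixels, psf.kernel, mode="same")
    if config.detector_bin > 1:
        blurred = _bin_mean(blurred, config.detector_bin)
    blurred = np.clip(blurred, 0.0, None)
    if blurred.max() == 0:
        return blurred
    return normalize_and_quantize(blurred, config.value_range, config.bit_depth)


def simulate_switching_series(
    gt: StructureImage,
    psf: PSFModel,
    config: AcquisitionConfig,
) -> SwitchingSeries:
    """Emulate one ON/OFF switching acquisition.

    ON frames carry the blurred, normalized signal plus background and
    fresh per-frame noise; OFF frames carry background (plus the optional
    residual-fluorescence fraction of the signal) and fresh noise. The
    background field is drawn from the stack config and reused for every
    frame — it is the fixed-pattern component the ON-OFF subtraction
    removes.
    """
    signal = blur_structure(gt, psf, config)
    camera_pitch = gt.pixel_nm * config.detector_bin
    rng = np.random.default_rng(config.seed)
    frame_cfg = config
    on = np.stack(
        [inject_noise(signal, frame_cfg, rng) for _ in range(config.frames_per_state)]
    )
    off_signal = config.off_residual_fraction * signal
    off = np.stack(
        [inject_noise(off_signal, frame_cfg, rng) for _ in range(config.frames_per_state)]
    )
    return SwitchingSeries(on, off, camera_pitch, config)
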