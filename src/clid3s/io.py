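"""TIFF / JSON / YAML input-output with provenance sidecars.

Conventions: row-major arrays, origin top-left, 0-based indices, physical
positions at pixel centres. Stacks are multi-page grayscale TIFF; a
switching series is stored either as two files (ON, OFF) or one
interleaved file with all ON pages followed by all OFF pages. Every
written image carries a JSON sidecar (same path + ".json") with the
pixel pitch and the parameters that produced it — enough to regenerate
the file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from clid3s.denoise3s import ClearImage, s3_denoise
from clid3s.metrics import metrics_report, two_peak_distance
from clid3s.psf import bessel_psf
from clid3s.recon import CLIDConfig, clid_pipeline
from clid3s.simulate import (
    AcquisitionConfig,
    SwitchingSeries,
    blur_structure,
    generate_bead_pair,
    generate_line_pair,
    generate_random_walk_structure,
    make_fixed_pattern_background,
    simulate_switching_series,
)


class FormatError(ValueError):
    """Unsupported image format or dtype."""


_ALLOWED_DTYPES = {"uint8", "uint16", "float32", "float64"}


def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def write_image(
    image: np.ndarray,
    path: str | Path,
    dtype: str = "float32",
    rescale: bool = False,
    pixel_nm: float | None = None,
    provenance: dict | None = None,
) -> Path:
    """Write a grayscale TIFF (single image or stack) plus JSON sidecar.

    Integer targets reject out-of-range values unless ``rescale`` maps the
    data linearly onto the full dtype range.
    """
    arr = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise FormatError("image contains NaN or Inf")
    if dtype not in _ALLOWED_DTYPES:
        raise FormatError(f"unsupported dtype {dtype!r}")
    if dtype.startswith("uint"):
        info = np.iinfo(dtype)
        if rescale:
            lo, hi = arr.min(), arr.max()
            arr = (
                np.zeros_like(arr)
                if hi == lo
                else (arr - lo) / (hi - lo) * info.max
            )
        elif arr.min() < info.min or arr.max() > info.max:
            raise FormatError(
                f"values outside {dtype} range; pass rescale=True to map them"
            )
        out = np.round(arr).astype(dtype)
    else:
        out = arr.astype(dtype)
    path = Path(path)
    tifffile.imwrite(path, out)
    sidecar = {"pixel_nm": pixel_nm, "dtype": dtype, "shape": list(out.shape)}
    if provenance:
        sidecar["provenance"] = provenance
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, default=str))
    return path


def read_image(path: str | Path, pixel_nm: float | None = None) -> tuple[np.ndarray, float]:
    """Read a grayscale TIFF as float; pitch from sidecar or argument."""
    arr = tifffile.imread(path)
    if arr.ndim not in (2, 3):
        raise FormatError("expected a 2-D image or a 3-D grayscale stack")
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:2]):
        raise FormatError("RGB(A) images are not supported")
    if str(arr.dtype) not in _ALLOWED_DTYPES | {"int16", "int32"}:
        raise FormatError(f"unsupported dtype {arr.dtype}")
    side = _sidecar_path(path)
    if pixel_nm is None and side.exists():
        pixel_nm = json.loads(side.read_text()).get("pixel_nm")
    if pixel_nm is None:
        raise FormatError(
            f"pixel pitch for {path} not given and no sidecar found; pass pixel_nm"
        )
    return arr.astype(float), float(pixel_nm)


def write_series(series: SwitchingSeries, path: str | Path, interleaved: bool = True) -> Path:
    """Write a switching series: all ON pages then all OFF pages."""
    if interleaved:
        stack = np.concatenate([series.on_frames, series.off_frames], axis=0)
        return write_image(
            stack,
            path,
            dtype="float32",
            pixel_nm=series.pixel_nm,
            provenance={"page_order": "all-ON-then-all-OFF", "n_per_state": series.on_frames.shape[0]},
        )
    base = Path(path)
    write_image(series.on_frames, base.with_suffix(".on.tif"), "float32", pixel_nm=series.pixel_nm)
    write_image(series.off_frames, base.with_suffix(".off.tif"), "float32", pixel_nm=series.pixel_nm)
    return base


def read_stack(
    path: str | Path,
    page_order: str = "stack",
    pixel_nm: float | None = None,
    off_path: str | Path | None = None,
) -> np.ndarray | SwitchingSeries:
    """Read a frame stack, or a switching series.

    ``page_order="stack"`` returns the raw (N, H, W) array.
    ``page_order="interleaved"`` splits the pages into ON (first half) and
    OFF (second half); an odd page count is an error. With ``off_path``
    the ON and OFF stacks come from two separate files.
    """
    arr, pitch = read_image(path, pixel_nm)
    if arr.ndim == 2:
        arr = arr[None]
    if off_path is not None:
        off, _ = read_image(off_path, pitch)
        if off.ndim == 2:
            off = off[None]
        return SwitchingSeries(arr, off, pitch)
    if page_order == "stack":
        return arr
    if page_order == "interleaved":
        if arr.shape[0] % 2:
            raise FormatError(
                "interleaved ON/OFF file must have an even page count"
            )
        n = arr.shape[0] // 2
        return SwitchingSeries(arr[:n], arr[n:], pitch)
    raise FormatError(f"unknown page order convention {page_order!r}")


# ---------------------------------------------------------------------------
# run configuration and end-to-end driver
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """Parameters for an end-to-end simulate -> denoise -> CLID -> evaluate run."""

    phantom: str = "lines"  # microtubule | lines | beads
    shape: tuple[int, int] = (96, 96)
    pixel_nm: float = 65.0
    spacing_nm: float = 130.0
    line_length_nm: float = 5200.0
    bead_diameter_nm: float = 100.0
    n_filaments: int = 8
    wavelength_nm: float = 488.0
    na: float = 1.49
    poisson_lam: float = 5.0
    gaussian_std: float = 5.0
    frames_per_state: int = 50
    background_mean: float = 20.0
    upsample_factor: int = 3
    interpolator: str = "lanczos"
    rl_iterations: int = 1000
    seed: int = 0
    outdir: str = "clid_run"

    def __post_init__(self) -> None:
        if self.phantom not in ("microtubule", "lines", "beads"):
            raise ValueError(f"unknown phantom {self.phantom!r}")
        if self.interpolator not in ("lanczos", "linear", "bicubic", "fourier"):
            raise ValueError(f"unknown interpolator {self.interpolator!r}")
        if self.upsample_factor < 1 or self.rl_iterations < 0:
            raise ValueError("invalid reconstruction parameters")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["shape"] = list(d["shape"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        return cls(**d)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate, 3S-denoise, reconstruct and evaluate; artifacts on disk.

    Deterministic given the config seed. Returns a dict with the metrics
    report and the paths of everything written.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if config.phantom == "lines":
        gt = generate_line_pair(
            config.spacing_nm, config.line_length_nm, "vertical", config.pixel_nm, config.shape
        )
    elif config.phantom == "beads":
        gt = generate_bead_pair(
            config.bead_diameter_nm, config.spacing_nm, config.pixel_nm, config.shape
        )
    else:
        gt = generate_random_walk_structure(
            config.shape, config.n_filaments, pixel_nm=config.pixel_nm, seed=config.seed
        )
    psf = bessel_psf(config.wavelength_nm, config.na, config.pixel_nm)
    acq = AcquisitionConfig(
        poisson_lam=config.poisson_lam,
        gaussian_std=config.gaussian_std,
        background=make_fixed_pattern_background(
            config.shape, seed=config.seed + 1, mean=config.background_mean
        ),
        frames_per_state=config.frames_per_state,
        seed=config.seed,
    )
    series = simulate_switching_series(gt, psf, acq)
    write_series(series, out / "series.tif")
    clear = s3_denoise(series)
    write_image(clear.pixels, out / "clear.tif", pixel_nm=clear.pixel_nm, provenance=clear.provenance)
    clid_cfg = CLIDConfig(
        upsample_factor=config.upsample_factor,
        interpolator=config.interpolator,  # type: ignore[arg-type]
        rl_iterations=config.rl_iterations,
    )
    sr = clid_pipeline(clear, psf, clid_cfg)
    write_image(sr, out / "clid.tif", pixel_nm=config.pixel_nm / config.upsample_factor)
    reference = blur_structure(gt, psf, acq)
    report = metrics_report(clear.pixels, reference, provenance={"stage": "clear-vs-GTblur"})
    if config.phantom == "lines":
        H3 = sr.shape[0]
        n_rows = max(int(H3 * 0.3), 1)
        profile = sr[H3 // 2 - n_rows : H3 // 2 + n_rows].mean(axis=0)
        coords = np.arange(sr.shape[1]) * config.pixel_nm / config.upsample_factor
        report.peak_distance_nm = two_peak_distance(profile, coords)
    report_dict = dataclasses.asdict(report)
    (out / "metrics.json").write_text(json.dumps(_scrub(report_dict), indent=2))
    config.to_yaml(out / "config.yaml")
    return {"report": report, "outdir": str(out)}


def _scrub(obj):
    if isinstance(obj, dict):
        return {k: _scrub(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_scrub(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj
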