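# clid3s — switching-series denoising and clear-image deconvolution

Single-frame computational super-resolution for fluorescence microscopy
with reversibly switchable fluorescent proteins (RSFPs), for microscopists
and image-analysis developers who want diffraction-limit-beating
reconstructions from ordinary widefield or spinning-disk data without
specialized SR hardware.

## The method

An RSFP can be toggled between a fluorescent ON state and a dark OFF
state, so the same field can be imaged N times with signal and N times
without. Camera noise then separates cleanly by its spatiotemporal
behaviour:

1. **3S denoising** (per-pixel, distribution-preserving):

       clear = clip( AVG(ON) − AVG(OFF), 0 )

   Frame averaging removes random noise (σ → σ·√(2/N)); the ON−OFF
   subtraction removes fixed-pattern background exactly. No neighborhood
   or frequency-domain operation touches the data, so the per-pixel
   intensity statistics survive — which is what keeps the next step
   stable.

2. **3Snet** (single-frame denoising): a compact U-net-style network
   trained per imaging system with the hybrid loss

       loss = ( ‖x̃ − y‖₂² + λ‖x̃ − GT‖₂² ) / (1 + λ)

   where (x, y) are two noisy realizations at the same noise level
   (built by averaging k ∈ {1,2,4,8,16} ON frames) and GT is the 3S
   clear image; λ is chosen from {0, 1, 2, 4, 8, 16, ∞} by held-out
   pSNR. After training, a *single* noisy frame suffices — live-cell
   imaging at full frame rate.

3. **CLID** (clear-image deconvolution): 3× Lanczos upsampling onto a
   finer computational grid, then Richardson–Lucy deconvolution
   (Biggs–Andrews-accelerated by default, 1000 iterations) with the Airy
   PSF H(r) = I₀[2J₁(kNAr)/(kNAr)]², regenerated analytically at the
   upsampled pitch.

The package also bundles the evaluation suite (pSNR, SSIM, uncertainty
STD, Gaussian-fit FWHM, two-peak distances, Fourier ring correlation
with the 1/7 threshold) and a synthetic-acquisition simulator
(random-walk filaments, line pairs, bead pairs; Poisson lam=5 +
Gaussian std=5 noise on a 0–255 scale; fixed-pattern background; 50
ON/OFF cycles) so the whole chain runs and is tested without a
microscope. See `docs/methods.md` for model details and numerical
choices.

## Worked example

Resolve a 130-nm line pair from a simulated switching acquisition:

```python
import numpy as np
from clid3s import (AcquisitionConfig, CLIDConfig, bessel_psf,
                    generate_line_pair, simulate_switching_series,
                    s3_denoise, clid_pipeline, two_peak_distance)
from clid3s.simulate import make_fixed_pattern_background

psf = bessel_psf(wavelength_nm=488, na=1.49, pixel_nm=65)
gt = generate_line_pair(spacing_nm=130, length_nm=4500, pixel_nm=65, shape=(96, 96))
cfg = AcquisitionConfig(background=make_fixed_pattern_background((96, 96), seed=1),
                        seed=0, frames_per_state=50)
series = simulate_switching_series(gt, psf, cfg)

clear = s3_denoise(series)                      # AVG(ON) - AVG(OFF)
sr = clid_pipeline(clear, psf, CLIDConfig())    # 3x Lanczos + RL x1000

profile = sr[72:216].mean(axis=0)               # perpendicular to the lines
coords = np.arange(profile.size) * 65 / 3
print(f"peak distance: {two_peak_distance(profile, coords):.1f} nm")
```

Output:

```
peak distance: 127.9 nm
```

The two lines, 130 nm apart and far below the 168-nm PSF FWHM, come out
as two distinct peaks whose fitted distance matches the ground truth to
a few nanometres. Richardson–Lucy on the raw noisy frame, for
comparison, leaves the same pair as a single blob.

The same stages are scriptable from the shell:

```
clid simulate --phantom lines --spacing-nm 130 --frames 50 -o series.tif
clid denoise3s --on series.tif -o clear.tif
clid run --input clear.tif --factor 3 --iters 1000 -o sr.tif
clid evaluate --recon sr.tif --gt gt.tif
```

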