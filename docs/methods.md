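# Methods

This note documents the models, numerical choices and limitations behind
`clid3s`. The package reconstructs super-resolved images from
reversibly-switchable-fluorophore (RSFP) acquisitions in three stages —
per-pixel denoising, grid refinement, and Richardson–Lucy (RL)
deconvolution — and ships a synthetic-acquisition simulator so every stage
is testable without a microscope.

## Acquisition model

A camera frame is modelled as

    frame = Q( clip( signal + background + P(lam) + N(0, std), 0 ) )

where `signal` is the structure convolved with the microscope PSF and
min–max normalized to a 0–255 working range, `background` is a
fixed-pattern field constant across frames, `P(lam)` is an additive
Poisson draw (default lam = 5 counts) and `N(0, std)` additive Gaussian
noise (default std = 5 on the 0–255 scale), and `Q` rounds at the camera
quantization step (span / (2^16 − 1) for the default 16-bit depth). The
Poisson term is an independent per-pixel event count, not shot noise; a
signal-dependent mode (`poisson_signal_dependent`) draws
`P(signal + lam)` instead for users who want physical shot noise.

The fixed-pattern background emulates what a real blank-region
acquisition provides: a smooth low-frequency Gaussian random field
(vignetting, stray light; mean 20, std 5, correlation length 8 px on the
0–255 scale) plus a per-pixel offset pattern (sensor nonuniformity,
std 2), clipped at zero and reused for every frame of a series. These
amplitudes were chosen once as representative of a well-corrected sCMOS
blank region; real backgrounds can be substantially stronger and more
structured, which mostly affects the *raw*-image scores, not the
denoised ones (the background cancels in the ON−OFF subtraction).

An ON/OFF switching acquisition is N ON frames (signal present) and N
OFF frames (background only; an optional `off_residual_fraction` models
incomplete switching, default 0), with fresh noise per frame. The
default N = 50 cycles.

### Phantoms

* **Filaments** — bounded random walks with a fixed step (65 nm) and a
  per-step heading change uniform on ±`max_turn_rad` (default 0.3 rad),
  so curvature is bounded by construction; rasterized with area-weighted
  anti-aliasing. By default filaments are re-drawn until they keep a
  small clearance from each other, so the scene's skeleton has exactly
  `n_filaments` components; crossing filaments can be allowed
  (`avoid_crossing=False`). Walk length and filament count are package
  defaults (scene-density choices), not measured quantities.
* **Line pairs** — two parallel 1-px lines at an exact centre-to-centre
  distance in nm; sub-pixel positions are drawn with linear
  anti-aliasing so the perpendicular intensity first moment reproduces
  the nominal spacing exactly.
* **Bead pairs** — filled disks with coverage-sampled (8×8 per pixel)
  anti-aliased edges; flux is proportional to disk area.

### Sub-pixel geometry and the camera aperture

Separations that are not integer multiples of the camera pitch cannot be
represented faithfully on the camera grid. For those, the phantom is
rasterized on a 3×-finer grid, blurred with the PSF sampled at that
pitch, and mean-binned 3×3 to the camera grid
(`AcquisitionConfig.detector_bin = 3`) — i.e., the camera pixel aperture
is modelled explicitly. On-grid separations use the simpler
rasterize-and-convolve-at-65-nm path; both forward models agree for
on-grid geometry up to the aperture term.

## PSF

The widefield PSF is the Airy pattern
`H(r) = I0 [2 J1(k NA r) / (k NA r)]²`, `k = 2π/λ`, sampled at pixel
centres (optionally area-averaged with `oversample`), with the removable
r→0 singularity evaluated by its limit. Default support contains the
third Airy ring (<0.5% truncated energy, renormalized to unit sum). For
λ = 488 nm, NA = 1.49 the first zero sits at 199.7 nm and the
central-lobe FWHM at 168.5 nm. Grid refinement regenerates the kernel
analytically at the finer pitch rather than interpolating. A
bead-calibration route (`na_from_fwhm`) solves for the effective NA that
matches a measured bead FWHM.

## 3S denoising

`clear = clip(mean(ON) − mean(OFF), 0)`. Averaging suppresses random
noise by 1/√N per stack; the subtraction removes anything constant
across frames exactly. For the default N = 50 and the default noise the
residual is √(lam + std²) · √(2/N) ≈ 1.1 on the 0–255 scale. Every
operation is per-pixel, so the per-pixel intensity distribution of the
signal is preserved — the property that makes the output a faithful
input for RL deconvolution. Negative residuals are clipped to zero
(required by RL's nonnegativity; the alternative signed output is not
offered). Unequal ON/OFF frame counts are accepted (means are
count-independent); the frame-paired baseline `MED(ON−OFF)` requires
equal counts.

## Single-frame denoiser (3Snet)

Training data: from each acquisition's 50 ON frames, five noise levels
are built by averaging k ∈ {1, 2, 4, 8, 16} frames; 50 distinct
k-subsets are drawn per level (all ≤ C(50, k)), with the subsets
recorded for reproducibility. Each training sample picks a level, two
distinct images of that level as input x and target y, and the
acquisition's 3S clear image as ground truth GT. Levels are mixed freely
within a batch. The loss is

    loss = ( ||x̃ − y||² + λ ||x̃ − GT||² ) / (1 + λ)

with λ = 0 purely self-supervised, λ = ∞ (sentinel) purely supervised.
λ is selected from the grid {0, 1, 2, 4, 8, 16, ∞} as the argmax of
held-out denoised pSNR; exact ties go to the smallest λ. Note the two
terms disagree about the fixed-pattern background — y contains it, GT
does not — so small λ converges to partial background removal and the
pSNR selection consequently favours large λ under the bundled
simulator's conditions.

The network is a compact U-net-style encoder-decoder (two scales, 12
base channels, 3×3 convolutions, leaky ReLU with slope 0.1, average-pool
down / nearest-up with skip concatenation, 1×1 output head) with a
global residual connection, implemented directly in NumPy with im2col
convolutions and manual backpropagation; Adam (lr 2e-3 with a
two-epoch linear warmup), batch 4, patch 64, horizontal flips. The
leaky activations and warmup exist for optimization robustness: with
plain ReLU and a cold start, a minority of seeds settled into a
dead-unit plateau an order of magnitude above the usual final loss.
Reference scale is 50 steps/epoch with 6 epochs per grid candidate and
32 epochs for the final model — minutes per model on one CPU. These sizes are deliberate desk-scale choices; the architecture and
schedule are configurable (`NetworkSpec`, `train_denoiser` kwargs).
Inputs are scaled by 1/255 and the inverse is applied on output; frames
larger than `tile_size` (256) are processed in overlapping tiles
(32-px overlap, linear blending). Inference is deterministic and the
output is clipped at zero.

## CLID reconstruction

The clear image is upsampled 3× with Lanczos (a = 3 windowed sinc;
separable interpolation matrices with per-output-pixel weight
normalization, so constants are preserved; `linear`, `bicubic`
(Catmull–Rom) and `fourier` (spectral zero-padding) are available for
comparison), then RL-deconvolved with the PSF regenerated analytically
at the upsampled pitch.

RL numerical choices: FFT convolutions with reflective padding by one
kernel radius; ratio guard ε = 1e-12 × image max; nonnegativity enforced
every iteration; iteration 0 returns the input; no regularization or
early stopping — the iteration count (default 1000) is the user's
control, and reconstructions should be inspected at increasing counts
for ringing before being quantified. Two update schedules are provided:

* **plain** multiplicative RL, which conserves total flux at every
  iteration (to FFT round-off) for unit-sum PSFs and objects away from
  the borders;
* **Biggs–Andrews vector extrapolation** (the default, as in the
  standard MATLAB `deconvlucy` implementation): the next iterate is
  predicted along the direction of the previous step with an adaptive
  coefficient clipped to [0, 1). Acceleration reaches a given contrast
  in several-fold fewer iterations; at 1000 iterations it is what lets
  the 65-nm line pair split under the reference noise conditions, where
  plain RL at the same count leaves only a ~1–4% dip. Flux is conserved
  only approximately under extrapolation.

## Resolvability criterion

A line pair is *resolved* when the reconstruction's perpendicular
profile (averaged over the central band of rows) shows two local maxima
(≥25% of the profile maximum, relative prominence ≥2%) separated by an
interior minimum, a two-Gaussian fit converges, and the fitted
peak-to-peak distance agrees with the nominal spacing (35% relative
tolerance with a floor of half a grid pixel of the profile — the
sub-pixel localization scale of the fit). The distance gate prevents
noise- or artifact-induced peak pairs at unrelated distances from
counting as resolution; without it, a tight sub-resolution pair can
"split" into two spurious peaks at roughly the PSF scale and be
mistaken for a resolved structure. A profile failing any gate is
"unresolved", which is a measurement outcome distinct from a fit error.

## Metrics

* **pSNR** = 10 log10(peak²/MSE) with the *theoretical* peak of the
  normalized scale (255), not the empirical maximum (switchable).
  Zero MSE reports infinity with a flag.
* **SSIM**: standard windowed form, uniform 7×7 window,
  C1 = (0.01 L)², C2 = (0.03 L)², covariance in the numerator. A literal
  variant with the product of window standard deviations in place of the
  covariance is available (`as_printed=True`); it cannot express
  anti-correlation and is reported for completeness only.
* **Uncertainty STD** of a difference image D, two conventions: the
  mean-absolute-deviation-style sum Σ|D − ⟨D⟩| / (n − 1) ("as printed")
  and the conventional sample standard deviation. They differ by a
  distribution-dependent factor (≈0.80 σ for Gaussian D); both are
  returned and labelled, neither is asserted as the intended one.
* **FWHM** from a least-squares Gaussian fit (amplitude, centre, σ,
  offset); FWHM = 2√(2 ln 2) σ.
* **FRC**: ring-normalized spectral cross-correlation of two independent
  images of one field; rings one frequency bin wide, no smoothing;
  resolution = 1/f at the first crossing below 1/7 (linear
  interpolation). A curve that never crosses is flagged "at the Nyquist
  bound". Decorrelation analysis is not implemented; FRC is this
  package's resolution metric.

## Reference experiments and what they show

`validation.s3_clid_ladder` (separations {65, 130, 195} nm) and
`validation.net_clid_ladder` ({30 … 210} nm after
`train_reference_denoiser`) run the two pipelines end-to-end at the
default 96×96 field, 50 cycles, and report the smallest resolved
separation with RL on a raw frame as negative control.
`validation.filament_benchmark` scores Raw / AVG(ON) / MED(ON) /
MED(ON−OFF) / Clear against the blurred ground truth and CLID outputs
across interpolators (at 3×) and Lanczos factors (2×/3×/4×) against the
finely rasterized ground truth on each factor's own grid.

Observed behaviour at these conditions: the 3S clear image beats the
median-difference baseline, which beats plain averaging, by a wide
margin; Lanczos at 3× beats linear/bicubic/Fourier at 3× and Lanczos at
2× in both pSNR and SSIM, but Lanczos 4× scores slightly above 3× here
(the relative ranking of 3× and 4× is sensitive to the noise floor and
background structure of the benchmark, and to the comparison grid; with
the plain RL schedule it is seed-dependent). The factor default remains
3×.

What passing these tests does *not* show: the simulator has no camera
read-noise maps or gain calibration, no drift, bleaching, or incomplete
switching by default, a weaker and smoother background than typical
real blank regions, and 2-D structures only. Results on real
acquisitions depend on those factors, on PSF mismatch, and on the
denoiser being retrained per imaging system.

## Known limitations

* The denoiser is desk-scale; real deployments would train longer, on
  larger patches, with more acquisitions.
* RL with an inaccurate PSF produces ringing; only matched (simulated)
  PSFs are exercised here. No blind estimation, no depth-variant PSFs,
  no 3-D.
* The resolvability criterion's thresholds (peak height, prominence,
  distance gate) are documented constants; profiles near the criterion
  boundary can flip with seed.
* Flux is not exactly conserved under accelerated RL; use
  `accelerated=False` where strict flux bookkeeping matters.
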