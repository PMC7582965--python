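# Methods

This note documents the models behind `skinmpm`, the parameters that matter,
the design choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not show about real tissue.

## Pulse train and wrapped decay (`timetag`)

An 80 MHz mode-locked laser gives a pulse period T = 12.5 ns, divided into
16 equal arrival-time bins (~780 ps, the sampling-limited temporal
resolution). Fluorescence lifetimes are comparable to T, so emission from
earlier pulses folds into the current period; the steady-state arrival-time
density is the wrapped exponential p(t) = e^(−t/τ) / (τ(1 − e^(−T/τ))) on
[0, T).

**Bin/pulse alignment.** The instrument's printed gate windows are
−0.4–1.2 ns (red) and 0.4–12 ns (green). Bin 0's leading edge is placed at
−0.4 ns so that, under the center-in-window snapping rule (whole bins are
assigned to virtual channels; hardware cannot weight fractional bins), red
maps to bins {0, 1} and green to bins {1..15} — realizing the documented
one-bin overlap of the two channels. Photons at negative times are late
photons from the previous pulse, reached through the periodic wrap. The
instrument's actual alignment is not published; this reconstruction is the
one that makes the printed windows realizable.

**Bin probabilities.** Per-bin masses are exact CDF differences of the
single-pulse response summed over pulse offsets kT. With a Gaussian
instrument response (IRF) the single-pulse response is the
exponentially-modified Gaussian, whose CDF is closed-form; beyond eight
periods the Gaussian factor is fully resolved and successive periods scale
exactly by e^(−T/τ), so the remainder is summed as a geometric tail rather
than truncated (the stated truncation tolerance, 1e−12 per period, applies
to the short-lifetime path where the tail is negligible). Second-harmonic
generation is modeled as a prompt emitter (all mass at t = 0 up to IRF
blur). A Monte-Carlo arrival-time sampler (exponential delay + Gaussian
jitter, wrapped) provides the independent oracle; tests require agreement
within three standard errors on the gate masses at 4–10⁶ samples.

**IRF default.** The detector's 570 ps rise time, read as an effective FWHM,
gives σ = 0.242 ns — sub-bin, consistent with the sampling-limited regime.
The `Irf` type defaults to this value for explicit decay modeling, but the
photon-count forward model defaults to the ideal prompt response: at 780 ps
bins the sub-bin IRF mainly smears bin edges, and the sampling-limited
approximation is the instrument's own description of its regime. Passing
`Irf()` to `expected_bin_rates` includes the blur.

## Skin phantom (`phantom`)

The phantom names and places the features endogenous-contrast skin imaging
actually sees; its geometry generators are inventions (the literature names
the features, not their generative models):

* stratum corneum (0–15 µm): keratin with corneocyte-scale (~12 µm)
  smooth texture;
* viable epidermis (15–60 µm): keratinocytes packed by dart-throwing
  (Poisson-disc-style) sampling at ≥11 µm spacing; each cell is an
  NAD(P)H/FAD-bright cytoplasm ellipsoid around a dark elliptical nucleus
  (5–10 µm diameter, axially flattened); a configurable fraction (default
  0.4) carries a perinuclear melanin cap — a 1.6 µm shell on the
  superficial side of the nucleus;
* melanocytic dendrites: branching random walks from the basal layer,
  ~1 µm diameter, upward drift, branch probability 0.08 per step, carrying
  melanin; ~60 per mm²;
* dermis (below 60 µm): collagen (prompt/SHG) and elastin as oriented
  band-pass noise (anisotropically smoothed white noise, upper-quantile
  thresholded), filling 35 % and 12 % of the dermal volume.

`melanin_truth` is exactly the set of voxels with positive melanin
concentration; `dendrite_truth` marks the walks. Same seed, same phantom,
bit for bit.

**Optical sectioning.** Sections are Gaussian-weighted axially (weights
normalized over slices) and blurred laterally, with FWHM 3.3 µm / 0.5 µm
per the instrument's printed axial/lateral resolutions; Gaussian is chosen
for separability. Ground-truth sections are attenuation-free by contract;
depth attenuation belongs to the photon model.

**Concentration units** are arbitrary; absolute photon budgets are set by
the fluorophore `brightness` (photons per µs dwell per unit concentration),
calibrated below.

## Photon counting (`photonsim`)

Expected single-frame counts per pixel: brightness × concentration section ×
per-frame dwell × e^(−depth/ℓ), with ℓ = 150 µm as a plausible effective
attenuation length for near-infrared excitation in skin. The 4 kHz
bidirectional resonant scan gives a 0.128 s frame (1024 lines), dwell
uniform over the raster (resonant velocity nonuniformity and duty cycle are
ignored — the ~9 µs / ~2 s arithmetic the instrument reports is consistent
with the uniform model). Counts are Poisson; n accumulated frames are one
draw at n-fold mean, which is exact. Training pairs bypass the time-binned
stack (a sum of Poisson bins is Poisson in the summed mean). Pair streams
are keyed by (seed, section, accumulation), so distinct accumulation levels
are independent while input = ground-truth accumulation degenerates to the
identical image.

**Photon-budget calibration.** Default brightnesses (melanin 3.0, keratin
0.75, NAD(P)H 0.6, elastin 0.6, FAD 0.3, collagen 1.2) are frozen so that
15-accumulation epidermal sections score mean SSIM ≈ 0.39 against
70-accumulation ground truth — inside the 0.3–0.5 band that regime is
reported to occupy — with melanin the brightest fluorophore. Lifetime
defaults (melanin 0.2 ns; NAD(P)H 0.4/2.5 ns at 0.75/0.25; keratin 1.4;
elastin 1.7; FAD 2.3; SHG prompt) are literature-informed and overridable.

## Gating and virtual staining (`gating`)

Red/green channels are whole-bin sums; corrected red = max(red − green, 0),
clipped after channel integration per image (never per bin). For melanin
(0.2 ns) the analytic gate-mass difference is +0.70 per detected photon
(with IRF; +0.85 ideal); every other default fluorophore is negative except
NAD(P)H, whose fast component leaves a small positive residue (+0.23) — the
main false-positive source in discrimination.

**Stain threshold policy.** Otsu's method on the pooled nonzero
corrected-red histogram of the stack. Otsu presumes the pool is bimodal
(clipping noise vs melanin); when its two classes are not separated (lower
mean > 60 % of upper mean — an effectively unimodal pool of pure signal),
all nonzero pixels count as positive. Degenerate pools fall back to a fixed
quantile (0.99). Dice scores the thresholded mask; ROC AUC scores the raw
corrected-red values and is threshold-free.

**Truth resampling for scoring.** An optical section gathers signal from a
~3.3 µm slab, and z-planes at k·5 µm fall on voxel boundaries of the 5 µm
phantom grid, so a plane's melanin label takes every phantom slice within
the axial profile's half-maximum support (both adjacent slices at a
boundary). The noise-free corrected-red expectation separates these labels
perfectly (AUC 1.0); the measured AUC ≈ 0.91 at 15 accumulations is set by
photon noise at the calibrated budget.

## Mosaics (`mosaic`)

Planners reproduce the instrument's worked geometries exactly: ceil-covering
strips (10 × 12 mm at 0.75 mm → 16 strips; 13 mm travel limit enforced),
ceil-covering tile grids on the effective step fov × (1 − overlap)
(4.5 mm / 0.9 mm → 5×5 = 25 nominal MPx; 6.3 mm → 7×7 = 49), and z-stacks
with planes at k·step, n = round(range/step) (150/5 → 30; the inclusive
convention is not published — this one reproduces the printed 30).

Strip simulation crops the truth at serpentine offsets (seeded Gaussian
lateral jitter, whole pixels; return strokes stored reversed); stitching
abuts at planned offsets — registration is attributed to hardware
synchronization, so no cross-correlation step, and jitter is exposed as a
simulation parameter instead. The anisotropic-raster rebin upsamples the
coarser axis bicubically (the 1.25 pitch ratio is the only one consistent
with the printed 64 → 80 MPx pair; the raw raster dimensions are not
published). Flat-field correction fits an order-2-per-axis 2-D polynomial
to the across-tile mean (content averages out, the shared gain does not),
normalized to unit mean — invariant to global intensity scale by
construction; the correction is described only as "trivial", so the
multiplicative low-order model is a choice.

## Restoration (`restore`, `_nn`)

The paired protocol: pixel-registered low/high-SNR pairs; grid-cut patches
(64–256 px, validated against the published patch-size study range); seeded
10 % validation split (floor convention: 35,200 → 3,520/31,680); both input
SNR levels pooled into one model; MSE loss.

**Network.** A small U-Net-style encoder-decoder written directly in numpy
(no deep-learning framework is part of the dependency footprint):
two-conv blocks, 2×2 mean pooling, nearest-neighbour upsampling with skip
concatenation, a 1×1 output head, and a global residual connection (the
model predicts a correction to its input, making the identity trivially
representable). Convolutions run as im2col matrix products in float32;
training is bit-reproducible for a fixed seed. The benchmark configuration
uses 3 scales × 12 base features (receptive field ≈ 45 px): in a protocol
study, two scales plateaued well below the achievable quality, and the
deeper model with a variance-stabilizing √counts transform on the input
(targets stay linear) recovered substantially more structure — the sqrt
compresses the bright melanin caps that otherwise dominate the MSE at the
expense of the dim cellular texture. Minibatches are augmented with the
eight flip/rotation symmetries (skin sections have no preferred in-plane
orientation). Adam at 3e−3, decayed ×1/3 at ⅔ of the epochs; one-cycle
schedules, dropping the global residual, and post-decay weight averaging
were also evaluated in the protocol study and did not help.

**Inference.** Overlap-blended tiled prediction (linear feather, weights
sum to one everywhere); output shape equals input shape. The benchmark
restores each 256² section as one tile and averages the prediction over
the same eight symmetries used in training. The model's output lives on
the target-normalized scale; `restore_image` can map it back to the
input's intensity scale, but evaluation uses the native output directly.

**Evaluation.** MSE/MAE/SSIM per image, mean ± sd over the set. Ground
truth and inputs are normalized by their own 0.1/99.9 percentiles (this
aligns the different accumulation scales); restored images are compared on
their native normalized scale — re-estimating percentile anchors from a
denoised image is biased, because denoising deflates the extreme
percentiles relative to a noisy reference. SSIM uses 7-px Gaussian windows
(σ 1.5), with the data range taken from the pooled normalized ground-truth
set. The published quality numbers (MSE 0.005 / MAE 0.05) depend on an
unpublished normalization convention and are not comparison targets.

**What the benchmark shows.** At the calibrated budget the noise-free field
scores SSIM ≈ 0.71 against the (itself noisy) 70-accumulation ground truth
— that is the ceiling any restorer can reach, and it is consistent with the
0.6–0.7 band reported for restored real images. The reduced-scale benchmark
(13 phantoms of 30×256×256, depths 20–50 µm, ~2,100 64-px patch pairs,
60 × 30 training steps, 20 held-out sections — sizes chosen so the full
benchmark runs in under a quarter hour on one CPU) lifts held-out SSIM
from ≈ 0.40–0.42 (raw 15-accumulation) to ≈ 0.57–0.61 depending on the
master seed, with every held-out section improving by 0.15–0.19 SSIM.
The residual gap to the 0.6–0.7 band of the full-scale protocol (35,200
patches of 128 px, a full-depth network, orders of magnitude more
optimization) is the expected cost of the reduction in scale.

## Seeds and reproducibility

One master seed fans out to per-stage streams (phantom, simulate, gate,
stitch, zstack, train, restore, eval) via `numpy.random.SeedSequence` spawn
keys, so any stage can be rerun independently and reproduce the stream it
saw in a full run. Every CLI output directory receives the resolved
configuration and package version.

## Limitations

The phantom's geometry generators are stylized: no hair follicles, sweat
glands or skin folds; no refractive-index heterogeneity, aberrations, or
depth-dependent PSF degradation; no detector afterpulsing, pile-up or
photobleaching; uniform resonant-scan dwell. Synthetic results therefore
demonstrate the *mechanisms* (gate discrimination at a photon budget,
mosaic geometry, paired-restoration gains) rather than clinical
performance: passing benchmarks here shows the chain is implemented
correctly and behaves as the physics predicts at the stated budgets, not
that identical numbers would be obtained on human skin. Restoration quality
on real tissue additionally depends on feature diversity the phantom only
partially emulates.
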