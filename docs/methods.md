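# Methods

## Problem setting

Conventional DNA-PAINT accumulates localizations over N ≈ 30,000 camera
frames to render one super-resolution image. `upaint` trains a U-Net to map
a *sparse* localization render — built from n ≪ N frames, so containing the
same structures at ~n/N of the point density — to the *dense* render,
optionally with a diffraction-limited widefield image as a second input
channel. Training pairs come either from real acquisitions (sparse and dense
renders of the same field) or from the microtubule simulator below.

## Microtubule simulator

Each simulated field contains `n_trajectories` (default 10) filaments.
A trajectory starts at a uniformly random point on the boundary of the
square working field and takes one step per frame for `n_frames` (default
500) frames. Every step has fixed length `step_length` (default 0.5 px,
small enough that consecutive points overlap into a continuous line after
blurring); its noise-free direction points from the current position toward
the field center, and the realized direction is that heading rotated by a
zero-mean normal angle with standard deviation `heading_noise_sd`.

Choices the protocol leaves open, fixed here:

- **Noise geometry.** The step perturbation is angular (rotation of the
  unit heading by N(0, `heading_noise_sd`), default 0.35 rad). This
  preserves the exact step length while making displacements normally
  distributed around the center-pointing heading. A displacement-space
  perturbation would instead randomize the step length.
- **Working grid.** `field_width` = 512 px rendered 1:1 (no rescale by
  default; `rescale_factor` is exposed) and center-cropped to the 256 px
  tile, so most filaments cross the crop region. Boundary sampling is
  uniform over the perimeter.
- **Binning.** Floor binning of continuous coordinates into 0-based pixel
  cells; cell (i, j) covers the half-open square [i, i+1) × [j, j+1), so no
  point is counted twice. Points that leave the field are clipped at render
  time, not during the walk.

The rendering chain: the all-frame overlay is blurred with a Gaussian of
σ = `gt_blur_sd` (1.25 px, reflective boundary handling to avoid dark rims
on crops) and center-cropped — that is the ground truth. The widefield
channel blurs the ground-truth tile with σ = `wf_blur_sd` (20 px), averages
it down to a `wf_small_size` (32 px) grid — an area average, matching a
camera pixel's integration — and rescales bilinearly back to tile size. The
sparse channel overlays a random `sparse_fraction` (10%, round-half-up,
minimum one frame) subset of frames and runs through the same chain; a
"first n frames" mode mirrors the real-data convention.

Filaments are single-point-wide paths: the ~26 nm hollow-cylinder geometry
of real microtubules is not modelled, so simulated filaments are thinner
than real ones. No photophysics (binding kinetics, photon shot noise,
camera noise) and no 3-D structure are simulated. Consequences for testing:
experiments on simulated data exercise the full pipeline and the network's
ability to restore dense line structure from sparse point renders, but say
nothing about robustness to real-data artifacts (drift residues, background,
label sparsity); models trained purely on these simulations are known to
need real-data fine-tuning before they restore real microtubules well.

## Triplet normalization

Real-data preparation tiles the full-field images on a 256-px grid, drops
tiles whose mean intensity is below `alpha` (default 1.0) × the uncut-field
mean — the keep mask is computed on the dense channel and applied to all
three channels — and divides intensities by the uncut field's maximum.
The widefield channel is always normalized to its own maximum. For the
localization renders the package defaults to a **shared divisor** (the dense
field's maximum) for sparse and dense: a sparse render is physically dimmer
than the dense one, and the shared divisor preserves that ~n/N intensity
ratio, which is also what makes "sparse total intensity ≤ dense total
intensity" hold for every triplet. `render_divisor="per_channel"` restores
the per-image convention (each render divided by its own maximum) for users
whose upstream pipeline normalizes that way.

## Network

The architecture is the standard image-restoration U-Net: an input double
convolution (two 3 × 3 same-padded convolutions, each followed by ReLU),
four downsampling stages (2 × 2 max pool then double convolution, channel
count doubling from a base of 64), four upsampling stages (2 × 2 transposed
convolution halving the channels, concatenation with the matching encoder
activation, double convolution), and a 1 × 1 output convolution — ten
stages in all. No normalization layers; He initialization. At the defaults
this is 31,030,593 trainable parameters (a second input channel adds
exactly 9 × 64 = 576 first-layer weights). Transposed-convolution
upsampling (rather than interpolation + convolution) is what places the
default spec slightly above the 31 M budget.

Training minimizes mean squared error on [0, 1] intensities — consistent
with evaluating by RMSE/PSNR — with Adam at learning rate 1e-4 by default
(plain SGD selectable); the published schedule for full-scale runs is 2,000
epochs on real triplets, 2,000 more on simulated triplets, then a 500-epoch
real-data fine-tune (`PUBLISHED_TRAINING_SCHEDULE`). Inputs per variant:
`3000` = sparse only, `WF` = widefield only, `WF+3000` = widefield + sparse
(two channels); the target is always the dense channel. Predictions are
clamped to [0, 1].

The engine is pure NumPy with explicit layer-by-layer backpropagation.
Activations are float32 in channel-major (C, B, H, W) layout so each
convolution — forward, weight gradient, and data gradient (a full
correlation with the 180°-rotated kernel) — is a single BLAS matrix product
over an im2col patch matrix. Training is deterministic for a fixed seed and
thread configuration; BLAS reduction order is the only caveat, and in
practice repeated runs agree bitwise.

## Evaluation

Images are affinely mapped to [0, 255] (for [0, 1] tiles: × 255; a constant
image with no declared range is rejected as ambiguous). RMSE is the root
mean squared pixel difference. PSNR is piecewise: exactly 100 when RMSE = 0,
else 20·log₁₀(255/RMSE) — the formula is applied as printed, with no cap
below 100. SSIM is *global* (whole-image means, variances, covariance — no
sliding window), with population moments by default (`sample_moments`
switches to n−1) and constants c₁ = (0.01·255)², c₂ = (0.03·255)². The
covariance numerator term is the standard doubled form 2·cov + c₂, which is
what makes SSIM exactly 1 for identical images; a `numerator="printed"`
mode with the bare cov + c₂ term is kept for comparison against sources
that state the formula that way. SSIM is bounded above by 1 but can be
negative for anti-correlated pairs; only the upper bound is asserted.
Model comparison uses the classic two-independent-sample t-test
(equal-variance, two-sided) on per-image metric values.

## Desk-scale experiment sizing

The test suite's end-to-end experiment runs the whole chain at a reduced
scale chosen to keep a single-CPU run in the tens of minutes: 200 simulated
fields of 64 × 64 px, 50 frames, 10% sparse fraction, step length 1.5 px
(so a 50-step walk crosses most of a 64 px field, as 500 half-pixel steps
cross a 256 px field), widefield blur σ = 5 px on an 8 px grid (the 256-px
protocol scaled by 1/4), and a reduced U-Net (depth 3, base 16, ≈ 0.48 M
parameters) trained for 200 epochs with Adam at 1e-3, batch 2, fixed seeds
throughout. A 20% source-level hold-out (40 tiles) is evaluated against
both the reconstruction and the raw sparse input. The learning rate is
higher than the full-scale default because the reduced problem tolerates
it; the improvement margins are large (tens of dB PSNR), so the outcome is
insensitive to these choices.

## Pipeline reproducibility

Every stochastic stage derives its stream as SHA-256(global seed : stage
name) reduced below 2³¹, so changing one stage's workload cannot perturb
another stage's draws. Runs write a manifest with the effective config,
derived seeds, and SHA-256 hashes of every emitted file; re-running the
same config and seed reproduces byte-identical metric CSVs.

## Known limitations

- The simulator's realism gaps listed above; in particular, no claim is
  made that metrics on simulated data predict real-data metrics.
- Full-scale training (256-px tiles, 31 M parameters, thousands of epochs)
  is impractical on a single CPU; the NumPy engine is sized for desk-scale
  experiments and inference.
- Upstream localization (spot detection, MLE fitting, drift correction) is
  out of scope; tables are assumed drift-corrected.
- The ellipticity convention 1 − min(sx, sy)/max(sx, sy) is this package's
  documented choice; users whose fitting software defines ellipticity
  differently should supply a precomputed `ellipticity` column.
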