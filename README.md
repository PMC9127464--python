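# upaint

Accelerated DNA-PAINT super-resolution reconstruction.

DNA-PAINT is a single-molecule localization microscopy (SMLM) technique:
dye-labeled imager strands bind transiently to docking strands on the target
structure, and tens of thousands of camera frames of such blinking events are
fitted and accumulated into one super-resolution image. The frame budget —
typically N ≈ 30,000 at 100 ms exposure — rules out fast or live imaging.
`upaint` implements the U-PAINT approach: a U-Net image-restoration network
that reconstructs the dense localization image from a **sparse** render built
from roughly one-tenth of the frames (n ≪ N), optionally assisted by a
diffraction-limited widefield image of the same field as a second input
channel.

The package is aimed at microscopists and methods developers who want to
train and evaluate such sparse-to-dense restoration models without GPU
infrastructure: the network runs on a compact NumPy engine with explicit
backpropagation.

## What is inside

| module | role |
|---|---|
| `upaint.simulate` | random-walk microtubule simulator: ~10 filaments per field walk in fixed half-pixel steps from the image boundary toward the center over 500 frames; ground truth = all-frame overlay blurred with σ = 1.25 px; widefield = σ = 20 px blur on a 32-px grid; sparse = random 10% frame subset |
| `upaint.localizations` | Picasso-style HDF5/CSV localization tables; ellipticity > 0.6 quality cut; first-n / random-n frame subsetting; 16×-oversampled histogram rendering (8 nm render pixels from 128 nm camera pixels) |
| `upaint.prep` | 256 × 256 grid tiling, mean-intensity tile exclusion, normalization to the uncut-field maximum, aligned (widefield, sparse, dense) triplets, leakage-free train/test splits |
| `upaint.network` | the U-Net (4 down / 4 up stages plus input and output blocks, base 64 channels, ≈ 31.0 M parameters), training variants `3000` / `WF` / `WF+3000`, prediction, tile stitching, checkpoints |
| `upaint.metrics` | evaluation on the [0, 255] scale: RMSE, piecewise PSNR (100 at zero error, else 20·log₁₀(255/RMSE)), global SSIM, two-sample t-test for model comparison |
| `upaint.pipeline` / `upaint.cli` | reproducible end-to-end runs (`upaint simulate|render|prepare|train|predict|evaluate|run`) with per-stage seeds and a hashed run manifest |

The evaluation metrics, with GT the ground truth and OP the reconstruction
(both mapped to [0, 255]):

    RMSE = √(mean((GT − OP)²))
    PSNR = 100 if RMSE = 0, else 20·log₁₀(255 / RMSE)
    SSIM = (2·μ_GT·μ_OP + c₁)(2·cov(GT,OP) + c₂) /
           ((μ_GT² + μ_OP² + c₁)(σ_GT² + σ_OP² + c₂))

with c₁ = (0.01·255)², c₂ = (0.03·255)² and whole-image (global) moments.

## Worked example

```python
import numpy as np
from upaint import (SimulationConfig, UNet, UNetSpec, TrainConfig,
                    generate_dataset, split_dataset, train, predict,
                    evaluate_pair, summarize_reports)

cfg = SimulationConfig(field_width=64, tile_size=64, n_frames=50,
                       step_length=1.5, wf_blur_sd=5.0, wf_small_size=8, seed=7)
triplets = generate_dataset(cfg, 60)
train_set, test_set = split_dataset(triplets, 0.15, np.random.default_rng(1))

model = UNet(UNetSpec(in_channels=1, depth=3, base_channels=16, tile_size=64), seed=2)
model, history = train(model, train_set,
                       TrainConfig(epochs=30, batch_size=2, learning_rate=1e-3, seed=3),
                       variant="3000")

model_reports = [evaluate_pair(t.dense, predict(model, sparse_tile=t.sparse))
                 for t in test_set]
sparse_reports = [evaluate_pair(t.dense, t.sparse) for t in test_set]
for name in ("psnr", "rmse", "ssim"):
    print(name,
          round(summarize_reports(model_reports)[name]["mean"], 3),
          "vs sparse", round(summarize_reports(sparse_reports)[name]["mean"], 3))
```

Output from this exact script:

```
psnr 43.856 vs sparse 28.004
rmse 1.661 vs sparse 10.152
ssim 0.989 vs sparse 0.346
```

Even this 30-epoch toy model reconstructs held-out tiles far closer to the
dense ground truth (PSNR ≈ 44 dB, SSIM ≈ 0.99) than the raw sparse inputs
(PSNR ≈ 28 dB, SSIM ≈ 0.35): the network restores the dense filament
structure from one-tenth of the frames.

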