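# echosr — beamline super-resolution for 2-D ultrasound

Ultrasound probes trade spatial against temporal resolution: every
beamline costs one pulse round trip, so a frame of `l` lines at depth `d`
cannot be acquired faster than `f = c / (2 d l)` (with `c` the speed of
sound).  Halving or quartering the number of acquired lines doubles or
quadruples the achievable frame rate — crucial for fast-moving anatomy
such as the mitral valve — at the price of lateral resolution.

`echosr` reconstructs the full lateral grid from such reduced (0.5X /
0.25X) acquisitions in two stages:

1. **Cubic-convolution up-sampling** of the missing beamlines with Keys'
   kernel (`a = -0.5`), strictly 1-D along the lateral axis; acquired
   lines are copied bit-exactly.
2. **Learned refinement** with a wide-activation residual network
   (WDSR-A style, constant resolution, weight-normalised convolutions;
   3×3 kernels for 2X, 5×5 for 4X, so every footprint spans at least two
   acquired lines).  The pinned 2X architecture has 888,989 trainable
   parameters (~889K).  Training minimises a masked logarithmic loss

       Loss(y, ŷ) = Σ log((|y_ld − ŷ_ld| + ε) / k),   ε = 1e-4, k = 5/255,

   summed over the *interpolated* lines only: errors below 5 grey levels
   (the visually indistinguishable band) are rewarded, outliers are
   tempered by the log, and the bit-exact acquired lines contribute
   nothing.

The package is aimed at researchers studying line-interpolation
super-resolution: it ships the full pipeline (dataset construction,
training, prediction, evaluation with PSNR / global SSIM / MAE / error
histograms / box-plot statistics, frame-wise video processing, and the
acquisition-frequency calculator) plus a synthetic speckle-phantom
generator — diffuse Rayleigh speckle, smooth inclusions, and specular
interface bands — so everything runs without proprietary scanner data.
The network and its training loop run directly on NumPy (BLAS-backed
convolutions, hand-written and finite-difference-verified gradients);
no deep-learning framework is required.

## Worked example

```python
import numpy as np
from echosr import (PhantomSpec, SamplingScheme, ExperimentConfig,
                    generate_phantom, downsample_beamlines,
                    superresolve_image, run_experiment, acquisition_frequency)

# a 64-line acquisition at 8 cm depth runs at
print(f"{acquisition_frequency(1540.0, 0.08, 64):.1f} Hz")   # 150.4 Hz
# versus 75.2 Hz for the full 128 lines.

# train the 2X refinement network on synthetic phantoms
# (150 train / 25 val / 25 test images of 64x64, 30 epochs, n_feats=8)
report, artifacts = run_experiment(ExperimentConfig(seed=1))
print(round(report.cohort["input_psnr"]["median"], 2))        # 37.06 dB  (cubic)
print(round(report.cohort["prediction_psnr"]["median"], 2))   # 37.07 dB  (network)
print(round(artifacts["history"]["loss"][0]))                 # -4498
print(round(artifacts["history"]["loss"][-1]))                # -5488
```

The cubic up-sampler already sits in the high-PSNR regime on these
phantoms (its error is dominated by statistically unpredictable
speckle), and the trained network adds a small median PSNR gain
concentrated at the specular interfaces — the lateral structures cubic
interpolation systematically blurs.  The training loss falls from its
identity-start value towards the floor `N_masked · log(ε/k)`; its
decrease and the prediction-vs-input comparison are the two headline
outputs.  With `out_dir` set, the driver writes per-image CSV and cohort
JSON reports, the training history, the model checkpoint, and optional
box-plot figures.

A command-line interface mirrors the library:

```bash
echosr simulate --n 10 --size 64 --out phantoms/
echosr train --up-factor 2 --seed 1 --out runs/demo
echosr predict --model runs/demo/model.npz --image low.png --out pred.png
echosr freq --depth 0.08 --lines 64
```

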