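# Methods

`echosr` implements a two-stage lateral super-resolution scheme for 2-D
B-mode ultrasound, together with the evaluation protocol and a synthetic
phantom generator that makes the whole pipeline trainable and testable
without scanner data.  This note records the model, the parameters that
matter, the numerical choices, and what the synthetic experiments do and
do not demonstrate.

## Problem and model

A B-mode frame is an `L x D` grid: `L` beamlines (lateral axis, one line
per transmit/receive event) by `D` depth samples.  Acquiring fewer lines
speeds up the frame — the achievable frame rate is `f = c / (2 d l)` for
speed of sound `c`, depth `d` and line count `l`, since every line costs
one round trip — but lowers lateral resolution.  The pipeline reconstructs
the full lateral grid from a half (0.5X) or quarter (0.25X) acquisition in
two stages:

1. **Cubic-convolution up-sampling.**  Missing lines are interpolated
   1-D along the lateral axis with Keys' piecewise-cubic kernel
   (`a = -0.5`, 4-line support, quadratic reproduction precision).
   Acquired lines are copied bit-exactly.  The depth axis is never
   resampled.
2. **Learned refinement.**  A wide-activation residual network (WDSR-A
   style) maps the up-sampled image to an approximation of the
   high-resolution target at constant resolution — no pixel shuffle or
   deconvolution, since stage 1 already restored the grid.

### Sampling conventions

* Acquired lines sit at lateral indices `l` with `(l - phase) mod s = 0`,
  `phase = 0` by default, so index 0 is always acquired and the 2X and 4X
  grids nest.
* If `L` is not divisible by `s`, trailing lines are trimmed before
  pairing (deterministic, keeps grid alignment trivial).
* Boundary handling uses Keys' quadratic extrapolation
  `f(-1) = 3 f(0) - 3 f(1) + f(2)` (mirrored at the far edge, applied
  recursively for the second guard line), which preserves the kernel's
  polynomial precision at the borders; a linear lateral ramp is therefore
  reproduced exactly everywhere, including the trailing extrapolated
  lines.
* Intensities are real-valued throughout; quantisation to 8/16 bits
  happens only at image export.  Interpolation overshoot is clipped back
  into the declared intensity range; acquired lines are never touched by
  the clip.

### Network

Input normalisation (subtract the training-set mean intensity, a fixed
affine map) → head convolution (1 → `n_feats`) → 8 residual blocks
[conv `n_feats` → 6·`n_feats`, ReLU, conv back, additive identity] → tail
convolution (`n_feats` → 1) → added to a 5×5 global skip convolution of
the normalised input → denormalisation.  All convolutions use zero
same-padding and weight normalisation (direction tensor + per-output-
channel scale + bias).  Kernel size is 3×3 for the 2X network and 5×5 for
the 4X network, so every footprint spans at least two acquired lines.

Pinned widths: `n_feats = 32` at 2X — 888,989 trainable parameters
(~889K), the count the closed-form formula and the instantiated model
must agree on exactly — and `n_feats = 10` at 4X (~242K).

The network runs directly on NumPy: convolutions are expressed as `k²`
large GEMMs over offset slices of the flattened zero-padded batch
(channels-last layout), which keeps all arithmetic inside BLAS on a
single CPU; forward/backward passes are hand-written and the gradients
are verified against central finite differences in the test suite.

**Initialisation.**  Kernels are He-uniform; weight-norm scales start at
1 — except the tail convolution's scale, which starts at 0, and the
global skip convolution, which starts as an identity (delta) kernel.  A
freshly built model is therefore exactly the identity map: training
starts from the cubic-interpolation baseline and can only be pushed away
from it by the loss.  This makes the refinement interpretable (the
learned part is literally the departure from cubic) and reproducible
under seed control.

### Masked logarithmic loss

Per image, on [0, 1]-normalised data,

    Loss(y, ŷ) = Σ_{masked l, all d} log((|y_ld - ŷ_ld| + ε) / k)

with `ε = 1e-4` and `k = 5/255 ≈ 0.019`.  A pixel whose error equals 5
grey levels contributes ≈ 0; smaller errors contribute negatively (the
loss rewards pushing pixels into the "visually indistinguishable" band),
and the log tempers outliers.  The global minimum over ŷ is
`N_masked · log(ε/k) ≈ -5.278 · N_masked`, attained at ŷ = y.

The mask covers the **interpolated** lines only.  The acquired lines are
copied bit-exactly by stage 1, so penalising them is vacuous; a config
switch (`mask_convention="interpolated"`) reproduces the complementary
residue-class convention for comparison.  The gradient with respect to
acquired-line pixels is identically zero; predictions may still alter
acquired lines at inference (no masking there), which mirrors the
intended deployment and is reported as the |input − prediction|
alteration statistic.

The log base is natural (base only rescales the loss); the per-image sum
is averaged over the batch so learning rates are batch-size independent.

### Training schedule

Adam, with the learning rate decaying geometrically from `lr_initial`
to the floor `1e-6`, reached exactly at the final epoch.  The full-scale
regime is 200 epochs; the desk-scale default used by the experiment
driver and the tests is 30 epochs on 150/25/25 images of 64×64 with
`n_feats = 8` — sizes chosen so a complete experiment trains in minutes
on one CPU while preserving every structural element of the method.
No early stopping (fixed epoch budget).  Training is bitwise reproducible
for a fixed seed.

The optimiser and its hyper-parameters are design choices of this
package (the method's description fixes only the floor and the epoch
count).  They were selected on training/validation convergence of the
masked log loss: this loss has an unusually noisy stochastic gradient —
its per-pixel magnitude is `1/(|e| + ε)`, so nearly-correct pixels
dominate each mini-batch with large, sign-alternating contributions, and
the systematic component of the error drifts out of the noise only over
many small steps.  Small batches (more optimisation steps per epoch) with
a moderate initial rate converge markedly better than few large steps.

## Synthetic phantoms

The generator emulates B-mode texture at the image-grid level with the
two standard scattering components:

* **Diffuse speckle** — a complex circular-Gaussian scatterer field
  (fully developed speckle limit), amplitude-scaled by an echogenicity
  map with smoothly tapered elliptical inclusions, convolved with a
  separable PSF: lateral Gaussian (`psf_lateral_sigma`, default 4 px)
  and axial Gaussian modulated by a carrier (pulse oscillation).  The
  envelope of the uniform field is pointwise Rayleigh (mean/std
  ≈ 1.91), the canonical speckle statistic.
* **Specular interfaces** — bright curved bands (fascia-, capsule- or
  vessel-wall-like) added to the complex field *after* the diffuse PSF,
  because coherent reflections are pulse-limited (axially sharp), not
  beam-limited.  Each band undulates in depth across lines; where its
  slope crosses a given depth, intensity changes sharply from line to
  line.  These crossings are exactly the structures lateral
  interpolation blurs, and the places where the learned refinement can
  systematically beat it.

The envelope is log-compressed over a 50 dB dynamic range onto [0, 1]
and optionally shifted in mean brightness.  Videos freeze the scatterer
noise and translate the anatomy, so features move over a coherent
speckle background.

**Calibration.**  The default lateral PSF width was set so that the
cubic-convolution 2X baseline lands in the regime typical of clinical
2X B-mode reconstruction (mean PSNR in the mid-to-high 30s dB); with
the default anatomy sampler the synthetic cubic baseline is ≈ 37–38 dB
median.  Without the specular component the diffuse field alone is so
laterally smooth at that calibration that cubic interpolation is
already statistically optimal and no refinement is learnable —
unrepresentative of real scans, where reconstruction error concentrates
at anatomical contours.  The interface component restores that regime.

**What the phantoms do not emulate:** attenuation and time-gain
compensation, shadowing and enhancement artefacts, sector-scan geometry,
motion deformation (videos translate rigidly), electronic noise, and
scanner post-processing.  Passing the synthetic experiments shows the
pipeline is correctly assembled and that training recovers learnable
structure at desk scale; it does not certify clinical image quality.

## Evaluation protocol

Metrics are computed on the 0–255 scale (where the published thresholds
of 5 and 20 grey levels live), target first:

* PSNR with the peak taken from the target image (printed-formula
  convention, not a fixed dynamic range); identical images report `inf`.
* SSIM as the global luminance·contrast·structure product with
  population moments and `C1 = (0.01 R)², C2 = (0.03 R)², C3 = C2/2`.
  The printed formula's asymmetric denominators (`μ_A² + μ_A²`,
  `σ_A² + σ_A²`) are treated as typos for the standard symmetric form.
  A sliding-window variant is exposed as an option.
* MAE, the pointwise |A − B| error image with its maximum, and the
  error histogram with half-open bins of width 5 ("error lower than 5"
  is strict; counts conserve the pixel total).
* Cohort statistics as box plots: median, linearly interpolated
  quartiles, Tukey 1.5·IQR whiskers (the whisker convention is pinned
  here; the method's description does not state one).

The experiment driver evaluates the trained prediction against the cubic
input on a held-out test split, writes per-image CSV and cohort JSON
reports, the |input − prediction| alteration maxima, the training
history, and optional box-plot/histogram figures.

## Degenerate inputs and numerical edges

* `psnr` returns `inf` at zero MSE and raises on an all-zero target with
  nonzero error.
* The cubic kernel requires `a < 0`; up-sampling requires ≥ 4 low-res
  lines (boundary extension undefined below that) and decimation
  requires `L ≥ 2s`.
* The image container enforces the declared value range and `L ≥ 2`
  (a 4X acquisition of an 8-line frame has 2 lines).
* Non-finite training loss aborts with the offending epoch (divergence
  signal).
* Histogram bin count adapts to the largest observed error; identical
  images produce a single bin holding every pixel.

## Known limitations

* At desk scale the PSNR margin of the refinement over cubic is small
  (hundredths of a dB on mostly-speckle phantoms) — fully developed
  speckle is statistically unpredictable from decimated lines, so only
  the systematic interface/edge component is recoverable.  Larger gains
  require large real data sets with far more deterministic structure
  than speckle phantoms provide.
* Videos are processed frame-independently; no temporal model.
* The optional denoising pre-process is a pluggable hook only (identity
  by default); no denoiser ships with the package.
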