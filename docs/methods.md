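# Methods

## Problem and scope

`spongehb` estimates surgical hemoglobin (Hb) loss from photographs of
blood-soaked surgical sponges. The quantity of interest is the Hb mass
per sponge in mg — concentration (g/L) times absorbed volume (mL) — and
the package implements and compares three estimators on images alone:

1. **Feature extraction + linear regression** — four predictors
   (color moments MEA, VAR, SKE and the blood-to-sponge area ratio) in
   an OLS model `y = b0 + b1·X1 + b2·X2 + b3·X3 + b4·X4`.
2. **ResNet regressor** — a bottleneck-block residual CNN with a
   single-unit regression head.
3. **SE-ResNet regressor** — the same backbone with
   squeeze-and-excitation channel attention (reduction 1/8).

Because no public sponge-image dataset with reference Hb masses exists,
the package ships a synthetic scene generator with exact ground truth;
all tests and the acceptance script run against it.

## Synthetic scene model

A scene is a uniform background (green drape, RGB (0.20, 0.35, 0.30)),
a textured sponge rectangle (base color (0.93, 0.91, 0.86), gray
multiplicative Gaussian texture, amplitude 0.02) and an irregular stain.
The defaults model a 10×10 cm sponge photographed at 40 px/cm in a
512×512 frame; `SceneParams.scaled(size)` renders the same physical
scene at a smaller frame (test suites use 96–128 px) without changing
any color, because the optics below depend only on physical densities.

**Stain geometry.** The sponge holds `a = 0.04` mL of blood per cm² of
stain (a thin-gauze absorbency, i.e. a ~0.4 mm fluid layer), so a volume
`v` spreads over `v / a` cm². The footprint is a circle of that area
with a low-order random Fourier perturbation of the boundary (relative
roughness 0.12, 6 harmonics) and a jittered center, clipped to the
sponge. Stain area is therefore proportional to volume — the area-ratio
feature X4 is a volume proxy.

**Stain color.** Each channel of a stained sponge pixel is attenuated
Beer–Lambert-style by `exp(-k_c · σ)`, where `σ = hb_mass / stain_area
= c · a` mg/cm² is the Hb surface density (independent of volume — more
blood spreads further but is not thicker) and
`k = (0.030, 0.145, 0.125)` cm²/mg. Red attenuates least, so stains are
red-brown; the green-channel optical depth spans ≈ 0.29–0.99 over the
clinical concentration range 50–170 g/L, which keeps mean stain
intensity strictly monotone in concentration and far above the
segmentation threshold even at maximal dilution.

**Noise and quantization.** Additive Gaussian camera noise (SD 2 on the
0–255 scale by default; tests that check exact colorimetry switch it
off), then rounding to 8-bit. Rendering is bit-exact under a fixed
`(sample, scene, seed)`; dataset generation fans a master seed out into
per-image seeds via `numpy.random.SeedSequence` and records them in the
manifest, so any single image is reproducible in isolation.

**Defaults as study conditions.** Concentrations are drawn uniformly
from 50–170 g/L (the clinical range of Hb values after hemodilution).
Applied volumes default to 0.2–3.0 mL, chosen so per-sponge masses span
~10–510 mg; at 3 mL the stain covers ~75% of the sponge, at 0.2 mL ~5%.

**What the generator does not emulate:** non-sanguineous contaminants
(ascites, saline dilution on the sponge itself), sponge wrinkling and
3-D folds, specular highlights, illumination drift between photographs,
and camera color response. Passing tests therefore demonstrate that the
estimators recover Hb mass when stain appearance is a clean monotone
function of Hb surface density — they bound implementation error, not
clinical performance.

## Region detection

The sponge/background contrast is handled by a deterministic detector:
pixels whose Euclidean RGB distance from the stated background color
exceeds 30/255 are foreground; connected components under 0.1% of the
frame are discarded; the tightest box around the survivors is returned.
Any callable `image -> BoundingBox` satisfies the same contract, so a
learned detector can be dropped in. VOC-dialect XML (1-based inclusive
`bndbox`) is converted to the package-wide 0-based half-open convention
at the I/O boundary only.

## Features and the linear model

Color moments use the population (divisor-N) definitions on the [0, 1]
intensity scale: MEA = mean, VAR = root-mean-square deviation,
SKE = signed cube root of the mean cubed deviation. They are computed
per channel and averaged across R, G, B to give the scalars X1–X3;
X4 is the fraction of crop pixels segmented as blood (color distance
from the sponge base > 30/255 **and** red channel dominant).

**Moment region.** Moments are taken over the whole sponge crop by
default (`region="crop"`), with a blood-pixels-only mode
(`region="blood"`, whole-crop fallback when the mask is empty) as an
alternative. The default is deliberate: with blood-only moments, MEA
carries concentration and X4 carries volume, but Hb mass is their
*product*, which no linear combination of separate concentration and
volume proxies can represent (the best attainable R² on the default
ranges is ≈ 0.93). The whole-crop mean instead satisfies
`MEA ≈ base · (1 − X4 · (1 − e^{−kσ}))`, whose deficit from the base
color is exactly the area–darkness product, an almost-linear function
of mass; this restores near-linearity (held-out R² > 0.99 noise-free)
and is the reading under which a four-feature linear model is a sound
design in the first place.

Negative fitted masses are clamped to 0 mg only in reported values;
metrics and agreement analysis use the raw predictions so they describe
the fitted model, not the reporting rule.

## CNN regressors

The layer stack (convolution via im2col, batch normalization, max
pooling, SE blocks, Adam) is implemented in numpy with explicit
backpropagation; every layer's gradient is verified against central
finite differences in the test suite, and im2col/col2im are checked as
adjoints. Two variants share the builder:

* **full** — stem 7×7/2 + 3×3/2 max pool, stages (3, 4, 6, 3) of
  bottleneck blocks with widths (256, 512, 1024, 2048), global average
  pool, one-unit head (~28.6 M parameters with SE). Constructed and
  shape-tested; training it for 1000 epochs is a GPU-scale exercise out
  of CPU test scope.
* **tiny** — 3×3 stem, three bottleneck stages of one block each
  (widths 32/64/128), ~38 k parameters, 64×64 input, 30-epoch preset.
  This is the variant all training tests and the acceptance experiment
  use.

SE blocks sit after each bottleneck's final convolution (post-BN),
before the residual addition, with reduction 1/8 (hidden width C/8) —
the placement of the original SE-ResNet design. Two exact algebraic
limits are tested: all-zero excitation parameters gate every channel by
sigmoid(0) = 1/2, and a saturated gate bias reproduces the input
identically, which also collapses an SE bottleneck onto its plain
counterpart.

**Training.** Loss is `MSE + λ·L1` with λ = 1 by default (the two terms
are combined with equal weight; λ is configurable). Optimizer is Adam
at 1e-3, batch 16. Targets are divided by 500 mg during optimization —
raw targets of O(100) against a freshly initialized network produce
huge early gradients — and predictions are rescaled to mg. Weight
initialization and shuffling derive from `config.seed`, making loss
histories exactly repeatable. A non-finite loss aborts with the epoch
index.

Inputs are resized (anti-aliased) to `input_size` and shifted to
[−0.5, 0.5]. Inference uses BN running statistics (momentum 0.1).

## Evaluation

MAE (mg), MAPE (%) and the coefficient of determination
`R² = 1 − SS_res / SS_tot` (negative for predictors worse than the
mean; not the squared correlation). MAPE refuses zero actuals rather
than silently dropping them.

Bland–Altman analysis of differences `d = predicted − actual`: bias =
mean(d), LOA = bias ± 1.96·sd(d) (sample SD, divisor n−1). Confidence
intervals default to the *matched* dialect — half-width `1.96·sd/√n`
for the bias **and** both LOA — because published agreement tables in
this domain print numerically identical half-widths for all three
lines, which the textbook LOA standard error `sd·√(3/n)` (available via
`loa_ci="textbook"`) does not reproduce. A distribution-free mode
(`mode="percentile"`) uses the 2.5th/97.5th percentiles as LOA, the
median as bias, and order-statistic (binomial) CIs; for large normal
samples it converges to the parametric limits, which is tested.

## Pipeline

`split_dataset` shuffles once with a seed and takes `floor(ratio·n)`
training records (851 records at 0.7 give exactly 595/256, the
motivating arithmetic); the split is unstratified. `run_experiment`
renders, splits, fits every requested model, scores the test group and
writes `predictions.csv`, `metrics.csv`, `agreement.csv`,
`improvements.csv` and a timestamp-free, key-sorted `summary.json` —
re-running an identical config reproduces it byte for byte, and every
table number is recomputable from the per-image predictions (tested).
`predict_batch` detects, crops and predicts any number of images,
skipping unreadable ones with a warning, and totals the clamped
per-sponge masses into a running surgical Hb loss — the batch
counterpart of an interactive upload interface.

## Problem sizes

The test suite and acceptance script run scaled-down experiments chosen
as the smallest sizes at which each claim is meaningful: 96–128 px
scenes, 50 renders for detector fidelity, 400 + 100 noise-free crops
for the tiny-CNN recovery check (held-out R² ≥ 0.9 at the 30-epoch
preset), and a 240-image three-model experiment (168/72 split) in the
acceptance script. The full 224 px, 1000-epoch configuration is
honored in `RegressorConfig` defaults but exercised only as a forward
shape test.

## Known limitations

* The synthetic forward model is invertible almost by construction;
  real sponges add confounds the generator omits (see above), so
  metric values here do not transfer to clinical images.
* The deterministic detector assumes a single sponge on a known,
  roughly uniform background.
* The percentile-mode Bland–Altman CIs are order-statistic intervals,
  which are wide for n < ~40.
* The numpy CNN stack is single-threaded CPU code; it is meant for
  desk-scale experiments and correctness, not throughput.
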