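# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and what the bundled benchmarks do and do not
demonstrate.

## 1. The estimation problem

One aligned overhead color + depth image pair, centered on a single plant
in a dense grid, is mapped to that plant's fresh above-ground biomass in
grams. The center plant is partially hidden by its own leaves and by
neighbors; no segmentation mask or localization label is available — only
the scalar mass. The estimator must therefore implicitly localize the
center plant and extrapolate its occluded portions.

## 2. Synthetic canopy scenes

Real datasets of this kind (plants grown, imaged and destructively weighed
over a full cropping cycle) are expensive and rarely published, so the
package generates its own scenes with exact ground truth.

**Geometry.** Plants sit on a square grid (spacing 76.2 mm, i.e. 3 in)
with uniform positional jitter of ±10 mm, matching the positional
tolerance of a belt-driven camera gantry. The camera looks straight down
from 370 mm. A rosette is a union of `n_leaves` (6–12) elliptical-
paraboloid lobes around a central dome; leaf peak heights vary
deterministically with leaf index, azimuthal phase is random. All linear
dimensions scale together, so shape is fixed while size varies.

**Mass model.** Ground-truth mass is a fixed effective density,
0.18 g/cm³, times the volume under the plant's *own* height field,
integrated on a plant-relative 256×256 grid. Two consequences are load-
bearing for testing: (i) mass is exactly invariant to neighbors, camera
exposure, and depth dropout — occlusion can never leak into the label —
and (ii) mass scales exactly with the cube of linear size, so a target
mass is hit exactly by solving for one scale factor. The density value
makes a 35 g head ≈ 95 mm in radius, which on a 76 mm grid produces the
near-continuous canopies that motivate the method; lettuce tissue is
~1 g/cm³ but a rosette is mostly air between leaves, hence the lower
effective value. Any fixed monotone geometry→mass map would do for
parameter-recovery testing; this one is physically plausible.

**Depth rendering.** Depth follows the sensor convention: integer 0.1 mm
units, tray background at 3700, surface at height h mm reads
3700 − 10·h, missing pixels are 0. Occlusion is a true z-buffer (nearest
surface wins). Missing depth is Bernoulli per pixel with probability
p₀ + 0.30·(h/h_max) on plant pixels (default p₀ = 0.02): stereo matching
fails more on tall, self-shadowing, specular canopy, so missing data
grows with plant size — the generated datasets reproduce a strong
positive rank correlation between center mass and missing-depth fraction.

**Color rendering.** Shaded green rosettes (brightness increasing with
height, per-plant hue perturbation) over a dark tray, plus pixel noise,
scaled by a per-scene exposure factor drawn from U[0.7, 1.3] to emulate
auto-exposure variability. Photorealism is a non-goal: the color channel
carries area/shape/shading cues, nothing more.

**Dataset statistics.** Center-plant masses are drawn from a lognormal
(median ≈ 3 g, σ = 1) clipped to [0.1, 35] g — right-skewed toward small,
young plants, as in any constant-rate transplanting regime. The eight
neighbors are drawn within ±30% of the center mass, emulating the
homogeneity of uniform cultivation (and creating the correlated-context
difficulty the method must survive: context predicts the label almost as
well as the plant itself).

**Growth experiments.** Each plant follows discrete logistic growth
m_{t+1} = m_t + r·s_t·m_t(1 − m_t/K)·Δt with plant-level variation
(r = 0.2/day CV 8%, K = 40 g CV 15%, m₀ = 0.4 g CV 25%; a 0.1 g → 30 g
trajectory over ~30 days, typical of baby-leaf lettuce). The stress
multiplier s_t relaxes toward 0 during water-only fertigation and back
toward 1 on nutrient solution with a first-order lag (default 1 day),
reflecting the near-immediate nutrient washout of stone-wool hydroponics
followed by depletion of internal stores. Schedules are (day, solution)
event lists; the four bundled treatment schedules exercise an early
stress pulse, staggered mid-cycle stress/recovery, and an unstressed
control.

## 3. Preprocessing

Depth values beyond 380 mm (3800 units) belong to the scene beyond the
tray and are **clamped** to 3800 — not zeroed — so background encodes as
"farthest" and is never aliased with missing pixels. The filtered image
is divided by 3800 (float32) and jet-encoded:
channel(x) = clip(1.5 − |4x − k|, 0, 1) with k = 3, 2, 1 for R, G, B,
giving (0, 0, 0.5) at 0 and (0.5, 0, 0) at 1. This 4-segment map is
injective across all 3801 representable depth levels, so no information
is lost, and it hands a color-convolutional branch smooth 3-channel
gradients. Missing depth (0) is left at 0 → deep blue; no inpainting.
Both modalities are center cropped (480 px at native 848×480 resolution;
the reduced-scale benchmark crops to 64 px).

**Augmentation** (training only): one rotation angle U[0°, 360°) applied
identically to both modalities about the image center (valid because the
labeled plant sits at the center and rosettes are roughly rotation-
symmetric); brightness/contrast/saturation factors U[0.5, 1.5], hue
offset U[−0.1, 0.1], and grayscale with probability 0.1 applied to the
color image **only** — the jet-encoded depth channels are geometry, and
color-jittering them would corrupt the encoded distances. The "hue
factor" range is not expressible as a multiplicative hue change; a small
additive offset is used instead. Order is fixed (rotate → jitter →
grayscale) and fully seed-reproducible. Rotation uses bilinear
interpolation with zero fill.

## 4. The fusion network and training protocol

Two branches (color, jet depth) each end in a `feature_dim`-dimensional
linear layer (default 1000, mirroring an ImageNet classifier with softmax
removed). Their outputs are concatenated (2·feature_dim) and fed to a
regression head: one hidden fully connected layer (default 1000) then a
single linear unit; ReLU between all layers except the final output.

Because no deep-learning framework (and no ImageNet weight file) is a
dependency of this package, branches are reduced convolutional stacks on
a small NumPy engine: 3×3 convolutions with batch normalization and ReLU
(strides 2, 2, 1), global average pooling, and the linear feature layer.
The registry offers `tiny` (16-32-64 channels), `wide` (24-48-96), and
`small` (4 convolutions). The final convolution keeps stride 1 so the
GradCAM plane is 16×16 at 64 px input — fine enough to resolve
transplant-sized plants. The fusion *topology* is what the package
studies; backbone depth is a capacity knob.

**Loss.** MAPE = (1/n)Σ|Aᵢ − Fᵢ|/Aᵢ on grams, gradient
−sign(Aᵢ − Fᵢ)/(n·Aᵢ). Labels must be strictly positive (the generator's
minimum is 0.1 g). MAPE equalizes relative pressure across the ~300×
mass range, at a known cost: per-sample gradients shrink as 1/A, so the
sparse large-mass tail trains slowly and is biased low — visible in the
per-bin reports, where the heaviest bins carry the largest relative
errors, and consistent with MAPE's documented underestimation bias.

**Protocol.** Stage 1 trains each branch as its own regressor (branch +
one linear unit). Stage 2 strips the heads, concatenates the branches,
and fine-tunes everything. Optimization is AdamW (weight decay 0.001),
minibatch 16, learning rate halved at epochs 20/40/60/80/100, early
stopping when validation MAPE has not improved for `patience_epochs`
(default 60), returning the best-validation checkpoint. Validation MAPE
is computed without augmentation. Defaults keep the transfer-learning
rate 1e-4; the from-scratch benchmark runs use 1e-3 (reduced backbones
start far from any solution) and initialize the output bias at the mean
training mass so optimization starts from the constant-mean predictor.
Epochs are 1-based full passes; data order reshuffles per epoch from the
seeded stream.

## 5. Evaluation

MAPE (reported ×100 as percent), RMSE in grams, Pearson r, overall and
per ground-truth mass bin with half-open edges
[0, 2, 5, 10, 15, 25, ∞) g, chosen to track occlusion regimes. Binning is
by *truth*, bins are [lo, hi), empty bins report n = 0 with null metrics.
Validation sets are drawn by weighting each sample inversely to the count
of its 1 g mass bin (35 bins) and sampling without replacement, which
flattens the skewed distribution so model selection is not dominated by
small plants.

**GradCAM.** For one branch (default color), channel weights are the
spatial means of ∂(output)/∂(activation) at the final convolutional
layer; the map is ReLU of the weighted activation sum, bilinearly
upsampled and max-normalized (an all-zero map stays zero). Guided
backpropagation is out of scope.

## 6. Growth monitoring

Per-plant mass series at 8 h spacing are smoothed with a *backwards*
window-3 moving average (first two timepoints dropped), then
GR_t = (m_t − m_{t−1})/Δt and RGR_t = GR_t/m_t, with m_t the current
smoothed mass — the only unit-consistent reading of the rate definition,
giving RGR units of (8 h)⁻¹. GR and RGR halve when Δt doubles; RGR is
invariant to mass rescaling.

At each timepoint, treatment means are compared with Tukey's HSD
(studentized range on pooled within-group variance, α = 0.05), computed
independently per timepoint with no cross-time correction. Because GR and
RGR fluctuate enough for sporadic single-timepoint separations, a stress
response is declared only at the second of **two consecutive**
significant timepoints; the smoother biomass series uses first
separation. Response time is detection day minus stress-onset day;
detection *before* onset is surfaced as an error (false positive).
Plants missing a value at a timepoint drop out of that timepoint's
groups only.

The studentized-range survival function is evaluated with fixed
Gauss–Legendre quadrature of its classical double-integral form (80 inner
× 100 outer nodes), agreeing with adaptive-quadrature references to
better than 1e-8 while being fast enough to run the test at every
timepoint of hundreds of replicated experiments; degenerate pooled
variance falls back to direct mean comparison (equal → p = 1, distinct →
p = 0).

## 7. Benchmark scale and what it shows

The regression benchmark renders 500 training-pool scenes plus 100 test
scenes at 96×72 px, 4.25 mm/px (the 64 px crop covers ~272 mm, the full
3×3 neighborhood), trains the two-stage protocol on the `wide` backbone
(feature dim 192, head hidden 256; 25 pretrain + 80 fusion epochs), and
evaluates held out. The wider backbone earns its cost in the sparse
large-mass tail, where the narrower `tiny` variant underpredicts. The monitoring benchmark runs 27 plants per
treatment, 8 h steps, onset at day 6, observed through 7% multiplicative
noise emulating the regression model's relative test error; detection
statistics aggregate 50 seeded replicates, and a 200-replicate null run
checks that per-timepoint Tukey significance stays at its nominal level.
These sizes run in minutes on one CPU; they are scale surrogates, not
reproductions of greenhouse-scale results.

Passing them shows the pipeline *recovers known parameters from its own
generative model* under occlusion, dropout, and exposure variation — a
necessary correctness property. It does not show performance on real
sensor data: the generator omits leaf texture, specular highlights,
stereo-matching artifacts beyond Bernoulli dropout, cultivar morphology
(purple leaves, stem elongation), wilting, and lighting spectra, and the
paraboloid-lobe allometry is far cleaner than biology.

## 8. Known limitations

- The large-mass tail (>25 g) is underpredicted: MAPE training gives the
  rare heaviest plants the weakest absolute gradients, and near-closed
  canopies genuinely underdetermine center mass. The per-bin report makes
  this visible rather than hiding it in the aggregate.
- Tukey per timepoint with a consecutive-significance guard controls
  sporadic flags pragmatically, not family-wise over the whole series;
  repeated-measures or mixed models are deliberately out of scope.
- The engine is single-threaded NumPy; it is sized for the benchmark
  scale, not for 480 px ResNet-50 training.
- `pretrained=True` raises: ImageNet initialization is unavailable
  without a deep-learning stack and weight files.
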