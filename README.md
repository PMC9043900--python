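# canopymass

Individual-plant fresh-biomass estimation from overhead RGB-D imagery of
dense, occluded leafy-green canopies — plus the growth-monitoring analysis
that turns per-plant mass predictions into early stress detection.

## The problem

In high-density hydroponic lettuce production, neighboring rosettes occlude
each other until the canopy is nearly continuous. Classical pipelines that
segment each plant and regress biomass from pixel counts or reconstructed
volume break down under that occlusion. The approach implemented here skips
segmentation entirely: a deep convolutional network maps an aligned
color + depth image pair, centered on one plant, directly to that plant's
fresh mass in grams. Mass predictions taken every 8 h then feed a
statistical monitor that flags nutrient stress within days of onset.

The package is aimed at plant-phenotyping and controlled-environment-
agriculture researchers who want to study or extend this estimation and
monitoring recipe. Because raw greenhouse datasets of this kind are rarely
shareable, the package ships a synthetic canopy-scene generator with exact
ground-truth masses, so every stage — preprocessing, training, evaluation,
explanation, monitoring — is testable end to end on one CPU.

## Method at a glance

- **Late-fusion regression network.** Two convolutional branches (color and
  depth) each emit a 1000-dimensional feature vector; the vectors are
  concatenated (2000 × 1) and passed to a regression head of one 1000-unit
  fully connected layer and a single linear output unit, ReLU between all
  layers except the last. Branches are first trained as single-modality
  regressors, then stripped of their heads and fine-tuned jointly.
- **MAPE loss.** Training minimizes mean absolute percentage error,
  MAPE = (1/n) Σ |Aᵢ − Fᵢ| / Aᵢ, which balances learning pressure across a
  ~300× range of plant masses (≈0.1 g transplants to >30 g heads).
- **Depth encoding.** Depth (0.1 mm integer units) is clamped at 380 mm,
  normalized to [0, 1], and mapped through the classic jet colormap so a
  color-convolutional branch can consume it; missing depth stays deep blue,
  background reads deep red. Inputs are center cropped.
- **Evaluation.** MAPE, RMSE = √((1/n) Σ (Aᵢ − Fᵢ)²), and Pearson r,
  reported overall and per ground-truth mass bin ([0,2), [2,5), [5,10),
  [10,15), [15,25), [25,∞) g); validation sets are drawn by
  inverse-frequency sampling over 1 g mass bins.
- **Growth monitoring.** Per-plant series are smoothed with a backwards
  window-3 moving average; GR = (mₜ − mₜ₋₁)/Δt and RGR = GR/mₜ (units
  (8 h)⁻¹). Treatment means are compared per timepoint with Tukey's HSD
  (α = 0.05); a stress response is declared on two consecutive significant
  timepoints for GR/RGR, first separation for biomass.
- **GradCAM.** Channel-weighted activations of a branch's final
  convolutional block visualize which pixels drive the scalar prediction —
  on a well-trained model, the center plant.

The network is implemented on a compact NumPy layer engine bundled with the
package (`canopymass.nn`: strided convolutions, batch norm, AdamW, exact
MAPE gradients), with reduced-depth backbones sized for CPU training; the
fusion topology is independent of backbone depth.

## Worked example

```bash
python examples/03_train_fusion_model.py
```

trains the demonstration-sized fusion model (160 synthetic scenes, reduced
epochs, ~1 min) and prints:

```
held-out n=40
  MAPE  23.3%   (mean-mass baseline 133%)
  RMSE  3.83 g
  r     0.826
single-modality ablation MAPE%: {'rgb': 26.6, 'depth': 137.2}

per-mass-bin error (bins follow occlusion regimes):
  [   0,    2) g  n=11  MAPE  23.8%  RMSE 0.33 g
  [   2,    5) g  n=15  MAPE  27.8%  RMSE 0.96 g
  [   5,   10) g  n=10  MAPE  10.4%  RMSE 0.65 g
  [  10,   15) g  n=3   MAPE  28.2%  RMSE 3.86 g
  [  25,  inf) g  n=1   MAPE  65.4%  RMSE 22.89 g
```

Even at this toy scale, held-out error sits far below the constant-mean
baseline; the full benchmark (500 scenes, wider backbone, longer
schedules, run by `scripts/acceptance.py`) reaches roughly a third of
this MAPE with r above 0.95.
The other examples cover scene generation (`01`), preprocessing/jet
encoding (`02`), GradCAM localization (`04`), and stress monitoring (`05`):

```
single experiment (stress onset day 6):
   biomass: detected 3.0 d after onset
        GR: detected 1.3 d after onset
       RGR: detected 1.0 d after onset
```

A thin CLI wraps the same calls for shell use:
`canopymass synth | synth-experiment | train | predict | evaluate | explain | monitor`
(see `canopymass --help`).

## Layout

```
src/canopymass/
  scene.py          synthetic canopy scenes, growth + stress simulation
  preprocess.py     depth filter/normalize/jet, crop, augmentation
  nn.py             NumPy layer engine (conv, BN, AdamW, backprop)
  model.py          branches, fusion network, MAPE loss, training protocol
  evaluation.py     binned metrics, weighted validation sampling, GradCAM
  monitoring.py     GR/RGR, Tukey HSD separation, detection criteria
  benchmark.py      end-to-end desk-scale workflows
  io.py, cli.py     PNG/CSV conventions and the typer CLI
docs/methods.md     model, assumptions, parameter choices, limitations
examples/           one runnable script per capability
```
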