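# Methods

This note records the modeling assumptions, default parameters and
numerical choices behind `fmridecoder`, and what the synthetic generator
does and does not emulate.

## 1. Problem setting

We decode the task state of a subject from a short 4D BOLD fragment: the
frames acquired during one task block plus an 8-second hemodynamic tail.
A frame at index t (TR = 0.72 s) belongs to a block with onset `o` and
duration `d` iff its acquisition interval is fully contained in the
response window:

    [t·TR, (t+1)·TR) ⊆ [o, o + d + 8 s)

For a 12-s block this yields exactly **27 frames**, and the rule is
invariant to TR-aligned onset shifts. Longer blocks yield more frames;
the network's `input_frames` is a fixed hyperparameter, so training uses a
random contiguous 27-frame crop of each sample per epoch (data
augmentation), while validation/test deterministically take the first 27
frames.

Volumes on the standard 91×109×91 2-mm grid are first cropped to the
brain-containing box (75×93×81, offsets (8, 8, 5)); the affine is updated
so world coordinates are preserved.

## 2. Decoder architecture

`ArchitectureConfig` defaults (frozen; see §7):

| stage | spec | output channels |
|---|---|---|
| temporal compression | 1×1×1 conv over the 27 input frames | 3 |
| stem | 3×3×3 conv, stride 2, padding 1 | 48 |
| residual blocks ×4 | one 3×3×3 conv each, strides (1, 2, 2, 2) | 32, 64, 64, 128 |
| full convolution | kernel = remaining feature extent (5×6×6 at 75×93×81) | 135 |
| head | FC 64 → FC n_classes → softmax | — |

Details:

- Every convolution except the full one uses "same" padding (padding 1 for
  kernel 3) and is **bias-free**, because it is followed by batch
  normalization (the BN shift makes a conv bias redundant).
- Residual shortcuts are identity when shape allows; otherwise a 3×3×3
  projection convolution **with bias and without BN**.
- The full convolution (with bias, no BN) replaces global pooling; its
  kernel equals the incoming feature-map extent, so its output is a
  1×1×1 map of 135 features.
- ReLU activations throughout; softmax only at the loss/inference.

With a 7-class head on 75×93×81 input this totals **3,981,852** trainable
parameters. `expected_parameter_count` computes the same number in closed
form per layer (conv: C_out·C_in·k³ (+C_out bias); BN: 2·C; FC:
out·in+out), independently of the instantiated arrays — the two routes
agreeing is a standing self-check.

Spatial dimensions use floor division: out = ⌊(in + 2p − k)/s⌋ + 1, with a
floor of 1 voxel per axis so very small grids still produce a valid
(pointwise) full convolution.

## 3. Training protocol

- Per-sample standardization: z-score over all voxels and frames of the
  27-frame fragment (removes the baseline ≈100 and per-subject gain).
- Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), initial learning rate 1e-3,
  batch size 32, cross-entropy loss.
- Plateau schedule: if validation loss fails to improve by ≥1e-4 for 15
  consecutive epochs, divide the learning rate by 10; at most 2 decays;
  at most 30 epochs.
- Model selection: the checkpoint with the best validation loss is
  restored at the end.
- **Subject-wise splits only**: `make_fold_plan` shuffles subjects with a
  seeded generator and partitions them 70/10/20 into train/val/test
  (20 subjects → 14/2/4); an audit helper rejects plans with leakage or
  duplicates. Within-subject splits would inflate accuracy via subject
  identity cues and are deliberately not offered.
- Transfer: `transfer()` copies every trunk parameter (all layers up to
  and including the full convolution and the 64-wide FC) into a model
  with a freshly initialized class head, then fine-tunes end to end with
  the same optimizer settings.

All stochastic choices (init, shuffling, crops) flow from explicit seeds;
identical seed + config reproduces bitwise-identical histories.

## 4. Evaluation

Per-label tallies from the confusion matrix use, by default, the
convention in which a label's TN is the sum of the other labels' TPs
(trace minus own TP) — appropriate when every trial belongs to exactly
one of the modeled classes and "true rest" does not exist. The standard
all-correct-rejections convention is available
(`tn_convention="standard"`) and both appear in `metrics_report`.
Derived scores: F1 = 2TP/(2TP+FP+FN), sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP); degenerate 0/0 denominators warn and return 0.
Chance level is 100/n rounded to 2 decimals (7 → 14.29%, 2 → 50%,
4 → 25%). One-vs-rest ROC sorts by score, groups ties into single sweep
steps, and integrates by trapezoid, which makes the AUC identical to the
Mann-Whitney U statistic with midpoint tie handling.

## 5. Pattern mapping

Guided back-propagation is the plain backward pass with one change: at
every ReLU the gradient is passed only where the forward input was
positive **and** the incoming gradient is positive. Because the engine's
backward passes are hand-written, this is a literal mask in `ReLU.backward`
rather than a framework hook. BN layers run in eval mode (frozen running
statistics) during attribution. The 4D input gradient is collapsed over
time by keeping, per voxel, the signed value of largest magnitude, then
normalized by the map's peak magnitude so maps are comparable across
subjects. Group maps: voxelwise Cohen's d = mean/SD (sample SD, ddof 1)
over ≥2 per-subject maps of the same class; zero-SD voxels are zeroed and
counted.

## 6. Synthetic data generator

Per subject and run the generator emits
`data = baseline + signal + noise + drift` on a 3D grid:

- **Signal**: each condition owns a disjoint ellipsoidal footprint
  (default: centers on an octant lattice, radii ≈ grid/8, min 2 voxels).
  Its time course is a boxcar of the block schedule convolved with a
  double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6, 32 s support)
  normalized to **unit peak**, scaled by the condition amplitude and a
  per-subject gain ~ N(1, 0.1²). Unit-peak normalization makes "SNR 3"
  literal (peak signal 3.0 over noise SD 1.0) and makes GLM betas equal
  planted amplitudes exactly in the noiseless case.
- **Schedule**: conditions are block-randomized per run; onsets are
  snapped up to the TR grid; inter-block gaps leave room for the
  hemodynamic tail so 27-frame samples never collide.
- **Noise**: temporal AR(1) per voxel (default ρ = 0.3) scaled so the
  *marginal* SD equals `noise_sd` (innovation SD = noise_sd·√(1−ρ²)),
  i.i.d. across voxels.
- **Drift**: slow cosine terms with small random coefficients.
- **Determinism**: the subject stream is keyed by
  blake2s(design seed, subject id), so runs are reproducible per subject
  and independent of generation order.

Defaults (the study conditions used by the full-scale checks): 4
conditions, 24×28×24 grid, 20 subjects, 2 blocks per condition per run,
12-s blocks, amplitude 3.0, noise SD 1.0, baseline 100.

What it does **not** emulate: spatial noise correlations and smoothness,
physiological confounds (cardiac/respiratory), head motion, HRF
variability across regions/subjects, anatomical structure, multi-run
sessions, and spatially overlapping or distributed codes — footprints are
disjoint by construction, which is exactly what makes localization
claims testable against ground truth.

## 7. Frozen calibration

The architecture defaults above are calibrated so the instantiated
network hits the published parameter total exactly, and they are frozen:
the acceptance-style checks (`tests/test_acceptance.py`,
`scripts/acceptance.py`) assert the framework count equals the closed
form equals 3,981,852, so any drift in a default fails loudly. The
synthetic defaults are likewise treated as fixed experimental conditions;
tests consume them rather than tuning them.

## 8. Numerical choices

- Compute dtype is float32 for the network (matching typical GPU
  practice and halving memory); tests that finite-difference-check
  gradients instantiate layers in float64.
- Convolution is im2col + GEMM; the im2col/col2im loops are numba-jitted
  (`cache=True`) with a pure-NumPy `sliding_window_view` fallback when
  numba is unavailable. On one CPU core a 32-sample training step on the
  24×28×24 grid takes ≈2–3 s (≈11 s/epoch, 30 epochs ≈ 5.5 min).
- BN running statistics use cumulative averaging (momentum=None style),
  which is exactly correct for the short trainings used here.
- GLM betas come from `numpy.linalg.lstsq`; design matrices are
  HRF-convolved condition boxcars + cosine drifts + intercept.
- SVMs are scikit-learn `SVC(kernel="linear", C=1)` (one-vs-one).
- The searchlight clips spheres at volume edges (no padding) and writes
  NaN outside the analysis mask.

## 9. Known limitations

- CPU-only and modest-scale: the full 75×93×81 network instantiates and
  counts parameters instantly, but training at that scale is impractical
  in this engine; the full-scale experiments run on the 24×28×24 study
  grid.
- The simulator's disjoint-footprint assumption makes decoding easier
  than real fMRI; reported accuracies characterize the pipeline, not
  expected performance on scanner data.
- Guided backprop highlights positive evidence only and is known to be
  partially input-dependent rather than purely model-dependent; Cohen's d
  group maps mitigate but do not remove this.
- Single run per subject; no support yet for multi-session designs or
  event-related (non-block) paradigms.
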