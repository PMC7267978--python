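# fmridecoder

Whole-brain task-state decoding from 4D BOLD fMRI with a 3D residual
convolutional network, guided-backprop pattern mapping, and classical
GLM + SVM-MVPA baselines — plus a built-in synthetic fMRI simulator that
makes the entire pipeline testable end to end on a laptop CPU.

## What it does

Block-design task fMRI experiments present a stimulus for a dozen seconds
while the scanner acquires a volume every TR (0.72 s by default). The
decoding question: given only a short 4D fragment of the BOLD signal (27
frames covering one block plus the hemodynamic tail), which task state was
the subject in?

The package answers it three ways:

1. **Deep decoder** — a 3D residual CNN reads the raw 4D fragment. A 1×1×1
   convolution first compresses the 27 input frames (treated as channels)
   into 3 temporal descriptor volumes; a strided 3×3×3 convolution and four
   residual blocks (32/64/64/128 channels, stride 2 in the last three)
   condense space; a final "full" convolution whose kernel equals the
   remaining feature-map extent replaces global pooling; two fully connected
   layers (64-wide, then the class head) produce softmax probabilities.
   Instantiated for 75×93×81 volumes with a 7-class head the network has
   exactly **3,981,852** trainable parameters (verify with
   `fmridecoder describe-model`).
2. **Pattern maps** — guided back-propagation pushes each class score back
   to the input: at every ReLU the gradient passes only where both the
   forward activation and the incoming gradient are positive, so only
   positively contributing paths survive. The 4D gradient collapses over
   time (signed maximum magnitude per voxel, normalized to max |value| 1)
   into a 3D pattern map; groups of maps condense into voxelwise Cohen's d
   effect maps.
3. **Classical baselines** — voxelwise OLS GLM betas (HRF-convolved boxcars
   + cosine drifts + intercept) feed linear SVMs: whole-brain, ROI, and a
   radius-3 searchlight (123 voxel offsets) that writes per-condition F1 at
   every sphere center.

Everything is trained and evaluated **subject-wise**: no individual ever
contributes data to more than one of train/validation/test.

The neural-network engine (3D convolution, batch norm, residual blocks,
Adam, and the guided-backprop rule) is implemented in NumPy with
numba-compiled im2col/col2im hot paths — no deep-learning framework
dependency, and the guided rule is a one-line switch in the hand-written
backward pass.

## Synthetic data

`fmridecoder.synth` simulates multi-subject runs in which each condition
activates a disjoint ellipsoidal footprint: signal = baseline 100 +
gain·amplitude·(boxcar ⊗ double-gamma HRF) on footprint voxels + AR(1)
noise + slow cosine drift, with per-subject amplitude jitter
(gain ~ N(1, 0.1)). Defaults plant 4 conditions on a 24×28×24 grid for 20
subjects, two 12-s blocks per condition per run, amplitude 3.0 over noise
SD 1.0 (SNR 3). Every run is deterministic in (design, subject, seed).

## Worked example

```python
import numpy as np
from fmridecoder import (ArchitectureConfig, TrainConfig, VolumeGrid,
                         build_model, default_design, generate_dataset,
                         make_fold_plan, train, evaluate_model)
from fmridecoder.training import label_index, split_by_subject

design = default_design(seed=11)            # 4 classes, 20 subjects, SNR 3
samples = generate_dataset(design)          # 160 labeled 27-frame fragments
fold = make_fold_plan(sorted({s.subject_id for s in samples}), seed=11)[0]

model = build_model(ArchitectureConfig(n_classes=4),
                    VolumeGrid(shape=design.grid.shape), seed=11)
model, history = train(model, samples, fold, TrainConfig(seed=11))

_, _, test_s = split_by_subject(samples, fold)
y, yhat, _ = evaluate_model(model, test_s, TrainConfig(), label_index(samples))
print((y == yhat).mean())
```

On one CPU this run takes about 5–6 minutes for the full 30 epochs
(~11 s/epoch) and prints a held-out subject-wise accuracy of **1.0**
(validation accuracy reaches 1.0 in the first epoch; chance is 25%). The
same protocol with randomly shuffled labels lands at **18.75%** — within
sampling noise of chance — and transferring the trained trunk to a harder
2-condition dataset (8 subjects, amplitude 1.5) reaches 90% validation
accuracy in the **first epoch**, while an identically seeded from-scratch
model fails to get there in 15.

The same pipeline from the shell:

```bash
fmridecoder simulate     --config config.yaml --out runs/      --seed 11
fmridecoder train        --config config.yaml --out run1/      --seed 11
fmridecoder evaluate     --config config.yaml --checkpoint run1/model.npz --out eval/
fmridecoder visualize    --config config.yaml --checkpoint run1/model.npz --out maps/
fmridecoder baseline-svm --config config.yaml --out svm/  --roi
fmridecoder searchlight  --config config.yaml --out sl/
```

Each command writes a `run_manifest.json` (config snapshot + SHA-256, seed,
package version, outputs, timestamp); the same seed and config reproduce
identical metrics JSON.

## Evaluation conventions

Per-label tallies use, by default, the convention in which a label's true
negatives are the summed true positives of the *other* labels (the usual
all-correct-rejections convention is available via
`tally_label(..., tn_convention="standard")`, and reports carry both).
F1 = 2TP/(2TP+FP+FN); sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
chance level = 100/n_classes rounded to two decimals (14.29% for 7 classes,
50% for 2, 25% for 4). One-vs-rest ROC groups tied scores so the
trapezoidal AUC equals the Mann-Whitney statistic with midpoint ties.

## Layout

| module | contents |
|---|---|
| `fmridecoder.io` | NIfTI/TSV I/O, volume cropping, block-sample extraction |
| `fmridecoder.synth` | HRF, design specs, multi-subject simulator |
| `fmridecoder.nn` | NumPy NN engine with hand-written backward passes |
| `fmridecoder.model` | architecture config, parameter accounting, checkpoints |
| `fmridecoder.training` | temporal-crop augmentation, subject-wise CV, Adam loop, transfer, learning curve |
| `fmridecoder.metrics` | confusion/F1/sensitivity/specificity/ROC/chance |
| `fmridecoder.saliency` | guided backprop, temporal collapse, Cohen's d maps |
| `fmridecoder.mvpa` | GLM betas, whole-brain/ROI SVM, searchlight |
| `fmridecoder.cli` | `fmridecoder` command group |

See `docs/methods.md` for modeling assumptions, parameter choices and known
limitations.
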