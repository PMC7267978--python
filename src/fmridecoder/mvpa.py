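"""GLM beta images and the SVM-MVPA comparison stack.

Run-wise condition betas come from a voxelwise ordinary-least-squares GLM
whose regressors are HRF-convolved boxcars (unit-peak HRF, so a planted
amplitude is recovered as its beta) plus cosine drift terms and an
intercept. The betas feed three decoders: a whole-brain linear SVM, an ROI
linear SVM, and a searchlight that classifies from a sphere of radius three
voxels around every location and writes each condition's F1 at the center.
Multi-class reduction is one-vs-one (the default of the reference SVM
routine); C = 1; folds are subject-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .io import BoldRun, EventTable, VolumeGrid
from .metrics import confusion_matrix, f1_score, tally_label
from .synth import HrfSpec, hrf_kernel

__all__ = [
    "DesignMatrix", "BetaDataset",
    "make_design_matrix", "fit_glm", "sphere_offsets",
    "subject_cv_folds", "whole_brain_svm", "roi_svm", "searchlight_classify",
    "glm_dataset_from_runs",
]


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (t, regressors)
    condition_names: list[str]  # names of the leading condition columns

    def __post_init__(self):
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")


@dataclass
class BetaDataset:
    """Condition beta volumes across runs/subjects: the SVM's input."""

    data: np.ndarray  # (n_samples, x, y, z)
    labels: list[str]
    subject_ids: list[str]
    grid: VolumeGrid


def make_design_matrix(events: EventTable, n_frames: int, tr_s: float,
                       hrf: HrfSpec = HrfSpec(), n_drift_terms: int = 3) -> DesignMatrix:
    """One HRF-convolved boxcar per condition + cosine drifts + intercept."""
    h = hrf_kernel(hrf, tr_s)
    names = sorted({label for _, _, label in events})
    frames_s = np.arange(n_frames) * tr_s
    cols = []
    for name in names:
        boxcar = np.zeros(n_frames)
        for onset, duration, label in events:
            if label == name:
                boxcar[(frames_s >= onset) & (frames_s < onset + duration)] = 1.0
        cols.append(np.convolve(boxcar, h)[:n_frames])
    t = np.arange(n_frames)
    for j in range(1, n_drift_terms + 1):
        cols.append(np.cos(np.pi * j * t / n_frames))
    cols.append(np.ones(n_frames))
    return DesignMatrix(np.column_stack(cols), names)


def fit_glm(run: BoldRun, events: EventTable, hrf: HrfSpec = HrfSpec(),
            n_drift_terms: int = 3) -> dict[str, np.ndarray]:
    """Voxelwise OLS; returns one beta volume per condition.

    With a unit-peak HRF and unit boxcar, a noiseless planted amplitude a
    appears as beta = a exactly (the regressor is the planted time course).
    """
    design = make_design_matrix(events, run.n_frames, run.tr_s, hrf, n_drift_terms)
    X = design.matrix
    Y = run.data.reshape(run.n_frames, -1).astype(np.float64)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return {
        name: beta[i].reshape(run.grid.shape)
        for i, name in enumerate(design.condition_names)
    }


def glm_dataset_from_runs(runs_events: list[tuple[BoldRun, EventTable]],
                          hrf: HrfSpec = HrfSpec()) -> BetaDataset:
    """Fit the GLM on every run and stack the condition betas into a dataset."""
    data, labels, subjects = [], [], []
    grid = runs_events[0][0].grid
    for run, events in runs_events:
        betas = fit_glm(run, events, hrf)
        for name, vol in betas.items():
            data.append(vol)
            labels.append(name)
            subjects.append(run.subject_id)
    return BetaDataset(np.stack(data), labels, subjects, grid)


# ---------------------------------------------------------------------------
# searchlight geometry
# ---------------------------------------------------------------------------

def sphere_offsets(radius_voxels: float) -> np.ndarray:
    """Integer offsets (dx,dy,dz) with dx^2+dy^2+dz^2 <= r^2; r=3 gives 123."""
    if radius_voxels < 0:
        raise ValueError("radius must be >= 0")
    r = int(np.floor(radius_voxels))
    span = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(span, span, span, indexing="ij")
    keep = dx ** 2 + dy ** 2 + dz ** 2 <= radius_voxels ** 2
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


# ---------------------------------------------------------------------------
# SVM decoding
# ---------------------------------------------------------------------------

def subject_cv_folds(subject_ids, n_folds: int = 5, seed: int = 0):
    """Subject-wise train/test folds (test groups partition the subjects)."""
    unique = list(dict.fromkeys(subject_ids))
    if len(unique) < n_folds:
        raise ValueError(f"need at least {n_folds} subjects")
    rng = np.random.default_rng(seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    groups = [list(g) for g in np.array_split(np.array(order, dtype=object), n_folds)]
    folds = []
    for i in range(n_folds):
        test = {str(s) for s in groups[i]}
        folds.append({"train": [s for s in order if s not in test],
                      "test": sorted(test)})
    return folds


def _fit_predict(features, labels, subjects, folds, C=1.0):
    """Per-fold linear one-vs-one SVM; returns pooled (y_true, y_pred, fold_id)."""
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    y_true, y_pred, fold_id = [], [], []
    for i, fold in enumerate(folds):
        tr = np.isin(subjects, fold["train"])
        te = np.isin(subjects, fold["test"])
        clf = SVC(kernel="linear", C=C)
        clf.fit(features[tr], labels[tr])
        pred = clf.predict(features[te])
        y_true.extend(labels[te])
        y_pred.extend(pred)
        fold_id.extend([i] * int(te.sum()))
    return np.array(y_true), np.array(y_pred), np.array(fold_id)


def whole_brain_svm(dataset: BetaDataset, folds=None, mask: np.ndarray | None = None,
                    n_folds: int = 5, seed: int = 0) -> list[float]:
    """Subject-wise fold accuracies of a linear SVM on flattened betas."""
    if folds is None:
        folds = subject_cv_folds(dataset.subject_ids, n_folds, seed)
    if mask is None:
        mask = np.ones(dataset.grid.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    features = dataset.data[:, mask]
    y_true, y_pred, fold_id = _fit_predict(features, dataset.labels,
                                           dataset.subject_ids, folds)
    return [float((y_pred[fold_id == i] == y_true[fold_id == i]).mean())
            for i in range(len(folds))]


def roi_svm(dataset: BetaDataset, roi_mask: np.ndarray, folds=None,
            n_folds: int = 5, seed: int = 0) -> list[float]:
    """Whole-brain SVM restricted to an ROI mask (required)."""
    if roi_mask is None or not np.asarray(roi_mask, dtype=bool).any():
        raise ValueError("roi_svm requires a non-empty ROI mask")
    return whole_brain_svm(dataset, folds=folds, mask=roi_mask,
                           n_folds=n_folds, seed=seed)


def searchlight_classify(dataset: BetaDataset, folds=None, radius: float = 3,
                         mask: np.ndarray | None = None, n_folds: int = 5,
                         seed: int = 0, C: float = 1.0) -> dict[str, np.ndarray]:
    """Per-condition F1 maps from a moving-sphere linear SVM.

    At every in-mask voxel the features are the betas inside the sphere
    (clipped at the mask/volume edge); predictions pool over subject-wise
    folds and the per-condition F1 is written at the center voxel. Voxels
    outside the mask are NaN.
    """
    if folds is None:
        folds = subject_cv_folds(dataset.subject_ids, n_folds, seed)
    shape = dataset.grid.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    offsets = sphere_offsets(radius)
    flat = dataset.data.reshape(dataset.data.shape[0], -1)
    mask_flat = mask.ravel()
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    class_names = sorted(set(dataset.labels))
    maps = {name: np.full(shape, np.nan) for name in class_names}
    centers = np.argwhere(mask)
    for cx, cy, cz in centers:
        pts = offsets + np.array([cx, cy, cz])
        ok = ((pts >= 0).all(axis=1) &
              (pts[:, 0] < shape[0]) & (pts[:, 1] < shape[1]) & (pts[:, 2] < shape[2]))
        pts = pts[ok]
        idx = pts @ strides
        idx = idx[mask_flat[idx]]
        if idx.size == 0:
            continue
        y_true, y_pred, _ = _fit_predict(flat[:, idx], dataset.labels,
                                         dataset.subject_ids, folds, C=C)
        cm = confusion_matrix(y_true, y_pred, labels=class_names)
        for name in class_names:
            maps[name][cx, cy, cz] = f1_score(tally_label(cm, name))
    return maps
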