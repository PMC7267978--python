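"""Training loop, temporal-crop augmentation, subject-wise cross-validation,
transfer learning and the subject-count learning curve.

Augmentation follows the block-design logic: during training a fragment of k
consecutive TRs is cropped at a uniformly random offset from each sample
every epoch; validation and testing always use the first k TRs. Folds are
assigned at the subject level so no individual contributes samples to more
than one partition. The optimizer is Adam (lr 1e-3, betas 0.9/0.999); the
learning rate is divided by 10 whenever the validation loss has not reached
a new minimum for ``plateau_patience`` epochs, and the checkpoint returned
is the one with minimum validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Bold4DSample
from .model import ArchitectureConfig, TaskCNN, build_model, clone_model
from .nn import Adam, cross_entropy, softmax

__all__ = [
    "TrainConfig", "FoldPlan", "DivergenceError",
    "random_temporal_crop", "deterministic_first_crop",
    "make_fold_plan", "split_by_subject", "audit_no_leakage",
    "train", "transfer", "evaluate_model", "learning_curve",
]


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    k: int = 27                      # fragment length in TRs
    batch_size: int = 32
    lr0: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    plateau_patience_epochs: int = 15
    lr_decay_factor: float = 10.0
    max_lr_decays: int = 2           # stop after this many decays w/o improvement
    max_epochs: int = 30
    min_delta: float = 1e-4          # improvement tolerance on validation loss
    standardize: bool = True         # per-sample z-scoring of the input
    seed: int = 0

    def __post_init__(self):
        if self.k < 1 or self.batch_size < 1 or self.lr0 <= 0:
            raise ValueError("k, batch_size must be >= 1 and lr0 > 0")


@dataclass
class FoldPlan:
    """Per-fold subject lists; folds partition subjects at the test level."""

    folds: list[dict]  # each: {"train": [...], "val": [...], "test": [...]}

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def __iter__(self):
        return iter(self.folds)

    def __getitem__(self, i):
        return self.folds[i]


# ---------------------------------------------------------------------------
# temporal crops
# ---------------------------------------------------------------------------

def random_temporal_crop(sample: Bold4DSample, k: int,
                         rng: np.random.Generator) -> Bold4DSample:
    """k consecutive frames starting at a uniform offset in [0, t-k]."""
    t = sample.n_frames
    if t < k:
        raise ValueError(f"sample has {t} frames, shorter than k={k}")
    start = int(rng.integers(0, t - k + 1))
    return Bold4DSample(data=sample.data[start:start + k], label=sample.label,
                        subject_id=sample.subject_id, tr_s=sample.tr_s)


def deterministic_first_crop(sample: Bold4DSample, k: int) -> Bold4DSample:
    """The first k frames — the fixed crop used for validation and testing."""
    if sample.n_frames < k:
        raise ValueError(f"sample has {sample.n_frames} frames, shorter than k={k}")
    if sample.n_frames == k:
        return sample
    return Bold4DSample(data=sample.data[:k], label=sample.label,
                        subject_id=sample.subject_id, tr_s=sample.tr_s)


# ---------------------------------------------------------------------------
# fold plans
# ---------------------------------------------------------------------------

def make_fold_plan(subject_ids, ratios=(0.7, 0.1, 0.2), n_folds: int = 5,
                   seed: int = 0) -> FoldPlan:
    """Subject-wise k-fold plan with train/validation/test ratios.

    Test groups partition the (shuffled) subjects across folds; within each
    fold the remaining subjects are split so that the validation share is
    ``round(n_subjects * ratios[1])``.
    """
    subject_ids = list(dict.fromkeys(subject_ids))  # stable unique
    n = len(subject_ids)
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} subjects, got {n}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    order = [subject_ids[i] for i in rng.permutation(n)]
    test_groups = [list(g) for g in np.array_split(np.array(order, dtype=object), n_folds)]
    folds = []
    for i in range(n_folds):
        test = [str(s) for s in test_groups[i]]
        rest = [s for s in order if s not in test]
        n_val = max(1, int(round(n * ratios[1])))
        # validation subjects rotate with the fold for determinism
        val = rest[:n_val]
        train = rest[n_val:]
        folds.append({"train": train, "val": val, "test": test})
    plan = FoldPlan(folds)
    audit_no_leakage(plan)
    return plan


def audit_no_leakage(plan: FoldPlan) -> None:
    """Raise if any subject appears in two partitions of a fold, or in two
    test lists across folds."""
    seen_test: set = set()
    for i, fold in enumerate(plan):
        parts = [set(fold["train"]), set(fold["val"]), set(fold["test"])]
        for a in range(3):
            for b in range(a + 1, 3):
                overlap = parts[a] & parts[b]
                if overlap:
                    raise ValueError(f"fold {i}: subjects straddle partitions: {overlap}")
        dup = seen_test & parts[2]
        if dup:
            raise ValueError(f"subjects test in more than one fold: {dup}")
        seen_test |= parts[2]


def split_by_subject(samples, fold: dict):
    """Partition samples into (train, val, test) lists per a fold's subjects."""
    groups = {k: [] for k in ("train", "val", "test")}
    members = {s: part for part in groups for s in fold[part]}
    for sample in samples:
        part = members.get(sample.subject_id)
        if part is not None:
            groups[part].append(sample)
    return groups["train"], groups["val"], groups["test"]


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=(1, 2, 3, 4), keepdims=True)
    sd = x.std(axis=(1, 2, 3, 4), keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mean) / sd


def samples_to_batch(samples, k: int, rng: np.random.Generator | None = None,
                     standardize: bool = True) -> np.ndarray:
    """Stack samples into (N, k, x, y, z); random crops iff an rng is given."""
    crops = [
        random_temporal_crop(s, k, rng) if rng is not None
        else deterministic_first_crop(s, k)
        for s in samples
    ]
    x = np.stack([c.data for c in crops]).astype(np.float32)
    return _standardize(x) if standardize else x


def label_index(samples) -> dict[str, int]:
    return {lab: i for i, lab in enumerate(sorted({s.label for s in samples}))}


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _snapshot(model: TaskCNN):
    from .model import BatchNorm3d, _iter_layers

    params = [p.value.copy() for p in model.params()]
    bns = [(l.running_mean.copy(), l.running_var.copy())
           for l in _iter_layers(model.net) if isinstance(l, BatchNorm3d)]
    return params, bns


def _restore(model: TaskCNN, snap) -> None:
    from .model import BatchNorm3d, _iter_layers

    params, bns = snap
    for p, v in zip(model.params(), params):
        p.value = v.copy()
    for l, (rm, rv) in zip(
            (l for l in _iter_layers(model.net) if isinstance(l, BatchNorm3d)), bns):
        l.running_mean = rm.copy()
        l.running_var = rv.copy()


def _eval_loss_acc(model: TaskCNN, samples, labels: dict, cfg: TrainConfig):
    if not samples:
        return float("nan"), float("nan")
    x = samples_to_batch(samples, cfg.k, rng=None, standardize=cfg.standardize)
    y = np.array([labels[s.label] for s in samples])
    losses, correct = [], 0
    for i in range(0, len(samples), cfg.batch_size):
        logits = model.forward_logits(x[i:i + cfg.batch_size], mode="eval")
        l, _ = cross_entropy(logits, y[i:i + cfg.batch_size])
        losses.append(l * len(y[i:i + cfg.batch_size]))
        correct += int((logits.argmax(axis=1) == y[i:i + cfg.batch_size]).sum())
    return float(np.sum(losses) / len(samples)), correct / len(samples)


def train(model: TaskCNN, samples, fold: dict, cfg: TrainConfig = TrainConfig()):
    """Train a model on one fold; returns (model, history).

    The model is left holding the minimum-validation-loss weights. ``history``
    is a list of per-epoch records plus a ``meta`` entry with seeds and the
    best epoch.
    """
    labels = label_index(samples)
    if len(labels) != model.cfg.n_classes:
        raise ValueError(
            f"dataset has {len(labels)} labels but model head expects "
            f"{model.cfg.n_classes}"
        )
    train_s, val_s, _ = split_by_subject(samples, fold)
    if not train_s or not val_s:
        raise ValueError("fold yields empty train or validation set")
    root = np.random.SeedSequence(cfg.seed)
    shuffle_rng, crop_rng = (np.random.default_rng(s) for s in root.spawn(2))

    opt = Adam(model.params(), lr=cfg.lr0, beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    y_train = np.array([labels[s.label] for s in train_s])

    history: list[dict] = []
    best_loss = np.inf
    best_snap = _snapshot(model)
    best_epoch = -1
    since_improve = 0
    n_decays = 0
    lr = cfg.lr0

    for epoch in range(cfg.max_epochs):
        order = shuffle_rng.permutation(len(train_s))
        ep_losses, ep_correct = [], 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = samples_to_batch([train_s[j] for j in idx], cfg.k, rng=crop_rng,
                                  standardize=cfg.standardize)
            yb = y_train[idx]
            logits = model.forward_logits(xb, mode="train")
            loss, g = cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(g)
            opt.lr = lr
            opt.step()
            ep_losses.append(loss * len(idx))
            ep_correct += int((logits.argmax(axis=1) == yb).sum())
        val_loss, val_acc = _eval_loss_acc(model, val_s, labels, cfg)
        history.append({
            "epoch": epoch,
            "lr": lr,
            "train_loss": float(np.sum(ep_losses) / len(train_s)),
            "train_acc": ep_correct / len(train_s),
            "val_loss": val_loss,
            "val_acc": val_acc,
        })
        if val_loss < best_loss - cfg.min_delta:
            best_loss = val_loss
            best_snap = _snapshot(model)
            best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.plateau_patience_epochs:
                n_decays += 1
                if n_decays > cfg.max_lr_decays:
                    break
                lr /= cfg.lr_decay_factor
                since_improve = 0

    _restore(model, best_snap)
    history.append({"meta": {"seed": cfg.seed, "best_epoch": best_epoch,
                             "best_val_loss": float(best_loss),
                             "labels": labels}})
    return model, history


def transfer(source: TaskCNN, new_n_classes: int, samples, fold: dict,
             cfg: TrainConfig = TrainConfig(), head_seed: int = 0):
    """Transfer learning: copy the trained trunk, re-initialize the class
    head for the new label set, then run the ordinary training loop."""
    model = clone_model(source, n_classes=new_n_classes, seed=head_seed)
    return train(model, samples, fold, cfg)


def evaluate_model(model: TaskCNN, samples, cfg: TrainConfig = TrainConfig(),
                   labels: dict | None = None):
    """Predict test samples with the first-k crop.

    Returns (y_true, y_pred, scores) with scores the softmax probabilities.
    """
    if labels is None:
        labels = label_index(samples)
    x = samples_to_batch(samples, cfg.k, rng=None, standardize=cfg.standardize)
    y = np.array([labels[s.label] for s in samples])
    scores = []
    for i in range(0, len(samples), cfg.batch_size):
        scores.append(softmax(model.forward_logits(x[i:i + cfg.batch_size], mode="eval")))
    scores = np.concatenate(scores)
    return y, scores.argmax(axis=1), scores


def learning_curve(samples, arch: ArchitectureConfig, grid,
                   n_subj_list=(1, 2, 4, 8, 17, 25, 34),
                   cfg: TrainConfig = TrainConfig(), seed: int = 0) -> pd.DataFrame:
    """Accuracy as a function of the number of training subjects.

    Subjects are shuffled once; a fixed tail is held out for validation and
    testing, and for each requested n the model trains on the first n
    remaining subjects and is evaluated on the fixed test set.
    """
    subjects = sorted({s.subject_id for s in samples})
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    n_test = max(1, int(round(0.2 * len(order))))
    n_val = max(1, int(round(0.2 * len(order))))
    test = order[:n_test]
    val = order[n_test:n_test + n_val]
    pool = order[n_test + n_val:]
    if max(n_subj_list) > len(pool):
        raise ValueError(
            f"requested {max(n_subj_list)} training subjects but only "
            f"{len(pool)} are available after holding out val/test"
        )
    labels = label_index(samples)
    rows = []
    for n in n_subj_list:
        fold = {"train": pool[:n], "val": val, "test": test}
        model = build_model(arch, grid, seed=seed)
        model, history = train(model, samples, fold, cfg)
        _, _, test_s = split_by_subject(samples, fold)
        y, yhat, _ = evaluate_model(model, test_s, cfg, labels)
        rows.append({"n_subjects": n, "accuracy": float((y == yhat).mean()),
                     "n_test_samples": len(y),
                     "epochs_run": len(history) - 1})
    return pd.DataFrame(rows)
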