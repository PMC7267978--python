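"""Guided-backprop pattern maps and group Cohen's d effect maps.

The class-score gradient is propagated back to the 4D input with the guided
rule — at every ReLU the gradient passes only where both the forward input
and the incoming gradient are positive — so only paths with positive
influence on the class score survive. The 4D gradient is collapsed over time
by keeping, per voxel, the signed value with the largest absolute magnitude,
and the 3D map is normalized by its maximum absolute value (sign-preserving,
bounding the map in [-1, 1]). A group of pattern maps condenses into a
per-voxel Cohen's d (mean / sample SD).
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .io import Bold4DSample, VolumeGrid
from .model import TaskCNN
from .training import TrainConfig, deterministic_first_crop, samples_to_batch

__all__ = [
    "Gradient4D", "PatternMap3D", "GroupEffectMap",
    "guided_backprop", "collapse_time", "cohens_d_map",
    "pattern_map", "group_pattern_maps", "save_map_nifti",
]


@dataclass
class Gradient4D:
    data: np.ndarray  # (t, x, y, z)
    class_label: str
    subject_id: str = ""


@dataclass
class PatternMap3D:
    data: np.ndarray  # (x, y, z), signed, max |value| == 1 unless all-zero
    class_label: str
    norm: float = 1.0  # the normalization constant that was divided out
    all_zero: bool = False


@dataclass
class GroupEffectMap:
    d: np.ndarray  # (x, y, z) Cohen's d
    n_maps: int
    n_zero_sd_voxels: int = 0


def guided_backprop(model: TaskCNN, sample: Bold4DSample | np.ndarray,
                    target_class: int, cfg: TrainConfig = TrainConfig()) -> Gradient4D:
    """Guided gradient of the target-class logit w.r.t. the input fragment.

    The sample passes through the same first-k crop and standardization as
    at test time; batch-norm layers run with frozen inference statistics.
    """
    if isinstance(sample, Bold4DSample):
        x = samples_to_batch([sample], cfg.k, rng=None, standardize=cfg.standardize)[0]
        label, subject = sample.label, sample.subject_id
    else:
        x = np.asarray(sample, dtype=np.float32)
        label, subject = str(target_class), ""
    g = model.input_gradient(x, target_class, guided=True)
    return Gradient4D(data=g, class_label=label, subject_id=subject)


def collapse_time(g: Gradient4D | np.ndarray) -> PatternMap3D:
    """Per voxel, keep the element of largest |value| across time (signed),
    then divide the whole 3D map by its maximum absolute value."""
    data = g.data if isinstance(g, Gradient4D) else np.asarray(g)
    if data.ndim != 4 or data.shape[0] < 1:
        raise ValueError("expected a (t, x, y, z) gradient")
    idx = np.abs(data).argmax(axis=0)
    collapsed = np.take_along_axis(data, idx[None], axis=0)[0]
    peak = float(np.abs(collapsed).max())
    label = g.class_label if isinstance(g, Gradient4D) else ""
    if peak == 0.0:
        return PatternMap3D(data=collapsed, class_label=label, norm=0.0, all_zero=True)
    return PatternMap3D(data=collapsed / peak, class_label=label, norm=peak)


def cohens_d_map(maps: list[PatternMap3D | np.ndarray]) -> GroupEffectMap:
    """Voxelwise Cohen's d = mean / sample SD (n-1) over a group of maps.

    Voxels with zero SD are set to 0 and counted.
    """
    if len(maps) < 2:
        raise ValueError("Cohen's d needs at least two maps")
    arrays = [m.data if isinstance(m, PatternMap3D) else np.asarray(m) for m in maps]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"maps have differing shapes: {shapes}")
    stack = np.stack(arrays).astype(np.float64)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    zero = sd == 0
    d = np.zeros_like(mean)
    d[~zero] = mean[~zero] / sd[~zero]
    return GroupEffectMap(d=d, n_maps=len(maps), n_zero_sd_voxels=int(zero.sum()))


def pattern_map(model: TaskCNN, sample: Bold4DSample, target_class: int,
                cfg: TrainConfig = TrainConfig()) -> PatternMap3D:
    """Guided backprop + temporal collapse for one sample."""
    return collapse_time(guided_backprop(model, sample, target_class, cfg))


def group_pattern_maps(model: TaskCNN, samples, labels: dict[str, int],
                       cfg: TrainConfig = TrainConfig()) -> dict[str, GroupEffectMap]:
    """Per-class group effect maps over a set of samples.

    Each sample contributes a pattern map for its own class; maps are grouped
    by class and condensed to Cohen's d.
    """
    by_class: dict[str, list[PatternMap3D]] = {}
    for s in samples:
        pm = pattern_map(model, s, labels[s.label], cfg)
        by_class.setdefault(s.label, []).append(pm)
    return {lab: cohens_d_map(maps) for lab, maps in by_class.items() if len(maps) >= 2}


def save_map_nifti(data: np.ndarray, grid: VolumeGrid, path) -> None:
    """Write a 3D map into the input grid as a NIfTI-1 volume."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    img.header.set_zooms(grid.voxel_size_mm)
    nib.save(img, str(path))
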