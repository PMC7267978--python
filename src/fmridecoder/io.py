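"""Reading, writing and slicing of 4D BOLD runs and block-design event tables.

Volumes travel as NIfTI-1 images (via :mod:`nibabel`); event tables are
BIDS-style TSV files with ``onset`` / ``duration`` / ``trial_type`` columns.
Internally time is always the leading axis, ``(t, x, y, z)``, and every index
range is 0-based and half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "BoldRun",
    "EventTable",
    "Bold4DSample",
    "DEFAULT_CROP_BOX",
    "read_bold_run",
    "write_bold_run",
    "crop_volume",
    "default_crop_box",
    "extract_block_sample",
    "extract_run_samples",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeGrid:
    """Spatial sampling grid of a volume: voxel counts, sizes and affine."""

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray = None  # 4x4 voxel->world (mm)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be three counts >= 1, got {self.shape}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.affine is None:
            aff = np.diag((*self.voxel_size_mm, 1.0))
            object.__setattr__(self, "affine", aff)
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4):
                raise ValueError("affine must be 4x4")
            if abs(np.linalg.det(aff)) < 1e-12:
                raise ValueError("affine must be invertible")
            object.__setattr__(self, "affine", aff)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class BoldRun:
    """A continuous BOLD series ``(t, x, y, z)`` with its repetition time."""

    data: np.ndarray
    tr_s: float
    subject_id: str
    grid: VolumeGrid

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD run must be 4-D (t,x,y,z), got ndim={self.data.ndim}")
        if self.data.shape[0] < 1:
            raise ValueError("run must contain at least one frame")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if tuple(self.data.shape[1:]) != self.grid.shape:
            raise ValueError(
                f"spatial shape {self.data.shape[1:]} does not match grid {self.grid.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.tr_s


@dataclass
class EventTable:
    """Block-design events: onset and duration in seconds plus a label."""

    frame: pd.DataFrame  # columns: onset, duration, trial_type

    def __post_init__(self):
        required = {"onset", "duration", "trial_type"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"event table missing columns: {sorted(missing)}")
        if (self.frame["onset"] < 0).any():
            raise ValueError("onsets must be >= 0")
        if (self.frame["duration"] <= 0).any():
            raise ValueError("durations must be > 0")
        if self.frame["trial_type"].astype(str).str.len().eq(0).any():
            raise ValueError("labels must be non-empty")

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        for row in self.frame.itertuples(index=False):
            yield float(row.onset), float(row.duration), str(row.trial_type)

    @classmethod
    def from_rows(cls, rows: Sequence[tuple[float, float, str]]) -> "EventTable":
        return cls(pd.DataFrame(rows, columns=["onset", "duration", "trial_type"]))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EventTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class Bold4DSample:
    """One labeled BOLD fragment — the classifier's input unit."""

    data: np.ndarray  # (t, x, y, z)
    label: str
    subject_id: str
    tr_s: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("sample must be 4-D (t,x,y,z)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[1:])


# ---------------------------------------------------------------------------
# NIfTI / TSV I/O
# ---------------------------------------------------------------------------

def read_bold_run(path, events_path=None, subject_id: str = "") -> tuple[BoldRun, EventTable | None]:
    """Load a 4-D NIfTI run (and optionally its events TSV).

    The repetition time is taken from the NIfTI header time step; the on-disk
    axis order (x, y, z, t) is moved so that time leads internally.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D image, got {img.ndim}-D")
    data = np.moveaxis(np.asanyarray(img.dataobj), -1, 0)
    zooms = img.header.get_zooms()
    tr_s = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr_s <= 0:
        raise ValueError(f"{path}: header carries no positive TR")
    grid = VolumeGrid(
        shape=tuple(int(s) for s in img.shape[:3]),
        voxel_size_mm=tuple(float(z) for z in zooms[:3]),
        affine=np.asarray(img.affine, dtype=float),
    )
    run = BoldRun(data=data, tr_s=tr_s, subject_id=subject_id, grid=grid)
    events = EventTable.from_tsv(events_path) if events_path is not None else None
    return run, events


def write_bold_run(run: BoldRun, path, events: EventTable | None = None, events_path=None) -> None:
    """Write a run as NIfTI-1 (time last on disk) plus an optional events TSV."""
    data = np.moveaxis(run.data, 0, -1)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), run.grid.affine)
    img.header.set_zooms((*run.grid.voxel_size_mm, run.tr_s))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    if events is not None:
        if events_path is None:
            events_path = Path(str(path)).with_suffix("").with_suffix("")
            events_path = events_path.parent / (events_path.name + "_events.tsv")
        events.to_tsv(events_path)


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

#: Centered crop taking the standard 91x109x91 MNI grid to 75x93x81.
DEFAULT_CROP_BOX = ((8, 83), (8, 101), (5, 86))


def default_crop_box(grid_shape: tuple[int, int, int],
                     target: tuple[int, int, int] = (75, 93, 81)):
    """Centered half-open crop box shrinking ``grid_shape`` to ``target``."""
    box = []
    for n, t in zip(grid_shape, target):
        if t > n:
            raise ValueError(f"target extent {t} exceeds grid extent {n}")
        off = (n - t) // 2
        box.append((off, off + t))
    return tuple(box)


def crop_volume(run: BoldRun, crop_box=None) -> BoldRun:
    """Spatially crop a run to half-open per-axis index ranges.

    The affine translation is updated so world coordinates of retained voxels
    are unchanged.
    """
    if crop_box is None:
        crop_box = default_crop_box(run.grid.shape)
    if len(crop_box) != 3:
        raise ValueError("crop_box must give one (start, stop) range per spatial axis")
    starts, stops = [], []
    for (lo, hi), n in zip(crop_box, run.grid.shape):
        lo, hi = int(lo), int(hi)
        if not (0 <= lo < hi <= n):
            raise IndexError(f"crop range ({lo}, {hi}) out of bounds for extent {n}")
        starts.append(lo)
        stops.append(hi)
    data = run.data[:, starts[0]:stops[0], starts[1]:stops[1], starts[2]:stops[2]]
    affine = run.grid.affine.copy()
    affine[:3, 3] += affine[:3, :3] @ np.array(starts, dtype=float)
    grid = VolumeGrid(shape=tuple(data.shape[1:]), voxel_size_mm=run.grid.voxel_size_mm,
                      affine=affine)
    return BoldRun(data=data, tr_s=run.tr_s, subject_id=run.subject_id, grid=grid)


# ---------------------------------------------------------------------------
# block-sample extraction
# ---------------------------------------------------------------------------

def _contained_frames(tr_s: float, window_start_s: float, window_stop_s: float) -> tuple[int, int]:
    """Frames whose whole acquisition interval [t*TR, (t+1)*TR) lies in the window.

    Returns a half-open frame range. A tiny tolerance absorbs float round-off
    so that e.g. 0.72*(n+1) <= 20.0 is decided exactly at the rational value.
    """
    eps = 1e-9
    first = int(np.ceil(window_start_s / tr_s - eps))
    # largest t with (t+1)*tr <= stop  ->  t = floor(stop/tr) - 1 up to round-off
    last_plus_one = int(np.floor(window_stop_s / tr_s + eps))
    return max(first, 0), last_plus_one


def extract_block_sample(run: BoldRun, onset_s: float, duration_s: float,
                         label: str, post_window_s: float = 8.0,
                         allow_truncate: bool = False) -> Bold4DSample:
    """Cut the labeled sample covering one block plus the HRF tail.

    The window is ``[onset, onset + duration + post_window)``; a frame is kept
    iff its whole acquisition interval lies inside the window. For the 12 s
    motor-style block at TR 0.72 s this yields 27 frames.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    stop_s = onset_s + duration_s + post_window_s
    lo, hi = _contained_frames(run.tr_s, onset_s, stop_s)
    if hi > run.n_frames:
        if not allow_truncate:
            raise ValueError(
                f"block window [{onset_s}, {stop_s}) s extends past the run "
                f"({run.duration_s:.2f} s); pass allow_truncate=True to clip"
            )
        hi = run.n_frames
    if hi <= lo:
        raise ValueError("window contains no complete frame")
    return Bold4DSample(data=run.data[lo:hi], label=label,
                        subject_id=run.subject_id, tr_s=run.tr_s)


def extract_run_samples(run: BoldRun, events: EventTable,
                        post_window_s: float = 8.0,
                        allow_truncate: bool = True) -> list[Bold4DSample]:
    """Extract one sample per event row."""
    return [
        extract_block_sample(run, onset, duration, label,
                             post_window_s=post_window_s, allow_truncate=allow_truncate)
        for onset, duration, label in events
    ]
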