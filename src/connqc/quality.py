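"""Per-scan image-quality metrics, each on a 'lower is better' scale.

Three metrics summarize scan quality:

* **iSNR** — negative signal-to-noise ratio estimated from two back-to-back
  volumes: ``-mean(I1, I2 pooled over masked voxels) / (std(I1 - I2) / sqrt(2))``.
  The difference image isolates thermal noise; dividing its SD by sqrt(2)
  recovers the single-volume noise level. More negative = better SNR.
* **head motion** — mean volume-to-volume translation in mm: the sum over
  successive volumes of the Euclidean displacement step, divided by N - 1.
* **atlas mismatch** — ``1 - Dice`` overlap between the scan's brain mask and
  the atlas template mask, in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


class UndefinedMetricError(ValueError):
    """A quality metric is mathematically undefined for the given input."""


@dataclass
class QualityTriple:
    isnr: float
    head_motion: float
    atlas_mismatch: float


@dataclass
class MotionTrace:
    """Per-volume displacements (mm) along left-right, anterior-posterior and
    longitudinal axes; row i is volume i. Rotations, when read from a
    realignment-parameter file, are parsed but do not enter the motion metric.
    """

    displacements: np.ndarray  # (N, 3) mm
    rotations: np.ndarray | None = None  # (N, 3) rad, unused by the metric

    def __post_init__(self):
        d = np.asarray(self.displacements, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3:
            raise ValueError(f"displacements must be (N, 3), got {d.shape}")
        self.displacements = d

    @property
    def n_volumes(self) -> int:
        return self.displacements.shape[0]


@dataclass
class BrainMask:
    voxels: np.ndarray                   # 3D binary
    voxel_dims: tuple = (1.0, 1.0, 1.0)  # mm, unused by pure-Dice mismatch

    def __post_init__(self):
        v = np.asarray(self.voxels).astype(bool)
        if v.ndim != 3:
            raise ValueError(f"mask must be 3D, got {v.ndim}D")
        self.voxels = v

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def _as_mask(mask) -> np.ndarray:
    return mask.voxels if isinstance(mask, BrainMask) else np.asarray(mask).astype(bool)


def isnr(vol1: np.ndarray, vol2: np.ndarray, mask) -> float:
    """Inverse SNR from two volumes acquired immediately after each other.

    The mean is taken over the masked voxels of *both* volumes pooled
    (symmetric in the two acquisitions); the noise SD uses the sample (n-1)
    denominator on the voxelwise difference image.
    """
    m = _as_mask(mask)
    v1 = np.asarray(vol1, dtype=float)
    v2 = np.asarray(vol2, dtype=float)
    if v1.shape != v2.shape or v1.shape != m.shape:
        raise ValueError("volumes and mask must share one shape")
    if m.sum() < 2:
        raise ValueError("mask must contain at least two voxels")
    a, b = v1[m], v2[m]
    noise = np.std(a - b, ddof=1) / np.sqrt(2.0)
    if noise == 0:
        raise UndefinedMetricError(
            "difference image has zero variance (identical volumes); iSNR undefined")
    return float(-np.mean(np.concatenate([a, b])) / noise)


def head_motion(trace: MotionTrace | np.ndarray) -> float:
    """Mean volume-to-volume translation in mm.

    Sum over i = 2..N of the Euclidean norm of the displacement step,
    divided by N - 1. Invariant to a constant offset of the whole trace.
    """
    d = trace.displacements if isinstance(trace, MotionTrace) else np.asarray(trace, float)
    if d.ndim != 2 or d.shape[1] != 3:
        raise ValueError("trace must be (N, 3)")
    if d.shape[0] < 2:
        raise ValueError("need at least two volumes to estimate motion")
    steps = np.linalg.norm(np.diff(d, axis=0), axis=1)
    return float(steps.sum() / (d.shape[0] - 1))


def atlas_mismatch(brain, atlas) -> float:
    """1 - Dice similarity of two brain masks: 0 = identical, 1 = disjoint.

    Computed on voxel counts in the native grid (voxel dimensions cancel).
    """
    A = _as_mask(brain)
    B = _as_mask(atlas)
    if A.shape != B.shape:
        raise ValueError("masks must share a grid shape")
    na, nb = int(A.sum()), int(B.sum())
    if na + nb == 0:
        raise UndefinedMetricError("both masks empty; Dice undefined")
    inter = int((A & B).sum())
    return float(1.0 - 2.0 * inter / (na + nb))


def read_motion_parameters(path, convention: str = "rotations_first") -> MotionTrace:
    """Parse a 6-column rigid-body realignment-parameter text file.

    ``rotations_first`` (default): columns are three rotations (rad) then
    three translations (mm); ``translations_first`` swaps the halves. One row
    per volume, whitespace-delimited.
    """
    if convention not in ("rotations_first", "translations_first"):
        raise ValueError(f"unknown column convention {convention!r}")
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(
                    f"{path}: line {ln}: expected 6 columns, got {len(parts)}")
            try:
                rows.append([float(x) for x in parts])
            except ValueError as e:
                raise ValueError(f"{path}: line {ln}: non-numeric value") from e
    if not rows:
        raise ValueError(f"{path}: no motion parameters found (empty file)")
    arr = np.asarray(rows, dtype=float)
    if convention == "rotations_first":
        rot, trans = arr[:, :3], arr[:, 3:]
    else:
        trans, rot = arr[:, :3], arr[:, 3:]
    return MotionTrace(displacements=trans, rotations=rot)


def quality_from_files(vol1_path, vol2_path, mask_path, atlas_path,
                       motion_path, convention: str = "rotations_first") -> QualityTriple:
    """Compute the full quality triple from NIfTI volumes/masks and a motion file."""
    import nibabel as nib

    def load(p):
        return np.asanyarray(nib.load(str(p)).dataobj)

    v1, v2 = load(vol1_path), load(vol2_path)
    if v1.ndim == 4:
        v1 = v1[..., 0]
    if v2.ndim == 4:
        v2 = v2[..., 0]
    mask = load(mask_path) > 0
    atlas = load(atlas_path) > 0
    trace = read_motion_parameters(motion_path, convention=convention)
    return QualityTriple(
        isnr=isnr(v1, v2, mask),
        head_motion=head_motion(trace),
        atlas_mismatch=atlas_mismatch(mask, atlas),
    )


def write_motion_parameters(trace: MotionTrace, path,
                            convention: str = "rotations_first") -> Path:
    rot = trace.rotations if trace.rotations is not None else np.zeros_like(trace.displacements)
    if convention == "rotations_first":
        arr = np.column_stack([rot, trace.displacements])
    elif convention == "translations_first":
        arr = np.column_stack([trace.displacements, rot])
    else:
        raise ValueError(f"unknown column convention {convention!r}")
    np.savetxt(path, arr, fmt="%.8f")
    return Path(path)
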