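"""Minimal 4D imaging fixtures with known quality-metric ground truth.

The fixture is not a realistic MR simulation: it is a constant-intensity
"brain" ellipsoid plus white Gaussian noise, rigidly shifted per volume along
a prescribed motion trace, with an atlas mask perturbed to hit an exact Dice
mismatch. Its purpose is that the quality-metric estimators applied to the
arrays reproduce the stored ground truth: exactly for motion and mismatch,
and within estimator sampling error for iSNR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .quality import BrainMask, MotionTrace, QualityTriple, write_motion_parameters

log = logging.getLogger(__name__)


@dataclass
class VolumeFixture:
    volumes: np.ndarray          # (x, y, z, t)
    brain_mask: np.ndarray       # 3D bool
    atlas_mask: np.ndarray       # 3D bool
    motion_trace: MotionTrace    # per-volume displacements, mm
    truth: QualityTriple
    voxel_dims: tuple = (2.0, 2.0, 2.0)
    requested_mismatch: float | None = None


def _ellipsoid(shape, semiaxes, center=None) -> np.ndarray:
    grid = np.indices(shape).astype(float)
    if center is None:
        center = [(s - 1) / 2 for s in shape]
    r = sum(((grid[k] - center[k]) / semiaxes[k]) ** 2 for k in range(3))
    return r <= 1.0


def generate_volume_fixture(n_volumes: int = 6, snr_target: float = 22.0,
                            motion_per_volume: float = 0.5,
                            mismatch_target: float = 0.087,
                            seed: int = 0,
                            shape: tuple = (46, 46, 36),
                            signal: float = 100.0,
                            voxel_dims: tuple = (2.0, 2.0, 2.0)) -> VolumeFixture:
    """Construct a 4D fixture whose quality metrics are known by design.

    * iSNR: brain intensity ``signal`` with additive Gaussian noise of SD
      ``signal / snr_target`` -> expected estimate ``-snr_target``.
    * motion: successive volumes are displaced by ``motion_per_volume`` mm
      along the x axis (alternating direction so the head stays in-frame);
      the mean volume-to-volume translation is ``motion_per_volume`` exactly.
      Volumes are rolled by the displacement rounded to whole voxels; the
      intensity region is dilated beyond the brain mask by the maximum shift
      so the mask always sees constant signal.
    * mismatch: the atlas mask is the brain mask with k boundary voxels
      swapped for k outside voxels, giving mismatch k / |mask| exactly; the
      nearest grid-achievable value is used (and logged) when
      ``mismatch_target * |mask|`` is not an integer.
    """
    if n_volumes < 2:
        raise ValueError("need at least two volumes")
    if snr_target <= 0:
        raise ValueError("snr_target must be positive")
    if motion_per_volume < 0:
        raise ValueError("motion_per_volume must be nonnegative")
    if not 0.0 <= mismatch_target < 1.0:
        raise ValueError("mismatch_target must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    vox = np.asarray(voxel_dims, dtype=float)

    # displacement trace: steps of +/- motion_per_volume mm along x
    steps = motion_per_volume * np.array([(-1) ** i for i in range(n_volumes - 1)])
    disp = np.zeros((n_volumes, 3))
    disp[1:, 0] = np.cumsum(steps)
    max_shift_vox = int(np.ceil(np.abs(disp[:, 0]).max() / vox[0]))

    semi = np.array([shape[0] * 0.30, shape[1] * 0.34, shape[2] * 0.34])
    brain = _ellipsoid(shape, semi)
    signal_region = _ellipsoid(shape, semi + max_shift_vox + 2)

    sigma = signal / snr_target
    base = np.where(signal_region, signal, 0.0)
    vols = np.empty(shape + (n_volumes,), dtype=float)
    for t in range(n_volumes):
        noisy = base + sigma * rng.standard_normal(shape)
        shift = int(round(disp[t, 0] / vox[0]))
        vols[..., t] = np.roll(noisy, shift, axis=0)

    # atlas mask: swap k interior-boundary voxels for k exterior neighbours
    A = int(brain.sum())
    k = int(round(mismatch_target * A))
    achieved = k / A
    if abs(achieved - mismatch_target) > 1e-12:
        log.info("mismatch_target %.6f not on the voxel grid; using nearest "
                 "achievable %.6f (k=%d of %d voxels)", mismatch_target, achieved, k, A)
    boundary = brain & ~_ellipsoid(shape, semi - 1.5)
    outside_ring = _ellipsoid(shape, semi + 1.5) & ~brain
    b_idx = np.flatnonzero(boundary.ravel())
    o_idx = np.flatnonzero(outside_ring.ravel())
    if k > min(b_idx.size, o_idx.size):
        raise ValueError(
            f"mismatch_target {mismatch_target} unreachable on this grid; nearest "
            f"achievable is {min(b_idx.size, o_idx.size) / A:.4f}")
    atlas = brain.copy().ravel()
    atlas[rng.choice(b_idx, size=k, replace=False)] = False
    atlas[rng.choice(o_idx, size=k, replace=False)] = True
    atlas = atlas.reshape(shape)

    trace = MotionTrace(displacements=disp, rotations=np.zeros_like(disp))
    truth = QualityTriple(isnr=-snr_target,
                          head_motion=float(motion_per_volume),
                          atlas_mismatch=achieved)
    return VolumeFixture(volumes=vols, brain_mask=brain, atlas_mask=atlas,
                         motion_trace=trace, truth=truth,
                         voxel_dims=tuple(vox), requested_mismatch=mismatch_target)


def write_fixture(fix: VolumeFixture, outdir,
                  convention: str = "rotations_first") -> dict[str, Path]:
    """Write the fixture as NIfTI-1 volumes/masks plus a motion text file."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(fix.voxel_dims) + [1.0])

    paths = {}

    def save(name, arr):
        p = outdir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), str(p))
        paths[name] = p

    save("volumes", fix.volumes)
    save("brain_mask", fix.brain_mask.astype(np.uint8))
    save("atlas_mask", fix.atlas_mask.astype(np.uint8))
    paths["motion"] = write_motion_parameters(
        fix.motion_trace, outdir / "motion.par", convention=convention)
    return paths


def fixture_quality(fix: VolumeFixture, volume_pair: tuple[int, int] = (0, 1)) -> QualityTriple:
    """Recompute the quality triple from the fixture arrays (the estimators'
    view of the ground truth stored in ``fix.truth``)."""
    from . import quality

    i, j = volume_pair
    mask = BrainMask(fix.brain_mask, fix.voxel_dims)
    return QualityTriple(
        isnr=quality.isnr(fix.volumes[..., i], fix.volumes[..., j], mask),
        head_motion=quality.head_motion(fix.motion_trace),
        atlas_mismatch=quality.atlas_mismatch(mask, BrainMask(fix.atlas_mask, fix.voxel_dims)),
    )
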