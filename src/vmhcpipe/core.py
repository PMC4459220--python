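"""Voxel-mirrored homotopic connectivity (VMHC).

For every gray-matter voxel, VMHC is the Pearson correlation between its
time series and the series of its left–right mirrored counterpart on a
symmetric grid; the Fisher r-to-z transform of that map (zVMHC) is the
quantity carried into group statistics.  Mirroring is pure index reversal
along the first axis, which requires an even left–right dimension so no
voxel is its own mirror.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .preproc import BoldSeries

R_CLIP = 1.0 - 1e-7


def mirror_index(i: int, nx: int) -> int:
    """Mirror voxel index along the left–right axis: ``nx - 1 - i``."""
    if nx % 2 != 0:
        raise ValueError("left-right axis length must be even (no self-mirrored voxel)")
    if not 0 <= i < nx:
        raise ValueError(f"index {i} outside [0, {nx})")
    return nx - 1 - i


@dataclass
class GrayMatterMask:
    """Gray-matter probability with a binary threshold (default 40%)."""

    probability: np.ndarray
    threshold: float = 0.40

    def __post_init__(self) -> None:
        self.probability = np.asarray(self.probability, float)
        if self.probability.ndim != 3:
            raise ValueError("gray-matter probability must be 3-D")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must be in [0, 1]")

    @property
    def binary(self) -> np.ndarray:
        return self.probability >= self.threshold

    @classmethod
    def from_nifti(cls, path: str | Path, threshold: float = 0.40) -> "GrayMatterMask":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, float), threshold)


@dataclass
class VmhcMap:
    """Per-subject mirror-correlation map and its Fisher-z transform.

    ``valid_mask`` marks voxels where both members of the mirror pair had
    nonzero variance and lie in gray matter; r and z are 0 elsewhere.
    """

    r_map: np.ndarray
    z_map: np.ndarray
    valid_mask: np.ndarray
    affine: np.ndarray | None = None

    def save(self, prefix: str | Path) -> None:
        aff = self.affine if self.affine is not None else np.eye(4)
        prefix = str(prefix)
        nib.save(nib.Nifti1Image(self.r_map.astype(np.float32), aff),
                 prefix + "_vmhc.nii.gz")
        nib.save(nib.Nifti1Image(self.z_map.astype(np.float32), aff),
                 prefix + "_zvmhc.nii.gz")
        nib.save(nib.Nifti1Image(self.valid_mask.astype(np.uint8), aff),
                 prefix + "_validmask.nii.gz")


def fisher_z(r):
    """Fisher r-to-z: atanh with |r| clipped just below 1."""
    r = np.clip(np.asarray(r, float), -R_CLIP, R_CLIP)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def compute_vmhc(bold: BoldSeries, mask: GrayMatterMask) -> VmhcMap:
    """Mirror-voxel Pearson correlation map within the gray-matter mask.

    The statistic is symmetric in its two series, so the resulting map
    equals its own left–right flip on valid voxels.
    """
    data = bold.data
    if data.shape[3] < 3:
        raise ValueError("need at least 3 time points for a correlation map")
    if data.shape[0] % 2 != 0:
        raise ValueError("left-right axis length must be even (no self-mirrored voxel)")
    if mask.probability.shape != data.shape[:3]:
        raise ValueError("gray-matter mask grid does not match the BOLD grid")

    x = data.astype(np.float64)
    y = x[::-1]  # mirrored counterpart of every voxel
    x = x - x.mean(axis=3, keepdims=True)
    y = y - y.mean(axis=3, keepdims=True)
    ssx = (x**2).sum(axis=3)
    ssy = (y**2).sum(axis=3)
    num = (x * y).sum(axis=3)
    nonzero = (ssx > 0) & (ssy > 0)
    gm = mask.binary
    valid = gm & gm[::-1] & nonzero

    r = np.zeros(data.shape[:3])
    np.divide(num, np.sqrt(ssx * ssy), out=r, where=nonzero)
    r[~valid] = 0.0
    # guard against rounding past +/-1 before atanh
    np.clip(r, -1.0, 1.0, out=r)
    z = np.zeros_like(r)
    z[valid] = fisher_z(r[valid])
    return VmhcMap(r_map=r, z_map=z, valid_mask=valid, affine=bold.affine)
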