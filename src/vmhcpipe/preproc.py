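"""Resting-state preprocessing: motion bookkeeping and temporal cleaning.

The retained chain, in fixed order: discard of initial volumes →
framewise displacement and motion-based exclusion → nuisance regression
(six rigid-motion parameters plus ventricle and white-matter mean
signals) → spatial smoothing → linear detrend → ideal temporal band-pass
(0.01–0.08 Hz).  Registration, slice timing and segmentation are out of
scope: the synthetic cohorts are generated on a common symmetric grid and
head motion enters only through the supplied motion-parameter traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .synthdata import FWHM_TO_SIGMA

#: per-axis motion-exclusion thresholds (strict inequality)
TRANSLATION_LIMIT_MM = 2.0
ROTATION_LIMIT_DEG = 2.0


@dataclass
class BoldSeries:
    """A 4-D BOLD scalar field (x, y, z, t) with grid geometry."""

    data: np.ndarray
    tr_seconds: float
    voxel_mm: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-D (x, y, z, t)")
        if self.data.shape[3] < 1:
            raise ValueError("BOLD series needs at least 1 time point")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_mm) + [1.0])

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return BoldSeries(data=data, tr_seconds=self.tr_seconds,
                          voxel_mm=self.voxel_mm, affine=self.affine)

    @classmethod
    def from_nifti(cls, path: str | Path, tr_seconds: float) -> "BoldSeries":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        return cls(data=np.asarray(img.dataobj, dtype=np.float32),
                   tr_seconds=tr_seconds,
                   voxel_mm=tuple(float(z) for z in zooms),
                   affine=np.asarray(img.affine))

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine),
                 str(path))


@dataclass
class MotionTrace:
    """Six rigid-motion parameters per volume.

    ``translations``: T×3 in mm; ``rotations``: T×3 in degrees.  File
    format: whitespace-delimited text, one row per volume, columns
    x/y/z translation then pitch/roll/yaw.
    """

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, float))
        if self.translations.shape != self.rotations.shape or self.translations.shape[1] != 3:
            raise ValueError("motion trace must be T x 3 translations and T x 3 rotations")

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]

    def discard_initial(self, n: int) -> "MotionTrace":
        if n >= self.n_volumes:
            raise ValueError("cannot discard all motion rows")
        return MotionTrace(self.translations[n:], self.rotations[n:])

    @classmethod
    def from_file(cls, path: str | Path) -> "MotionTrace":
        arr = np.loadtxt(str(path), ndmin=2)
        if arr.shape[1] != 6:
            raise ValueError(f"{path}: expected 6 columns, got {arr.shape[1]}")
        return cls(arr[:, :3], arr[:, 3:])

    def to_file(self, path: str | Path) -> None:
        np.savetxt(str(path), np.hstack([self.translations, self.rotations]),
                   fmt="%.6f")


@dataclass
class FdSeries:
    """Power-style framewise displacement, mm (first frame defined as 0)."""

    values: np.ndarray

    @property
    def mean_fd(self) -> float:
        return float(np.mean(self.values))


def discard_initial_volumes(bold: BoldSeries, n_discard: int) -> BoldSeries:
    """Drop the first ``n_discard`` frames (signal-equilibration discard)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= bold.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {bold.n_volumes} volumes"
        )
    if n_discard == 0:
        return bold
    return bold.with_data(bold.data[..., n_discard:])


def compute_fd(trace: MotionTrace, sphere_radius_mm: float = 50.0) -> FdSeries:
    """Scalar FD per frame: sum of absolute backward differences.

    Rotations are converted from degrees to arc length on a sphere of
    ``sphere_radius_mm`` (default 50 mm).  ``FD(1) = 0`` by definition.
    """
    if trace.n_volumes < 2:
        raise ValueError("FD needs at least 2 motion rows")
    dt = np.abs(np.diff(trace.translations, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(np.deg2rad(trace.rotations), axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], dt + sphere_radius_mm * dr])
    return FdSeries(values=fd)


def motion_summary(trace: MotionTrace) -> tuple[float, float]:
    """Max per-axis absolute excursion from the first frame (mm, degrees)."""
    t_exc = np.abs(trace.translations - trace.translations[0]).max()
    r_exc = np.abs(trace.rotations - trace.rotations[0]).max()
    return float(t_exc), float(r_exc)


def exclusion_flags(
    traces: dict[str, MotionTrace],
    translation_limit_mm: float = TRANSLATION_LIMIT_MM,
    rotation_limit_deg: float = ROTATION_LIMIT_DEG,
) -> pd.DataFrame:
    """Per-subject motion exclusion table.

    A subject is excluded iff any per-axis translation excursion strictly
    exceeds ``translation_limit_mm`` or any rotation excursion strictly
    exceeds ``rotation_limit_deg`` (excursions measured from the first
    retained frame).  Returns a DataFrame indexed by subject id with
    columns ``max_translation_mm``, ``max_rotation_deg``, ``excluded``.
    """
    rows = {}
    for sid, trace in traces.items():
        t_exc, r_exc = motion_summary(trace)
        rows[sid] = dict(
            max_translation_mm=t_exc,
            max_rotation_deg=r_exc,
            excluded=(t_exc > translation_limit_mm) or (r_exc > rotation_limit_deg),
        )
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df


def _drop_dependent_columns(design: np.ndarray) -> np.ndarray:
    """Keep a maximal independent subset of columns, leftmost first."""
    keep: list[int] = []
    for j in range(design.shape[1]):
        cand = design[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
    if len(keep) < design.shape[1]:
        warnings.warn(
            f"nuisance design rank-deficient: dropped {design.shape[1] - len(keep)} "
            "dependent column(s), leftmost kept", stacklevel=3
        )
    return design[:, keep]


def regress_nuisance(bold: BoldSeries, regressors: np.ndarray) -> BoldSeries:
    """Replace each voxel series with its residual against [1 | regressors].

    Residuals are exactly orthogonal to every regressor column (least
    squares via QR).  Rank-deficient designs are pruned deterministically,
    keeping the leftmost of any dependent set.
    """
    regressors = np.atleast_2d(np.asarray(regressors, float))
    if regressors.shape[0] != bold.n_volumes:
        raise ValueError("regressor rows must equal the number of volumes")
    if regressors.shape[1] >= bold.n_volumes:
        raise ValueError("more regressors than time points")
    X = np.column_stack([np.ones(bold.n_volumes), regressors])
    X = _drop_dependent_columns(X)
    Q, _ = np.linalg.qr(X)
    flat = bold.data.reshape(-1, bold.n_volumes).T  # T x V
    resid = flat - Q @ (Q.T @ flat)
    return bold.with_data(
        resid.T.reshape(bold.data.shape).astype(bold.data.dtype, copy=False)
    )


def detrend_linear(bold: BoldSeries) -> BoldSeries:
    """Remove the per-voxel best-fit line (intercept + slope·t)."""
    if bold.n_volumes < 3:
        raise ValueError("linear detrend needs at least 3 time points")
    T = bold.n_volumes
    t = np.arange(T, dtype=float)
    X = np.column_stack([np.ones(T), t - t.mean()])
    Q, _ = np.linalg.qr(X)
    flat = bold.data.reshape(-1, T).T
    resid = flat - Q @ (Q.T @ flat)
    return bold.with_data(
        resid.T.reshape(bold.data.shape).astype(bold.data.dtype, copy=False)
    )


def bandpass(
    bold: BoldSeries, low_hz: float = 0.01, high_hz: float = 0.08
) -> BoldSeries:
    """Ideal frequency-domain band-pass.

    Discrete-Fourier components with frequency in [low_hz, high_hz] are
    retained; everything else, including the DC component, is zeroed.
    """
    nyquist = 1.0 / (2.0 * bold.tr_seconds)
    if not (0.0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz must be below the Nyquist frequency {nyquist:g} Hz")
    T = bold.n_volumes
    freqs = np.fft.rfftfreq(T, d=bold.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(bold.data, axis=3)
    spec[..., ~keep] = 0.0
    out = np.fft.irfft(spec, n=T, axis=3)
    return bold.with_data(out.astype(bold.data.dtype, copy=False))


def smooth_gaussian(
    volume: np.ndarray, fwhm_mm: float, voxel_mm: Sequence[float]
) -> np.ndarray:
    """Separable Gaussian smoothing, σ = FWHM / (2√(2 ln 2)) per axis.

    Boundary handling is reflective, which conserves the total sum.
    ``fwhm_mm = 0`` is the identity.  Accepts a 3-D volume or a 4-D series
    (smoothed frame-wise).
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return np.asarray(volume).copy()
    volume = np.asarray(volume, float)
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_mm]
    if volume.ndim == 4:
        sigma_vox = sigma_vox + [0.0]
    elif volume.ndim != 3:
        raise ValueError("expected a 3-D volume or 4-D series")
    return gaussian_filter(volume, sigma=sigma_vox, mode="reflect")


def smooth_bold(bold: BoldSeries, fwhm_mm: float) -> BoldSeries:
    """Frame-wise spatial smoothing of a 4-D series."""
    out = smooth_gaussian(bold.data, fwhm_mm, bold.voxel_mm)
    return bold.with_data(out.astype(bold.data.dtype, copy=False))


@dataclass
class SymmetricTemplate:
    """A 3-D field that equals its own left–right flip exactly."""

    data: np.ndarray


def build_symmetric_template(volumes: Sequence[np.ndarray]) -> SymmetricTemplate:
    """Average volumes, then average with the left–right flip.

    ``out = (mean + flip_x(mean)) / 2`` is exactly flip-invariant in
    floating point (addition is commutative).
    """
    if len(volumes) == 0:
        raise ValueError("need at least one volume")
    shape = np.asarray(volumes[0]).shape
    for i, v in enumerate(volumes):
        if np.asarray(v).shape != shape:
            raise ValueError(f"volume {i} has shape {np.asarray(v).shape}, expected {shape}")
    mean = np.mean([np.asarray(v, float) for v in volumes], axis=0)
    sym = (mean + mean[::-1]) / 2.0
    return SymmetricTemplate(data=sym)


def preprocess_bold(
    bold: BoldSeries,
    motion: MotionTrace,
    nuisance_signals: np.ndarray | None = None,
    n_discard: int = 10,
    fwhm_mm: float = 4.0,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
) -> tuple[BoldSeries, FdSeries]:
    """Run the full retained chain on one subject.

    Order: discard → FD → nuisance regression (6 motion parameters +
    optional extra signals, e.g. ventricle / white-matter means) →
    smoothing → detrend → band-pass.  ``motion`` must cover the
    pre-discard volumes; it is truncated alongside the BOLD data.
    Returns the cleaned series and the FD series of the retained frames.
    """
    if motion.n_volumes != bold.n_volumes:
        raise ValueError("motion trace and BOLD series disagree on volume count")
    bold = discard_initial_volumes(bold, n_discard)
    motion = motion.discard_initial(n_discard) if n_discard else motion
    fd = compute_fd(motion)
    reg = np.hstack([motion.translations, motion.rotations])
    if nuisance_signals is not None:
        extra = np.atleast_2d(np.asarray(nuisance_signals, float))
        if extra.shape[0] != bold.n_volumes:
            extra = extra.T
        reg = np.hstack([reg, extra])
    bold = regress_nuisance(bold, reg)
    bold = smooth_bold(bold, fwhm_mm)
    bold = detrend_linear(bold)
    bold = bandpass(bold, low_hz, high_hz)
    if not np.isfinite(bold.data).all():
        raise FloatingPointError("non-finite values after preprocessing")
    return bold, fd
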