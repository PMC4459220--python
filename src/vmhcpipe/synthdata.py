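"""Synthetic resting-state cohort generator with known homotopic ground truth.

Builds a self-contained cohort — 4-D BOLD NIfTI volumes, six-column motion
traces, a left–right symmetric gray-matter probability volume and a subject
table — in which the population correlation between every mirror-voxel pair
is planted exactly.  Each mirrored pair of time series is constructed as

    x = sqrt(rho) * c + sqrt(1 - rho) * e1
    y = sqrt(rho) * c + sqrt(1 - rho) * e2

with ``c``, ``e1``, ``e2`` independent unit-variance AR(1) processes, so the
population Pearson correlation of (x, y) equals ``rho`` exactly.  Regional
``rho`` values may differ by clinical group, which is what the downstream
group statistics are meant to recover.  Clinical scores are linearly coupled
to the subject's realized regional homotopic connectivity with a chosen
population correlation, so score–connectivity recovery is also testable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.signal import lfilter

GROUPS = ("AVH", "NonAVH", "Control")
#: patient groups that receive PANSS ratings; AHRS applies to AVH only
PATIENT_GROUPS = ("AVH", "NonAVH")
SCORE_NAMES = ("panss_pos", "panss_neg", "panss_gen", "panss_total", "ahrs")

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def grid_affine(shape: Sequence[int], voxel_mm: float) -> np.ndarray:
    """Affine placing the grid center at the coordinate origin.

    With an even first (left–right) dimension, voxel ``i`` and voxel
    ``nx - 1 - i`` map to ``+x`` and ``-x`` mm: index reversal along axis 0
    is exactly the left–right mirror about the mid-sagittal plane.
    """
    aff = np.diag([float(voxel_mm)] * 3 + [1.0])
    aff[:3, 3] = -(np.asarray(shape, float) - 1.0) / 2.0 * voxel_mm
    return aff


@dataclass(frozen=True)
class RegionEffect:
    """A spherical region with group-specific homotopic correlation.

    The region is defined in one hemisphere; its mirror is implied by the
    symmetric construction and never stored separately.
    """

    name: str
    center_mni: tuple[float, float, float]
    radius_mm: float
    rho_by_group: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"region {self.name!r}: radius must be positive")
        for g, rho in self.rho_by_group.items():
            if g not in GROUPS:
                raise ValueError(f"region {self.name!r}: unknown group {g!r}")
            if not (0.0 <= rho < 1.0):
                raise ValueError(f"region {self.name!r}: rho must be in [0, 1)")


@dataclass(frozen=True)
class NoiseSpec:
    """Temporal and spatial noise structure of the simulated BOLD."""

    ar1_coefficient: float = 0.3
    spatial_fwhm_mm: float = 0.0
    background_rho: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar1_coefficient < 1.0):
            raise ValueError("ar1_coefficient must be in [0, 1) (stationarity)")
        if self.spatial_fwhm_mm < 0:
            raise ValueError("spatial_fwhm_mm must be non-negative")
        if not (0.0 <= self.background_rho < 1.0):
            raise ValueError("background_rho must be in [0, 1)")


@dataclass(frozen=True)
class ScoreCoupling:
    """Linear coupling of a clinical score to a region's homotopic z value.

    ``score = mean + sd * (target_r * standardized zVMHC
                           + sqrt(1 - target_r^2) * noise)``
    so the population correlation between score and regional zVMHC is
    ``target_r`` within the listed groups.
    """

    score_name: str
    region_name: str
    target_r: float
    score_mean: float
    score_sd: float
    groups: tuple[str, ...] = PATIENT_GROUPS

    def __post_init__(self) -> None:
        if self.score_name not in SCORE_NAMES:
            raise ValueError(f"unknown score {self.score_name!r}")
        if not (-1.0 < self.target_r < 1.0):
            raise ValueError("target_r must be in (-1, 1)")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups {sorted(bad)}")
        if self.score_name == "ahrs" and set(self.groups) - {"AVH"}:
            raise ValueError("AHRS is rated only in the AVH group")


def default_regions() -> list[RegionEffect]:
    """Three planted regions spanning the study's qualitative outcomes.

    One region aberrant in the AVH group only, one in the NonAVH group only,
    one shared by both patient groups, mirroring the three dysconnectivity
    categories of the group analysis.  Coordinates are placed on the default
    20x24x20 voxel grid (a scaled-down head), not at the study's MNI peaks.
    """
    return [
        RegionEffect(  # anterior cingulate-like: reduced in AVH only
            "ACC", (12.0, 12.0, 6.0), 6.0,
            {"Control": 0.75, "NonAVH": 0.75, "AVH": 0.35},
        ),
        RegionEffect(  # superior temporal-like: raised in NonAVH only
            "STG", (15.0, -15.0, 0.0), 6.0,
            {"Control": 0.35, "NonAVH": 0.75, "AVH": 0.35},
        ),
        RegionEffect(  # striatum-like: shared aberrance in both patient groups
            "STR", (9.0, 6.0, -9.0), 6.0,
            {"Control": 0.75, "NonAVH": 0.35, "AVH": 0.35},
        ),
    ]


def default_score_model() -> list[ScoreCoupling]:
    """Score couplings with Table-1-plausible means and spreads."""
    return [
        ScoreCoupling("panss_pos", "ACC", -0.45, 25.0, 9.0),
        ScoreCoupling("panss_neg", "ACC", -0.35, 24.0, 8.0),
        ScoreCoupling("panss_gen", "ACC", -0.30, 48.0, 9.0),
        ScoreCoupling("panss_total", "ACC", -0.45, 97.0, 20.0),
        ScoreCoupling("ahrs", "STR", -0.45, 26.0, 8.0, groups=("AVH",)),
    ]


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    Defaults mirror the study conditions: TR = 2 s, 240 acquired volumes of
    which the first 10 are discarded, 3 mm isotropic analysis grid, and
    post-exclusion group sizes 16 (AVH) / 18 (NonAVH) / 20 (Control).
    """

    n_per_group: tuple[int, int, int] = (16, 18, 20)  # AVH, NonAVH, Control
    n_volumes: int = 240
    n_discard: int = 10
    tr_seconds: float = 2.0
    grid_shape: tuple[int, int, int] = (20, 24, 20)
    voxel_mm: float = 3.0
    regions: tuple[RegionEffect, ...] = field(
        default_factory=lambda: tuple(default_regions())
    )
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    score_model: tuple[ScoreCoupling, ...] = field(
        default_factory=lambda: tuple(default_score_model())
    )
    n_motion_outliers: int = 0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_shape[0] % 2 != 0:
            raise ValueError(
                "grid_shape[0] must be even so every voxel has a distinct mirror"
            )
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("every group needs at least 2 subjects")
        if self.n_volumes <= self.n_discard:
            raise ValueError("n_volumes must exceed n_discard")
        if self.voxel_mm <= 0 or self.tr_seconds <= 0:
            raise ValueError("voxel_mm and tr_seconds must be positive")
        for reg in self.regions:
            self._region_half_mask(reg)  # validates placement
        region_names = {r.name for r in self.regions}
        for coup in self.score_model:
            if coup.region_name not in region_names:
                raise ValueError(
                    f"score {coup.score_name!r} is coupled to unknown region "
                    f"{coup.region_name!r}"
                )

    @classmethod
    def study_cohort(cls, master_seed: int = 0) -> "CohortSpec":
        """Pre-exclusion layout: 18/18/20 with 2 AVH motion outliers.

        After motion exclusion this retains 16/18/20 = 54 subjects.
        """
        return cls(n_per_group=(18, 18, 20), n_motion_outliers=2,
                   master_seed=master_seed)

    # ---- geometry -------------------------------------------------------

    @property
    def affine(self) -> np.ndarray:
        return grid_affine(self.grid_shape, self.voxel_mm)

    def _voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        aff = self.affine
        axes = [
            aff[d, d] * np.arange(self.grid_shape[d]) + aff[d, 3]
            for d in range(3)
        ]
        return tuple(axes)  # type: ignore[return-value]

    def _region_half_mask(self, region: RegionEffect) -> np.ndarray:
        """Boolean mask of the region on the x > 0 half-grid.

        The planted sphere is reflected into the positive-x hemisphere; its
        negative-x mirror is implied.  Raises if the sphere pokes outside the
        grid or touches the mid-sagittal plane (a self-mirrored region would
        make the planted correlation ill-defined).
        """
        cx, cy, cz = region.center_mni
        cx = abs(cx)
        xs, ys, zs = self._voxel_centers_mm()
        lo = (cx - region.radius_mm, cy - region.radius_mm, cz - region.radius_mm)
        hi = (cx + region.radius_mm, cy + region.radius_mm, cz + region.radius_mm)
        bounds = [(xs[0], xs[-1]), (ys[0], ys[-1]), (zs[0], zs[-1])]
        for d in range(3):
            if lo[d] < bounds[d][0] - self.voxel_mm / 2 or hi[d] > bounds[d][1] + self.voxel_mm / 2:
                raise ValueError(
                    f"region {region.name!r} extends outside the grid along axis {d}"
                )
        d2 = (
            (xs[:, None, None] - cx) ** 2
            + (ys[None, :, None] - cy) ** 2
            + (zs[None, None, :] - cz) ** 2
        )
        mask = d2 <= region.radius_mm**2
        if not mask.any():
            raise ValueError(f"region {region.name!r} contains no voxel")
        if mask[xs <= 0].any():
            raise ValueError(
                f"region {region.name!r} touches or crosses the mid-sagittal plane"
            )
        return mask

    def rho_field(self, group: str) -> np.ndarray:
        """Per-voxel target mirror correlation for one group (full grid).

        Background gray matter gets ``noise.background_rho``; planted region
        voxels (and their mirrors) get the group's regional rho.
        """
        rho = np.full(self.grid_shape, self.noise.background_rho)
        for reg in self.regions:
            m = self._region_half_mask(reg)
            rho[m] = reg.rho_by_group.get(group, self.noise.background_rho)
        # mirror to the other hemisphere
        half = self.grid_shape[0] // 2
        rho[:half] = rho[half:][::-1]
        return rho

    def gray_matter_probability(self) -> np.ndarray:
        """Smooth ellipsoidal gray-matter probability, exactly flip-symmetric."""
        xs, ys, zs = self._voxel_centers_mm()
        semi = [0.85 * (ax[-1] - ax[0]) / 2 for ax in (xs, ys, zs)]
        r2 = (
            (xs[:, None, None] / semi[0]) ** 2
            + (ys[None, :, None] / semi[1]) ** 2
            + (zs[None, None, :] / semi[2]) ** 2
        )
        prob = np.clip(1.25 - r2, 0.0, 1.0)
        return (prob + prob[::-1]) / 2.0


# ---- temporal noise -----------------------------------------------------


def _ar1(rng: np.random.Generator, phi: float, shape: tuple[int, ...]) -> np.ndarray:
    """Stationary unit-variance AR(1) along the last axis."""
    e = rng.standard_normal(shape)
    if phi == 0.0:
        return e
    e[..., 1:] *= np.sqrt(1.0 - phi * phi)  # innovations; e[...,0] ~ N(0,1)
    return lfilter([1.0], [1.0, -phi], e, axis=-1)


def _smooth_within_hemispheres(
    field4d: np.ndarray, fwhm_mm: float, voxel_mm: float
) -> np.ndarray:
    """Smooth spatially inside each hemisphere, preserving unit variance.

    Smoothing never crosses the mid-sagittal plane, so it cannot introduce
    mirror-pair correlation; the variance lost to averaging is restored by a
    global rescale computed from the kernel's sum of squares.
    """
    if fwhm_mm <= 0:
        return field4d
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_mm
    half = field4d.shape[0] // 2
    out = np.empty_like(field4d)
    sig = (sigma_vox, sigma_vox, sigma_vox, 0.0)
    out[:half] = gaussian_filter(field4d[:half], sigma=sig, mode="reflect")
    out[half:] = gaussian_filter(field4d[half:], sigma=sig, mode="reflect")
    # kernel energy on an interior impulse gives the variance shrink factor
    probe = np.zeros((2 * half, 9, 9))
    probe[half // 2, 4, 4] = 1.0
    k = gaussian_filter(probe[: half], sigma=(sigma_vox,) * 3, mode="constant")
    energy = float((k**2).sum())
    if energy > 0:
        out /= np.sqrt(energy)
    return out


def simulate_subject(
    spec: CohortSpec, group: str, subject_seed: int
) -> tuple["BoldSeries", "MotionTrace"]:
    """One subject's 4-D BOLD and motion trace, bit-reproducible under seed.

    The returned motion trace is a non-outlier; outlier planting is decided
    by the cohort layout in :func:`simulate_cohort` (or call
    :func:`simulate_motion` with ``outlier=True`` directly).
    """
    from .preproc import BoldSeries  # local import to avoid a cycle

    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(subject_seed)
    nx, ny, nz = spec.grid_shape
    half = nx // 2
    T = spec.n_volumes
    phi = spec.noise.ar1_coefficient

    rho = spec.rho_field(group)[half:]  # (half, ny, nz), mirrored halves equal
    shared = _ar1(rng, phi, (half, ny, nz, T))
    noise = _ar1(rng, phi, (nx, ny, nz, T))
    noise = _smooth_within_hemispheres(noise, spec.noise.spatial_fwhm_mm, spec.voxel_mm)

    a = np.sqrt(rho)[..., None]
    b = np.sqrt(1.0 - rho)[..., None]
    data = np.empty((nx, ny, nz, T), dtype=np.float32)
    data[half:] = a * shared + b * noise[half:]
    data[:half] = (a * shared + b * noise[:half][::-1])[::-1]

    bold = BoldSeries(
        data=data,
        tr_seconds=spec.tr_seconds,
        voxel_mm=(spec.voxel_mm,) * 3,
        affine=spec.affine,
    )
    motion = simulate_motion(spec, outlier=False, seed=subject_seed + 1)
    return bold, motion


def simulate_motion(spec: CohortSpec, outlier: bool, seed: int) -> "MotionTrace":
    """Random-walk motion trace: 3 translations (mm), 3 rotations (degrees).

    A non-outlier trace keeps every per-axis excursion from the first
    retained frame strictly below 2.0 mm and 2.0 degrees; an outlier trace
    exceeds one of the thresholds on a randomly chosen axis.
    """
    from .preproc import MotionTrace

    rng = np.random.default_rng(seed)
    T = spec.n_volumes
    walk = np.cumsum(rng.normal(0.0, 0.02, size=(T, 6)), axis=0)
    ref = walk[spec.n_discard]
    exc = np.abs(walk - ref).max(axis=0)
    # rescale each axis so the worst excursion sits at ~1.2 units (< 2 strictly)
    target = 1.2
    scale = np.where(exc > 0, target / np.maximum(exc, target), 1.0)
    walk = ref + (walk - ref) * scale
    if outlier:
        axis = int(rng.integers(0, 6))
        t_peak = int(rng.integers(spec.n_discard + 5, T))
        bump = 2.5 - (walk[t_peak, axis] - ref[axis])
        walk[t_peak:, axis] += bump
    return MotionTrace(translations=walk[:, :3], rotations=walk[:, 3:])


# ---- cohort assembly ----------------------------------------------------


@dataclass
class CohortManifest:
    """Everything needed to reload and check a simulated cohort."""

    root: Path
    spec: CohortSpec
    subjects: pd.DataFrame  # subject_id, group, file names, outlier flag, scores
    gray_matter_file: str
    ventricle_mask_file: str
    white_matter_mask_file: str
    true_regional_z: pd.DataFrame  # subject_id x region: realized regional zVMHC

    def path(self, name: str) -> Path:
        return self.root / name


def subject_seed(master_seed: int, group: str, index: int) -> int:
    """Deterministic per-subject seed below 2**31."""
    gi = GROUPS.index(group)
    ss = np.random.SeedSequence([int(master_seed), gi, int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _regional_mean_mirror_r(
    spec: CohortSpec, data: np.ndarray, region: RegionEffect
) -> float:
    """Sample mean mirror correlation over a region's retained frames."""
    half = spec.grid_shape[0] // 2
    m = spec._region_half_mask(region)[half:]
    x = data[half:][m][:, spec.n_discard:]
    y = data[:half][::-1][m][:, spec.n_discard:]
    x = x - x.mean(axis=1, keepdims=True)
    y = y - y.mean(axis=1, keepdims=True)
    num = (x * y).sum(axis=1)
    den = np.sqrt((x**2).sum(axis=1) * (y**2).sum(axis=1))
    return float(np.mean(num / den))


def simulate_cohort(
    spec: CohortSpec, out_dir: str | Path, overwrite: bool = False
) -> CohortManifest:
    """Write a full cohort to disk and return its manifest.

    Outputs per subject: ``<id>_bold.nii.gz`` and ``<id>_motion.txt``
    (whitespace-delimited, T rows x 6 columns: x/y/z translation in mm,
    then three rotations in degrees).  Cohort-level: a flip-symmetric
    gray-matter probability volume, ventricle and white-matter nuisance
    masks, ``subjects.tsv`` and a ``manifest.yaml`` ground-truth record.
    Motion outliers are planted in the AVH group (first subjects).
    """
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    manifest_path = root / "manifest.yaml"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} already exists; pass overwrite=True to replace"
        )
    if spec.n_motion_outliers > spec.n_per_group[0]:
        raise ValueError("more planted outliers than AVH subjects")

    aff = spec.affine
    gm = spec.gray_matter_probability()
    nib.save(nib.Nifti1Image(gm.astype(np.float32), aff), root / "gray_matter.nii.gz")

    # small symmetric nuisance-source masks near the grid center, clear of
    # the planted regions (used for ventricle / white-matter mean signals)
    nx, ny, nz = spec.grid_shape
    vent = np.zeros(spec.grid_shape, dtype=np.uint8)
    vent[nx // 2 - 2 : nx // 2 + 2, ny // 2 - 1 : ny // 2 + 1, nz // 2 - 1 : nz // 2 + 1] = 1
    wm = np.zeros(spec.grid_shape, dtype=np.uint8)
    wm[nx // 2 - 3 : nx // 2 + 3, ny // 2 + 3 : ny // 2 + 5, nz // 2 - 1 : nz // 2 + 1] = 1
    nib.save(nib.Nifti1Image(vent, aff), root / "ventricle_mask.nii.gz")
    nib.save(nib.Nifti1Image(wm, aff), root / "white_matter_mask.nii.gz")

    rows = []
    zreg: dict[str, dict[str, float]] = {}
    for group, n in zip(GROUPS, spec.n_per_group):
        for idx in range(n):
            sid = f"sub-{group}{idx + 1:02d}"
            seed = subject_seed(spec.master_seed, group, idx)
            bold, _ = simulate_subject(spec, group, seed)
            is_outlier = group == "AVH" and idx < spec.n_motion_outliers
            motion = simulate_motion(spec, outlier=is_outlier, seed=seed + 1)
            bold_file = f"{sid}_bold.nii.gz"
            motion_file = f"{sid}_motion.txt"
            nib.save(nib.Nifti1Image(bold.data, aff), root / bold_file)
            motion.to_file(root / motion_file)
            zreg[sid] = {
                reg.name: float(np.arctanh(np.clip(
                    _regional_mean_mirror_r(spec, bold.data, reg),
                    -1 + 1e-7, 1 - 1e-7)))
                for reg in spec.regions
            }
            rows.append(
                dict(subject_id=sid, group=group, outlier=is_outlier,
                     bold_file=bold_file, motion_file=motion_file)
            )
    subjects = pd.DataFrame(rows)
    true_z = pd.DataFrame.from_dict(zreg, orient="index").rename_axis("subject_id")

    # clinical scores coupled to realized regional zVMHC
    score_rng = np.random.default_rng(
        np.random.SeedSequence([spec.master_seed, 999]).generate_state(1)[0] % 2**31
    )
    for name in SCORE_NAMES:
        subjects[name] = np.nan
    for coup in spec.score_model:
        sel = subjects["group"].isin(coup.groups)
        if not sel.any():
            continue
        z = true_z.loc[subjects.loc[sel, "subject_id"], coup.region_name].to_numpy()
        zs = (z - z.mean()) / z.std(ddof=0) if z.std(ddof=0) > 0 else np.zeros_like(z)
        noise = score_rng.standard_normal(len(z))
        noise = (noise - noise.mean()) / noise.std(ddof=0)
        # orthogonalize noise to zs so the sample correlation tracks target_r
        noise = noise - zs * (noise @ zs) / (zs @ zs) if (zs @ zs) > 0 else noise
        if noise.std(ddof=0) > 0:
            noise = noise / noise.std(ddof=0)
        latent = coup.target_r * zs + np.sqrt(1 - coup.target_r**2) * noise
        subjects.loc[sel, coup.score_name] = coup.score_mean + coup.score_sd * latent
    # scores only exist for the groups they apply to
    patient = subjects["group"].isin(PATIENT_GROUPS)
    for name in SCORE_NAMES[:-1]:
        subjects.loc[~patient, name] = np.nan
    subjects.loc[subjects["group"] != "AVH", "ahrs"] = np.nan

    subjects.to_csv(root / "subjects.tsv", sep="\t", index=False, na_rep="")
    true_z.to_csv(root / "true_regional_z.tsv", sep="\t")

    manifest = dict(
        format_version=1,
        master_seed=spec.master_seed,
        spec=_spec_to_dict(spec),
        gray_matter_file="gray_matter.nii.gz",
        ventricle_mask_file="ventricle_mask.nii.gz",
        white_matter_mask_file="white_matter_mask.nii.gz",
        subject_table="subjects.tsv",
        true_regional_z="true_regional_z.tsv",
        subjects=[
            dict(subject_id=r.subject_id, group=r.group, outlier=bool(r.outlier),
                 bold_file=r.bold_file, motion_file=r.motion_file)
            for r in subjects.itertuples()
        ],
    )
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return CohortManifest(
        root=root, spec=spec, subjects=subjects,
        gray_matter_file="gray_matter.nii.gz",
        ventricle_mask_file="ventricle_mask.nii.gz",
        white_matter_mask_file="white_matter_mask.nii.gz",
        true_regional_z=true_z,
    )


def _spec_to_dict(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["regions"] = [dataclasses.asdict(r) for r in spec.regions]
    for r in d["regions"]:
        r["center_mni"] = list(r["center_mni"])
        r["rho_by_group"] = dict(r["rho_by_group"])
    d["score_model"] = [dataclasses.asdict(c) for c in spec.score_model]
    for c in d["score_model"]:
        c["groups"] = list(c["groups"])
    d["n_per_group"] = list(d["n_per_group"])
    d["grid_shape"] = list(d["grid_shape"])
    return d


def spec_from_dict(d: Mapping) -> CohortSpec:
    """Inverse of the manifest serialization (round-trip identity)."""
    regions = tuple(
        RegionEffect(r["name"], tuple(r["center_mni"]), r["radius_mm"],
                     dict(r["rho_by_group"]))
        for r in d["regions"]
    )
    score_model = tuple(
        ScoreCoupling(c["score_name"], c["region_name"], c["target_r"],
                      c["score_mean"], c["score_sd"], tuple(c["groups"]))
        for c in d["score_model"]
    )
    return CohortSpec(
        n_per_group=tuple(d["n_per_group"]),
        n_volumes=d["n_volumes"],
        n_discard=d["n_discard"],
        tr_seconds=d["tr_seconds"],
        grid_shape=tuple(d["grid_shape"]),
        voxel_mm=d["voxel_mm"],
        regions=regions,
        noise=NoiseSpec(**d["noise"]),
        score_model=score_model,
        n_motion_outliers=d["n_motion_outliers"],
        master_seed=d["master_seed"],
    )


def load_manifest(cohort_dir: str | Path) -> CohortManifest:
    """Reload a cohort manifest written by :func:`simulate_cohort`."""
    root = Path(cohort_dir)
    d = yaml.safe_load((root / "manifest.yaml").read_text())
    spec = spec_from_dict(d["spec"])
    subjects = pd.read_csv(root / d["subject_table"], sep="\t")
    true_z = pd.read_csv(root / d["true_regional_z"], sep="\t", index_col="subject_id")
    return CohortManifest(
        root=root, spec=spec, subjects=subjects,
        gray_matter_file=d["gray_matter_file"],
        ventricle_mask_file=d["ventricle_mask_file"],
        white_matter_mask_file=d["white_matter_mask_file"],
        true_regional_z=true_z,
    )
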