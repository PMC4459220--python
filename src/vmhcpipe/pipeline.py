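"""Stage orchestration: simulate → preprocess → VMHC → group → correlate.

Each stage consumes and produces documented on-disk formats (NIfTI
volumes, TSV tables, YAML manifests) so any stage can be re-run or
inspected in isolation; ``run_all`` chains them and returns an in-memory
summary used by the report writer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .clinstats import correlation_table, wide_table
from .config import RunConfig
from .core import GrayMatterMask, compute_vmhc
from .groupstats import (
    ClusterResult,
    ancova_f_map,
    estimate_smoothness,
    extract_sphere_mean,
    grf_cluster_correct,
    one_sample_group_map,
    posthoc_bonferroni,
    stat_to_z,
    two_sample_t_map,
)
from .preproc import BoldSeries, MotionTrace, exclusion_flags, preprocess_bold
from .synthdata import GROUPS, load_manifest

PAIRWISE = (("Control", "AVH"), ("Control", "NonAVH"), ("AVH", "NonAVH"))


@dataclass
class GroupResults:
    fd_table: pd.DataFrame
    fd_anova: tuple[float, float]  # F, p across retained groups
    anova_clusters: ClusterResult
    cluster_regions: list[str]
    sphere_means: pd.DataFrame  # subject x region
    posthoc: pd.DataFrame
    classification: pd.DataFrame
    first_level: dict[str, pd.DataFrame]
    pairwise_clusters: dict[str, pd.DataFrame]
    correlations: dict[str, pd.DataFrame]


def _missing(path: Path, stage: str) -> None:
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found — run the '{stage}' stage first"
        )


def stage_preprocess(
    cohort_dir: str | Path, out_dir: str | Path, config: RunConfig
) -> pd.DataFrame:
    """Motion bookkeeping plus temporal cleaning for every subject.

    Writes ``fd_motion.tsv`` (mean FD, per-axis maxima, exclusion flag) and
    ``preproc/<id>_preproc.nii.gz`` for each retained subject.  Returns the
    FD table.
    """
    man = load_manifest(cohort_dir)
    out = Path(out_dir)
    (out / "preproc").mkdir(parents=True, exist_ok=True)
    spec = man.spec

    traces = {}
    for row in man.subjects.itertuples():
        trace = MotionTrace.from_file(man.path(row.motion_file))
        traces[row.subject_id] = trace.discard_initial(config.n_discard)
    flags = exclusion_flags(
        traces, config.translation_limit_mm, config.rotation_limit_deg
    )

    vent = np.asarray(nib.load(str(man.path(man.ventricle_mask_file))).dataobj) > 0
    wm = np.asarray(nib.load(str(man.path(man.white_matter_mask_file))).dataobj) > 0

    fd_rows = []
    for row in man.subjects.itertuples():
        sid = row.subject_id
        excluded = bool(flags.loc[sid, "excluded"])
        mean_fd = np.nan
        if not excluded:
            bold = BoldSeries.from_nifti(man.path(row.bold_file), spec.tr_seconds)
            motion = MotionTrace.from_file(man.path(row.motion_file))
            retained = bold.data[..., config.n_discard:]
            nuis = np.column_stack([
                retained[vent].mean(axis=0), retained[wm].mean(axis=0)
            ])
            clean, fd = preprocess_bold(
                bold, motion, nuisance_signals=nuis,
                n_discard=config.n_discard, fwhm_mm=config.fwhm_mm,
                low_hz=config.band_low_hz, high_hz=config.band_high_hz,
            )
            clean.to_nifti(out / "preproc" / f"{sid}_preproc.nii.gz")
            mean_fd = fd.mean_fd
        fd_rows.append(dict(
            subject_id=sid, group=row.group, mean_fd=mean_fd,
            max_translation_mm=flags.loc[sid, "max_translation_mm"],
            max_rotation_deg=flags.loc[sid, "max_rotation_deg"],
            excluded=excluded,
        ))
    fd_table = pd.DataFrame(fd_rows)
    fd_table.to_csv(out / "fd_motion.tsv", sep="\t", index=False)
    return fd_table


def stage_vmhc(
    cohort_dir: str | Path, out_dir: str | Path, config: RunConfig
) -> list[str]:
    """Per-subject VMHC and zVMHC maps for retained subjects."""
    man = load_manifest(cohort_dir)
    out = Path(out_dir)
    _missing(out / "fd_motion.tsv", "preprocess")
    fd_table = pd.read_csv(out / "fd_motion.tsv", sep="\t")
    (out / "vmhc").mkdir(parents=True, exist_ok=True)
    gm = GrayMatterMask.from_nifti(
        man.path(man.gray_matter_file), threshold=config.gm_threshold
    )
    done = []
    for row in fd_table[~fd_table["excluded"]].itertuples():
        sid = row.subject_id
        path = out / "preproc" / f"{sid}_preproc.nii.gz"
        _missing(path, "preprocess")
        bold = BoldSeries.from_nifti(path, man.spec.tr_seconds)
        vmhc = compute_vmhc(bold, gm)
        vmhc.save(out / "vmhc" / sid)
        done.append(sid)
    return done


def nearest_region_label(peak_mm, regions) -> str:
    """Name a peak after the closest planted region (mirror-aware).

    Region naming is a lookup, not an inference: for synthetic cohorts the
    planted regions are the lookup table; for other data supply your own.
    """
    p = np.asarray(peak_mm, float)
    best, best_d = "unlabeled", np.inf
    for reg in regions:
        c = np.asarray(reg.center_mni, float)
        for cx in (c[0], -c[0]):
            d = float(np.linalg.norm(p - np.array([cx, c[1], c[2]])))
            if d < best_d:
                best, best_d = reg.name, d
    return best


def classify_regions(posthoc: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Three-way dysconnectivity classification from post hoc p-values.

    A region is 'AVH_only' when Control-vs-AVH is significant but
    Control-vs-NonAVH is not, 'NonAVH_only' for the reverse, 'shared' when
    both patient groups differ from Control, 'none' otherwise.
    """
    rows = []
    for region, sub in posthoc.groupby("region", sort=False):
        def sig(a: str, b: str) -> bool:
            m = sub[((sub.group_a == a) & (sub.group_b == b))
                    | ((sub.group_a == b) & (sub.group_b == a))]
            return bool((m["p_bonferroni"] < alpha).any())

        avh = sig("Control", "AVH")
        non = sig("Control", "NonAVH")
        cat = ("shared" if avh and non else
               "AVH_only" if avh else
               "NonAVH_only" if non else "none")
        rows.append(dict(region=region, control_vs_avh_sig=avh,
                         control_vs_nonavh_sig=non, category=cat))
    return pd.DataFrame(rows)


def stage_group(
    cohort_dir: str | Path, out_dir: str | Path, config: RunConfig
) -> GroupResults:
    """Group statistics: first-level maps, FD-covaried ANOVA with GRF
    cluster correction, pairwise t maps, sphere extraction and post hocs."""
    man = load_manifest(cohort_dir)
    spec = man.spec
    out = Path(out_dir)
    _missing(out / "fd_motion.tsv", "preprocess")
    fd_table = pd.read_csv(out / "fd_motion.tsv", sep="\t")
    retained = fd_table[~fd_table["excluded"]].reset_index(drop=True)
    gdir = out / "group"
    gdir.mkdir(parents=True, exist_ok=True)

    gm = GrayMatterMask.from_nifti(
        man.path(man.gray_matter_file), threshold=config.gm_threshold
    )
    mask = gm.binary
    affine = spec.affine

    zmaps, groups, fds, sids = [], [], [], []
    for row in retained.itertuples():
        path = out / "vmhc" / f"{row.subject_id}_zvmhc.nii.gz"
        _missing(path, "vmhc")
        zmaps.append(np.asarray(nib.load(str(path)).dataobj, dtype=np.float64))
        groups.append(row.group)
        fds.append(row.mean_fd)
        sids.append(row.subject_id)
    zarr = np.asarray(zmaps)
    groups = np.asarray(groups)
    fds = np.asarray(fds, float)

    # FD comparability across retained groups (one-way ANOVA on mean FD)
    fd_anova = stats.f_oneway(*[fds[groups == g] for g in GROUPS])
    fd_anova = (float(fd_anova.statistic), float(fd_anova.pvalue))

    # first-level one-sample maps per group
    first_level: dict[str, pd.DataFrame] = {}
    for g in GROUPS:
        _, clusters = one_sample_group_map(
            zarr[groups == g], mask, affine,
            fdr_q=config.first_level_q, min_extent=config.first_level_extent,
        )
        tab = clusters.table()
        tab.to_csv(gdir / f"first_level_{g}_clusters.tsv", sep="\t", index=False)
        first_level[g] = tab

    # ANOVA with FD covariate, F -> Z, GRF cluster correction
    fmap, resid = ancova_f_map(zarr, groups, fds, mask)
    zstat = stat_to_z(fmap)
    smoothness = estimate_smoothness(resid, mask, (spec.voxel_mm,) * 3)
    anova_clusters = grf_cluster_correct(
        zstat, mask, affine, smoothness,
        cluster_forming_z=config.cluster_forming_z, alpha=config.cluster_alpha,
    )
    nib.save(nib.Nifti1Image(fmap.values.astype(np.float32), affine),
             gdir / "anova_f.nii.gz")
    nib.save(nib.Nifti1Image(zstat.values.astype(np.float32), affine),
             gdir / "anova_z.nii.gz")
    cluster_regions = [
        nearest_region_label(c.peak_mni_mm, spec.regions)
        for c in anova_clusters.clusters
    ]
    tab = anova_clusters.table()
    tab.insert(0, "region_label", cluster_regions)
    tab.to_csv(gdir / "anova_clusters.tsv", sep="\t", index=False)

    # pairwise two-sample t maps (FD covariate kept), both directions share
    # one map; GRF applied to each tail
    pairwise_clusters: dict[str, pd.DataFrame] = {}
    for a, b in PAIRWISE:
        ia = groups == a
        ib = groups == b
        cov = np.concatenate([fds[ia], fds[ib]])
        tmap, tresid = two_sample_t_map(zarr[ia], zarr[ib], cov, mask)
        tz = stat_to_z(tmap)
        sm = estimate_smoothness(tresid, mask, (spec.voxel_mm,) * 3)
        tabs = []
        for direction, zvals in (("gt", tz.values), ("lt", -tz.values)):
            cres = grf_cluster_correct(
                dataclasses.replace(tz, values=zvals), mask, affine, sm,
                cluster_forming_z=config.cluster_forming_z,
                alpha=config.cluster_alpha,
            )
            t = cres.table()
            t.insert(0, "direction", f"{a}_{direction}_{b}")
            tabs.append(t)
        key = f"{a}_vs_{b}"
        nonempty = [t for t in tabs if not t.empty]
        pairwise_clusters[key] = (pd.concat(nonempty, ignore_index=True)
                                  if nonempty else tabs[0])
        pairwise_clusters[key].to_csv(
            gdir / f"two_sample_{key}_clusters.tsv", sep="\t", index=False
        )
        nib.save(nib.Nifti1Image(tz.values.astype(np.float32), affine),
                 gdir / f"two_sample_{key}_z.nii.gz")

    # 5-mm sphere means at ANOVA cluster peaks
    roi_centers: dict[str, tuple[float, float, float]] = {}
    for c, name in zip(anova_clusters.clusters, cluster_regions):
        roi_centers.setdefault(name, c.peak_mni_mm)
    sphere = pd.DataFrame(
        {name: [extract_sphere_mean(z, ctr, affine, config.sphere_radius_mm)
                for z in zarr]
         for name, ctr in roi_centers.items()},
        index=pd.Index(sids, name="subject_id"),
    )
    sphere.to_csv(gdir / "sphere_means.tsv", sep="\t")

    # Bonferroni post hocs on sphere means and three-way classification
    ph_rows = []
    for name in sphere.columns:
        ph = posthoc_bonferroni(sphere[name].to_numpy(), groups)
        ph.insert(0, "region", name)
        ph_rows.append(ph)
    posthoc = (pd.concat(ph_rows, ignore_index=True) if ph_rows
               else pd.DataFrame(columns=["region", "group_a", "group_b",
                                          "mean_a", "mean_b", "t",
                                          "p_uncorrected", "p_bonferroni"]))
    posthoc.to_csv(gdir / "posthoc.tsv", sep="\t", index=False)
    classification = classify_regions(posthoc, alpha=config.posthoc_alpha)
    classification.to_csv(gdir / "classification.tsv", sep="\t", index=False)

    return GroupResults(
        fd_table=fd_table, fd_anova=fd_anova, anova_clusters=anova_clusters,
        cluster_regions=cluster_regions, sphere_means=sphere, posthoc=posthoc,
        classification=classification, first_level=first_level,
        pairwise_clusters=pairwise_clusters, correlations={},
    )


def stage_correlate(
    cohort_dir: str | Path, out_dir: str | Path, config: RunConfig
) -> dict[str, pd.DataFrame]:
    """Score–connectivity correlation tables for the patient cohorts."""
    man = load_manifest(cohort_dir)
    out = Path(out_dir)
    gdir = out / "group"
    _missing(gdir / "sphere_means.tsv", "group")
    sphere = pd.read_csv(gdir / "sphere_means.tsv", sep="\t",
                         index_col="subject_id")
    fd_table = pd.read_csv(out / "fd_motion.tsv", sep="\t")
    records = man.subjects.merge(
        fd_table[["subject_id", "excluded"]], on="subject_id"
    )
    records["included"] = ~records["excluded"]
    cdir = out / "correlate"
    cdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    panss = ("panss_pos", "panss_neg", "panss_gen", "panss_total")
    if not sphere.columns.empty:
        tables["all_patients"] = correlation_table(
            sphere, records, cohort="all_patients", scores=panss
        )
        tables["avh_only"] = correlation_table(
            sphere, records, cohort="avh_only", scores=("ahrs",)
        )
        for name, tab in tables.items():
            tab.to_csv(cdir / f"correlations_{name}.tsv", sep="\t", index=False)
            wide_table(tab).to_csv(cdir / f"correlations_{name}_wide.tsv",
                                   sep="\t", index=False)
    return tables


def write_run_log(
    cohort_dir: str | Path, out_dir: str | Path, config: RunConfig,
    stages: list[str],
) -> None:
    man = load_manifest(cohort_dir)
    fd_path = Path(out_dir) / "fd_motion.tsv"
    excluded = []
    if fd_path.exists():
        fd = pd.read_csv(fd_path, sep="\t")
        excluded = [
            dict(subject_id=r.subject_id,
                 reason=f"motion excursion {r.max_translation_mm:.2f} mm / "
                        f"{r.max_rotation_deg:.2f} deg")
            for r in fd[fd["excluded"]].itertuples()
        ]
    log = dict(
        software=f"vmhcpipe {__version__}",
        config=config.to_dict(),
        cohort=str(Path(cohort_dir).resolve()),
        master_seed=man.spec.master_seed,
        stages_completed=stages,
        excluded_subjects=excluded,
    )
    (Path(out_dir) / "run_log.yaml").write_text(
        yaml.safe_dump(log, sort_keys=False)
    )


def run_all(
    cohort_dir: str | Path, out_dir: str | Path, config: RunConfig | None = None,
    make_report: bool = True,
) -> GroupResults:
    """Run every stage on an existing cohort directory."""
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_preprocess(cohort_dir, out, config)
    stage_vmhc(cohort_dir, out, config)
    results = stage_group(cohort_dir, out, config)
    results.correlations = stage_correlate(cohort_dir, out, config)
    stages = ["preprocess", "vmhc", "group", "correlate"]
    if make_report:
        from .report import write_report

        write_report(results, out / "report", load_manifest(cohort_dir), config)
        stages.append("report")
    write_run_log(cohort_dir, out, config, stages)
    return results
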