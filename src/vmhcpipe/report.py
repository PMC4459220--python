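"""Human-readable run report: exclusion summary, FD comparability,
cluster table, three-way dysconnectivity classification, correlation
matrices, and orthogonal-slice PNGs of the ANOVA F map."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import nibabel as nib
import numpy as np
import pandas as pd

from .clinstats import wide_table
from .config import RunConfig
from .pipeline import GroupResults
from .synthdata import CohortManifest


def _slice_png(volume: np.ndarray, out_path: Path, title: str) -> None:
    """Orthogonal mid-slices of a 3-D statistic volume."""
    fig, axes = plt.subplots(1, 3, figsize=(9, 3.2))
    centers = [s // 2 for s in volume.shape]
    views = [
        (volume[centers[0], :, :].T, "sagittal"),
        (volume[:, centers[1], :].T, "coronal"),
        (volume[:, :, centers[2]].T, "axial"),
    ]
    vmax = float(np.percentile(np.abs(volume), 99.5)) or 1.0
    for ax, (img, name) in zip(axes, views):
        ax.imshow(img, origin="lower", cmap="hot", vmin=0, vmax=vmax)
        ax.set_title(name, fontsize=9)
        ax.axis("off")
    fig.suptitle(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)


def _fmt_table(df: pd.DataFrame, floatfmt: str = "{:.3g}") -> str:
    if df.empty:
        return "  (empty)\n"
    show = df.copy()
    for c in show.columns:
        if show[c].dtype.kind == "f":
            show[c] = show[c].map(lambda v: floatfmt.format(v)
                                  if pd.notna(v) else "")
    return show.to_string(index=False) + "\n"


def write_report(
    results: GroupResults,
    report_dir: str | Path,
    manifest: CohortManifest,
    config: RunConfig,
) -> Path:
    """Write ``report.txt`` plus slice PNGs; returns the report path."""
    rdir = Path(report_dir)
    rdir.mkdir(parents=True, exist_ok=True)
    fd = results.fd_table
    lines: list[str] = []
    w = lines.append

    w("Inter-hemispheric homotopic connectivity — run report")
    w("=" * 60)
    w("")
    w("Subject exclusion")
    w("-" * 60)
    n_total = len(fd)
    n_excl = int(fd["excluded"].sum())
    w(f"subjects simulated: {n_total}; excluded for motion: {n_excl}; "
      f"retained: {n_total - n_excl}")
    for r in fd[fd["excluded"]].itertuples():
        w(f"  excluded {r.subject_id}: max translation "
          f"{r.max_translation_mm:.2f} mm, max rotation "
          f"{r.max_rotation_deg:.2f} deg")
    w("")
    w("Head-motion comparability (one-way ANOVA on mean FD, retained subjects)")
    w("-" * 60)
    w(f"F = {results.fd_anova[0]:.2f}, p = {results.fd_anova[1]:.2f}")
    w("")
    w("Group-difference clusters (FD-covaried ANOVA, "
      f"Z > {config.cluster_forming_z}, cluster p < {config.cluster_alpha}, "
      "GRF corrected)")
    w("-" * 60)
    tab = results.anova_clusters.table()
    if tab.empty:
        w("no significant clusters")
    else:
        tab.insert(0, "region_label", results.cluster_regions)
        w(_fmt_table(tab))
    w("")
    w("Post hoc classification (Bonferroni-corrected sphere-mean contrasts)")
    w("-" * 60)
    if results.classification.empty:
        w("no regions to classify")
    else:
        w(_fmt_table(results.classification))
        w(_fmt_table(results.posthoc))
    w("")
    w("Score-connectivity correlations")
    w("-" * 60)
    if not results.correlations:
        w("no correlation tables (no significant regions)")
    for name, table in results.correlations.items():
        w(f"cohort: {name} (r and two-tailed p per region x score)")
        w(_fmt_table(wide_table(table)))
    report_path = rdir / "report.txt"
    report_path.write_text("\n".join(lines) + "\n")

    f_img = Path(rdir).parent / "group" / "anova_f.nii.gz"
    if f_img.exists():
        vol = np.asarray(nib.load(str(f_img)).dataobj, float)
        _slice_png(vol, rdir / "anova_f.png", "ANOVA F map (group effect)")
    return report_path
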