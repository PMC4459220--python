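"""Voxelwise group inference on zVMHC maps.

First-level one-sample maps with Benjamini–Hochberg FDR plus a
cluster-extent filter; covariate-adjusted one-way ANOVA (ANCOVA) F maps
across the three groups with mean framewise displacement as covariate;
two-sample t maps; probability-preserving conversion of F/t fields to Z;
Gaussian-random-field (GRF) cluster-level correction with smoothness
(resel) estimation from residuals; a permutation max-cluster oracle used
to validate the GRF approximation; peak localization, 5-mm-sphere mean
extraction at cluster peaks, and Bonferroni-corrected pairwise post hocs
on the sphere means.

The GRF correction follows the standard Gaussian-field cluster-extent
approximation: with resel count R and cluster-forming threshold z0, the
expected number of clusters is E[m] = R * rho3(z0) with the 3-D Euler
characteristic density

    rho3(z) = (4 ln 2)^{3/2} (2 pi)^{-2} (z^2 - 1) exp(-z^2 / 2),

the extent tail is P(S >= k) = exp(-beta k^{2/3}) with beta chosen so the
mean extent matches E[N]/E[m], and the familywise cluster p-value is
1 - exp(-E[m] * P(S >= k)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gamma as gamma_fn

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

#: 26-connectivity structuring element for cluster labeling
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class StatMap:
    """A voxelwise statistic field with its degrees of freedom."""

    values: np.ndarray
    kind: str  # "F", "t" or "Z"
    df: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("F", "t", "Z"):
            raise ValueError(f"unknown statistic kind {self.kind!r}")


@dataclass
class Cluster:
    label: int
    size_voxels: int
    peak_index: tuple[int, int, int]
    peak_mni_mm: tuple[float, float, float]
    peak_value: float
    p_corrected: float | None = None


@dataclass
class ClusterResult:
    label_field: np.ndarray
    clusters: list[Cluster] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        rows = [
            dict(
                cluster_size_voxels=c.size_voxels,
                peak_value=c.peak_value,
                peak_mni_x=c.peak_mni_mm[0],
                peak_mni_y=c.peak_mni_mm[1],
                peak_mni_z=c.peak_mni_mm[2],
                corrected_p=c.p_corrected,
            )
            for c in self.clusters
        ]
        return pd.DataFrame(
            rows,
            columns=["cluster_size_voxels", "peak_value", "peak_mni_x",
                     "peak_mni_y", "peak_mni_z", "corrected_p"],
        )


def _stack(zmaps) -> np.ndarray:
    arr = np.asarray([np.asarray(z, float) for z in zmaps])
    if arr.ndim != 4:
        raise ValueError("expected a sequence of 3-D maps")
    return arr


def find_peak(
    cluster_mask: np.ndarray, statmap: np.ndarray, affine: np.ndarray
) -> tuple[tuple[int, int, int], tuple[float, float, float], float]:
    """Voxel of maximum statistic in a cluster; ties -> smallest linear index."""
    idx = np.flatnonzero(cluster_mask.ravel())
    if idx.size == 0:
        raise ValueError("empty cluster")
    vals = statmap.ravel()[idx]
    best = idx[int(np.argmax(vals))]  # argmax returns the first maximum
    vox = np.unravel_index(best, cluster_mask.shape)
    mm = affine @ np.array([vox[0], vox[1], vox[2], 1.0])
    return (tuple(int(v) for v in vox), tuple(float(m) for m in mm[:3]),
            float(statmap[vox]))


def label_clusters(
    suprathreshold: np.ndarray, statmap: np.ndarray, affine: np.ndarray
) -> ClusterResult:
    """Label 26-connected supra-threshold components with peak info."""
    labels, n = ndimage.label(suprathreshold, structure=CONNECTIVITY_26)
    clusters = []
    for lab in range(1, n + 1):
        m = labels == lab
        vox, mm, val = find_peak(m, statmap, affine)
        clusters.append(Cluster(label=lab, size_voxels=int(m.sum()),
                                peak_index=vox, peak_mni_mm=mm, peak_value=val))
    return ClusterResult(label_field=labels, clusters=clusters)


# ---- first level ---------------------------------------------------------


def one_sample_group_map(
    zmaps, mask: np.ndarray, affine: np.ndarray,
    fdr_q: float = 0.01, min_extent: int = 20,
) -> tuple[StatMap, ClusterResult]:
    """One-sample t against zero with FDR + extent thresholding.

    Voxelwise two-tailed p-values within the mask are controlled with
    Benjamini–Hochberg FDR at ``fdr_q``; surviving voxels are additionally
    filtered by 26-connected extent >= ``min_extent`` voxels.
    """
    arr = _stack(zmaps)
    n = arr.shape[0]
    if n < 3:
        raise ValueError("one-sample map needs at least 3 subjects")
    mask = np.asarray(mask, bool)
    m = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    t = np.zeros_like(m)
    np.divide(m, sd / np.sqrt(n), out=t, where=sd > 0)
    df = n - 1
    pvals = 2.0 * stats.t.sf(np.abs(t[mask]), df)
    surviving = np.zeros_like(mask)
    if pvals.size:
        reject, *_ = multipletests(pvals, alpha=fdr_q, method="fdr_bh")
        surviving[mask] = reject
    labels, nlab = ndimage.label(surviving, structure=CONNECTIVITY_26)
    if nlab:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_extent)
        surviving &= ~np.isin(labels, small[small > 0])
    result = label_clusters(surviving, np.abs(t), affine)
    return StatMap(values=t, kind="t", df=(df,)), result


# ---- GLM machinery -------------------------------------------------------


def _design_groups(groups, covariate) -> tuple[np.ndarray, int]:
    """Full design [1 | group dummies (Control ref) | demeaned covariate].

    Returns the design and the number of group columns.
    """
    groups = np.asarray(groups)
    levels = [g for g in ("AVH", "NonAVH", "Control") if g in set(groups)]
    if not levels:
        levels = sorted(set(groups))
    ref = levels[-1]
    dummies = [(groups == g).astype(float) for g in levels if g != ref]
    cols = [np.ones(len(groups))] + dummies
    if covariate is not None:
        cov = np.asarray(covariate, float)
        if cov.std() > 0:
            cols.append(cov - cov.mean())
    return np.column_stack(cols), len(dummies)


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares per column of Y under design X."""
    Q, _ = np.linalg.qr(X)
    resid = Y - Q @ (Q.T @ Y)
    return (resid**2).sum(axis=0)


def ancova_f_map(
    zmaps, groups, covariate, mask: np.ndarray
) -> tuple[StatMap, np.ndarray]:
    """Group-effect F map from the model z ~ 1 + group dummies + covariate.

    F is the residual-sum-of-squares comparison between the full model and
    the reduced model (intercept + covariate), with df = (g-1, n - p_full).
    Returns the StatMap and the full-model residual array (n_subj, x, y, z)
    for smoothness estimation.
    """
    arr = _stack(zmaps)
    groups = np.asarray(groups)
    n = arr.shape[0]
    if len(groups) != n:
        raise ValueError("group labels must match the number of maps")
    for g in np.unique(groups):
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    Xf, n_dummies = _design_groups(groups, covariate)
    if n_dummies == 0:
        raise ValueError("need at least 2 groups")
    keep_reduced = [0] + list(range(1 + n_dummies, Xf.shape[1]))
    Xr = Xf[:, keep_reduced]
    mask = np.asarray(mask, bool)
    Y = arr.reshape(n, -1)[:, mask.ravel()]
    rss_f = _rss(Xf, Y)
    rss_r = _rss(Xr, Y)
    df1 = n_dummies
    df2 = n - Xf.shape[1]
    F = np.zeros(mask.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_vals = ((rss_r - rss_f) / df1) / (rss_f / df2)
    F[mask] = np.where(np.isfinite(f_vals), np.maximum(f_vals, 0.0), 0.0)
    Q, _ = np.linalg.qr(Xf)
    resid = (Y - Q @ (Q.T @ Y))
    resid_maps = np.zeros((n,) + mask.shape)
    resid_maps.reshape(n, -1)[:, mask.ravel()] = resid
    return StatMap(values=F, kind="F", df=(df1, df2)), resid_maps


def two_sample_t_map(
    zmaps_a, zmaps_b, covariate, mask: np.ndarray
) -> tuple[StatMap, np.ndarray]:
    """Covariate-adjusted two-sample t map (GLM contrast on a group dummy).

    Positive t means group a > group b.  ``covariate`` is the concatenated
    per-subject covariate (a first, then b) or None.  Returns the StatMap
    and the full-model residuals.
    """
    a = _stack(zmaps_a)
    b = _stack(zmaps_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("map grids differ between groups")
    n = a.shape[0] + b.shape[0]
    indicator = np.concatenate([np.ones(a.shape[0]), np.zeros(b.shape[0])])
    cols = [np.ones(n), indicator]
    if covariate is not None:
        cov = np.asarray(covariate, float)
        if len(cov) != n:
            raise ValueError("covariate length must equal total subjects")
        if cov.std() > 0:
            cols.append(cov - cov.mean())
    X = np.column_stack(cols)
    mask = np.asarray(mask, bool)
    Y = np.concatenate([a, b]).reshape(n, -1)[:, mask.ravel()]
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ Y)
    resid = Y - X @ beta
    df = n - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / df
    c = np.zeros(X.shape[1])
    c[1] = 1.0
    var_c = c @ np.linalg.inv(X.T @ X) @ c
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = beta[1] / np.sqrt(sigma2 * var_c)
    t = np.zeros(mask.shape)
    t[mask] = np.where(np.isfinite(t_vals), t_vals, 0.0)
    resid_maps = np.zeros((n,) + mask.shape)
    resid_maps.reshape(n, -1)[:, mask.ravel()] = resid
    return StatMap(values=t, kind="t", df=(df,)), resid_maps


def stat_to_z(statmap: StatMap) -> StatMap:
    """Convert an F or t field to standard-normal deviates.

    Each value maps to the normal deviate with the same tail probability:
    F one-sided (upper tail), t preserving sign.  Extreme tails are
    clipped to keep the output finite.
    """
    v = statmap.values
    if statmap.kind == "Z":
        return statmap
    if statmap.kind == "F":
        df1, df2 = statmap.df
        logp = stats.f.logsf(v, df1, df2)
        z = -stats.norm.ppf(np.exp(np.maximum(logp, -700.0)))
        z = np.where(np.isfinite(z), z, stats.norm.isf(1e-300))
    else:
        (df,) = statmap.df
        # map via the upper tail of |t|, restoring the sign afterwards
        logp = stats.t.logsf(np.abs(v), df)
        zmag = -stats.norm.ppf(np.exp(np.maximum(logp, -700.0)))
        zmag = np.where(np.isfinite(zmag), zmag, stats.norm.isf(1e-300))
        z = np.sign(v) * zmag
    return StatMap(values=z, kind="Z", df=())


# ---- smoothness and GRF --------------------------------------------------


def estimate_smoothness(
    residual_maps, mask: np.ndarray, voxel_mm
) -> tuple[np.ndarray, float]:
    """Per-axis FWHM (mm) and resel count from standardized residuals.

    Residuals are standardized voxelwise across maps; the lag-1 spatial
    correlation along each axis, estimated from the variance of first
    differences (E[d^2] = 2(1 - rho)), is inverted through the Gaussian
    autocorrelation model rho(delta) = exp(-delta^2 / (4 sigma^2)) to give
    the smoothing-kernel sigma, hence FWHM.  Resels = mask voxels *
    prod(voxel / FWHM).
    """
    arr = _stack(residual_maps)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 residual maps")
    mask = np.asarray(mask, bool)
    if min(mask.shape) < 3:
        raise ValueError("mask too small for smoothness estimation")
    voxel_mm = np.broadcast_to(np.asarray(voxel_mm, float), (3,))
    sd = arr.std(axis=0)
    u = np.zeros_like(arr)
    np.divide(arr - arr.mean(axis=0), sd, out=u, where=sd > 0)
    fwhm = np.empty(3)
    for ax in range(3):
        d = np.diff(u, axis=ax + 1)
        lo = [slice(None)] * 3
        lo[ax] = slice(0, mask.shape[ax] - 1)
        hi = [slice(None)] * 3
        hi[ax] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        pair_ok = mask[lo] & mask[hi] & (sd[lo] > 0) & (sd[hi] > 0)
        if not pair_ok.any():
            raise ValueError("mask too small for smoothness estimation")
        vd = float(np.mean(d[:, pair_ok] ** 2))
        rho = np.clip(1.0 - vd / 2.0, 1e-8, 1.0 - 1e-8)
        sigma2 = -voxel_mm[ax] ** 2 / (4.0 * np.log(rho))
        fwhm[ax] = np.sqrt(8.0 * np.log(2.0) * sigma2)
    fwhm = np.maximum(fwhm, 0.1 * voxel_mm)
    resels = float(mask.sum() * np.prod(voxel_mm / fwhm))
    return fwhm, resels


def _ec_density_3d(z: float) -> float:
    """3-D Euler-characteristic density of a unit Gaussian field (per resel)."""
    return ((4.0 * np.log(2.0)) ** 1.5 / (2.0 * np.pi) ** 2
            * (z * z - 1.0) * np.exp(-z * z / 2.0))


def grf_cluster_p(
    size_voxels: int, cluster_forming_z: float, resels: float, n_mask_voxels: int
) -> float:
    """Familywise corrected p for one cluster of the given extent."""
    z0 = cluster_forming_z
    em = max(resels * _ec_density_3d(z0), 1e-12)
    en = n_mask_voxels * stats.norm.sf(z0) / em  # expected extent, voxels
    if en <= 0:
        return 1.0
    beta = (gamma_fn(2.5) / en) ** (2.0 / 3.0)
    p_tail = np.exp(-beta * size_voxels ** (2.0 / 3.0))
    return float(1.0 - np.exp(-em * p_tail))


def grf_cluster_correct(
    zmap: StatMap,
    mask: np.ndarray,
    affine: np.ndarray,
    smoothness: tuple[np.ndarray, float],
    cluster_forming_z: float = 2.3,
    alpha: float = 0.05,
) -> ClusterResult:
    """GRF cluster-extent correction of a Z map at threshold ``z0``.

    Supra-threshold 26-connected components get corrected p-values from
    Gaussian-random-field cluster-extent theory; only clusters with
    corrected p < ``alpha`` are retained.  An empty supra-threshold set is
    a valid (empty) result.
    """
    if zmap.kind != "Z":
        raise ValueError("grf_cluster_correct expects a Z map (use stat_to_z)")
    mask = np.asarray(mask, bool)
    vals = np.where(mask, zmap.values, -np.inf)
    if not np.isfinite(zmap.values[mask]).all():
        raise ValueError("Z map contains non-finite values inside the mask")
    supra = vals > cluster_forming_z
    _, resels = smoothness
    all_clusters = label_clusters(supra, zmap.values, affine)
    kept = []
    for c in all_clusters.clusters:
        c.p_corrected = grf_cluster_p(
            c.size_voxels, cluster_forming_z, resels, int(mask.sum())
        )
        if c.p_corrected < alpha:
            kept.append(c)
    keep_labels = {c.label for c in kept}
    labels = np.where(np.isin(all_clusters.label_field, list(keep_labels)),
                      all_clusters.label_field, 0)
    kept.sort(key=lambda c: -c.size_voxels)
    return ClusterResult(label_field=labels, clusters=kept)


def permutation_cluster_null(
    zmaps,
    groups,
    covariate,
    mask: np.ndarray,
    n_perm: int,
    cluster_forming_z: float = 2.3,
    seed: int = 0,
    stat: str = "anova",
) -> np.ndarray:
    """Null distribution of the maximum supra-threshold cluster size.

    Group labels are permuted across subjects (each subject keeps its own
    covariate value); per permutation the chosen statistic map is computed,
    converted to Z, thresholded at ``cluster_forming_z``, and the largest
    26-connected component size (0 if none) recorded.  Deterministic under
    ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    arr = _stack(zmaps)
    groups = np.asarray(groups)
    mask = np.asarray(mask, bool)
    rng = np.random.default_rng(seed)
    affine = np.eye(4)
    maxes = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        perm = rng.permutation(len(groups))
        g = groups[perm]
        if stat == "anova":
            sm, _ = ancova_f_map(arr, g, covariate, mask)
        elif stat == "two_sample":
            labs = np.unique(g)
            ia = np.flatnonzero(g == labs[0])
            ib = np.flatnonzero(g == labs[1])
            cov = None
            if covariate is not None:
                cov = np.concatenate([np.asarray(covariate)[ia],
                                      np.asarray(covariate)[ib]])
            sm, _ = two_sample_t_map(arr[ia], arr[ib], cov, mask)
        else:
            raise ValueError(f"unknown stat {stat!r}")
        z = stat_to_z(sm).values
        supra = np.where(mask, z, -np.inf) > cluster_forming_z
        labels, n = ndimage.label(supra, structure=CONNECTIVITY_26)
        maxes[i] = int(np.bincount(labels.ravel())[1:].max()) if n else 0
    return maxes


def permutation_cluster_p(null_max_sizes: np.ndarray, size_voxels: int) -> float:
    """P(max null cluster >= observed size), with the +1 correction."""
    null_max_sizes = np.asarray(null_max_sizes)
    return float((1 + (null_max_sizes >= size_voxels).sum())
                 / (1 + len(null_max_sizes)))


# ---- ROI extraction and post hocs ---------------------------------------


def sphere_voxels(
    center_mm, radius_mm: float, shape, affine: np.ndarray
) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within the sphere."""
    shape = tuple(shape)
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    mm = vox @ affine.T
    d2 = ((mm[..., :3] - np.asarray(center_mm, float)) ** 2).sum(axis=-1)
    return d2 <= radius_mm**2


def extract_sphere_mean(
    zmap: np.ndarray, center_mm, affine: np.ndarray, radius_mm: float = 5.0
) -> float:
    """Unweighted mean of the map over a sphere of voxel centers."""
    m = sphere_voxels(center_mm, radius_mm, np.asarray(zmap).shape, affine)
    if not m.any():
        raise ValueError("sphere contains no voxel on this grid")
    return float(np.asarray(zmap)[m].mean())


def posthoc_bonferroni(values, groups) -> pd.DataFrame:
    """Pairwise pooled-variance t tests, Bonferroni-corrected (x3, capped).

    Uses the within-group mean square from the one-way ANOVA on the sphere
    means as the pooled variance, df = N - 3.  Returns a DataFrame with
    one row per unordered group pair: group_a, group_b, mean_a, mean_b,
    t, p_uncorrected, p_bonferroni.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = [g for g in ("Control", "NonAVH", "AVH") if g in set(groups)]
    if len(levels) != 3:
        raise ValueError("post hoc tests need all 3 groups present")
    ns = {g: int((groups == g).sum()) for g in levels}
    means = {g: float(values[groups == g].mean()) for g in levels}
    N = len(values)
    ssw = sum(((values[groups == g] - means[g]) ** 2).sum() for g in levels)
    df = N - 3
    msw = ssw / df
    rows = []
    for i in range(3):
        for j in range(i + 1, 3):
            a, b = levels[i], levels[j]
            se = np.sqrt(msw * (1.0 / ns[a] + 1.0 / ns[b]))
            t = (means[a] - means[b]) / se if se > 0 else 0.0
            p = 2.0 * stats.t.sf(abs(t), df)
            rows.append(dict(group_a=a, group_b=b, mean_a=means[a],
                             mean_b=means[b], t=t, p_uncorrected=p,
                             p_bonferroni=min(3.0 * p, 1.0)))
    return pd.DataFrame(rows)
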