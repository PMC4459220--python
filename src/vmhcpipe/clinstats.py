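"""Score–connectivity correlation analyses.

Pearson correlations between regional zVMHC sphere means and clinical
ratings: PANSS subscale/total scores across all patients, AHRS within
the hallucinating (AVH) group only.  Two-tailed p-values come from the
exact t transformation t = r sqrt(n-2) / sqrt(1-r^2) with n-2 degrees
of freedom.  Missing scores (AHRS outside the AVH group) are handled by
pairwise deletion, never imputation; no multiplicity correction is
applied by default, matching the uncorrected presentation the analysis
is modeled on (an optional Benjamini–Hochberg flag is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PATIENT_COHORTS = {
    "all_patients": ("AVH", "NonAVH"),
    "avh_only": ("AVH",),
    "nonavh_only": ("NonAVH",),
}

SCORE_COLUMNS = ("panss_pos", "panss_neg", "panss_gen", "panss_total", "ahrs")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t_stat: float
    p_two_tailed: float
    score_name: str = ""
    region_name: str = ""


def p_from_r(r: float, n: int) -> float:
    """Two-tailed p for a sample Pearson r at sample size n.

    p = 2 * (1 - T_{n-2}(|r| sqrt(n-2) / sqrt(1-r^2))) with the central
    t distribution.  |r| = 1 returns 0 with a degeneracy warning.
    """
    if n < 3:
        raise ValueError("p_from_r needs n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        warnings.warn("|r| = 1 is degenerate; returning p = 0", stacklevel=2)
        return 0.0
    t = abs(r) * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(t, n - 2))


def pearson_r(x, y, score_name: str = "", region_name: str = "") -> CorrelationResult:
    """Sample Pearson correlation with t statistic and two-tailed p.

    Pairs with a missing value in either variable are dropped first.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("pearson_r needs at least 3 complete pairs")
    for name, v in (("x", x), ("y", y)):
        if np.std(v) == 0:
            raise ValueError(f"variable {name!r} has zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, t_stat=float(t), p_two_tailed=p,
                             score_name=score_name, region_name=region_name)


def correlation_table(
    sphere_means: pd.DataFrame,
    records: pd.DataFrame,
    cohort: str = "all_patients",
    scores: tuple[str, ...] | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """All (score, region) correlations on one patient cohort, long format.

    ``sphere_means`` is subject x region (index = subject_id); ``records``
    needs columns subject_id, group, the score columns and (if present) an
    ``included`` flag.  Returns a DataFrame with columns region, score,
    cohort, r, n, t, p (plus p_fdr when ``fdr``).  Cells with fewer than 3
    complete pairs are reported with NaN statistics.
    """
    if cohort not in PATIENT_COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")
    recs = records.copy()
    if "included" in recs.columns:
        recs = recs[recs["included"]]
    recs = recs[recs["group"].isin(PATIENT_COHORTS[cohort])]
    if recs.empty:
        raise ValueError(f"cohort {cohort!r} is empty")
    if scores is None:
        scores = tuple(s for s in SCORE_COLUMNS if s in recs.columns)
    rows = []
    for region in sphere_means.columns:
        z = sphere_means.reindex(recs["subject_id"])[region].to_numpy()
        if np.isnan(z).all():
            raise ValueError(f"region {region!r} absent from sphere means")
        for score in scores:
            s = recs[score].to_numpy(float)
            ok = np.isfinite(z) & np.isfinite(s)
            if ok.sum() < 3:
                rows.append(dict(region=region, score=score, cohort=cohort,
                                 r=np.nan, n=int(ok.sum()), t=np.nan, p=np.nan))
                continue
            res = pearson_r(z[ok], s[ok], score_name=score, region_name=region)
            rows.append(dict(region=region, score=score, cohort=cohort,
                             r=res.r, n=res.n, t=res.t_stat, p=res.p_two_tailed))
    out = pd.DataFrame(rows)
    if fdr:
        ok = out["p"].notna()
        out["p_fdr"] = np.nan
        if ok.any():
            out.loc[ok, "p_fdr"] = multipletests(
                out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def wide_table(long: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Alternating r/p rows per region, one column per score.

    Mirrors the published correlation-matrix layout; rounding happens here
    at serialization only, never upstream.
    """
    regions = list(dict.fromkeys(long["region"]))
    scores = list(dict.fromkeys(long["score"]))
    rows = []
    for region in regions:
        sub = long[long["region"] == region].set_index("score")
        rows.append([region, "r"] + [round(float(sub.loc[s, "r"]), decimals)
                                     if s in sub.index else np.nan for s in scores])
        rows.append([region, "p"] + [round(float(sub.loc[s, "p"]), decimals)
                                     if s in sub.index else np.nan for s in scores])
    return pd.DataFrame(rows, columns=["region", "stat"] + scores)
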