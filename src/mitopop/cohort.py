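"""Cohort-level statistics: distribution diagnostics of the MitoTracker-low
proportion, deterministic 1-D k-means stratification, and association with
TNF secretion and atherosclerosis covariates."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normality_test",
    "kmeans2",
    "pearson",
    "ttest_ind",
    "summarize",
    "tnf_metrics",
    "cohort_report",
    "holm",
    "CohortReport",
]

log = logging.getLogger(__name__)

CLUSTER_COVARIATES = ["imt", "plaque_score", "tnf_basal", "tnf_lps",
                      "tnf_increase", "tnf_fold"]


def normality_test(values) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value; constant input is degenerate."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        warnings.warn("constant input: normality test degenerate", stacklevel=2)
        return float("nan"), float("nan")
    stat, p = stats.shapiro(x)
    return float(stat), float(p)


def kmeans2(values) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 1-D k-means (k=2) by exhaustive contiguous-split search.

    For 1-D data the optimal 2-partition is a contiguous split of the sorted
    values, so scanning all n-1 splits attains the global within-cluster-SS
    optimum.  Clusters are renumbered so center 1 < center 2; labels are 1/2.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct values")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    csq = np.concatenate([[0.0], np.cumsum(xs ** 2)])

    def seg_ss(i, j):  # within-SS of xs[i:j]
        s, q, m = csum[j] - csum[i], csq[j] - csq[i], j - i
        return q - s * s / m

    splits = np.array([seg_ss(0, s) + seg_ss(s, n) for s in range(1, n)])
    s_best = int(np.argmin(splits)) + 1
    labels_sorted = np.where(np.arange(n) < s_best, 1, 2)
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    centers = np.array([xs[:s_best].mean(), xs[s_best:].mean()])
    return labels, centers


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with two-tailed p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def ttest_ind(group_a, group_b, welch: bool = False) -> tuple[float, float]:
    """Two-sample t-test; Student's pooled-variance by default."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def summarize(group) -> tuple[float, float]:
    """Mean and SEM (sd / sqrt(n), ddof=1); SEM is NaN for n < 2."""
    g = np.asarray(group, dtype=float)
    sem = float(g.std(ddof=1) / np.sqrt(g.size)) if g.size > 1 else float("nan")
    return float(g.mean()), sem


def tnf_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Add LPS-induced increase and fold-change of TNF secretion."""
    out = table.copy()
    out["tnf_increase"] = out["tnf_lps"] - out["tnf_basal"]
    out["tnf_fold"] = np.where(out["tnf_basal"] > 0,
                               out["tnf_lps"] / out["tnf_basal"], np.nan)
    return out


def holm(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    adj = np.full(len(p), np.nan)
    valid = np.flatnonzero(~np.isnan(p))
    m = len(valid)
    order = valid[np.argsort(p[valid])]
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


@dataclass
class CohortReport:
    normality: tuple[float, float]
    clusters: pd.DataFrame  # per subject: patient_id, prop_low, cluster
    centers: np.ndarray
    table2: pd.DataFrame  # correlations of prop_low vs TNF covariates
    table3: pd.DataFrame  # per-cluster mean +- SEM and t-tests
    fig5_density: pd.DataFrame  # KDE of across-subject proportions


def _proportion_density(prop: np.ndarray) -> pd.DataFrame:
    est = stats.gaussian_kde(prop, bw_method="silverman")
    h = float(np.sqrt(est.covariance[0, 0]))
    grid = np.linspace(prop.min() - 3 * h, prop.max() + 3 * h, 256)
    return pd.DataFrame({"prop_low": grid, "density": est(grid)})


def cohort_report(table: pd.DataFrame, welch: bool = False) -> CohortReport:
    """Full cohort analysis over a covariate table with a prop_low column.

    Subjects with missing covariates are dropped with a logged warning.
    Emits Pearson correlations of prop_low vs basal and LPS-induced TNF,
    the 2-cluster stratification, and per-cluster comparisons of IMT,
    plaque score and TNF metrics (raw plus Holm-adjusted p-values).
    """
    needed = ["prop_low", "imt", "plaque_score", "tnf_basal", "tnf_lps"]
    complete = table.dropna(subset=[c for c in needed if c in table.columns])
    if len(complete) < len(table):
        log.warning("dropped %d subjects with missing covariates",
                    len(table) - len(complete))
    if len(complete) < 4:
        raise ValueError("need >= 4 subjects with complete covariates")
    df = tnf_metrics(complete.reset_index(drop=True))

    prop = df["prop_low"].to_numpy()
    norm = normality_test(prop)

    rows = []
    for name, col in [("tnf_basal", "tnf_basal"), ("tnf_lps", "tnf_lps")]:
        r, p = pearson(prop, df[col].to_numpy())
        rows.append({"covariate": name, "pearson_r": r, "p_value": p})
    table2 = pd.DataFrame(rows)

    labels, centers = kmeans2(prop)
    clusters = pd.DataFrame({
        "patient_id": df["patient_id"] if "patient_id" in df else np.arange(len(df)) + 1,
        "prop_low": prop, "cluster": labels})

    rows = []
    for cov in CLUSTER_COVARIATES:
        a = df.loc[labels == 1, cov].dropna()
        b = df.loc[labels == 2, cov].dropna()
        m1, s1 = summarize(a) if len(a) else (np.nan, np.nan)
        m2, s2 = summarize(b) if len(b) else (np.nan, np.nan)
        if len(a) >= 2 and len(b) >= 2:
            t, p = ttest_ind(a, b, welch=welch)
        else:  # cluster too small to test; report summaries only
            t, p = np.nan, np.nan
        rows.append({"covariate": cov, "n1": len(a), "n2": len(b),
                     "mean1": m1, "sem1": s1, "mean2": m2, "sem2": s2,
                     "t": t, "p_value": p})
    table3 = pd.DataFrame(rows)
    table3["p_holm"] = holm(table3["p_value"].to_numpy())

    return CohortReport(normality=norm, clusters=clusters, centers=centers,
                        table2=table2, table3=table3,
                        fig5_density=_proportion_density(prop))
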