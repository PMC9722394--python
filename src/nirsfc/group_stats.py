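"""Mass-univariate edge statistics: pooled t, BH-FDR, ROC screening.

Each edge's Fisher-z values are compared between groups with the
equal-variance (pooled) two-sample t-test (df = n1 + n2 - 2, i.e. 126 for
64 vs 64), adjusted for multiple comparisons with Benjamini-Hochberg FDR
within each analysis level, and screened with the ROC AUC oriented so
that edges reduced in the patient group score above 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix

#: default screening thresholds
ALPHA_SIG = 0.05
ALPHA_STRONG = 0.01
AUC_SCREEN = 0.65


def edge_ttest(z_hc: np.ndarray, z_mci: np.ndarray) -> tuple[float, int, float]:
    """Pooled-variance two-sample t (HC minus MCI), df, two-sided p."""
    a = np.asarray(z_hc, float)
    b = np.asarray(z_mci, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 subjects")
    df = a.size + b.size - 2
    res = stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(res.statistic):
        raise ValueError("zero pooled variance; t undefined")
    return float(res.statistic), df, float(res.pvalue)


def fdr_adjust(p_values: np.ndarray, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (order-preserving).

    ``method="fdr_by"`` switches to Benjamini-Yekutieli.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def edge_roc(z_hc: np.ndarray, z_mci: np.ndarray) -> tuple[float, float, float, float]:
    """ROC screening of one edge: (auc, sensitivity, specificity, threshold).

    AUC follows the Mann-Whitney identity -- the fraction of (HC, MCI)
    pairs with z_HC > z_MCI, ties counted half -- so edges weakened in the
    patient group score above 0.5.  The operating point maximises
    Youden's J; sensitivity is the fraction of MCI subjects below the
    threshold, specificity the fraction of HC subjects at or above it.
    """
    a = np.asarray(z_hc, float)
    b = np.asarray(z_mci, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    y = np.concatenate([np.ones(a.size), np.zeros(b.size)])
    scores = np.concatenate([a, b])
    fpr, tpr, thresholds = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = int(np.argmax(j))
    thr = float(thresholds[best])
    sensitivity = float(np.mean(b < thr))
    specificity = float(np.mean(a >= thr))
    return auc, sensitivity, specificity, thr


def run_edge_stats(matrices: list[ConnectivityMatrix],
                   alpha_sig: float = ALPHA_SIG,
                   alpha_strong: float = ALPHA_STRONG,
                   auc_screen: float = AUC_SCREEN,
                   fdr_method: str = "fdr_bh") -> pd.DataFrame:
    """Per-edge group statistics for a cohort of same-level matrices.

    Returns one row per undirected edge with group moments, pooled t,
    BH-FDR-adjusted p (within this level's edge family), ROC quantities
    and significance flags; ROI-level tables are additionally ranked by
    AUC for feature screening.
    """
    levels = {cm.level for cm in matrices}
    if len(levels) != 1:
        raise ValueError(f"mixed analysis levels: {levels}")
    level = levels.pop()
    labels = matrices[0].labels
    hc = np.array([cm.upper_values() for cm in matrices if cm.group == "HC"])
    mci = np.array([cm.upper_values() for cm in matrices if cm.group == "MCI"])
    if hc.shape[0] < 2 or mci.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")

    iu = np.triu_indices(len(labels), 1)
    n_edges = iu[0].size
    rows = []
    for e in range(n_edges):
        a = hc[:, e]
        b = mci[:, e]
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if a.size < 2 or b.size < 2 or (a.std() == 0 and b.std() == 0):
            rows.append((np.nan,) * 10)
            continue
        t, df, p = edge_ttest(a, b)
        auc, sens, spec, thr = edge_roc(a, b)
        rows.append((a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1),
                     t, df, p, auc, sens) + (spec,))

    cols = ["mean_hc", "sd_hc", "mean_mci", "sd_mci", "t", "df", "p_raw",
            "auc", "sens", "spec"]
    out = pd.DataFrame([r[:10] for r in rows], columns=cols)
    out.insert(0, "node_j", [labels[j] for j in iu[1]])
    out.insert(0, "node_i", [labels[i] for i in iu[0]])
    out.insert(0, "level", level)

    valid = out["p_raw"].notna()
    p_fdr = np.full(n_edges, np.nan)
    if valid.any():
        p_fdr[valid.to_numpy()] = fdr_adjust(out.loc[valid, "p_raw"].to_numpy(),
                                             method=fdr_method)
    out["p_fdr"] = p_fdr
    out["sig"] = out["p_fdr"] < alpha_sig
    out["strong"] = out["p_fdr"] < alpha_strong
    out["screened"] = out["sig"] & (out["auc"] > auc_screen)
    if level == "roi":
        out["auc_rank"] = out["auc"].rank(ascending=False)
    return out
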