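"""Subtype characterization statistics.

Cross-tabulation of subtype labels against external annotations with
per-cell hypergeometric enrichment; developmental-stage correlation of
subtype centroids against a timecourse; mean-expression signature
scoring (e.g. an EMT signature); and Kaplan-Meier / log-rank survival
comparison between subtypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "crosstab_association",
    "select_development_genes",
    "stage_correlation",
    "signature_score",
    "km_logrank",
    "KMResult",
]


def crosstab_association(labelsA, labelsB) -> pd.DataFrame:
    """Cross-tabulate two labelings with per-cell enrichment statistics.

    Over the samples shared by both labelings, reports per cell: count,
    row percentage (count / row total), column percentage, fold
    enrichment observed / (row total * column total / grand total),
    upper-tail hypergeometric p, and BH FDR across all cells. Both
    percentage conventions are emitted so the caller never has to guess
    which one a table uses.
    """
    a = pd.Series(labelsA)
    b = pd.Series(labelsB)
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise ValueError("no shared samples between the two labelings")
    a, b = a.loc[shared], b.loc[shared]
    table = pd.crosstab(a, b)
    grand = table.to_numpy().sum()
    rows = []
    for ra in table.index:
        for cb in table.columns:
            k = int(table.at[ra, cb])
            row_total = int(table.loc[ra].sum())
            col_total = int(table[cb].sum())
            expected = row_total * col_total / grand
            fold = k / expected if expected > 0 else np.nan
            p = sps.hypergeom.sf(k - 1, grand, col_total, row_total)
            rows.append((ra, cb, k, row_total, col_total,
                         100.0 * k / row_total, 100.0 * k / col_total,
                         fold, p))
    out = pd.DataFrame(rows, columns=["row", "col", "count", "row_total",
                                      "col_total", "row_pct", "col_pct",
                                      "fold", "p"])
    out["fdr"] = sps.false_discovery_control(out["p"], method="bh")
    return out


def select_development_genes(timecourse: pd.DataFrame,
                             rho_threshold: float = 0.9,
                             top_n: int = 1000) -> list:
    """Development-related genes from an ordered timecourse.

    Keeps genes whose |Spearman correlation| with the timepoint rank
    exceeds ``rho_threshold`` (constant genes, whose rho is undefined,
    are excluded), then returns the ``top_n`` of them by median absolute
    deviation across timepoints (all if fewer). ``timecourse`` columns
    must be in temporal order.
    """
    if timecourse.shape[1] < 4:
        raise ValueError("need at least 4 timepoints")
    t = np.arange(timecourse.shape[1])
    X = timecourse.to_numpy()
    keep = []
    for i, gene in enumerate(timecourse.index):
        if np.ptp(X[i]) == 0:
            continue
        rho = sps.spearmanr(X[i], t).statistic
        if np.isfinite(rho) and abs(rho) > rho_threshold:
            keep.append(gene)
    if not keep:
        raise ValueError("no gene passes the Spearman filter")
    sub = timecourse.loc[keep]
    mad = sub.sub(sub.median(axis=1), axis=0).abs().median(axis=1)
    ranked = mad.sort_values(ascending=False, kind="stable")
    return list(ranked.index[:top_n])


def stage_correlation(centroids: pd.DataFrame, timecourse: pd.DataFrame,
                      genes) -> pd.DataFrame:
    """Pearson correlation of each subtype centroid with each timepoint.

    Returns one row per (subtype, timepoint) with r and its 95%
    confidence interval from the Fisher z transform at n = number of
    genes.
    """
    genes = [g for g in genes
             if g in centroids.index and g in timecourse.index]
    if len(genes) < 4:
        raise ValueError("need at least 4 shared genes")
    C = centroids.loc[genes]
    T = timecourse.loc[genes]
    n = len(genes)
    zcrit = sps.norm.ppf(0.975)
    rows = []
    for subtype in C.columns:
        for tp in T.columns:
            r = float(np.corrcoef(C[subtype], T[tp])[0, 1])
            if abs(r) >= 1.0:      # degenerate: Fisher z is infinite
                lo = hi = r
            else:
                z = np.arctanh(r)
                half = zcrit / np.sqrt(n - 3)
                lo, hi = float(np.tanh(z - half)), float(np.tanh(z + half))
            rows.append((subtype, tp, r, lo, hi))
    return pd.DataFrame(rows, columns=["subtype", "timepoint", "r",
                                       "ci_low", "ci_high"])


def signature_score(expr, gene_set) -> pd.Series:
    """Per-sample mean expression over the signature genes present.

    Expression is assumed already centered on the relevant reference
    (per-dataset or normal-sample centering upstream), so the score
    reads as the signature's average log-ratio in each sample; values
    are averaged as given, without re-centering. Absent signature genes
    are logged.
    """
    values = expr.values if hasattr(expr, "genes") else expr
    present = [g for g in gene_set if g in values.index]
    absent = len(set(gene_set)) - len(set(present))
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    if absent:
        logger.info("%d signature genes absent from the matrix", absent)
    return values.loc[present].mean(axis=0).rename("signature_score")


@dataclass
class KMResult:
    """Kaplan-Meier curves per group with the k-group log-rank test."""

    curves: dict                 # group -> DataFrame(timeline, survival)
    statistic: float             # log-rank chi-square
    p: float
    df: int


def km_logrank(surv: pd.DataFrame) -> KMResult:
    """Product-limit survival curves and the k-group log-rank test.

    ``surv`` needs columns time (positive), event (0/1) and group. The
    log-rank chi-square has k - 1 degrees of freedom under the null of
    equal hazards in all groups.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    required = {"time", "event", "group"}
    if not required.issubset(surv.columns):
        raise ValueError(f"survival table needs columns {sorted(required)}")
    if (surv["time"] <= 0).any():
        raise ValueError("times must be positive")
    if not surv["event"].isin((0, 1)).all():
        raise ValueError("event indicator must be 0 or 1")
    groups = sorted(surv["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if surv["event"].sum() == 0:
        raise ValueError("need at least one observed event")

    curves = {}
    for g in groups:
        block = surv[surv["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(block["time"], block["event"])
        curves[g] = pd.DataFrame({
            "timeline": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
        })
    res = multivariate_logrank_test(surv["time"], surv["group"], surv["event"])
    return KMResult(curves=curves, statistic=float(res.test_statistic),
                    p=float(res.p_value), df=len(groups) - 1)
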