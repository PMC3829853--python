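"""Consensus-clustering subtype discovery and core-sample selection.

Samples are repeatedly subsampled and clustered by average-linkage
hierarchical clustering under 1 - Pearson correlation distance; the
fraction of resamples in which two samples co-cluster forms the
consensus matrix, whose CDF area guides the choice of cluster number.
Pairwise cluster significance is assessed with a SigClust-style
Gaussian-null simulation, and samples with positive silhouette width
are retained as "core" representatives of their subtype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusResult",
    "consensus_cluster",
    "choose_k",
    "sigclust_pair",
    "silhouette_widths",
    "core_samples",
    "SubtypeAssignment",
]


def correlation_distance(values: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between columns (samples) of genes x samples."""
    corr = np.corrcoef(values.T)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


@dataclass
class ConsensusResult:
    """Per-k consensus matrices and their CDF summaries."""

    samples: pd.Index
    consensus: dict[int, np.ndarray]      # NaN where a pair was never co-sampled
    cdf: dict[int, tuple[np.ndarray, np.ndarray]]   # (grid, ecdf value)
    area: dict[int, float]

    def matrix(self, k: int) -> pd.DataFrame:
        return pd.DataFrame(self.consensus[k], index=self.samples,
                            columns=self.samples)


def consensus_cluster(expr, genes, k_range, n_resamples: int = 1000,
                      sample_fraction: float = 0.8, seed: int = 0) -> ConsensusResult:
    """Consensus average-linkage hierarchical clustering over module genes.

    Each resample draws ``sample_fraction`` of the samples without
    replacement, clusters them with average linkage under 1 - Pearson
    distance, and cuts the tree at each k in ``k_range``. Consensus
    entry (i, j) is the number of resamples where i and j co-clustered
    divided by the number where both were drawn; pairs never co-sampled
    are flagged NaN and excluded from the CDF.
    """
    genes = list(genes)
    missing = set(genes) - set(expr.genes)
    if missing:
        raise ValueError(f"genes not in expression matrix: {sorted(missing)[:5]}")
    X = expr.values.loc[genes].to_numpy()
    n = X.shape[1]
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or k_range[0] < 2 or k_range[-1] > n - 1:
        raise ValueError("k_range must lie within [2, n_samples - 1]")

    D = correlation_distance(X)
    m = max(2, int(round(sample_fraction * n)))
    rng = np.random.default_rng(seed)

    co_sampled = np.zeros((n, n))
    co_clustered = {k: np.zeros((n, n)) for k in k_range}
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = D[np.ix_(idx, idx)]
        Z = linkage(squareform(sub, checks=False), method="average")
        co_sampled[np.ix_(idx, idx)] += 1
        for k in k_range:
            labels = fcluster(Z, t=k, criterion="maxclust")
            same = labels[:, None] == labels[None, :]
            co_clustered[k][np.ix_(idx, idx)] += same

    consensus, cdf, area = {}, {}, {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in k_range:
            mat = np.where(co_sampled > 0, co_clustered[k] / co_sampled, np.nan)
            np.fill_diagonal(mat, 1.0)
            consensus[k] = mat
            iu = np.triu_indices(n, k=1)
            vals = mat[iu]
            vals = np.sort(vals[~np.isnan(vals)])
            grid = np.linspace(0, 1, 101)
            ecdf = np.searchsorted(vals, grid, side="right") / max(len(vals), 1)
            cdf[k] = (grid, ecdf)
            area[k] = float(np.trapezoid(ecdf, grid))
    never = int(np.isnan(consensus[k_range[0]]).sum() // 2)
    if never:
        logger.warning("%d sample pairs were never co-sampled", never)
    return ConsensusResult(expr.samples, consensus, cdf, area)


def choose_k(result: ConsensusResult, rel_increase: float = 0.1) -> int:
    """Largest k whose relative CDF-area gain over k-1 exceeds ``rel_increase``.

    Mirrors reading the consensus CDF plot: stability that still rises
    appreciably at k justifies k clusters. Falls back to the smallest k
    when no gain qualifies. The per-k areas in ``result.area`` remain
    available for visual inspection.
    """
    ks = sorted(result.area)
    if len(ks) == 1:
        return ks[0]
    chosen = ks[0]
    for prev, k in zip(ks[:-1], ks[1:]):
        gain = (result.area[k] - result.area[prev]) / max(result.area[prev], 1e-12)
        if gain > rel_increase:
            chosen = k
    return chosen


def sigclust_pair(expr, samplesA, samplesB, n_sim: int = 1000,
                  seed: int = 0) -> float:
    """SigClust-style significance of a 2-way split.

    The observed statistic is the 2-cluster index (within-cluster sum of
    squares over total sum of squares) of the given split. The null is a
    single multivariate Gaussian with diagonal covariance whose
    eigenvalues come from the pooled sample covariance with
    background-noise thresholding (eigenvalues below the MAD-based
    background variance are raised to it). Each simulated dataset is
    split by 2-means and its best cluster index recorded;
    p = (1 + #{simulated <= observed}) / (1 + n_sim).
    """
    from sklearn.cluster import KMeans

    A = sorted(samplesA)
    B = sorted(samplesB)
    if set(A) & set(B):
        raise ValueError("sample sets must be disjoint")
    if len(A) < 2 or len(B) < 2 or len(A) + len(B) < 4:
        raise ValueError("need at least 2 samples per group and 4 in total")
    X = expr.values[A + B].to_numpy().T     # samples x genes
    labels = np.array([0] * len(A) + [1] * len(B))

    obs = _cluster_index(X, labels)

    # null covariance eigenvalues with background-noise thresholding
    centered = X - X.mean(axis=0)
    n, d = X.shape
    mad = np.median(np.abs(X - np.median(X)))
    sigma2_bg = (mad / 0.6744897501960817) ** 2
    # eigenvalues of the d x d covariance via the n x n Gram trick
    gram = centered @ centered.T / (n - 1)
    eig = np.sort(np.linalg.eigvalsh(gram))[::-1]
    eigvals = np.full(d, 0.0)
    eigvals[:min(n, d)] = np.clip(eig[:min(n, d)], 0.0, None)
    eigvals = np.maximum(eigvals, sigma2_bg)

    rng = np.random.default_rng(seed)
    count = 0
    scales = np.sqrt(eigvals)
    for i in range(n_sim):
        sim = rng.normal(size=(n, d)) * scales
        km = KMeans(n_clusters=2, n_init=2, max_iter=100,
                    random_state=int(rng.integers(2 ** 31)))
        sim_labels = km.fit_predict(sim)
        if _cluster_index(sim, sim_labels) <= obs:
            count += 1
    return (1 + count) / (1 + n_sim)


def _cluster_index(X: np.ndarray, labels: np.ndarray) -> float:
    total = ((X - X.mean(axis=0)) ** 2).sum()
    within = 0.0
    for lab in np.unique(labels):
        block = X[labels == lab]
        within += ((block - block.mean(axis=0)) ** 2).sum()
    return within / total


def silhouette_widths(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Silhouette width s(i) = (b(i) - a(i)) / max(a(i), b(i)).

    a(i): mean distance to the other members of i's cluster; b(i): the
    smallest mean distance to the members of another cluster. Samples in
    singleton clusters get s(i) = 0 (flagged via a warning).
    """
    labels = np.asarray(labels)
    D = np.asarray(D, dtype=float)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    n = len(labels)
    s = np.zeros(n)
    singleton = False
    for i in range(n):
        own = (labels == labels[i])
        n_own = own.sum() - 1
        if n_own == 0:
            singleton = True
            continue
        a = D[i, own].sum() / n_own
        b = min(D[i, labels == lab].mean() for lab in uniq if lab != labels[i])
        s[i] = (b - a) / max(a, b)
    if singleton:
        logger.warning("singleton cluster(s): silhouette set to 0 for their "
                       "samples (neither core nor anti-core)")
    return s


@dataclass
class SubtypeAssignment:
    """Per-sample cluster label, silhouette width and core flag."""

    table: pd.DataFrame     # columns: label, silhouette, core

    @property
    def core_sample_ids(self) -> pd.Index:
        return self.table.index[self.table["core"]]


def core_samples(expr, labels, genes=None) -> SubtypeAssignment:
    """Silhouette widths under 1 - Pearson distance; core = s(i) > 0.

    ``labels`` maps sample -> cluster id (Series or dict). Distances are
    computed over ``genes`` (default: all genes in ``expr``).
    """
    labels = pd.Series(labels)
    labels = labels.loc[expr.samples]
    uniq = labels.unique()
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    counts = labels.value_counts()
    if (counts == 0).any():
        raise ValueError("every cluster must be nonempty")
    X = expr.values if genes is None else expr.values.loc[list(genes)]
    D = correlation_distance(X.to_numpy())
    s = silhouette_widths(D, labels.to_numpy())
    table = pd.DataFrame({"label": labels.values,
                          "silhouette": s,
                          "core": s > 0}, index=expr.samples)
    return SubtypeAssignment(table)
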