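"""Driver-subnetwork inference by random walk with restart.

Somatic mutation and copy-number calls are binarized, converted into a
per-gene start-probability vector (column-wise normalization so samples
with few alterations count more, then row-wise summation, mutation and
CNV combined with equal weight), and propagated over the signaling
network's largest connected component with a random walk with restart
(restart probability 0.5 by default). Significance of each gene's
steady-state score is assessed against walks run from randomly permuted
start probabilities: a local p compares the gene to its own permutation
scores, a global p to the pooled scores of all genes. The largest
connected component of genes significant on both counts is reported as
the driver subnetwork.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats

logger = logging.getLogger(__name__)

__all__ = [
    "binarize_mutations",
    "binarize_cnv",
    "StartProbabilityVector",
    "start_probabilities",
    "WalkScores",
    "random_walk",
    "SignificanceResult",
    "permutation_significance",
    "extract_driver_subnetwork",
    "geneset_enrichment",
]

DEFAULT_SILENT_CLASSES = frozenset({"Silent", "silent", "Synonymous",
                                    "synonymous"})


def binarize_mutations(calls: pd.DataFrame, genes, samples,
                       silent_classes=DEFAULT_SILENT_CLASSES,
                       unknown_is_nonsilent: bool = True) -> pd.DataFrame:
    """Binary gene x sample matrix: 1 iff >= 1 non-silent call.

    ``calls`` has columns (sample, gene, variant_class). Variant classes
    in ``silent_classes`` are ignored; unknown classes are warned about
    and treated as non-silent by default. Samples without calls keep
    their all-zero column.
    """
    if "variant_class" not in calls.columns:
        raise ValueError("calls need a variant_class column")
    genes = list(genes)
    samples = list(samples)
    known = set(silent_classes) | {
        "Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
        "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins", "Splice_Site",
        "Nonstop_Mutation", "Translation_Start_Site", "missense",
        "nonsense", "frameshift", "splice",
    }
    unknown = set(calls["variant_class"]) - known
    if unknown:
        logger.warning("unknown variant classes %s treated as %s",
                       sorted(unknown)[:5],
                       "non-silent" if unknown_is_nonsilent else "silent")
    nonsilent = ~calls["variant_class"].isin(set(silent_classes))
    if not unknown_is_nonsilent:
        nonsilent &= ~calls["variant_class"].isin(unknown)

    mat = pd.DataFrame(0, index=genes, columns=samples, dtype=np.int8)
    kept = calls[nonsilent]
    kept = kept[kept["gene"].isin(mat.index) & kept["sample"].isin(mat.columns)]
    for g, s in zip(kept["gene"], kept["sample"]):
        mat.at[g, s] = 1
    return mat


def binarize_cnv(ratios: pd.DataFrame, hi: float = 1.2,
                 lo: float = 0.8) -> pd.DataFrame:
    """Binary matrix: 1 iff copy ratio >= hi (gain) or <= lo (loss).

    Both cutoffs are inclusive. Ratios must be positive.
    """
    if (ratios <= 0).any().any():
        raise ValueError("copy ratios must be positive")
    return ((ratios >= hi) | (ratios <= lo)).astype(np.int8)


@dataclass
class StartProbabilityVector:
    """Normalized per-gene alteration weight feeding the walk.

    S_mut(i) and S_cnv(i) are row sums of the column-normalized binary
    matrices (columns with no alterations contribute 0); p0 is their
    equal-weight sum normalized to 1 over genes.
    """

    p0: pd.Series
    s_mut: pd.Series
    s_cnv: pd.Series
    n_genes: int
    n_samples: int


def _column_normalized_rowsum(mat: pd.DataFrame) -> pd.Series:
    col_sums = mat.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        normed = mat / col_sums.replace(0, np.nan)
    return normed.fillna(0.0).sum(axis=1)


def start_probabilities(mut: pd.DataFrame,
                        cnv: pd.DataFrame | None = None) -> StartProbabilityVector:
    """Start probabilities from binary mutation and CNV matrices.

    Column-wise normalization (each sample's alterations sum to 1, so
    alterations in quiet genomes weigh more) followed by row-wise
    summation turns each matrix into a per-gene score; the two scores
    are added with equal weight and normalized to a probability vector.
    """
    if cnv is None:
        cnv = pd.DataFrame(0, index=mut.index, columns=mut.columns)
    if not mut.index.equals(cnv.index) or not mut.columns.equals(cnv.columns):
        raise ValueError("mutation and CNV matrices must share gene and "
                         "sample universes")
    for name, m in (("mutation", mut), ("cnv", cnv)):
        vals = m.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} matrix must be binary")
    s_mut = _column_normalized_rowsum(mut)
    s_cnv = _column_normalized_rowsum(cnv)
    combined = s_mut + s_cnv
    total = combined.sum()
    if total <= 0:
        raise ValueError("all-zero alteration matrices: walk undefined")
    return StartProbabilityVector(p0=combined / total, s_mut=s_mut,
                                  s_cnv=s_cnv, n_genes=mut.shape[0],
                                  n_samples=mut.shape[1])


@dataclass
class WalkScores:
    """Steady-state visiting probabilities of the restart walk."""

    scores: pd.Series
    restart: float
    iterations: int
    residual: float


def _walk_operator(network: nx.Graph):
    """Largest connected component and its column-normalized adjacency."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    lcc = max(nx.connected_components(network), key=lambda c: (len(c), sorted(c)))
    nodes = sorted(lcc)
    sub = network.subgraph(nodes)
    A = nx.to_scipy_sparse_array(sub, nodelist=nodes, format="csc", weight=None)
    deg = np.asarray(A.sum(axis=0)).ravel()
    W = A.multiply(1.0 / deg[np.newaxis, :]).tocsr()    # column-normalized
    return nodes, W


def _align_p0(p0, nodes) -> np.ndarray:
    vec = p0.p0 if isinstance(p0, StartProbabilityVector) else pd.Series(p0)
    outside = vec.index.difference(nodes)
    mass_out = float(vec.loc[outside].sum()) if len(outside) else 0.0
    if len(outside):
        logger.info("dropping %d genes outside the largest component "
                    "(%.3f start mass)", len(outside), mass_out)
    v = vec.reindex(nodes).fillna(0.0).to_numpy(dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("start probability has no mass on the largest "
                         "connected component")
    return v / total


def random_walk(network: nx.Graph, p0, r: float = 0.5,
                epsilon: float = 1e-6, max_iter: int = 10_000) -> WalkScores:
    """Random walk with restart on the network's largest component.

    Iterates p_{t+1} = (1 - r) W^T p_t + r p0 from p_0 = p0, W the
    column-normalized adjacency, until the L1 change drops below
    ``epsilon``. Start mass outside the largest component is dropped and
    the vector renormalized.
    """
    if not 0.0 < r <= 1.0:
        raise ValueError("restart probability must lie in (0, 1]")
    nodes, W = _walk_operator(network)
    v0 = _align_p0(p0, nodes)
    p = v0.copy()
    for it in range(1, max_iter + 1):
        p_next = (1.0 - r) * (W @ p) + r * v0
        delta = float(np.abs(p_next - p).sum())
        p = p_next
        if delta < epsilon:
            return WalkScores(pd.Series(p, index=nodes), r, it, delta)
    raise RuntimeError(f"walk did not converge in {max_iter} iterations "
                       f"(L1 residual {delta:.3g})")


@dataclass
class SignificanceResult:
    """Observed walk score with local and global permutation p-values."""

    table: pd.DataFrame     # columns: p0, score, local_p, global_p

    def significant_genes(self, alpha: float = 0.05) -> pd.Index:
        t = self.table
        return t.index[(t["local_p"] < alpha) & (t["global_p"] < alpha)]


def permutation_significance(network: nx.Graph, p0, n_perm: int = 1000,
                             seed: int = 0, r: float = 0.5,
                             epsilon: float = 1e-6, max_iter: int = 10_000,
                             global_mode: str = "pooled_all") -> SignificanceResult:
    """Permutation significance of walk scores.

    Each permutation shuffles the start-probability values across the
    network genes (values preserved, assignment randomized) and reruns
    the walk; all permutations advance simultaneously as columns of one
    iteration. Local p_i compares gene i's observed score to its own
    permutation scores; global p_i compares it to permutation scores
    pooled over all genes and permutations (``global_mode='pooled_all'``)
    or per permutation averaged over permutations (``'per_perm'``).
    Add-one estimators keep p-values in (0, 1].
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    nodes, W = _walk_operator(network)
    v0 = _align_p0(p0, nodes)
    n = len(nodes)

    observed = random_walk(network, pd.Series(v0, index=nodes), r=r,
                           epsilon=epsilon, max_iter=max_iter)
    obs = observed.scores.to_numpy()

    rng = np.random.default_rng(seed)
    P0 = np.empty((n, n_perm))
    for j in range(n_perm):
        P0[:, j] = v0[rng.permutation(n)]
    P = P0.copy()
    for it in range(1, max_iter + 1):
        P_next = (1.0 - r) * (W @ P) + r * P0
        delta = float(np.abs(P_next - P).sum(axis=0).max())
        P = P_next
        if delta < epsilon:
            break
    else:
        raise RuntimeError("permutation walks did not converge")

    local_ge = (P >= obs[:, None]).sum(axis=1)
    local_p = (1 + local_ge) / (1 + n_perm)

    if global_mode == "pooled_all":
        pooled = np.sort(P.ravel())
        ge = len(pooled) - np.searchsorted(pooled, obs, side="left")
        global_p = (1 + ge) / (1 + n_perm * n)
    elif global_mode == "per_perm":
        ge = (P[None, :, :] >= obs[:, None, None]).sum(axis=1)  # gene x perm
        global_p = ((1 + ge) / (1 + n)).mean(axis=1)
    else:
        raise ValueError("global_mode must be 'pooled_all' or 'per_perm'")

    table = pd.DataFrame({"p0": v0, "score": obs, "local_p": local_p,
                          "global_p": global_p}, index=pd.Index(nodes, name="gene"))
    return SignificanceResult(table)


def extract_driver_subnetwork(network: nx.Graph, sig: SignificanceResult,
                              alpha: float = 0.05) -> nx.Graph:
    """Largest connected component of genes significant on both p-values.

    Component ties are broken by node count, then edge count, then the
    lexicographically smallest member. Returns an empty graph (with a
    warning) when no gene is significant.
    """
    hits = sig.significant_genes(alpha)
    sub = network.subgraph(hits)
    if sub.number_of_nodes() == 0:
        logger.warning("no genes significant at alpha=%.3g: empty driver "
                       "subnetwork", alpha)
        return nx.Graph()
    comps = list(nx.connected_components(sub))
    max_nodes = max(len(c) for c in comps)
    comps = [c for c in comps if len(c) == max_nodes]
    max_edges = max(sub.subgraph(c).number_of_edges() for c in comps)
    comps = [c for c in comps if sub.subgraph(c).number_of_edges() == max_edges]
    best = min(comps, key=lambda c: min(c))
    return nx.Graph(sub.subgraph(best))


def geneset_enrichment(subnetwork_genes, background,
                       collections: dict) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets with BH FDR.

    For each set: overlap with the subnetwork genes, upper-tail
    hypergeometric p (population = background), and Benjamini-Hochberg
    FDR across all tested sets.
    """
    if not collections:
        raise ValueError("empty gene-set collection")
    subnet = set(subnetwork_genes)
    bg = set(background)
    if not subnet <= bg:
        raise ValueError("subnetwork genes must be a subset of the background")
    N, n = len(bg), len(subnet)
    rows = []
    for name, members in collections.items():
        K = len(set(members) & bg)
        k = len(set(members) & subnet)
        p = stats.hypergeom.sf(k - 1, N, K, n) if K else 1.0
        rows.append((name, k, K, p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"])
    out["fdr"] = stats.false_discovery_control(out["p"], method="bh")
    return out.sort_values("p", kind="stable").reset_index(drop=True)
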