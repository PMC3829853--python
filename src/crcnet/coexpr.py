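"""Co-expression network construction and module discovery.

The correlation threshold is chosen by a knowledge-guided rule: gene
pairs are binned by Pearson correlation, each bin's mean Resnik semantic
similarity (from ontology annotations) is computed, and the smallest
|r| at which functional similarity rises sharply above the low-|r|
baseline — on both the positive and negative side — is taken as the
threshold. Modules are then extracted from the thresholded network by
iterative clique enumeration (ICE): maximal cliques are processed in
decreasing size, and a clique is merged into an existing module when it
overlaps it heavily, otherwise it seeds a new module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "n_pairs",
    "pairwise_correlations",
    "correlation_matrix",
    "ResnikSimilarity",
    "resnik_similarity",
    "CorrelationBinCurve",
    "threshold_curve",
    "select_threshold",
    "build_network",
    "ModuleSet",
    "ice_modules",
]


def n_pairs(n_genes: int) -> int:
    """Number of unordered gene pairs, n*(n-1)/2."""
    return n_genes * (n_genes - 1) // 2


def correlation_matrix(expr) -> pd.DataFrame:
    """Gene x gene Pearson correlation over samples."""
    values = expr.values.to_numpy()
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values)
    return pd.DataFrame(corr, index=expr.genes, columns=expr.genes)


def pairwise_correlations(expr):
    """Yield (geneA, geneB, r) for every unordered gene pair once.

    Zero-variance genes are skipped (their correlation is undefined) and
    logged; requires at least 3 samples.
    """
    if expr.values.shape[1] < 3:
        raise ValueError("need at least 3 samples for meaningful correlations")
    values = expr.values.to_numpy()
    sd = values.std(axis=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("skipping %d zero-variance genes in pair stream",
                       n_dropped)
    genes = expr.genes[keep]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values[keep])
    m = len(genes)
    for i in range(m):
        row = corr[i]
        for j in range(i + 1, m):
            yield genes[i], genes[j], float(row[j])


# ----------------------------------------------------------- Resnik

class ResnikSimilarity:
    """Resnik semantic similarity between genes over an ontology DAG.

    Information content of a term t is -ln of the fraction of annotated
    genes annotated to t or any of its descendants (annotations are
    closed over ancestors). The gene-pair score is the maximum, over all
    cross pairs of their annotation terms, of the information content of
    the most informative common ancestor. Edges of ``ontology`` point
    child -> parent.
    """

    def __init__(self, ontology: nx.DiGraph, annotations: dict):
        self.ontology = ontology
        # ancestors including self, following child->parent edges
        self._anc: dict = {}
        for t in ontology.nodes:
            self._anc[t] = set(nx.descendants(ontology, t)) | {t}
        # ancestor-closed annotation sets
        self._gene_terms: dict = {}
        for gene, terms in annotations.items():
            closed: set = set()
            for t in terms:
                if t not in self._anc:
                    raise KeyError(f"annotation term {t!r} not in ontology")
                closed |= self._anc[t]
            self._gene_terms[gene] = closed
        n_annotated = len(self._gene_terms)
        counts: dict = {}
        for terms in self._gene_terms.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        self.ic = {t: -math.log(counts.get(t, 0) / n_annotated)
                   if counts.get(t, 0) > 0 else math.inf
                   for t in ontology.nodes}
        self._pair_cache: dict = {}

    def term_similarity(self, t1: str, t2: str) -> float:
        common = self._anc[t1] & self._anc[t2]
        return max((self.ic[t] for t in common
                    if math.isfinite(self.ic[t])), default=0.0)

    def gene_similarity(self, geneA: str, geneB: str) -> float:
        key = (geneA, geneB) if geneA <= geneB else (geneB, geneA)
        hit = self._pair_cache.get(key)
        if hit is not None:
            return hit
        for g in (geneA, geneB):
            if g not in self._gene_terms:
                raise KeyError(f"gene {g!r} has no ontology annotation")
        # closed term sets already contain all common ancestors, so the
        # max over the intersection equals the max over cross term pairs
        # of the most informative common ancestor
        common = self._gene_terms[geneA] & self._gene_terms[geneB]
        score = max((self.ic[t] for t in common
                     if math.isfinite(self.ic[t])), default=0.0)
        self._pair_cache[key] = score
        return score

    def __call__(self, geneA: str, geneB: str) -> float:
        return self.gene_similarity(geneA, geneB)


def resnik_similarity(geneA: str, geneB: str, ontology: nx.DiGraph,
                      annotations: dict) -> float:
    """One-shot Resnik gene similarity; build a ResnikSimilarity to score
    many pairs against the same ontology."""
    return ResnikSimilarity(ontology, annotations).gene_similarity(geneA, geneB)


# ------------------------------------------------- threshold selection

@dataclass
class CorrelationBinCurve:
    """Mean functional similarity of gene pairs per correlation bin."""

    bin_edges: np.ndarray
    mean_similarity: np.ndarray   # NaN where the bin holds no pairs
    pair_counts: np.ndarray
    similarity_var: np.ndarray = field(default=None)

    @property
    def empty_bins(self) -> np.ndarray:
        return self.pair_counts == 0


def threshold_curve(correlations, similarity,
                    bins: np.ndarray | None = None) -> CorrelationBinCurve:
    """Bin gene pairs by correlation and average their semantic similarity.

    ``correlations`` is an iterable of (geneA, geneB, r); ``similarity``
    a callable (geneA, geneB) -> score. Default bins are width 0.05 over
    [-1, 1]. Pairs whose genes lack annotations are skipped.
    """
    if bins is None:
        bins = np.round(np.arange(-1.0, 1.0001, 0.05), 10)
    bins = np.asarray(bins, dtype=float)
    if bins[0] > -1 or bins[-1] < 1:
        raise ValueError("bins must cover [-1, 1]")
    nb = len(bins) - 1
    count = np.zeros(nb, dtype=np.int64)
    total = np.zeros(nb)
    total_sq = np.zeros(nb)
    for a, b, r in correlations:
        try:
            s = similarity(a, b)
        except KeyError:
            continue
        idx = min(np.searchsorted(bins, r, side="right") - 1, nb - 1)
        idx = max(idx, 0)
        count[idx] += 1
        total[idx] += s
        total_sq[idx] += s * s
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        var = np.where(count > 1,
                       (total_sq - count * mean ** 2) / np.maximum(count - 1, 1),
                       np.nan)
    mean = np.where(count > 0, mean, np.nan)
    return CorrelationBinCurve(bins, mean, count, var)


def select_threshold(curve: CorrelationBinCurve,
                     manual: float | None = None,
                     baseline_cut: float = 0.3,
                     n_se: float = 2.0) -> float:
    """Knowledge-guided correlation threshold.

    If ``manual`` is given it is returned unchanged. Otherwise the
    baseline is the pooled mean similarity over bins with |r| <
    ``baseline_cut``; the threshold is the smallest bin edge t >=
    baseline_cut whose bin mean exceeds the baseline by at least
    ``n_se`` pooled standard errors on both the positive ([t, t+w)) and
    the negative ((-t-w, -t]) side. Empty bins are excluded. Raises if
    no edge qualifies, instructing a manual choice.
    """
    if manual is not None:
        return float(manual)
    edges = curve.bin_edges
    centers = (edges[:-1] + edges[1:]) / 2
    base_mask = (np.abs(centers) < baseline_cut) & (curve.pair_counts > 0)
    if not base_mask.any():
        raise ValueError("no pairs in the |r| < baseline_cut region; "
                         "choose the threshold manually")
    n_base = curve.pair_counts[base_mask].sum()
    base_mean = np.sum(curve.mean_similarity[base_mask]
                       * curve.pair_counts[base_mask]) / n_base
    var = curve.similarity_var
    base_var = np.nansum(np.where(base_mask & (curve.pair_counts > 1),
                                  var * (curve.pair_counts - 1), 0.0))
    dof = max(int(curve.pair_counts[base_mask].sum() - base_mask.sum()), 1)
    base_var = base_var / dof
    base_se2 = base_var / n_base

    def bin_passes(i: int) -> bool:
        if curve.pair_counts[i] == 0 or np.isnan(curve.mean_similarity[i]):
            return False
        v = var[i] if var is not None and not np.isnan(var[i]) else base_var
        se = math.sqrt(base_se2 + v / curve.pair_counts[i])
        return curve.mean_similarity[i] - base_mean >= n_se * se

    pos_edges = [e for e in edges[:-1] if e >= baseline_cut - 1e-12]
    for t in pos_edges:
        i_pos = int(np.searchsorted(edges, t, side="right")) - 1
        i_neg = int(np.searchsorted(edges, -t, side="left")) - 1
        if i_pos >= len(centers) or i_neg < 0:
            continue
        if bin_passes(i_pos) and bin_passes(i_neg):
            return float(round(t, 10))
    raise ValueError("no correlation bin shows a significant similarity "
                     "increase on both sides; supply the threshold manually")


# -------------------------------------------------------- network & ICE

def build_network(correlations, threshold: float) -> nx.Graph:
    """Keep edges with |r| >= threshold; isolated genes are excluded."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly in (0, 1)")
    graph = nx.Graph()
    for a, b, r in correlations:
        if a != b and abs(r) >= threshold:
            graph.add_edge(a, b, weight=r)
    if graph.number_of_edges() == 0:
        raise ValueError("no edges survive the threshold")
    return graph


@dataclass
class ModuleSet:
    """Named co-expression modules with their seed-clique provenance."""

    modules: dict[str, set]
    provenance: dict[str, list] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.modules)

    def __getitem__(self, name: str) -> set:
        return self.modules[name]

    def all_genes(self) -> set:
        out: set = set()
        for members in self.modules.values():
            out |= members
        return out


def ice_modules(network: nx.Graph, min_clique: int = 5, min_module: int = 20,
                merge_overlap: float = 0.5) -> ModuleSet:
    """Iterative clique enumeration.

    Maximal cliques of size >= ``min_clique`` are processed in
    decreasing size (ties broken by lexicographically smallest member
    list). A clique sharing at least ``merge_overlap`` of its own nodes
    with an existing module is merged into the module of greatest
    overlap (earliest module on ties); otherwise it seeds a new module.
    Only modules with >= ``min_module`` unique genes are returned,
    renamed M01, M02, ... in decreasing size.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    cliques = [sorted(c) for c in nx.find_cliques(network)
               if len(c) >= min_clique]
    cliques.sort(key=lambda c: (-len(c), c))

    modules: list[set] = []
    provenance: list[list] = []
    for clique in cliques:
        cset = set(clique)
        best, best_frac = None, 0.0
        for i, mod in enumerate(modules):
            frac = len(cset & mod) / len(cset)
            if frac > best_frac:
                best, best_frac = i, frac
        if best is not None and best_frac >= merge_overlap:
            modules[best] |= cset
            provenance[best].append(clique)
        else:
            modules.append(set(cset))
            provenance.append([clique])

    keep = [(m, p) for m, p in zip(modules, provenance) if len(m) >= min_module]
    keep.sort(key=lambda mp: (-len(mp[0]), sorted(mp[0])))
    named = {f"M{i + 1:02d}": m for i, (m, _) in enumerate(keep)}
    prov = {f"M{i + 1:02d}": p for i, (_, p) in enumerate(keep)}
    if not named:
        logger.warning("no module reached %d genes", min_module)
    return ModuleSet(named, prov)
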