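"""End-to-end orchestration of the discovery and driver-inference stages.

`run_discovery` takes a (multi-dataset) expression cohort plus an
ontology with annotations and produces co-expression modules, consensus
subtypes and core samples. `run_driver_inference` takes the subtype
labels plus binary alteration matrices and a signaling network and
produces one driver subnetwork per subtype. Both are thin compositions
of the stage functions; every stage remains individually callable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import coexpr, driver, preprocess, subtypes

logger = logging.getLogger(__name__)

__all__ = ["DiscoveryResult", "run_discovery", "run_driver_inference"]


@dataclass
class DiscoveryResult:
    """Artifacts of the subtype-discovery stage."""

    threshold: float
    network_nodes: int
    network_edges: int
    modules: coexpr.ModuleSet
    consensus: subtypes.ConsensusResult
    k: int
    assignment: subtypes.SubtypeAssignment
    extras: dict = field(default_factory=dict)

    @property
    def module_genes(self) -> list:
        return sorted(self.modules.all_genes())


def run_discovery(expr, ontology, annotations, *,
                  threshold: float | None = None,
                  k: int | None = None, k_range=(2, 3, 4, 5),
                  min_clique: int = 5, min_module: int = 20,
                  n_resamples: int = 1000, sample_fraction: float = 0.8,
                  seed: int = 0) -> DiscoveryResult:
    """Discover transcriptional subtypes from a raw multi-dataset cohort.

    Steps: per-dataset mean-centering; all-pairs Pearson correlations;
    knowledge-guided (or manual) correlation threshold; co-expression
    network; ICE modules; consensus average-linkage clustering of the
    samples over module genes; cluster-number choice from the consensus
    CDF (unless ``k`` is given); silhouette core-sample selection.
    """
    centered = preprocess.center_within_dataset(expr)

    sim = coexpr.ResnikSimilarity(ontology, annotations)
    if threshold is None:
        curve = coexpr.threshold_curve(
            coexpr.pairwise_correlations(centered), sim)
        threshold = coexpr.select_threshold(curve)
        logger.info("knowledge-guided threshold: %.3f", threshold)
    network = coexpr.build_network(
        coexpr.pairwise_correlations(centered), threshold)
    modules = coexpr.ice_modules(network, min_clique=min_clique,
                                 min_module=min_module)
    genes = sorted(modules.all_genes())
    if not genes:
        raise ValueError("no co-expression module found; lower the "
                         "threshold or module size")
    logger.info("%d modules, %d unique genes", len(modules), len(genes))

    consensus = subtypes.consensus_cluster(
        centered, genes, k_range, n_resamples=n_resamples,
        sample_fraction=sample_fraction, seed=seed)
    chosen_k = k if k is not None else subtypes.choose_k(consensus)

    # final labels: consensus-matrix average-linkage clustering at chosen k
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform
    import numpy as np

    cons = consensus.consensus[chosen_k].copy()
    cons[~np.isfinite(cons)] = 0.0
    d = 1.0 - cons
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    Z = linkage(squareform(d, checks=False), method="average")
    labels = pd.Series(fcluster(Z, t=chosen_k, criterion="maxclust"),
                       index=centered.samples, name="subtype")

    assignment = subtypes.core_samples(centered, labels, genes=genes)
    return DiscoveryResult(threshold=float(threshold),
                           network_nodes=network.number_of_nodes(),
                           network_edges=network.number_of_edges(),
                           modules=modules, consensus=consensus,
                           k=int(chosen_k), assignment=assignment)


def run_driver_inference(network: nx.Graph, mut: pd.DataFrame,
                         cnv: pd.DataFrame, subtype_of: pd.Series, *,
                         n_perm: int = 1000, restart: float = 0.5,
                         alpha: float = 0.05, seed: int = 0) -> dict:
    """Infer one driver subnetwork per subtype.

    For each subtype, the binary mutation/CNV columns of that subtype's
    samples are converted into start probabilities, propagated by random
    walk with restart over the network, and thresholded at local and
    global permutation p < ``alpha``; the largest connected component of
    the significant genes is the subtype's driver subnetwork.

    Returns {subtype: {"significance": SignificanceResult,
    "subnetwork": Graph, "p0": StartProbabilityVector}}.
    """
    subtype_of = pd.Series(subtype_of)
    shared = mut.columns.intersection(subtype_of.index)
    if shared.empty:
        raise ValueError("no samples shared between alterations and labels")
    out = {}
    for i, k in enumerate(sorted(subtype_of.loc[shared].unique())):
        cols = [s for s in shared if subtype_of.loc[s] == k]
        p0 = driver.start_probabilities(mut[cols], cnv[cols])
        sig = driver.permutation_significance(
            network, p0, n_perm=n_perm, seed=seed + i, r=restart)
        subnet = driver.extract_driver_subnetwork(network, sig, alpha=alpha)
        out[k] = {"p0": p0, "significance": sig, "subnetwork": subnet}
        logger.info("subtype %s: %d samples, %d-node driver subnetwork",
                    k, len(cols), subnet.number_of_nodes())
    return out
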