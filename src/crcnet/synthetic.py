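"""Synthetic multi-dataset cohorts with planted ground truth.

Emulates the statistical structure of a multi-site colorectal tumor
expression compendium with known answers, so every pipeline stage can be
validated end-to-end without any external download:

* an expression cohort with planted co-expression modules (one shared
  latent factor per module), three transcriptional subtypes expressed as
  module-activity shifts, and additive per-dataset batch offsets;
* a scale-free signaling network with, per subtype, a planted connected
  driver subnetwork;
* sparse binary somatic-mutation and copy-number matrices enriched on
  the planted drivers of each sample's subtype;
* subtype-dependent exponential survival;
* a small random ontology DAG whose annotations make planted modules
  functionally coherent.

All generators are fully determined by their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticTruth",
    "gen_expression_cohort",
    "gen_signaling_network",
    "plant_driver_genes",
    "gen_alteration_data",
    "gen_survival",
    "gen_ontology_and_annotations",
]


@dataclass
class SyntheticCohortSpec:
    """Parameters of the generated cohort.

    Defaults describe the standard test cohort: 1200 genes measured in
    three datasets of 60 samples, three subtypes, fifteen planted
    modules of 25-40 genes driven by a latent factor (loading 0.9,
    within-subtype factor SD 0.6, a quarter of members on a negatively
    loaded arm), residual noise SD 0.5, subtype shifts of 1.0
    (= 2 x noise SD) on module activity, and dataset batch offsets of
    SD 0.3.
    """

    n_genes: int = 1200
    n_samples_per_dataset: tuple = (60, 60, 60)
    n_subtypes: int = 3
    n_modules: int = 15
    module_size_range: tuple = (25, 40)
    module_correlation: float = 0.9
    module_neg_fraction: float = 0.25
    factor_sd: float = 0.6
    subtype_effect: float = 1.0
    batch_sd: float = 0.3
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [self.n_genes, self.n_subtypes, self.n_modules,
                  *self.n_samples_per_dataset, *self.module_size_range]
        if any(int(c) <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.module_size_range[0] < 20:
            raise ValueError("module sizes must be >= 20 so planted modules "
                             "are discoverable at the pipeline's minimum size")
        if not 0.0 <= self.module_correlation <= 1.0:
            raise ValueError("module_correlation must lie in [0, 1]")
        if not 0.0 <= self.module_neg_fraction <= 0.5:
            raise ValueError("module_neg_fraction must lie in [0, 0.5]")
        if self.batch_sd < 0 or self.noise_sd < 0 or self.factor_sd <= 0:
            raise ValueError("scales must be nonnegative (factor_sd positive)")


@dataclass
class SyntheticTruth:
    """Planted ground truth for a generated cohort."""

    sample_subtype: pd.Series
    module_members: dict[str, set] = field(default_factory=dict)
    driver_genes: dict[int, set] = field(default_factory=dict)
    survival_hazard: dict[int, float] = field(default_factory=dict)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def gen_expression_cohort(spec: SyntheticCohortSpec):
    """Generate the expression cohort and its ground truth.

    Each planted module m has a per-sample latent factor
    f_ms ~ N(mu[m, subtype(s)], factor_sd); member genes are
    x = loading * f + eps with eps ~ N(0, noise_sd). Each module is
    associated with one subtype (round-robin) whose samples get a
    +subtype_effect shift on the factor mean. Non-module genes are pure
    noise. Every gene then receives an additive per-dataset batch offset
    ~ N(0, batch_sd), which per-dataset mean-centering removes.

    Returns (ExpressionMatrix, SyntheticTruth). Default survival hazards
    per subtype (events per month: 0.04, 0.01, 0.02, cycling) are stored
    on the truth for the survival generator.
    """
    from .preprocess import ExpressionMatrix

    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)

    sizes = rng.integers(spec.module_size_range[0],
                         spec.module_size_range[1] + 1,
                         size=spec.n_modules)
    if sizes.sum() > spec.n_genes:
        raise ValueError("module sizes sum to more than n_genes")

    # module membership: disjoint blocks at the start of the gene list,
    # so most genes stay background noise
    module_members: dict[str, set] = {}
    cursor = 0
    for m, size in enumerate(sizes):
        module_members[f"M{m + 1:02d}"] = set(genes[cursor:cursor + size])
        cursor += size

    # samples, datasets, subtypes (subtypes balanced within each dataset)
    sample_ids, dataset_labels, subtype_labels = [], [], []
    for d, n_d in enumerate(spec.n_samples_per_dataset):
        ids = [f"D{d + 1}S{i:03d}" for i in range(n_d)]
        subtypes = (np.arange(n_d) % spec.n_subtypes) + 1
        rng.shuffle(subtypes)
        sample_ids.extend(ids)
        dataset_labels.extend([f"D{d + 1}"] * n_d)
        subtype_labels.extend(subtypes.tolist())
    n_samples = len(sample_ids)
    subtype = np.asarray(subtype_labels)

    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_samples))
    gene_pos = {g: i for i, g in enumerate(genes)}

    for m, (name, members) in enumerate(module_members.items()):
        target = (m % spec.n_subtypes) + 1
        mean = np.where(subtype == target, spec.subtype_effect, 0.0)
        factor = rng.normal(mean, spec.factor_sd)
        rows = np.array([gene_pos[g] for g in sorted(members)])
        # a minority of members load negatively, as in real co-expression
        # modules with a repressed arm; makes the signed correlation
        # structure two-sided
        n_neg = int(round(spec.module_neg_fraction * len(rows)))
        signs = np.ones(len(rows))
        if n_neg:
            signs[rng.permutation(len(rows))[:n_neg]] = -1.0
        loading = spec.module_correlation * signs
        values[rows, :] += loading[:, np.newaxis] * factor[np.newaxis, :]

    # additive per-(gene, dataset) batch offsets
    dataset_arr = np.asarray(dataset_labels)
    for d in pd.unique(dataset_arr):
        offs = rng.normal(0.0, spec.batch_sd, size=spec.n_genes)
        values[:, dataset_arr == d] += offs[:, np.newaxis]

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=sample_ids),
        pd.Series(dataset_labels, index=sample_ids),
    )
    hazards = {k + 1: [0.04, 0.01, 0.02][k % 3] for k in range(spec.n_subtypes)}
    truth = SyntheticTruth(
        sample_subtype=pd.Series(subtype, index=sample_ids),
        module_members=module_members,
        survival_hazard=hazards,
    )
    return expr, truth


def gen_signaling_network(n_nodes: int, edges_per_node: int, seed: int,
                          genes: list[str] | None = None) -> nx.Graph:
    """Connected scale-free (preferential attachment) signaling network.

    Node names are drawn from ``genes`` (first ``n_nodes`` of the cohort
    gene universe) or default to the standard synthetic gene names.
    """
    if not (n_nodes > edges_per_node >= 1):
        raise ValueError("need n_nodes > edges_per_node >= 1")
    graph = nx.barabasi_albert_graph(n_nodes, edges_per_node, seed=seed)
    names = (genes or _gene_names(n_nodes))[:n_nodes]
    if len(names) < n_nodes:
        raise ValueError("gene universe smaller than n_nodes")
    return nx.relabel_nodes(graph, dict(enumerate(names)))


def plant_driver_genes(network: nx.Graph, truth: SyntheticTruth,
                       n_per_subtype: int, seed: int) -> SyntheticTruth:
    """Plant one connected driver gene set per subtype into the truth.

    Each subtype's driver set is grown by breadth-first expansion from a
    random seed node, so it induces a connected subgraph; sets of
    different subtypes are kept disjoint where the network allows.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(network.nodes)
    taken: set = set()
    subtypes = sorted(set(truth.sample_subtype))
    for k in subtypes:
        free = [v for v in nodes if v not in taken]
        rng.shuffle(free)
        chosen: list = []
        for start in free:
            frontier = [start]
            chosen = []
            while frontier and len(chosen) < n_per_subtype:
                v = frontier.pop(0)
                if v in chosen or v in taken:
                    continue
                chosen.append(v)
                nbrs = sorted(n for n in network.neighbors(v)
                              if n not in chosen and n not in taken)
                rng.shuffle(nbrs)
                frontier.extend(nbrs)
            if len(chosen) == n_per_subtype:
                break
        if len(chosen) < n_per_subtype:
            raise ValueError("network too small/fragmented to plant disjoint "
                             "driver sets of the requested size")
        truth.driver_genes[k] = set(chosen)
        taken.update(chosen)
    return truth


def gen_alteration_data(network: nx.Graph, truth: SyntheticTruth,
                        background_rate: float, driver_rate: float,
                        seed: int):
    """Binary mutation and CNV matrices over the network's gene universe.

    For a sample of subtype k, genes in ``truth.driver_genes[k]`` are
    altered with probability ``driver_rate`` and every other gene with
    ``background_rate``; mutation and CNV calls are drawn independently.
    Returns (mut, cnv) as binary genes x samples DataFrames.
    """
    if not (0.0 <= background_rate < driver_rate <= 1.0):
        raise ValueError("need 0 <= background_rate < driver_rate <= 1")
    genes = sorted(network.nodes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for k, drivers in truth.driver_genes.items():
        missing = drivers - set(genes)
        if missing:
            raise ValueError(f"driver genes of subtype {k} absent from "
                             f"network: {sorted(missing)[:5]}")

    samples = list(truth.sample_subtype.index)
    probs = np.full((len(genes), len(samples)), background_rate)
    for j, s in enumerate(samples):
        k = truth.sample_subtype.loc[s]
        rows = [gene_pos[g] for g in sorted(truth.driver_genes.get(k, ()))]
        probs[rows, j] = driver_rate

    rng = np.random.default_rng(seed)
    mut = (rng.random(probs.shape) < probs).astype(np.int8)
    cnv = (rng.random(probs.shape) < probs).astype(np.int8)
    mut = pd.DataFrame(mut, index=genes, columns=samples)
    cnv = pd.DataFrame(cnv, index=genes, columns=samples)
    return mut, cnv


def gen_survival(truth: SyntheticTruth, censor_rate: float,
                 seed: int) -> pd.DataFrame:
    """Exponential survival with subtype-specific hazards.

    Event times are Exponential(hazard[subtype]); independent
    exponential censoring is calibrated so the expected censored
    fraction equals ``censor_rate`` (0 disables censoring). Returns a
    tidy (sample, time, event, group) table, time in months.
    """
    if any(h <= 0 for h in truth.survival_hazard.values()):
        raise ValueError("hazards must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for s, k in truth.sample_subtype.items():
        h = truth.survival_hazard[k]
        t_event = rng.exponential(1.0 / h)
        if censor_rate > 0:
            c_hazard = h * censor_rate / (1.0 - censor_rate)
            t_cens = rng.exponential(1.0 / c_hazard)
        else:
            t_cens = np.inf
        time = min(t_event, t_cens)
        rows.append((s, time, int(t_event <= t_cens), k))
    return pd.DataFrame(rows, columns=["sample", "time", "event", "group"])


def gen_ontology_and_annotations(n_terms: int, genes: list[str],
                                 truth: SyntheticTruth, seed: int):
    """Random rooted ontology DAG plus gene annotations.

    The DAG grows by preferential parenting under the root; each planted
    module gets a dedicated deep (information-rich) term annotated to
    its members, so within-module functional similarity exceeds
    between-module similarity by construction. All genes are annotated
    to the root. Edges point child -> parent.

    Returns (ontology: nx.DiGraph, annotations: gene -> term set).
    """
    if n_terms < 2:
        raise ValueError("need at least a root and one child term")
    rng = np.random.default_rng(seed)
    root = "T0000"
    onto = nx.DiGraph()
    onto.add_node(root, name="root")
    terms = [root]
    depth = {root: 0}
    n_generic = max(1, n_terms - 1 - len(truth.module_members))
    for i in range(1, n_generic + 1):
        t = f"T{i:04d}"
        parent = terms[rng.integers(len(terms))]
        onto.add_node(t, name=f"term {i}")
        onto.add_edge(t, parent)
        depth[t] = depth[parent] + 1
        terms.append(t)
        if rng.random() < 0.3 and len(terms) > 2:
            extra = terms[rng.integers(len(terms) - 1)]
            if extra != t and not nx.has_path(onto, extra, t):
                onto.add_edge(t, extra)

    # one dedicated leaf per planted module, hung under a deep term
    module_term: dict[str, str] = {}
    deep_parents = sorted(depth, key=lambda t: (-depth[t], t))
    for m, name in enumerate(sorted(truth.module_members)):
        t = f"T{n_generic + 1 + m:04d}"
        parent = deep_parents[m % max(1, len(deep_parents) // 2)]
        onto.add_node(t, name=f"module term {name}")
        onto.add_edge(t, parent)
        module_term[name] = t

    annotations: dict[str, set] = {g: {root} for g in genes}
    for name, members in truth.module_members.items():
        for g in members:
            if g in annotations:
                annotations[g].add(module_term[name])
    # every gene additionally carries one random generic term, so
    # cross-module pairs look like background pairs and only shared
    # module terms raise similarity
    generic_terms = [t for t in terms if t != root]
    for g in genes:
        if generic_terms:
            t = generic_terms[rng.integers(len(generic_terms))]
            annotations[g].add(t)
    return onto, annotations
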