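"""Cross-dataset expression preprocessing.

Multi-cohort microarray compendia cannot be compared on raw log2 scale:
each dataset carries platform- and site-specific offsets. The pipeline
therefore works on expression that has been (a) collapsed from probes to
gene symbols, (b) mean-centered per gene within each dataset, (c) merged
on the common gene universe, and optionally (d) re-centered against a set
of reference (e.g. normal mucosa) samples so that signed changes are
interpretable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "collapse_probes",
    "center_within_dataset",
    "merge_cohorts",
    "center_to_reference",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with per-sample dataset-of-origin.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol, columns are sample ids.
        Missing values are rejected: silent imputation would distort
        the correlation structure everything downstream relies on.
    dataset_of
        Series mapping sample id -> dataset label; must cover every
        sample in ``values``.
    """

    values: pd.DataFrame
    dataset_of: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene identifiers: {list(dup)[:5]}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample identifiers: {list(dup)[:5]}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values; "
                             "complete matrices are required")
        self.dataset_of = pd.Series(self.dataset_of)
        missing = self.values.columns.difference(self.dataset_of.index)
        if len(missing):
            raise ValueError(f"samples without a dataset label: {list(missing)[:5]}")
        self.dataset_of = self.dataset_of.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def datasets(self) -> list:
        return list(pd.unique(self.dataset_of))

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.dataset_of)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(self.values[samples], self.dataset_of.loc[samples])


def collapse_probes(probe_matrix: pd.DataFrame,
                    mapping: pd.DataFrame | dict,
                    dataset_of: pd.Series | None = None,
                    dataset: str | None = None) -> ExpressionMatrix:
    """Collapse a probes x samples matrix to genes x samples.

    Probes mapping to more than one gene are eliminated; when several
    probes map to the same gene the per-sample median represents the
    gene. Probes absent from the mapping are dropped.

    ``mapping`` is either a two-column (probe, gene) DataFrame with one
    row per pair, or a dict probe -> gene / iterable of genes.
    """
    if isinstance(mapping, dict):
        rows = []
        for probe, genes in mapping.items():
            if isinstance(genes, str):
                genes = [genes]
            for g in genes:
                rows.append((probe, g))
        map_df = pd.DataFrame(rows, columns=["probe", "gene"])
    else:
        map_df = mapping.copy()
        map_df.columns = ["probe", "gene"]

    map_df = map_df.drop_duplicates()
    n_genes_per_probe = map_df.groupby("probe")["gene"].nunique()
    ambiguous = n_genes_per_probe.index[n_genes_per_probe > 1]
    if len(ambiguous):
        logger.info("dropping %d probes mapped to multiple genes", len(ambiguous))
    unique_map = map_df[~map_df["probe"].isin(ambiguous)].set_index("probe")["gene"]

    keep = probe_matrix.index.intersection(unique_map.index)
    if keep.empty:
        raise ValueError("no probes left after multi-gene filtering / mapping")
    collapsed = probe_matrix.loc[keep].groupby(unique_map.loc[keep]).median()
    collapsed.index.name = "gene"

    if dataset_of is None:
        label = dataset if dataset is not None else "dataset0"
        dataset_of = pd.Series(label, index=collapsed.columns)
    return ExpressionMatrix(collapsed, dataset_of)


def center_within_dataset(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's within-dataset mean, per dataset independently.

    Removes additive dataset offsets so expression is comparable across
    cohorts. Idempotent.
    """
    out = expr.values.copy()
    for ds in expr.datasets:
        cols = expr.samples[expr.dataset_of.values == ds]
        if len(cols) == 0:
            continue
        block = out[cols]
        out[cols] = block.sub(block.mean(axis=1), axis=0)
    return ExpressionMatrix(out, expr.dataset_of)


def merge_cohorts(cohorts: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Merge cohorts on the intersection of their gene sets.

    Samples are concatenated and dataset labels preserved; duplicate
    sample ids across cohorts are an error.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts to merge")
    common = cohorts[0].genes
    for c in cohorts[1:]:
        common = common.intersection(c.genes)
    if common.empty:
        raise ValueError("gene intersection across cohorts is empty")
    common = common.sort_values()

    all_samples = pd.Index(np.concatenate([c.samples for c in cohorts]))
    if all_samples.has_duplicates:
        dup = all_samples[all_samples.duplicated()].unique()
        raise ValueError(f"duplicate sample ids across cohorts: {list(dup)[:5]}")

    values = pd.concat([c.values.loc[common] for c in cohorts], axis=1)
    dataset_of = pd.concat([c.dataset_of for c in cohorts])
    return ExpressionMatrix(values, dataset_of)


def center_to_reference(expr: ExpressionMatrix, reference_samples) -> ExpressionMatrix:
    """Center each gene by its mean over the given reference samples.

    Typically the reference set is normal tissue, so centered values read
    as tumor-vs-normal log ratios.
    """
    ref = pd.Index(reference_samples)
    if ref.empty:
        raise ValueError("reference sample set is empty")
    unknown = ref.difference(expr.samples)
    if len(unknown):
        raise ValueError(f"unknown reference samples: {list(unknown)[:5]}")
    ref_mean = expr.values[ref].mean(axis=1)
    return ExpressionMatrix(expr.values.sub(ref_mean, axis=0), expr.dataset_of)
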