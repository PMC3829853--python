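"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression travels as tab-delimited genes x samples matrices with a
sidecar sample-annotation table; networks as two-column edge lists (a
SIF dialect is also read); gene sets as GMT; ontologies as OBO
(parsed with obonet); annotations as a two-column gene->term table;
mutations as a minimal MAF-like long table; survival as a tidy
(sample, time, event, group) table.
"""

from __future__ import annotations

import networkx as nx
import obonet
import pandas as pd

from .preprocess import ExpressionMatrix

__all__ = [
    "read_expression", "write_expression",
    "read_probe_mapping",
    "read_edge_list", "write_edge_list",
    "read_gmt", "write_gmt",
    "read_obo", "write_obo",
    "read_annotations", "write_annotations",
    "read_maf", "read_matrix", "write_matrix",
    "read_survival", "write_survival",
]


# ---------------------------------------------------------------- expression

def read_expression(matrix_path, annotation_path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a (sample, dataset) annotation TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    ann = pd.read_csv(annotation_path, sep="\t")
    dataset_of = ann.set_index(ann.columns[0])[ann.columns[1]]
    return ExpressionMatrix(values, dataset_of)


def write_expression(expr: ExpressionMatrix, matrix_path, annotation_path,
                     extra_annotations: pd.DataFrame | None = None) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="gene")
    ann = pd.DataFrame({"sample": expr.samples,
                        "dataset": expr.dataset_of.values})
    if extra_annotations is not None:
        ann = ann.merge(extra_annotations, left_on="sample",
                        right_index=True, how="left")
    ann.to_csv(annotation_path, sep="\t", index=False)


def read_probe_mapping(path) -> pd.DataFrame:
    """Read a (probe, gene) pair table, one row per pair."""
    df = pd.read_csv(path, sep="\t")
    df.columns = ["probe", "gene"]
    return df


# ------------------------------------------------------------------ networks

def read_edge_list(path) -> nx.Graph:
    """Read an undirected network from a 2- or 3-column tab-delimited file.

    Two columns are (geneA, geneB); three columns are either
    (geneA, geneB, weight) or the SIF dialect (geneA, interaction, geneB),
    distinguished by whether the middle/last column parses as a number.
    """
    graph = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or parts[0].startswith("#"):
                continue
            if len(parts) == 2:
                graph.add_edge(parts[0], parts[1])
            else:
                try:
                    w = float(parts[2])
                    graph.add_edge(parts[0], parts[1], weight=w)
                except ValueError:
                    # SIF: source, interaction type, target(s)
                    for target in parts[2:]:
                        graph.add_edge(parts[0], target)
    return graph


def write_edge_list(graph: nx.Graph, path, weight: str | None = "weight") -> None:
    with open(path, "w") as fh:
        for a, b, data in graph.edges(data=True):
            if weight is not None and weight in data:
                fh.write(f"{a}\t{b}\t{data[weight]:.6g}\n")
            else:
                fh.write(f"{a}\t{b}\n")


# --------------------------------------------------------------------- GMT

def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection: name, description, members."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# --------------------------------------------------------------- ontologies

def read_obo(path) -> nx.MultiDiGraph:
    """Parse an OBO ontology; edges point child -> parent (obonet convention)."""
    return obonet.read_obo(path)


def write_obo(ontology: nx.DiGraph, path, name: str = "synthetic-ontology") -> None:
    """Write a DAG whose edges point child -> parent as minimal OBO."""
    with open(path, "w") as fh:
        fh.write(f"format-version: 1.2\nontology: {name}\n\n")
        for term in sorted(ontology.nodes):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {ontology.nodes[term].get('name', term)}\n")
            for parent in sorted(ontology.successors(term)):
                fh.write(f"is_a: {parent}\n")
            fh.write("\n")


def read_annotations(path) -> dict[str, set[str]]:
    """Read a two-column (gene, term) table into gene -> term-set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"],
                     comment="!")
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        out.setdefault(gene, set()).add(term)
    return out


def write_annotations(annotations: dict, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


# ------------------------------------------------------- alterations & misc

def read_maf(path) -> pd.DataFrame:
    """Read a MAF-like long table with columns sample, gene, variant_class."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    required = {"sample", "gene", "variant_class"}
    if not required.issubset(df.columns):
        raise ValueError(f"MAF-like table needs columns {sorted(required)}")
    return df[["sample", "gene", "variant_class"]]


def read_matrix(path) -> pd.DataFrame:
    """Read a generic gene x sample numeric TSV (CNV ratios, binary calls)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError("matrix contains missing values")
    return df


def write_matrix(df: pd.DataFrame, path, index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    if not {"sample", "time", "event"}.issubset(df.columns):
        raise ValueError("survival table needs columns sample, time, event")
    return df


def write_survival(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
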