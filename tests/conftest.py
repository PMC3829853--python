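import networkx as nx
import numpy as np
import pandas as pd
import pytest

from crcnet.preprocess import ExpressionMatrix
from crcnet.synthetic import (SyntheticCohortSpec, SyntheticTruth,
                              gen_expression_cohort,
                              gen_ontology_and_annotations)


@pytest.fixture(scope="session")
def default_cohort():
    """The standard synthetic cohort at its default settings."""
    spec = SyntheticCohortSpec(seed=1)
    expr, truth = gen_expression_cohort(spec)
    return spec, expr, truth


@pytest.fixture(scope="session")
def default_ontology(default_cohort):
    _, expr, truth = default_cohort
    return gen_ontology_and_annotations(60, list(expr.genes), truth, seed=11)


@pytest.fixture
def toy_dag():
    """Hand-built 5-term DAG (child -> parent edges) with annotations.

    root
    ├── A ── C (C is_a A)
    │        └ (C is_a B too: diamond)
    └── B ── D
    Genes: g1:{C}, g2:{C}, g3:{D}, g4:{A}, g5:{root}
    """
    onto = nx.DiGraph()
    onto.add_edges_from([("A", "root"), ("B", "root"),
                         ("C", "A"), ("C", "B"), ("D", "B")])
    annotations = {"g1": {"C"}, "g2": {"C"}, "g3": {"D"},
                   "g4": {"A"}, "g5": {"root"}}
    return onto, annotations


def make_expression(values, sample_prefix="s", dataset="d1", genes=None):
    """Small helper to build an ExpressionMatrix from an array."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"{sample_prefix}{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(df, pd.Series(dataset, index=samples))


@pytest.fixture
def expr_factory():
    return make_expression
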