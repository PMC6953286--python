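import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cohortsig.datatypes import CovariateTable, FeatureMatrix


@pytest.fixture
def two_triangles() -> nx.Graph:
    """Two unweighted triangles joined by a single bridge edge."""
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
    return g


@pytest.fixture
def two_four_cliques() -> nx.Graph:
    """Two 4-cliques joined by one edge; optimum partition = the cliques."""
    g = nx.Graph()
    for base in (0, 4):
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(base + i, base + j)
    g.add_edge(3, 4)
    return g


@pytest.fixture
def small_matrix() -> FeatureMatrix:
    rng = np.random.default_rng(7)
    n = 60
    values = pd.DataFrame(
        {
            "met_a": rng.normal(size=n),
            "met_b": rng.normal(size=n),
            "lab_a": rng.normal(size=n),
            "micro_a": rng.dirichlet(np.ones(3), size=n)[:, 0],
        },
        index=[f"S{i}" for i in range(n)],
    )
    modality = pd.Series(
        ["metabolome", "metabolome", "clinical_labs", "microbiome"],
        index=values.columns,
    )
    return FeatureMatrix(values, modality)


@pytest.fixture
def covariates_for(small_matrix) -> CovariateTable:
    rng = np.random.default_rng(11)
    n = len(small_matrix.sample_ids)
    return CovariateTable(
        pd.DataFrame(
            {
                "age": rng.normal(size=n),
                "sex": rng.integers(0, 2, n).astype(float),
                "pc1": rng.normal(size=n),
                "pc2": rng.normal(size=n),
                "pc3": rng.normal(size=n),
                "pc4": rng.normal(size=n),
            },
            index=small_matrix.sample_ids,
        )
    )
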