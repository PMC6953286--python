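"""Plain-text readers/writers for the pipeline's tabular interfaces.

Feature matrix: TSV with samples as rows, a ``sample_id`` index column and
one column per feature; empty cells are missing. Modality map: two-column
TSV (feature_id, modality). Covariates: TSV with sample_id, age, sex,
pc1..pc4. Preprocess models are JSON; edge lists and assignments are TSV.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .datatypes import CovariateTable, FeatureMatrix
from .preprocess import PreprocessModel


def write_feature_matrix(fm: FeatureMatrix, matrix_path, modality_path) -> None:
    fm.values.to_csv(matrix_path, sep="\t", index_label="sample_id")
    fm.modality_of.rename("modality").to_csv(
        modality_path, sep="\t", index_label="feature_id"
    )


def read_feature_matrix(matrix_path, modality_path) -> FeatureMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col="sample_id")
    values.index.name = None
    modality = pd.read_csv(modality_path, sep="\t", index_col="feature_id")["modality"]
    modality.index.name = None
    return FeatureMatrix(values, modality)


def write_covariates(cov: CovariateTable, path) -> None:
    cov.table.to_csv(path, sep="\t", index_label="sample_id")


def read_covariates(path) -> CovariateTable:
    table = pd.read_csv(path, sep="\t", index_col="sample_id")
    table.index.name = None
    return CovariateTable(table)


def write_preprocess_model(model: PreprocessModel, path) -> None:
    Path(path).write_text(model.to_json())


def read_preprocess_model(path) -> PreprocessModel:
    return PreprocessModel.from_json(Path(path).read_text())


def write_edge_list(network: nx.Graph, path) -> None:
    rows = [
        {
            "feature_a": u,
            "feature_b": v,
            "modality_a": network.nodes[u]["modality"],
            "modality_b": network.nodes[v]["modality"],
            "rho": d["rho"],
            "p": d["p"],
            "n_used": d["n_used"],
            "weight": d["weight"],
            "excluded": d["excluded"],
        }
        for u, v, d in network.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_graphml(network: nx.Graph, path) -> None:
    nx.write_graphml(network, path)


def write_assignments(subset_of: pd.Series, distances: pd.DataFrame | None,
                      path) -> None:
    out = subset_of.rename("subset").to_frame()
    if distances is not None:
        out = out.join(distances.add_prefix("dist_subset_"))
    out.to_csv(path, sep="\t", index_label="sample_id")


def write_memberships(memberships: dict, path) -> None:
    rows = [
        {"feature_id": node, "module_ids": ",".join(map(str, sorted(mods)))}
        for node, mods in sorted(memberships.items(), key=lambda kv: str(kv[0]))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
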