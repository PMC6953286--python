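"""Cross-modality Spearman association network.

For every unordered pair of features from *different* modalities, Spearman's
rho is computed on the individuals for which both features are present
(average ranks for ties), with a two-sided p-value from the t approximation.
Pairs with fewer than ``min_pairs`` complete observations (default 30) are
skipped. Significance is decided by one global Benjamini-Hochberg family at
FDR ``q`` over all computed pairs. Significant pairs become edges of an
undirected network weighted by -ln(p) (p floored at 1e-300); edges between
designated modality pairs (metabolome vs clinical labs by default) are kept
in the structure but flagged as excluded from community detection, so those
dominant associations do not dictate the module structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import FeatureMatrix

P_FLOOR = 1e-300
DEFAULT_MIN_PAIRS = 30
DEFAULT_EXCLUDED_MODALITY_PAIRS = (("metabolome", "clinical_labs"),)


@dataclass
class AssociationResult:
    """All computed cross-modality associations plus skip bookkeeping."""

    table: pd.DataFrame  # feature_a, feature_b, modality_a/b, rho, p, n_used
    n_computed: int
    n_skipped: int
    skipped: pd.DataFrame = field(default_factory=pd.DataFrame)


def _rho_p_from_ranks(ra: np.ndarray, rb: np.ndarray) -> tuple[float, float, int]:
    n = ra.size
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra @ ra) * (rb @ rb))
    if denom == 0.0:
        return np.nan, np.nan, n
    rho = float(np.clip((ra @ rb) / denom, -1.0, 1.0))
    if n <= 2:
        return rho, np.nan, n
    if abs(rho) >= 1.0:
        return rho, 0.0, n
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p, n


def spearman_pairwise(
    matrix: FeatureMatrix, min_pairs: int = DEFAULT_MIN_PAIRS
) -> AssociationResult:
    """Spearman rho/p for every cross-modality feature pair.

    Complete columns share precomputed ranks (vectorized inner products);
    pairs touched by missingness are re-ranked on their complete cases, as
    Spearman on pairwise-complete data requires.
    """
    if min_pairs < 3:
        raise ValueError("min_pairs must be >= 3")
    x = matrix.values.to_numpy(dtype=float)
    cols = matrix.feature_ids
    mods = matrix.modality_of.to_numpy()
    obs = ~np.isnan(x)
    complete = obs.all(axis=0)
    ranks = np.full_like(x, np.nan)
    for j in np.flatnonzero(complete):
        ranks[:, j] = stats.rankdata(x[:, j], method="average")
    if complete.all():
        return _spearman_complete(ranks, cols, mods)
    rows, skip_rows = [], []
    for i, j in itertools.combinations(range(len(cols)), 2):
        if mods[i] == mods[j]:
            continue
        if complete[i] and complete[j]:
            rho, p, n = _rho_p_from_ranks(ranks[:, i], ranks[:, j])
        else:
            shared = obs[:, i] & obs[:, j]
            n = int(shared.sum())
            if n < min_pairs:
                skip_rows.append((cols[i], cols[j], n, "n_below_min"))
                continue
            ra = stats.rankdata(x[shared, i], method="average")
            rb = stats.rankdata(x[shared, j], method="average")
            rho, p, n = _rho_p_from_ranks(ra, rb)
        if n < min_pairs:
            skip_rows.append((cols[i], cols[j], n, "n_below_min"))
            continue
        if np.isnan(rho):
            skip_rows.append((cols[i], cols[j], n, "zero_variance"))
            continue
        rows.append((cols[i], cols[j], mods[i], mods[j], rho, p, n))
    table = pd.DataFrame(
        rows,
        columns=["feature_a", "feature_b", "modality_a", "modality_b",
                 "rho", "p", "n_used"],
    )
    skipped = pd.DataFrame(
        skip_rows, columns=["feature_a", "feature_b", "n_used", "reason"]
    )
    return AssociationResult(
        table=table, n_computed=len(table), n_skipped=len(skipped), skipped=skipped
    )


def _spearman_complete(ranks: np.ndarray, cols, mods) -> AssociationResult:
    """Vectorized path when no column has missing values: one rank
    correlation matrix serves every cross-modality pair."""
    n = ranks.shape[0]
    z = ranks - ranks.mean(axis=0)
    norms = np.sqrt((z * z).sum(axis=0))
    constant = norms == 0
    norms[constant] = 1.0
    corr = np.clip((z / norms).T @ (z / norms), -1.0, 1.0)
    ii, jj = np.triu_indices(len(cols), 1)
    cross = mods[ii] != mods[jj]
    ii, jj = ii[cross], jj[cross]
    bad = constant[ii] | constant[jj]
    rho = corr[ii, jj]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho * rho, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    col_arr = np.asarray(cols, dtype=object)
    table = pd.DataFrame(
        {
            "feature_a": col_arr[ii[~bad]],
            "feature_b": col_arr[jj[~bad]],
            "modality_a": mods[ii[~bad]],
            "modality_b": mods[jj[~bad]],
            "rho": rho[~bad],
            "p": p[~bad],
            "n_used": n,
        }
    )
    skipped = pd.DataFrame(
        {
            "feature_a": col_arr[ii[bad]],
            "feature_b": col_arr[jj[bad]],
            "n_used": n,
            "reason": "zero_variance",
        }
    )
    return AssociationResult(
        table=table, n_computed=len(table), n_skipped=len(skipped), skipped=skipped
    )


def bh_select(p_values: np.ndarray | pd.Series, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up selection flags over one family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def build_network(
    edges: pd.DataFrame,
    exclude_modality_pairs=DEFAULT_EXCLUDED_MODALITY_PAIRS,
    known_modalities=None,
) -> nx.Graph:
    """Assemble the weighted association network from significant pairs.

    Nodes are the features incident to at least one significant edge, with
    their modality as a node attribute. Edge weight is -ln(p) with p floored
    at 1e-300. Edges joining a modality pair in ``exclude_modality_pairs``
    get ``excluded=True`` (kept in the graph, ignored by module detection).
    """
    exclude = {frozenset(p) for p in exclude_modality_pairs}
    present = set(edges["modality_a"]) | set(edges["modality_b"])
    if known_modalities is not None:
        present = present | set(known_modalities)
    for pair in exclude:
        unknown = pair - present
        if unknown:
            raise ValueError(f"unknown modality in exclusion list: {sorted(unknown)}")
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        a, b = sorted((row.feature_a, row.feature_b))
        weight = float(-np.log(max(row.p, P_FLOOR)))
        mod_a = row.modality_a if a == row.feature_a else row.modality_b
        mod_b = row.modality_b if a == row.feature_a else row.modality_a
        g.add_node(a, modality=mod_a)
        g.add_node(b, modality=mod_b)
        g.add_edge(
            a, b,
            rho=float(row.rho), p=float(row.p), n_used=int(row.n_used),
            weight=weight,
            excluded=frozenset((row.modality_a, row.modality_b)) in exclude,
        )
    return g


def detection_graph(network: nx.Graph) -> nx.Graph:
    """The network with excluded-for-modules edges removed (nodes kept)."""
    g = network.copy()
    g.remove_edges_from(
        [(u, v) for u, v, d in g.edges(data=True) if d.get("excluded", False)]
    )
    return g


def significant_association_network(
    matrix: FeatureMatrix,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    q: float = 0.05,
    exclude_modality_pairs=DEFAULT_EXCLUDED_MODALITY_PAIRS,
) -> tuple[nx.Graph, AssociationResult]:
    """Convenience wrapper: associations -> BH selection -> network."""
    assoc = spearman_pairwise(matrix, min_pairs=min_pairs)
    if len(assoc.table):
        selected = bh_select(assoc.table["p"].to_numpy(), q=q)
        edges = assoc.table.loc[selected]
    else:
        edges = assoc.table
    net = build_network(
        edges,
        exclude_modality_pairs=exclude_modality_pairs,
        known_modalities=set(matrix.modality_of),
    )
    return net, assoc
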