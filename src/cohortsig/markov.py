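"""Key-biomarker selection through a Graphical-Lasso Markov network.

For a chosen correlation module: rank its features by weighted eigenvector
centrality, keep the top-k central features, mean-impute then rank-INT
their data, and estimate a sparse precision (inverse covariance) matrix by
Graphical Lasso. Edges of the resulting conditional-independence network
include within-modality pairs; the key biomarkers are the features that
retain at least one edge to a feature from a *different* modality, so that
strong within-modality dependence cannot crowd out cross-modal structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

from .preprocess import rank_int

EDGE_TOL = 1e-8
EBIC_GAMMA = 0.5


@dataclass
class CentralityRanking:
    scores: dict  # node -> eigenvector centrality, max-normalized to 1
    order: list  # nodes sorted by descending score, ties by node id


@dataclass
class MarkovNetwork:
    nodes: list
    modality_of: pd.Series
    precision: pd.DataFrame
    penalty: float
    edge_tol: float = EDGE_TOL

    @property
    def edges(self) -> list[tuple]:
        """(a, b, partial_correlation) for every retained edge."""
        theta = self.precision.to_numpy()
        d = np.sqrt(np.diag(theta))
        out = []
        for i in range(len(self.nodes)):
            for j in range(i + 1, len(self.nodes)):
                if abs(theta[i, j]) > self.edge_tol:
                    pcor = -theta[i, j] / (d[i] * d[j])
                    out.append((self.nodes[i], self.nodes[j], float(pcor)))
        return out

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n, modality=self.modality_of[n])
        for a, b, pcor in self.edges:
            g.add_edge(a, b, partial_correlation=pcor)
        return g


@dataclass
class KeyBiomarkerSet:
    biomarkers: list
    pre_override: list
    overrides: dict = field(default_factory=dict)


def eigenvector_centrality(graph: nx.Graph, weighted: bool = True,
                           tol: float = 1e-10,
                           max_iter: int = 100000) -> CentralityRanking:
    """Leading-eigenvector centrality by power iteration.

    Scores are computed on the largest connected component (ties broken by
    smallest node id); nodes outside it score 0. Entries are non-negative
    and max-normalized to 1. Order sorts by descending score, then node id.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("centrality undefined on an empty graph")
    components = sorted(
        nx.connected_components(graph), key=lambda c: (-len(c), min(map(str, c)))
    )
    main = sorted(components[0], key=str)
    scores = {n: 0.0 for n in graph.nodes}
    if len(main) == 1:
        scores[main[0]] = 1.0
    else:
        a = nx.to_numpy_array(
            graph.subgraph(main), nodelist=main,
            weight="weight" if weighted else None,
        )
        v = np.ones(len(main)) / np.sqrt(len(main))
        for _ in range(max_iter):
            # shifted iteration (A + I) avoids oscillation on bipartite
            # components while preserving the leading eigenvector
            nv = a @ v + v
            norm = np.linalg.norm(nv)
            if norm == 0:
                break
            nv /= norm
            if np.abs(nv - v).max() < tol:
                v = nv
                break
            v = nv
        v = np.abs(v)
        v /= v.max()
        scores.update({n: float(s) for n, s in zip(main, v)})
    order = sorted(scores, key=lambda n: (-scores[n], str(n)))
    return CentralityRanking(scores=scores, order=order)


def select_central_features(ranking: CentralityRanking, k: int) -> list:
    """Top-k features by centrality with the deterministic tie-break."""
    if k < 2 or k > len(ranking.order):
        raise ValueError("k must satisfy 2 <= k <= module size")
    return list(ranking.order[:k])


def impute_and_transform(values: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Mean-impute each feature, then rank-INT; returns the matrix and the
    fraction of cells that required imputation."""
    arr = values.to_numpy(dtype=float, copy=True)
    missing = np.isnan(arr)
    if missing.all(axis=0).any():
        bad = values.columns[missing.all(axis=0)]
        raise ValueError(f"all-missing features: {list(bad)[:5]}")
    frac = float(missing.mean())
    col_means = np.nanmean(arr, axis=0)
    idx = np.where(missing)
    arr[idx] = col_means[idx[1]]
    out = np.column_stack([rank_int(arr[:, j]) for j in range(arr.shape[1])])
    return pd.DataFrame(out, index=values.index, columns=values.columns), frac


def _glasso_precision(s: np.ndarray, lam: float) -> np.ndarray:
    if lam == 0.0:
        return np.linalg.inv(s)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # near-converged small-lambda fits warn; the EBIC scan never keeps them
        _warnings.simplefilter("ignore")
        _, precision = _sk_graphical_lasso(s, alpha=lam, max_iter=500, tol=1e-8)
    return precision


def _ebic(s: np.ndarray, theta: np.ndarray, n: int, gamma: float,
          edge_tol: float) -> float:
    p = s.shape[0]
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    loglik = 0.5 * n * (logdet - np.trace(s @ theta))
    iu = np.triu_indices(p, 1)
    n_edges = int(np.sum(np.abs(theta[iu]) > edge_tol))
    return -2.0 * loglik + n_edges * np.log(n) + 4.0 * gamma * n_edges * np.log(p)


def graphical_lasso(
    data: pd.DataFrame,
    penalty: float | str = "ebic",
    modality_of: pd.Series | None = None,
    edge_tol: float = EDGE_TOL,
    ebic_gamma: float = EBIC_GAMMA,
    n_lambdas: int = 15,
) -> MarkovNetwork:
    """Sparse precision estimate over a complete, Gaussianized matrix.

    Minimizes -logdet(Theta) + tr(S Theta) + lambda * sum_{i != j} |Theta_ij|
    over positive-definite matrices. ``penalty`` is a fixed lambda >= 0, or
    ``"ebic"`` to pick lambda on a log grid by the extended BIC
    (gamma = ``ebic_gamma``).
    """
    if data.isna().any().any():
        raise ValueError("graphical_lasso requires a complete matrix")
    n, p = data.shape
    if n <= 3:
        raise ValueError("need more than 3 samples")
    x = data.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    s = (x.T @ x) / n
    if isinstance(penalty, str):
        if penalty != "ebic":
            raise ValueError("penalty must be a float or 'ebic'")
        lam_max = np.abs(s - np.diag(np.diag(s))).max()
        lam_max = max(lam_max, 1e-3)
        grid = np.logspace(np.log10(lam_max), np.log10(0.01 * lam_max), n_lambdas)
        best_lam, best_score, best_theta = None, np.inf, None
        worse_in_a_row = 0
        for lam in grid:
            try:
                theta = _glasso_precision(s, float(lam))
            except FloatingPointError:
                continue
            score = _ebic(s, theta, n, ebic_gamma, edge_tol)
            if score < best_score:
                best_lam, best_score, best_theta = float(lam), score, theta
                worse_in_a_row = 0
            else:
                # the EBIC path is effectively unimodal in lambda; once it
                # deteriorates repeatedly, the remaining (slow, dense) fits
                # at smaller lambda cannot win
                worse_in_a_row += 1
                if worse_in_a_row >= 3:
                    break
        lam, theta = best_lam, best_theta
    else:
        lam = float(penalty)
        if lam < 0:
            raise ValueError("penalty must be >= 0")
        theta = _glasso_precision(s, lam)
    theta = 0.5 * (theta + theta.T)
    if modality_of is None:
        modality_of = pd.Series("unknown", index=data.columns)
    precision = pd.DataFrame(theta, index=data.columns, columns=data.columns)
    return MarkovNetwork(
        nodes=list(data.columns),
        modality_of=modality_of.reindex(data.columns),
        precision=precision,
        penalty=lam,
        edge_tol=edge_tol,
    )


def select_key_biomarkers(
    network: MarkovNetwork,
    overrides: Mapping[str, str] | None = None,
    available_features: Sequence[str] | None = None,
) -> KeyBiomarkerSet:
    """Features with >= 1 Markov edge to a different modality.

    ``overrides`` replaces a selected biomarker by a stated stand-in (e.g.
    a near-interchangeable measurement preferred on expert grounds); the
    replacement must exist among ``available_features`` when given.
    """
    overrides = dict(overrides or {})
    mods = network.modality_of
    keep = set()
    for a, b, _ in network.edges:
        if mods[a] != mods[b]:
            keep.add(a)
            keep.add(b)
    pre = sorted(keep, key=str)
    post = list(pre)
    for old, new in overrides.items():
        if old not in keep:
            continue
        universe = set(available_features) if available_features is not None else None
        if universe is not None and new not in universe:
            raise KeyError(f"override replacement {new!r} not in available features")
        post = [new if f == old else f for f in post]
    return KeyBiomarkerSet(biomarkers=post, pre_override=pre, overrides=overrides)
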