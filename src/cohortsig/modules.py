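"""Consensus Louvain community detection with robustness scores.

Louvain is run ``n_runs`` times (seeds 1..n_runs); a consensus matrix
counts how often each node pair lands in the same module; the consensus
partition is the maximum-modularity run (ties to the lowest seed). A node
gains additional module memberships when it has at least ``margin`` more
significant associations with another module than with its own. The
per-module consistency score is the mean co-assignment frequency over the
module's feature pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import detection_graph

DEFAULT_N_RUNS = 300
DEFAULT_MARGIN = 20


@dataclass
class ModulePartition:
    assignment: dict  # node -> module id (0-based, renumbered by size)
    modularity: float
    seed: int


@dataclass
class ModuleSet:
    consensus: ModulePartition
    memberships: dict  # node -> set of module ids (after expansion)
    consensus_matrix: pd.DataFrame
    n_runs: int
    run_modularities: list[float] = field(default_factory=list)

    def module_nodes(self, module_id: int) -> list:
        return sorted(
            n for n, m in self.consensus.assignment.items() if m == module_id
        )

    def modules_by_size(self) -> list[tuple[int, int]]:
        """(module id, node count), largest first, ties by module id."""
        counts: dict[int, int] = {}
        for m in self.consensus.assignment.values():
            counts[m] = counts.get(m, 0) + 1
        return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def consistency(self, module_id: int) -> float:
        return consistency_score(
            self.consensus_matrix, self.module_nodes(module_id), self.n_runs
        )


def modularity(graph: nx.Graph, assignment: dict, weight: str = "weight") -> float:
    """Weighted Newman modularity Q = sum_c [W_c/W - (S_c/2W)^2].

    ``W`` is the total edge weight, ``W_c`` the intra-community weight and
    ``S_c`` the summed node strength of community ``c``.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("modularity undefined on an empty graph")
    uncovered = set(graph.nodes) - set(assignment)
    if uncovered:
        raise ValueError(f"assignment misses nodes: {sorted(uncovered)[:5]}")
    w_total = sum(d.get(weight, 1.0) for _, _, d in graph.edges(data=True))
    if w_total == 0:
        return 0.0
    intra: dict = {}
    strength: dict = {}
    for u, v, d in graph.edges(data=True):
        w = d.get(weight, 1.0)
        strength[assignment[u]] = strength.get(assignment[u], 0.0) + w
        strength[assignment[v]] = strength.get(assignment[v], 0.0) + w
        if assignment[u] == assignment[v]:
            intra[assignment[u]] = intra.get(assignment[u], 0.0) + w
    q = 0.0
    communities = set(assignment[n] for n in graph.nodes)
    for c in communities:
        q += intra.get(c, 0.0) / w_total - (strength.get(c, 0.0) / (2 * w_total)) ** 2
    return q


def _renumber_by_size(communities: list[set]) -> dict:
    """Stable module ids: 0 = largest community (ties by smallest node id)."""
    ordered = sorted(communities, key=lambda c: (-len(c), min(map(str, c))))
    return {node: i for i, com in enumerate(ordered) for node in com}


def louvain_partition(graph: nx.Graph, seed: int,
                      weight: str = "weight") -> ModulePartition:
    """One seeded Louvain run on the module-detection graph.

    The graph must already have excluded-for-modules edges removed (see
    :func:`cohortsig.network.detection_graph`); isolated nodes become their
    own modules.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty graph")
    communities = nx.community.louvain_communities(graph, weight=weight, seed=seed)
    assignment = _renumber_by_size([set(c) for c in communities])
    q = modularity(graph, assignment, weight=weight)
    return ModulePartition(assignment=assignment, modularity=q, seed=seed)


def run_consensus(network: nx.Graph, n_runs: int = DEFAULT_N_RUNS,
                  margin: int = DEFAULT_MARGIN,
                  weight: str = "weight") -> ModuleSet:
    """Seeded repeat Louvain runs -> consensus matrix, best-Q partition,
    and multi-membership expansion.

    Seeds 1..n_runs are used in order; the consensus partition is the run
    with maximal modularity (tie broken toward the lowest seed).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    g = detection_graph(network)
    nodes = sorted(g.nodes, key=str)
    index = {n: i for i, n in enumerate(nodes)}
    counts = np.zeros((len(nodes), len(nodes)), dtype=np.int32)
    best: ModulePartition | None = None
    run_q: list[float] = []
    for seed in range(1, n_runs + 1):
        part = louvain_partition(g, seed=seed, weight=weight)
        run_q.append(part.modularity)
        groups: dict[int, list[int]] = {}
        for node, m in part.assignment.items():
            groups.setdefault(m, []).append(index[node])
        for idxs in groups.values():
            ix = np.asarray(idxs)
            counts[np.ix_(ix, ix)] += 1
        if best is None or part.modularity > best.modularity:
            best = part
    consensus_matrix = pd.DataFrame(counts, index=nodes, columns=nodes)
    memberships = expand_multimembership(g, best, margin=margin)
    return ModuleSet(
        consensus=best,
        memberships=memberships,
        consensus_matrix=consensus_matrix,
        n_runs=n_runs,
        run_modularities=run_q,
    )


def expand_multimembership(graph: nx.Graph, partition: ModulePartition,
                           margin: int = DEFAULT_MARGIN) -> dict:
    """Multi-membership rule on unweighted significant-edge degree.

    A node assigned to module M additionally joins module M' when
    deg(node -> M') - deg(node -> M) >= margin. The original assignment is
    never removed.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    assignment = partition.assignment
    memberships: dict = {}
    for node in graph.nodes:
        own = assignment[node]
        deg_to: dict[int, int] = {}
        for nbr in graph.neighbors(node):
            m = assignment[nbr]
            deg_to[m] = deg_to.get(m, 0) + 1
        members = {own}
        own_deg = deg_to.get(own, 0)
        for m, deg in deg_to.items():
            if m != own and deg - own_deg >= margin:
                members.add(m)
        memberships[node] = members
    return memberships


def consistency_score(consensus_matrix: pd.DataFrame, feature_set,
                      n_runs: int) -> float:
    """Mean pairwise co-assignment frequency of ``feature_set``, in [0, 1]."""
    features = sorted(set(feature_set), key=str)
    if len(features) < 2:
        raise ValueError("consistency score requires >= 2 features")
    total = 0.0
    n_pairs = 0
    for a, b in itertools.combinations(features, 2):
        total += consensus_matrix.loc[a, b] / n_runs
        n_pairs += 1
    return total / n_pairs
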