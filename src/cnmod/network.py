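"""Interaction-network construction and module detection.

The graph is built from a STRING-style weighted edge list: edges with
combined score strictly greater than the threshold (default 0.4) are
kept, duplicate unordered pairs collapse to their maximum score, and
every catalog gene is a node even when isolated.  Modules are found by
greedy multilevel (Louvain) maximization of resolution-parameterized
modularity

    Q_r = (1/2m) * sum_ij [A_ij - r * k_i k_j / (2m)] * delta(c_i, c_j)

with the resolution ``r`` multiplying the null-model term
(Reichardt-Bornholdt convention, as in Gephi).  The best of
``n_restarts`` seeded runs is returned, with modules relabeled 1..K by
descending size (ties broken by smallest contained gene id) so results
are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ModulePartition",
    "build_graph",
    "detect_modules",
    "module_contributions",
    "module_composition",
]


@dataclass
class ModulePartition:
    """Disjoint assignment of genes to modules 1..K.

    ``membership`` maps gene id to module id; ``modularity`` is Q_r of
    the stored partition on the filtered graph at ``resolution``.
    """

    membership: dict[str, int]
    modularity: float
    resolution: float

    @property
    def n_modules(self) -> int:
        return len(set(self.membership.values()))

    @property
    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for m in self.membership.values():
            sizes[m] = sizes.get(m, 0) + 1
        return dict(sorted(sizes.items()))

    def genes_in(self, module_id: int) -> list[str]:
        return sorted(g for g, m in self.membership.items() if m == module_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.membership.items()), columns=["gene_id", "module_id"]
        )


def build_graph(
    edges: pd.DataFrame, catalog: pd.DataFrame, threshold: float = 0.4
) -> nx.Graph:
    """Filtered undirected interaction graph over the catalog universe.

    Keeps edges with ``combined_score`` strictly above ``threshold``;
    self-loops are dropped and duplicate unordered pairs collapse to the
    maximum score.  Edge gene ids must all occur in the catalog.
    """
    if len(catalog) == 0:
        raise ValueError("empty gene catalog")
    required = {"gene_a", "gene_b", "combined_score"}
    missing = required - set(edges.columns)
    if missing:
        raise ValueError(f"edge list missing columns: {sorted(missing)}")
    scores = edges["combined_score"].to_numpy(dtype=float)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("combined scores must lie in [0, 1]")
    genes = set(catalog["gene_id"])
    seen = set(edges["gene_a"]) | set(edges["gene_b"])
    unknown = sorted(seen - genes)
    if unknown:
        raise ValueError(f"edge list references genes absent from catalog: {unknown}")

    G = nx.Graph()
    G.add_nodes_from(catalog["gene_id"])
    for a, b, s in edges[["gene_a", "gene_b", "combined_score"]].itertuples(index=False):
        if a == b or s <= threshold:
            continue
        if G.has_edge(a, b):
            G[a][b]["weight"] = max(G[a][b]["weight"], float(s))
        else:
            G.add_edge(a, b, weight=float(s))
    return G


def _relabel(communities: list[set[str]]) -> dict[str, int]:
    # descending size, ties by smallest contained gene id
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    return {g: i + 1 for i, c in enumerate(ordered) for g in c}


def detect_modules(
    graph: nx.Graph,
    resolution: float = 0.8,
    n_restarts: int = 20,
    seed: int = 0,
) -> ModulePartition:
    """Best-of-restarts Louvain partition at the given resolution.

    Each restart runs seeded Louvain with a distinct node sweep order;
    the partition with the highest Q_r wins (ties keep the earliest
    restart).  An edgeless graph yields all-singleton modules with
    Q_r = 0 and a logged warning.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if graph.number_of_edges() == 0:
        logger.warning("graph has no edges; every gene becomes a singleton module")
        membership = _relabel([{n} for n in graph.nodes])
        return ModulePartition(membership=membership, modularity=0.0, resolution=resolution)

    rng = np.random.default_rng([int(seed) % (2**31), 97])
    best: list[set[str]] | None = None
    best_q = -np.inf
    for _ in range(max(1, int(n_restarts))):
        restart_seed = int(rng.integers(0, 2**31 - 1))
        comms = nx.community.louvain_communities(
            graph, weight="weight", resolution=resolution, seed=restart_seed
        )
        q = nx.community.modularity(graph, comms, weight="weight", resolution=resolution)
        if q > best_q + 1e-12:
            best_q = q
            best = [set(c) for c in comms]
    assert best is not None
    return ModulePartition(
        membership=_relabel(best), modularity=float(best_q), resolution=resolution
    )


def module_contributions(partition: ModulePartition) -> dict[int, float]:
    """Percent of catalog genes in each module (sums to 100)."""
    total = len(partition.membership)
    if total == 0:
        raise ValueError("empty partition")
    return {
        m: 100.0 * size / total for m, size in partition.module_sizes.items()
    }


def module_composition(
    partition: ModulePartition, catalog: pd.DataFrame
) -> pd.DataFrame:
    """Cross-tabulation of module id x pathway category (gene counts)."""
    df = catalog[["gene_id", "category"]].copy()
    missing = set(df["gene_id"]) - set(partition.membership)
    if missing:
        raise ValueError(f"partition does not cover catalog genes: {sorted(missing)}")
    df["module_id"] = df["gene_id"].map(partition.membership)
    table = pd.crosstab(df["module_id"], df["category"])
    table.index.name = "module_id"
    return table
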