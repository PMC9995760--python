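"""Independent oracles used by the tests.

Everything here is deliberately naive — straight-line re-derivations of
the quantities the package computes, kept free of any cnmod internals so
agreement is meaningful.
"""

from __future__ import annotations

import networkx as nx


def set_partitions(nodes):
    """Yield every partition of ``nodes`` as a list of sets."""
    nodes = list(nodes)
    if not nodes:
        yield []
        return
    first = nodes[0]
    for rest in set_partitions(nodes[1:]):
        for i, block in enumerate(rest):
            yield rest[:i] + [block | {first}] + rest[i + 1:]
        yield [{first}] + rest


def resolution_modularity(G: nx.Graph, blocks, resolution: float) -> float:
    """Q_r from the definition, summed over ordered node pairs."""
    two_m = 2.0 * sum(d.get("weight", 1.0) for _, _, d in G.edges(data=True))
    if two_m == 0:
        return 0.0
    deg = dict(G.degree(weight="weight"))
    q = 0.0
    for block in blocks:
        for u in block:
            for v in block:
                a = G[u][v].get("weight", 1.0) if G.has_edge(u, v) else 0.0
                q += a - resolution * deg[u] * deg[v] / two_m
    return q / two_m


def brute_force_max_modularity(G: nx.Graph, resolution: float) -> float:
    """Exhaustive maximum of Q_r over all partitions (use only for <= 8 nodes)."""
    return max(
        resolution_modularity(G, blocks, resolution)
        for blocks in set_partitions(list(G.nodes))
    )


def livak_rel_expr(ct_rows, housekeeping: str, calibrator: str):
    """Spreadsheet-style 2^-ddCt on a list of (gene, tissue, cond, rep, ct).

    Returns {(gene, tissue, cond, rep): rel_expr} using plain dict
    arithmetic, independent of any pandas grouping.
    """
    hk = {}
    for gene, tissue, cond, rep, ct in ct_rows:
        if gene == housekeeping:
            hk[(tissue, cond, rep)] = ct
    dct = {}
    for gene, tissue, cond, rep, ct in ct_rows:
        if gene == housekeeping or (tissue, cond, rep) not in hk:
            continue
        dct[(gene, tissue, cond, rep)] = ct - hk[(tissue, cond, rep)]
    cal_mean = {}
    for (gene, tissue, cond, rep), v in dct.items():
        if cond == calibrator:
            cal_mean.setdefault((gene, tissue), []).append(v)
    cal_mean = {k: sum(v) / len(v) for k, v in cal_mean.items()}
    return {
        key: 2.0 ** -(v - cal_mean[(key[0], key[1])])
        for key, v in dct.items()
    }


def small_graph_suite():
    """>= 20 connected/weighted graphs with <= 8 nodes for oracle checks."""
    graphs = []
    a = nx.relabel_nodes(nx.complete_graph(4), lambda i: f"a{i}")
    b = nx.relabel_nodes(nx.complete_graph(4), lambda i: f"b{i}")
    bridged = nx.union(a, b)
    bridged.add_edge("a0", "b0", weight=0.5)
    graphs.append(("bridged_4cliques", bridged))
    graphs.append(("triangle", nx.cycle_graph(3)))
    graphs.append(("two_triangles", nx.disjoint_union(nx.cycle_graph(3), nx.cycle_graph(3))))
    for n in (4, 5, 6, 7, 8):
        graphs.append((f"path_{n}", nx.path_graph(n)))
    for n in (4, 6, 8):
        graphs.append((f"star_{n}", nx.star_graph(n - 1)))
    for n in (4, 5, 6, 8):
        graphs.append((f"cycle_{n}", nx.cycle_graph(n)))
    for n in (4, 5):
        graphs.append((f"complete_{n}", nx.complete_graph(n)))
    graphs.append(("barbell_3_1", nx.barbell_graph(3, 1)))
    graphs.append(("karate_first8", nx.karate_club_graph().subgraph(range(8)).copy()))
    graphs.append(("grid_2x4", nx.grid_2d_graph(2, 4)))
    graphs.append(("wheel_6", nx.wheel_graph(6)))
    graphs.append(("lollipop_4_3", nx.lollipop_graph(4, 3)))
    weighted = nx.cycle_graph(6)
    for u, v in weighted.edges():
        weighted[u][v]["weight"] = 0.9 if u % 2 == 0 else 0.3
    graphs.append(("weighted_cycle_6", weighted))
    out = []
    for name, G in graphs:
        G = nx.relabel_nodes(G, {n: str(n) for n in G.nodes})
        for _, _, d in G.edges(data=True):
            d.setdefault("weight", 1.0)
        out.append((name, G))
    return out
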