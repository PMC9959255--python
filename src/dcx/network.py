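"""Network assembly, betweenness centrality, topological attack, ORA.

Graphs are simple (no self-loops, no multi-edges) with typed nodes
(gene / TF / miRNA / protein). Centrality is exact shortest-path
betweenness; the attack curve iteratively removes the most central (or
highest-degree) node and tracks the largest connected component.
Over-representation analysis is an upper-tail hypergeometric test of a
query gene set against each set of a library, BH-adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from dcx.diffexpr import bh_adjust

NODE_TYPES = ("gene", "TF", "miRNA", "protein")


def build_graph(
    edges: list[tuple[str, str]] | pd.DataFrame,
    node_types: dict[str, str] | None = None,
    directed: bool = False,
) -> nx.Graph:
    """Assemble a simple annotated graph from an edge list.

    Self-loops are dropped with a warning; duplicate edges collapse.
    ``node_types`` maps node id -> type; untyped nodes default to
    ``gene``.
    """
    if isinstance(edges, pd.DataFrame):
        pairs = list(zip(edges.iloc[:, 0].astype(str), edges.iloc[:, 1].astype(str)))
    else:
        pairs = [(str(a), str(b)) for a, b in edges]
    g = nx.DiGraph() if directed else nx.Graph()
    n_loops = 0
    for a, b in pairs:
        if a == b:
            n_loops += 1
            continue
        g.add_edge(a, b)
    if n_loops:
        warnings.warn(f"dropped {n_loops} self-loop(s)")
    node_types = node_types or {}
    for n in g.nodes:
        g.nodes[n]["type"] = node_types.get(n, "gene")
    return g


def betweenness(graph: nx.Graph, normalized: bool = False) -> pd.Series:
    """Exact shortest-path betweenness centrality per node.

    Unnormalized counts pair contributions with equal-length shortest
    paths split equally; undirected graphs count each unordered pair
    once. The normalized variant divides by (n-1)(n-2)/2 (undirected)
    or (n-1)(n-2) (directed).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    bc = nx.betweenness_centrality(graph, normalized=normalized)
    return pd.Series(bc, name="betweenness").sort_index()


@dataclass
class AttackCurve:
    removal_order: list[str]
    lcc_sizes: list[int]          # after each removal
    n_components: list[int]
    initial_lcc: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self.removal_order) + 1),
                "removed": self.removal_order,
                "lcc_size": self.lcc_sizes,
                "n_components": self.n_components,
            }
        )


def _lcc_size(g: nx.Graph) -> int:
    if g.number_of_nodes() == 0:
        return 0
    comps = (
        nx.weakly_connected_components(g) if g.is_directed() else nx.connected_components(g)
    )
    return max(len(c) for c in comps)


def _n_components(g: nx.Graph) -> int:
    if g.number_of_nodes() == 0:
        return 0
    if g.is_directed():
        return nx.number_weakly_connected_components(g)
    return nx.number_connected_components(g)


def topological_attack(
    graph: nx.Graph,
    strategy: str = "betweenness",
    recompute: bool = True,
    stop_fraction: float = 1.0,
    order: list[str] | None = None,
) -> AttackCurve:
    """Iterative node-removal robustness analysis.

    ``strategy`` is ``betweenness``, ``degree`` or ``given-order`` (with
    ``order`` supplied). With ``recompute`` the ranking is refreshed
    after every removal; otherwise the initial ranking is replayed. Ties
    break lexicographically by node id. Records the largest-connected-
    component size and component count after each removal until the
    graph is empty or ``stop_fraction`` of nodes has been removed.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if strategy not in ("betweenness", "degree", "given-order"):
        raise ValueError(f"unknown strategy {strategy!r}")
    g = graph.copy()
    n0 = g.number_of_nodes()
    max_removals = int(np.ceil(stop_fraction * n0))

    def ranking(h: nx.Graph) -> list[str]:
        if strategy == "betweenness":
            score = nx.betweenness_centrality(h, normalized=False)
        elif strategy == "degree":
            score = dict(h.degree())
        else:
            if order is None:
                raise ValueError("given-order strategy requires an order")
            return [n for n in order if n in h]
        return sorted(score, key=lambda n: (-score[n], n))

    initial_lcc = _lcc_size(g)
    static_order = None if recompute and strategy != "given-order" else ranking(g)

    removed, lcc_sizes, n_comps = [], [], []
    step = 0
    while g.number_of_nodes() > 0 and step < max_removals:
        if static_order is not None:
            target = static_order[step]
        else:
            target = ranking(g)[0]
        g.remove_node(target)
        removed.append(target)
        lcc_sizes.append(_lcc_size(g))
        n_comps.append(_n_components(g))
        step += 1
    return AttackCurve(removed, lcc_sizes, n_comps, initial_lcc)


def rank_understudied(
    centrality: pd.Series, literature_counts: dict[str, int] | pd.Series
) -> pd.DataFrame:
    """Score nodes by centrality rank percentile minus literature rank percentile.

    High scores mark high-centrality, low-literature-coverage nodes.
    Nodes missing from the count table get count 0 and a flag.
    """
    counts = pd.Series(literature_counts, dtype=float)
    nodes = centrality.index
    missing = [n for n in nodes if n not in counts.index]
    full_counts = counts.reindex(nodes).fillna(0.0)

    c_pct = centrality.rank(pct=True, method="average")
    l_pct = full_counts.rank(pct=True, method="average")
    score = c_pct - l_pct
    out = pd.DataFrame(
        {
            "betweenness": centrality,
            "literature_count": full_counts,
            "centrality_pct": c_pct,
            "literature_pct": l_pct,
            "understudied_score": score,
            "count_missing": [n in set(missing) for n in nodes],
        }
    )
    return out.sort_values("understudied_score", ascending=False)


@dataclass(frozen=True)
class OraResult:
    set_id: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_hyper: float
    p_adj: float = float("nan")
    overlap_genes: tuple[str, ...] = ()


def ora_enrichment(
    query: set[str],
    collections: dict[str, set[str]],
    universe: set[str],
) -> list[OraResult]:
    """Hypergeometric over-representation of a query set in each library set.

    Each library set is intersected with the universe first; the p-value
    is the upper tail P(X >= overlap) for a hypergeometric with
    population ``|universe|``, successes ``|set|``, draws ``|query|``.
    BH adjustment is applied across the library. Results are sorted by
    raw p.
    """
    query = set(query)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        extra = sorted(query - universe)
        raise ValueError(f"query genes outside universe: {extra[:5]}")

    results = []
    for set_id, members in collections.items():
        members = set(members) & universe
        overlap_genes = tuple(sorted(query & members))
        k = len(overlap_genes)
        # P(X >= k) = sf(k - 1)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(query)))
        results.append(
            OraResult(
                set_id=set_id,
                overlap=k,
                set_size=len(members),
                query_size=len(query),
                universe_size=len(universe),
                p_hyper=min(p, 1.0),
                overlap_genes=overlap_genes,
            )
        )
    if results:
        adj = bh_adjust([r.p_hyper for r in results])
        results = [
            OraResult(
                r.set_id, r.overlap, r.set_size, r.query_size, r.universe_size,
                r.p_hyper, float(a), r.overlap_genes,
            )
            for r, a in zip(results, adj)
        ]
    results.sort(key=lambda r: (r.p_hyper, r.set_id))
    return results
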