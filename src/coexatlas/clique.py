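"""Maximum clique of the module overlap graph.

A clique here is a set of modules, one per tissue (the graph has no
intra-tissue edges), every pair of which overlaps significantly — the
modules conserved across those tissues.

The default search is an exact branch-and-bound over bitset adjacency
with a greedy-coloring upper bound (Tomita-style).  Among equally sized
maximum cliques the lexicographically smallest node set is returned, so
results are deterministic.  The search counts branching steps against a
budget; if exceeded it falls back to a greedy-plus-swap local search and
flags the result as heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

DEFAULT_BUDGET = 10_000_000


@dataclass(frozen=True)
class Clique:
    """A clique of the module graph; ``exact`` records the search mode."""

    members: frozenset
    exact: bool = True

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list:
        return sorted(self.members)


class _Budget(Exception):
    pass


def _greedy_color_order(P: int, adj: list[int]) -> tuple[list[int], list[int]]:
    """Greedy coloring of candidate set P (bitmask); returns vertices in
    color order with their color numbers (1-based upper bounds)."""
    order: list[int] = []
    colors: list[int] = []
    color = 0
    uncolored = P
    while uncolored:
        color += 1
        avail = uncolored
        while avail:
            v = (avail & -avail).bit_length() - 1
            order.append(v)
            colors.append(color)
            uncolored &= ~(1 << v)
            avail &= ~(1 << v) & ~adj[v]
    return order, colors


def max_clique(graph: nx.Graph, budget: int = DEFAULT_BUDGET) -> Clique:
    """Exact maximum clique (lexicographically smallest among ties).

    Falls back to :func:`greedy_clique` when the branching budget is
    exhausted, flagging the result with ``exact=False``.  The empty graph
    yields an empty clique.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return Clique(frozenset(), exact=True)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v in graph.edges:
        if u == v:
            continue
        i, j = index[u], index[v]
        adj[i] |= 1 << j
        adj[j] |= 1 << i

    best: list[int] = []
    steps = 0

    def bits(mask: int):
        while mask:
            b = mask & -mask
            yield b.bit_length() - 1
            mask ^= b

    def expand(R: list[int], P: int) -> None:
        nonlocal best, steps
        order, colors = _greedy_color_order(P, adj)
        for v, c in zip(reversed(order), reversed(colors)):
            if len(R) + c < len(best):
                return
            steps += 1
            if steps > budget:
                raise _Budget
            R.append(v)
            P2 = P & adj[v]
            if P2:
                expand(R, P2)
            else:
                if len(R) > len(best) or (
                    len(R) == len(best)
                    and [nodes[i] for i in sorted(R)]
                    < [nodes[i] for i in sorted(best)]
                ):
                    best = list(R)
            R.pop()
            P &= ~(1 << v)

    try:
        expand([], (1 << n) - 1)
    except _Budget:
        return greedy_clique(graph)
    return Clique(frozenset(nodes[i] for i in best), exact=True)


def greedy_clique(graph: nx.Graph) -> Clique:
    """Greedy construction plus single-swap local search; flagged heuristic."""
    nodes = sorted(graph.nodes)
    if not nodes:
        return Clique(frozenset(), exact=False)
    deg = dict(graph.degree)
    best: set = set()
    # seed from each vertex in decreasing-degree order, extend greedily
    seeds = sorted(nodes, key=lambda v: (-deg[v], v))
    for seed in seeds[: max(1, len(nodes) // 2)]:
        clique = {seed}
        cand = set(graph.neighbors(seed))
        while cand:
            v = max(cand, key=lambda u: (sum(1 for w in cand if graph.has_edge(u, w)), u))
            clique.add(v)
            cand &= set(graph.neighbors(v))
        improved = True
        while improved:  # 1-out 2-in swaps
            improved = False
            for v in sorted(clique):
                rest = clique - {v}
                common = set.intersection(*(set(graph.neighbors(u)) for u in rest)) - clique
                addable = sorted(u for u in common)
                picked = []
                for u in addable:
                    if all(graph.has_edge(u, w) for w in picked):
                        picked.append(u)
                if len(picked) >= 2:
                    clique = rest | set(picked)
                    improved = True
                    break
        if len(clique) > len(best) or (
            len(clique) == len(best) and sorted(clique) < sorted(best)
        ):
            best = clique
    return Clique(frozenset(best), exact=False)


def verify_clique(clique: Clique, graph: nx.Graph) -> bool:
    """Independent check that every member pair is an edge of the graph."""
    members = clique.sorted_members()
    return all(
        graph.has_edge(u, v)
        for i, u in enumerate(members)
        for v in members[i + 1 :]
    )


def clique_report(clique: Clique, partitions) -> "pd.DataFrame":
    """One row per clique member with its gene set, for enrichment."""
    import pandas as pd

    by_tissue = {p.tissue: p for p in partitions}
    rows = []
    for tissue, module in clique.sorted_members():
        genes = sorted(by_tissue[tissue].modules()[module])
        rows.append(
            {
                "tissue": tissue,
                "module": module,
                "size": len(genes),
                "genes": ",".join(genes),
            }
        )
    return pd.DataFrame(rows, columns=["tissue", "module", "size", "genes"])
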