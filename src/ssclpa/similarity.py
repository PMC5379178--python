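"""Sørensen–Dice neighbourhood similarity (SDI) between node pairs.

The SDI of nodes x and y is the Dice overlap of their *reduced*
neighbourhoods — each endpoint is excluded from the other's neighbour set:

    SDI(x, y) = 2 |N(x)\\{y} ∩ N(y)\\{x}| / (|N(x)\\{y}| + |N(y)\\{x}|)

The score is 1 when the reduced neighbourhoods are identical and nonempty,
and defined as 0 when both reduced neighbourhoods are empty (a mutually
adjacent degree-1 pair); grouping such isolated dyads on similarity alone
would be spurious.

SDI depends only on the static graph, so the table is computed once and
never updated during detection. Only pairs at graph distance <= 2 can have
a nonzero score; everything else is an implicit zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import Graph

__all__ = ["SdiTable", "sdi", "sdi_table", "mean_sdi", "highest_sdi_neighbors"]


def sdi(graph: Graph, x: int, y: int) -> float:
    """Sørensen–Dice index of two distinct nodes (internal indices)."""
    if x == y:
        raise ValueError("sdi requires two distinct nodes")
    n = graph.n
    if not (0 <= x < n and 0 <= y < n):
        raise KeyError(f"unknown node index {x if not 0 <= x < n else y}")
    nx_ = graph.adj[x] - {y}
    ny_ = graph.adj[y] - {x}
    denom = len(nx_) + len(ny_)
    if denom == 0:
        return 0.0
    return 2.0 * len(nx_ & ny_) / denom


@dataclass
class SdiTable:
    """Sparse symmetric table of nonzero SDI scores.

    ``scores`` is keyed by an ordered index pair (i, j), i < j; lookups for
    absent pairs return 0. ``top`` caches each node's highest SDI score over
    its neighbours, used by the initial-grouping stage and by CLP 1.
    """

    scores: dict[tuple[int, int], float]
    top: dict[int, float] = field(default_factory=dict)

    def get(self, x: int, y: int) -> float:
        if x == y:
            raise ValueError("sdi requires two distinct nodes")
        key = (x, y) if x < y else (y, x)
        return self.scores.get(key, 0.0)


def sdi_table(graph: Graph) -> SdiTable:
    """Compute SDI for every pair that can be nonzero.

    Candidate pairs are adjacent pairs plus pairs sharing at least one
    neighbour (distance-2 pairs); adjacency-only pairs with no shared
    neighbour score 0 and are not stored.
    """
    pairs: set[tuple[int, int]] = set()
    for z in range(graph.n):
        nbrs = sorted(graph.adj[z])
        for a_pos, i in enumerate(nbrs):
            for j in nbrs[a_pos + 1 :]:
                pairs.add((i, j))
    scores: dict[tuple[int, int], float] = {}
    for i, j in pairs:
        s = sdi(graph, i, j)
        if s > 0.0:
            scores[(i, j)] = s
    table = SdiTable(scores=scores)
    for v in range(graph.n):
        if graph.adj[v]:
            table.top[v] = max(table.get(v, u) for u in graph.adj[v])
    return table


def mean_sdi(table: SdiTable, node: int, members: set[int] | frozenset[int]) -> float:
    """Mean SDI between ``node`` and a nonempty set of member nodes."""
    if not members:
        raise ValueError("mean_sdi over an empty member set")
    return sum(table.get(node, u) for u in members) / len(members)


def highest_sdi_neighbors(
    table: SdiTable, node: int, graph: Graph
) -> tuple[float, set[int]]:
    """Highest SDI score of ``node`` over its neighbours, with the argmax set."""
    nbrs = graph.adj[node]
    if not nbrs:
        raise ValueError(f"node {node} is isolated")
    best = max(table.get(node, u) for u in nbrs)
    return best, {u for u in nbrs if table.get(node, u) == best}
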