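"""Partition-quality metrics: NMI, modularity Q, modularity density Q_ds.

* ``nmi`` — normalised mutual information between two partitions of the
  same node set, with the arithmetic-mean (Danon) normalisation:

      NMI = -2 Σ_ij N_ij ln(N_ij n / (N_i N_j))
            / [Σ_i N_i ln(N_i/n) + Σ_j N_j ln(N_j/n)]

  where N is the contingency table of the two partitions. NMI = 1 for
  identical partitions, 0 for independent ones.

* ``modularity`` — Newman modularity Q = Σ_c [m_c/m − (d_c/(2m))²].

* ``modularity_density`` — Q_ds, the split-penalised modularity density:
  each community contributes its modularity term scaled by the internal
  edge density d_c = 2 m_c/(n_c (n_c − 1)), minus a penalty for the edges
  it shares with every other community, weighted by the pairwise density
  d_cc' = m_cc'/(n_c n_c'). Unlike Q it does not reward coarse merges of
  loosely connected groups, so it discriminates against both trivial and
  over-split detections.
"""

from __future__ import annotations

import math

from .graph import Graph, Partition

__all__ = ["nmi", "modularity", "modularity_density"]


def _contingency(p1: Partition, p2: Partition) -> tuple[dict, dict, dict, int]:
    if set(p1.labels) != set(p2.labels):
        raise ValueError("partitions cover different node sets")
    counts: dict[tuple[str, str], int] = {}
    row: dict[str, int] = {}
    col: dict[str, int] = {}
    for node, a in p1.labels.items():
        b = p2.labels[node]
        counts[(a, b)] = counts.get((a, b), 0) + 1
        row[a] = row.get(a, 0) + 1
        col[b] = col.get(b, 0) + 1
    return counts, row, col, len(p1.labels)


def nmi(p1: Partition, p2: Partition) -> float:
    """Normalised mutual information of two partitions of one node set."""
    counts, row, col, n = _contingency(p1, p2)
    num = 0.0
    for (a, b), nij in counts.items():
        num += nij * math.log(nij * n / (row[a] * col[b]))
    den = sum(ni * math.log(ni / n) for ni in row.values()) + sum(
        nj * math.log(nj / n) for nj in col.values()
    )
    if den == 0.0:
        # both partitions trivial (single community): identical by convention
        return 1.0
    return -2.0 * num / den


def _community_stats(graph: Graph, p: Partition):
    if graph.m == 0:
        raise ValueError("metrics undefined on an edgeless graph")
    labels = [p.labels[graph.nodes[i]] for i in range(graph.n)]
    comms = sorted(set(labels))
    size = {c: 0 for c in comms}
    deg = {c: 0 for c in comms}
    intra = {c: 0 for c in comms}
    inter: dict[tuple[str, str], int] = {}
    for i in range(graph.n):
        ci = labels[i]
        size[ci] += 1
        deg[ci] += graph.degree(i)
        for j in graph.adj[i]:
            if i < j:
                cj = labels[j]
                if ci == cj:
                    intra[ci] += 1
                else:
                    key = (ci, cj) if ci < cj else (cj, ci)
                    inter[key] = inter.get(key, 0) + 1
    return comms, size, deg, intra, inter


def modularity(graph: Graph, p: Partition) -> float:
    """Newman modularity of a partition."""
    comms, _, deg, intra, _ = _community_stats(graph, p)
    m = graph.m
    return sum(intra[c] / m - (deg[c] / (2.0 * m)) ** 2 for c in comms)


def modularity_density(graph: Graph, p: Partition) -> float:
    """Split-penalised modularity density Q_ds."""
    comms, size, _, intra, inter = _community_stats(graph, p)
    m = graph.m
    boundary = {c: 0 for c in comms}
    for (a, b), e in inter.items():
        boundary[a] += e
        boundary[b] += e
    q = 0.0
    for c in comms:
        nc = size[c]
        mc = intra[c]
        dc = 2.0 * mc / (nc * (nc - 1)) if nc > 1 else 0.0
        q += (mc / m) * dc - ((2.0 * mc + boundary[c]) / (2.0 * m)) ** 2 * dc
    for (a, b), e in inter.items():
        d_ab = e / (size[a] * size[b])
        q -= 2.0 * (e / (2.0 * m)) * d_ab  # once for each orientation
    return q
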