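"""Seeded benchmark-graph generators with planted ground truth.

Two generator families cover the standard evaluation protocol for
community detection on undirected, unweighted graphs:

* Girvan–Newman (GN): 128 nodes in 4 equal communities of 32, expected
  degree 16, with a mixing parameter mu giving the expected fraction of
  each node's edges that leave its community. Implemented as a classical
  planted-partition (stochastic block model) draw: per-pair probabilities
  p_in and p_out are solved from the expected intra/inter degrees, so
  realised degrees fluctuate around 16.

* Relaxed Caveman (RC): 512 nodes in 16 cliques of heterogeneous size.
  A degradation fraction D of the clique edges is removed and replaced by
  uniformly random inter-community non-edges, conserving the edge count
  while progressively dissolving the community structure.

Both are pure functions of their parameters and seed. LFR graphs are not
generated here; ``lfr_preset`` records the parameter sets for the
published external LFR generator, whose output files load through the
ordinary edge-list reader.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph import Graph, Partition, from_networkx

__all__ = [
    "BenchmarkSpec",
    "generate_planted",
    "generate_gn",
    "generate_rc",
    "rc_default_sizes",
    "LFR_PRESETS",
    "lfr_preset",
]

GN_N = 128
GN_COMMUNITIES = 4
GN_SIZE = 32
GN_DEGREE = 16

RC_N = 512
RC_COMMUNITIES = 16
RC_MIN_CLIQUE = 8


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of a planted-partition benchmark draw."""

    kind: str  # "gn" | "rc" | "planted"
    sizes: tuple[int, ...]
    mixing: float  # mu for gn/planted, degradation D for rc
    expected_degree: float | None = None
    seed: int = 0
    p_in: float | None = field(default=None)
    p_out: float | None = field(default=None)


def _planted_truth(sizes) -> Partition:
    labels = {}
    node = 0
    for block, s in enumerate(sizes):
        for _ in range(s):
            labels[str(node)] = str(block + 1)
            node += 1
    return Partition(labels=labels)


def generate_planted(
    sizes, p_in: float, p_out: float, seed: int
) -> tuple[Graph, Partition]:
    """Generic planted-partition (stochastic block model) graph."""
    sizes = tuple(int(s) for s in sizes)
    if min(sizes) < 1:
        raise ValueError("community sizes must be positive")
    for p in (p_in, p_out):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"edge probability {p} outside [0, 1]")
    k = len(sizes)
    probs = [[p_in if i == j else p_out for j in range(k)] for i in range(k)]
    g = nx.stochastic_block_model(list(sizes), probs, seed=int(seed))
    return from_networkx(g), _planted_truth(sizes)


def generate_gn(mu: float, seed: int) -> tuple[Graph, Partition]:
    """Girvan–Newman benchmark draw at mixing mu (expected inter fraction)."""
    if not 0.0 <= mu < 1.0:
        raise ValueError(f"mixing parameter must be in [0, 1), got {mu}")
    # expected intra degree 16(1-mu) over 31 intra partners, inter degree
    # 16 mu over 96 inter partners
    p_in = GN_DEGREE * (1.0 - mu) / (GN_SIZE - 1)
    p_out = GN_DEGREE * mu / (GN_N - GN_SIZE)
    return generate_planted((GN_SIZE,) * GN_COMMUNITIES, p_in, p_out, seed)


def rc_default_sizes(seed: int) -> tuple[int, ...]:
    """Heterogeneous clique sizes: a seeded log-uniform split of 512 into
    16 parts with minimum size 8."""
    rng = np.random.default_rng(seed)
    weights = np.exp(rng.uniform(0.0, math.log(64.0), RC_COMMUNITIES))
    extra_total = RC_N - RC_COMMUNITIES * RC_MIN_CLIQUE
    raw = weights / weights.sum() * extra_total
    extras = np.floor(raw).astype(int)
    # hand the rounding remainder to the largest fractional parts
    order = np.argsort(-(raw - extras), kind="stable")
    for i in order[: extra_total - int(extras.sum())]:
        extras[i] += 1
    return tuple(int(RC_MIN_CLIQUE + e) for e in extras)


def generate_rc(
    D: float, sizes=None, seed: int = 0
) -> tuple[Graph, Partition]:
    """Relaxed Caveman benchmark: cliques degraded by edge rewiring.

    round(D * E_intra) clique edges, chosen uniformly at random, are each
    replaced by a uniformly random inter-community non-edge; the total
    edge count is conserved.
    """
    if not 0.0 <= D < 1.0:
        raise ValueError(f"degradation must be in [0, 1), got {D}")
    rng = np.random.default_rng(seed)
    if sizes is None:
        sizes = rc_default_sizes(seed)
    sizes = tuple(int(s) for s in sizes)
    n = sum(sizes)
    block = np.empty(n, dtype=int)
    edges: list[tuple[int, int]] = []
    start = 0
    for b, s in enumerate(sizes):
        block[start : start + s] = b
        for i in range(start, start + s):
            for j in range(i + 1, start + s):
                edges.append((i, j))
        start += s
    total = len(edges)
    r = round(D * total)
    edge_set = set(edges)
    removed_idx = rng.choice(total, size=r, replace=False)
    removed = {edges[i] for i in removed_idx}
    kept = [e for e in edges if e not in removed]
    # capacity check: distinct inter-community pairs available
    inter_pairs = (n * (n - 1)) // 2 - total
    if r > inter_pairs:
        raise ValueError("not enough inter-community non-edges to rewire into")
    new_edges: set[tuple[int, int]] = set()
    while len(new_edges) < r:
        u, v = int(rng.integers(n)), int(rng.integers(n))
        if u == v or block[u] == block[v]:
            continue
        pair = (u, v) if u < v else (v, u)
        if pair in edge_set or pair in new_edges:
            continue
        new_edges.add(pair)
    all_edges = kept + sorted(new_edges)
    graph = Graph.from_edges(
        ((str(u), str(v)) for u, v in all_edges), nodes=(str(i) for i in range(n))
    )
    return graph, _planted_truth(sizes)


# Parameter presets for the external LFR benchmark generator: small/large
# network (SN/LN) crossed with small/large communities (SC/LC).
LFR_PRESETS: dict[str, dict] = {
    name: {
        "N": N,
        "k_avg": 20,
        "k_max": 50,
        "gamma": 2,
        "beta": 1,
        "c_min": cmin,
        "c_max": cmax,
        "mu": [round(0.1 * i, 1) for i in range(1, 9)],
    }
    for name, N, cmin, cmax in [
        ("SNSC", 1000, 10, 50),
        ("SNLC", 1000, 20, 100),
        ("LNSC", 5000, 10, 50),
        ("LNLC", 5000, 20, 100),
    ]
}


def lfr_preset(name: str) -> dict:
    """Parameter set for the external LFR generator (SNSC/SNLC/LNSC/LNLC)."""
    try:
        return dict(LFR_PRESETS[name.upper()])
    except KeyError:
        raise KeyError(
            f"unknown LFR preset {name!r}; choose from {sorted(LFR_PRESETS)}"
        ) from None
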