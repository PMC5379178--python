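"""Mutable community bookkeeping used by the propagation and merging passes.

Tracks, incrementally under single-node moves: community membership, each
node's intra-community degree, and the solo/grouped split. A node is *solo*
while its community has a single member (itself) and *grouped* as soon as it
shares a community with at least one other node.

Community strength is the per-community mean of member node strengths,
where a node's strength is the fraction of its edges that stay inside its
community. Strength drives two constraint mechanisms:

* the quartile thresholds (Q0 = minimum, Q1 = first quartile, Q2 = median)
  that an entered community's strength must not fall below, and
* community exemption: communities at strength >= alpha are frozen out of
  propagation and merging, which delays monster-community formation.

Singleton communities are excluded from the strength distribution and can
never be exempted: their strength is degenerately 0 and would distort the
quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import Graph, Partition

__all__ = [
    "CommunityState",
    "StrengthSummary",
    "node_strength",
    "community_strength",
    "strength_summary",
    "exempted_set",
    "apply_move",
]


@dataclass(frozen=True)
class StrengthSummary:
    """Quartiles of the community-strength distribution (sizes >= 2 only)."""

    Q0: float
    Q1: float
    Q2: float

    def threshold(self, name: str | None) -> float | None:
        if name is None:
            return None
        return {"Q0": self.Q0, "Q1": self.Q1, "Q2": self.Q2}[name]


class CommunityState:
    """Label assignment over a graph with incremental derived quantities."""

    __slots__ = ("graph", "labels", "members", "intra")

    def __init__(self, graph: Graph):
        self.graph = graph
        # every node starts as a singleton community labelled by its index
        self.labels: list[int] = list(range(graph.n))
        self.members: dict[int, set[int]] = {v: {v} for v in range(graph.n)}
        self.intra: list[int] = [0] * graph.n

    # -- basic queries ---------------------------------------------------

    def is_solo(self, v: int) -> bool:
        return len(self.members[self.labels[v]]) == 1

    @property
    def solo(self) -> set[int]:
        return {v for v in range(self.graph.n) if self.is_solo(v)}

    @property
    def grouped(self) -> set[int]:
        return {v for v in range(self.graph.n) if not self.is_solo(v)}

    def community_count(self) -> int:
        return len(self.members)

    def solo_neighbor_count(self, v: int) -> int:
        return sum(1 for u in self.graph.adj[v] if self.is_solo(u))

    def clone(self) -> "CommunityState":
        out = CommunityState.__new__(CommunityState)
        out.graph = self.graph
        out.labels = list(self.labels)
        out.members = {c: set(s) for c, s in self.members.items()}
        out.intra = list(self.intra)
        return out

    def to_partition(self) -> Partition:
        nodes = self.graph.nodes
        return Partition(labels={nodes[v]: str(self.labels[v]) for v in range(self.graph.n)})

    # -- strength sums, kept O(|c|) on demand ----------------------------

    def strength_sum(self, c: int) -> float:
        """Sum over members of intra_degree/degree (degree-0 members count 0)."""
        g = self.graph
        return sum(
            self.intra[u] / g.degree(u) for u in self.members[c] if g.degree(u) > 0
        )

    def check_consistency(self) -> None:
        """Assert the incremental bookkeeping against a from-scratch recount."""
        seen: set[int] = set()
        for c, mem in self.members.items():
            assert mem, f"empty community {c} retained"
            for v in mem:
                assert self.labels[v] == c
            seen |= mem
        assert seen == set(range(self.graph.n))
        for v in range(self.graph.n):
            true_intra = sum(
                1 for u in self.graph.adj[v] if self.labels[u] == self.labels[v]
            )
            assert self.intra[v] == true_intra, f"intra mismatch at node {v}"


def node_strength(state: CommunityState, v: int) -> float:
    """Fraction of v's edges that are intra-community; requires v grouped."""
    if state.is_solo(v):
        raise ValueError(f"node {v} is solo; strength undefined")
    deg = state.graph.degree(v)
    if deg == 0:
        raise ValueError(f"node {v} has degree 0")
    return state.intra[v] / deg


def community_strength(state: CommunityState, c: int) -> float:
    """Mean member node strength of community ``c``."""
    mem = state.members.get(c)
    if not mem:
        raise KeyError(f"unknown or empty community {c}")
    return state.strength_sum(c) / len(mem)


def strength_summary(state: CommunityState) -> StrengthSummary:
    """Quartiles of community strengths over communities of size >= 2.

    Linear interpolation on the sorted values (the p*(n-1) rank convention);
    all three quantities are 0 when no community is eligible.
    """
    vals = [
        state.strength_sum(c) / len(mem)
        for c, mem in state.members.items()
        if len(mem) >= 2
    ]
    if not vals:
        return StrengthSummary(0.0, 0.0, 0.0)
    arr = np.asarray(vals, dtype=float)
    return StrengthSummary(
        Q0=float(arr.min()),
        Q1=float(np.percentile(arr, 25)),
        Q2=float(np.percentile(arr, 50)),
    )


def exempted_set(state: CommunityState, alpha: float) -> set[int]:
    """Communities of size >= 2 with strength >= alpha (frozen communities)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return {
        c
        for c, mem in state.members.items()
        if len(mem) >= 2 and state.strength_sum(c) / len(mem) >= alpha
    }


def apply_move(state: CommunityState, v: int, new_label: int) -> CommunityState:
    """Relabel node v into community ``new_label``, updating bookkeeping.

    ``new_label`` must be an existing community or v's own singleton label.
    Mutates ``state`` in place and returns it. Moving v into its current
    community is a no-op.
    """
    old = state.labels[v]
    if new_label == old:
        return state
    if new_label not in state.members and new_label != v:
        raise KeyError(f"community {new_label} does not exist")
    adj_v = state.graph.adj[v]

    state.members[old].discard(v)
    for u in adj_v:
        if state.labels[u] == old:
            state.intra[u] -= 1
    if not state.members[old]:
        del state.members[old]

    dest = state.members.setdefault(new_label, set())
    dest.add(v)
    state.labels[v] = new_label
    intra_v = 0
    for u in adj_v:
        if state.labels[u] == new_label:
            state.intra[u] += 1
            intra_v += 1
    state.intra[v] = intra_v
    return state
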