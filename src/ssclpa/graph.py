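"""Graph and partition data model with edge-list / GML / partition-file I/O.

Graphs are undirected, unweighted and simple. Node identifiers are opaque
strings; each node also receives a dense internal index in first-appearance
order. That order is the final deterministic tie-breaker used everywhere
downstream, so it is part of the data model, not an implementation detail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "Partition",
    "GraphParseError",
    "read_edge_list",
    "read_gml",
    "from_networkx",
    "read_partition",
    "write_partition",
]


class GraphParseError(ValueError):
    """Raised when a graph or partition file cannot be parsed."""


@dataclass(frozen=True)
class Graph:
    """Immutable undirected simple graph.

    Attributes
    ----------
    nodes : tuple of str
        Node identifiers in first-appearance order; position = internal index.
    adj : tuple of frozenset of int
        ``adj[i]`` holds the internal indices of node *i*'s neighbours.
    """

    nodes: tuple[str, ...]
    adj: tuple[frozenset[int], ...]
    index: Mapping[str, int] = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return sum(len(a) for a in self.adj) // 2

    def degree(self, i: int) -> int:
        return len(self.adj[i])

    def neighbors(self, i: int) -> frozenset[int]:
        return self.adj[i]

    def index_of(self, node: str) -> int:
        try:
            return self.index[node]
        except KeyError:
            raise KeyError(f"unknown node {node!r}") from None

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for i, nbrs in enumerate(self.adj):
            for j in nbrs:
                if i < j:
                    g.add_edge(self.nodes[i], self.nodes[j])
        return g

    @staticmethod
    def from_edges(
        edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()
    ) -> "Graph":
        """Build a graph from (u, v) pairs; duplicates collapsed, loops dropped."""
        order: dict[str, int] = {}
        adj: list[set[int]] = []

        def intern(tok: str) -> int:
            if tok not in order:
                order[tok] = len(adj)
                adj.append(set())
            return order[tok]

        for tok in nodes:
            intern(tok)
        loops = 0
        for u, v in edges:
            iu, iv = intern(u), intern(v)
            if iu == iv:
                loops += 1
                continue
            adj[iu].add(iv)
            adj[iv].add(iu)
        if loops:
            logger.warning("dropped %d self-loop(s)", loops)
        if not adj:
            raise GraphParseError("empty graph")
        return Graph(
            nodes=tuple(order),
            adj=tuple(frozenset(a) for a in adj),
            index=dict(order),
        )


def read_edge_list(stream: IO[str] | str) -> Graph:
    """Read a whitespace-delimited two-column edge list.

    Lines starting with ``#`` or ``%`` are comments. A third column (e.g. an
    edge weight) is rejected: the model is unweighted by contract.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    edges: list[tuple[str, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line[0] in "#%":
            continue
        toks = line.split()
        if len(toks) != 2:
            raise GraphParseError(
                f"line {lineno}: expected 2 node tokens, got {len(toks)}"
                + (" (weighted input is not supported)" if len(toks) == 3 else "")
            )
        edges.append((toks[0], toks[1]))
    return Graph.from_edges(edges)


def read_gml(stream: IO[str] | str) -> Graph:
    """Read a GML file (nodes and edges only; attributes ignored)."""
    text = stream if isinstance(stream, str) else stream.read()
    try:
        g = nx.parse_gml(text, label="id")
    except Exception as exc:  # networkx raises several parse error types
        raise GraphParseError(f"GML parse failure: {exc}") from exc
    if g.is_directed():
        g = g.to_undirected()
    nodes = [str(v) for v in g.nodes()]
    edges = [(str(u), str(v)) for u, v in g.edges()]
    return Graph.from_edges(edges, nodes=nodes)


def from_networkx(g: nx.Graph) -> Graph:
    """Convert a networkx graph; node order follows ``g.nodes()``."""
    nodes = [str(v) for v in g.nodes()]
    edges = [(str(u), str(v)) for u, v in g.edges()]
    return Graph.from_edges(edges, nodes=nodes)


@dataclass(frozen=True)
class Partition:
    """Disjoint community assignment: a total node -> label mapping."""

    labels: Mapping[str, str]

    @property
    def communities(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for node, lab in self.labels.items():
            out.setdefault(lab, set()).add(node)
        return out

    def __len__(self) -> int:
        return len(set(self.labels.values()))


def read_partition(stream: IO[str] | str) -> Partition:
    """Read "node label" lines into a Partition.

    A node repeated with a different label is an error: communities are
    disjoint by contract.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    labels: dict[str, str] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line[0] in "#%":
            continue
        toks = line.split()
        if len(toks) != 2:
            raise GraphParseError(f"line {lineno}: expected 'node label'")
        node, lab = toks
        if node in labels and labels[node] != lab:
            raise GraphParseError(
                f"line {lineno}: node {node!r} assigned two labels "
                f"({labels[node]!r}, {lab!r})"
            )
        labels[node] = lab
    if not labels:
        raise GraphParseError("empty partition")
    return Partition(labels=labels)


def write_partition(partition: Partition, stream: IO[str]) -> None:
    """Write one "node label" line per node, in node order.

    Labels are renumbered 1..K by first appearance so the output is
    bit-stable regardless of internal label values.
    """
    renumber: dict[str, int] = {}
    for node, lab in partition.labels.items():
        if lab not in renumber:
            renumber[lab] = len(renumber) + 1
        stream.write(f"{node} {renumber[lab]}\n")
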