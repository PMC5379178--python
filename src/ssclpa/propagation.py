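"""Constrained label-propagation processes.

The algorithm family distinguishes *solo* nodes (still in their own
singleton community) from *grouped* nodes, and runs two kinds of sweeps:

* CLP — constrained label propagation, which assigns solo nodes into
  detected communities. CLP 2..6 are synchronous (all moves evaluated
  against the sweep-start state, then applied together); CLP 1 is
  asynchronous and additionally requires the target community to hold a
  member attaining the node's highest SDI score.
* GNR — grouped-node reallocation, the same decision rule applied
  asynchronously to grouped nodes, whose own community is always a
  candidate ("stay put" needs no conditions).

Every candidate community must (1) maximise the number of edges from the
node, (2) not be exempted — unless the variant allows entry into an
exempted community whose edge count is at least twice the second-highest,
and (3) keep its strength, recomputed as if the node were admitted, at or
above the variant's quartile threshold. Ties between surviving candidates
are broken by the higher mean SDI between the node and its neighbours
inside each community; a residual tie means no move. Constraints are
relaxed from variant 1 to 6 through the threshold schedule below.

Also here: the two initial-grouping steps (degree-1 attachment and the
reciprocal highest-SDI pairing) and the smallest-to-largest CLP that lets
small communities absorb adjacent solo nodes ahead of large ones.
"""

from __future__ import annotations

from dataclasses import dataclass

from .similarity import SdiTable, mean_sdi
from .state import (
    CommunityState,
    StrengthSummary,
    apply_move,
    exempted_set,
    strength_summary,
)

__all__ = [
    "ProcessVariant",
    "VARIANTS",
    "update_sequence",
    "candidate_communities",
    "clp",
    "gnr",
    "k1_grouping",
    "hth_sdi_grouping",
    "stl_clp",
]

_EPS = 1e-12


@dataclass(frozen=True)
class ProcessVariant:
    """Parameter bundle selecting which propagation constraints are active."""

    name: str
    targets: str  # "solo" | "grouped"
    synchronous: bool
    require_sdi_member: bool = False
    enforce_exemption: bool = True
    allow_exempt_entry_2x: bool = False
    strength_threshold: str | None = "Q1"  # None | "Q0" | "Q1" | "Q2"
    strength_threshold_exempt: str | None = "Q1"
    donor_threshold: str | None = None  # grouped targets: bar on the donor

    def __post_init__(self) -> None:
        if self.targets == "grouped" and self.synchronous:
            raise ValueError("grouped nodes are updated asynchronously")


# Constraint schedule, relaxed from variant 1 (median bar) to 6 (no bar).
# Variants 3-5 admit entry into exempted communities under the 2x
# edge-count override, with a stricter threshold on the exempted side.
# Grouped-node variants carry a donor bar: a reallocation may not leave
# the donor community below the same quartile, which is what stops strong
# communities from being cannibalised node by node into one giant
# component ("monster") on weakly structured graphs.
VARIANTS: dict[str, ProcessVariant] = {
    v.name: v
    for v in [
        ProcessVariant("CLP1", "solo", synchronous=False, require_sdi_member=True,
                       enforce_exemption=False, strength_threshold="Q2",
                       strength_threshold_exempt="Q2"),
        ProcessVariant("GNR1", "grouped", synchronous=False,
                       enforce_exemption=False, strength_threshold="Q2",
                       strength_threshold_exempt="Q2", donor_threshold="Q2"),
        ProcessVariant("CLP2", "solo", synchronous=True, strength_threshold="Q1"),
        ProcessVariant("GNR2", "grouped", synchronous=False, strength_threshold="Q1",
                       donor_threshold="Q1"),
        ProcessVariant("CLP3", "solo", synchronous=True, allow_exempt_entry_2x=True,
                       strength_threshold="Q1", strength_threshold_exempt="Q2"),
        ProcessVariant("GNR3", "grouped", synchronous=False, allow_exempt_entry_2x=True,
                       strength_threshold="Q1", strength_threshold_exempt="Q2",
                       donor_threshold="Q1"),
        ProcessVariant("CLP4", "solo", synchronous=True, allow_exempt_entry_2x=True,
                       strength_threshold="Q0", strength_threshold_exempt="Q1"),
        ProcessVariant("GNR4", "grouped", synchronous=False, allow_exempt_entry_2x=True,
                       strength_threshold="Q0", strength_threshold_exempt="Q1",
                       donor_threshold="Q0"),
        ProcessVariant("CLP5", "solo", synchronous=True, allow_exempt_entry_2x=True,
                       strength_threshold="Q0", strength_threshold_exempt="Q0"),
        ProcessVariant("GNR5", "grouped", synchronous=False, allow_exempt_entry_2x=True,
                       strength_threshold="Q0", strength_threshold_exempt="Q0",
                       donor_threshold="Q0"),
        ProcessVariant("CLP6", "solo", synchronous=True, allow_exempt_entry_2x=True,
                       strength_threshold=None, strength_threshold_exempt=None),
    ]
}


def update_sequence(state: CommunityState, targets) -> list[int]:
    """Deterministic node order: fewest solo neighbours, then lowest degree,
    then lowest internal index."""
    g = state.graph
    return sorted(
        targets, key=lambda v: (state.solo_neighbor_count(v), g.degree(v), v)
    )


def candidate_communities(
    state: CommunityState, v: int
) -> tuple[set[int], dict[int, int]]:
    """Communities of v's grouped neighbours maximising the edge count to v.

    Returns the argmax label set and the full label -> edge-count map
    (needed by the 2x exempt-entry override).
    """
    counts: dict[int, int] = {}
    for u in state.graph.adj[v]:
        if not state.is_solo(u):
            c = state.labels[u]
            counts[c] = counts.get(c, 0) + 1
    if not counts:
        return set(), counts
    best = max(counts.values())
    return {c for c, k in counts.items() if k == best}, counts


def admitted_strength(state: CommunityState, c: int, v: int, k_in: int) -> float:
    """Strength of community c recomputed as if node v were admitted."""
    g = state.graph
    total = state.strength_sum(c)
    for u in g.adj[v]:
        if state.labels[u] == c and not state.is_solo(u) and g.degree(u) > 0:
            total += 1.0 / g.degree(u)
    if g.degree(v) > 0:
        total += k_in / g.degree(v)
    return total / (len(state.members[c]) + 1)


def _departed_strength(state: CommunityState, c: int, v: int) -> float:
    """Strength of community c recomputed as if member v had left."""
    g = state.graph
    total = state.strength_sum(c)
    if g.degree(v) > 0:
        total -= state.intra[v] / g.degree(v)
    for u in g.adj[v]:
        if state.labels[u] == c and u != v and g.degree(u) > 0:
            total -= 1.0 / g.degree(u)
    return total / (len(state.members[c]) - 1)


def _passes_conditions(
    state: CommunityState,
    v: int,
    c: int,
    counts: dict[int, int],
    variant: ProcessVariant,
    summary: StrengthSummary,
    exempted: set[int],
    table: SdiTable,
) -> bool:
    """CLP Conditions (2) and (3) plus the variant-1 SDI-member requirement
    for moving node v into community c (Condition (1) pre-selected c)."""
    if c in exempted:
        if not variant.allow_exempt_entry_2x:
            return False
        second = max((k for d, k in counts.items() if d != c), default=0)
        if counts[c] < 2 * second:
            return False
        # entering a frozen community is an exception to exemption, so it
        # must not weaken the community: its strength may not decrease
        current = state.strength_sum(c) / len(state.members[c])
        if admitted_strength(state, c, v, counts[c]) < current - _EPS:
            return False
        thr_name = variant.strength_threshold_exempt
    else:
        thr_name = variant.strength_threshold
    if variant.require_sdi_member:
        top = table.top.get(v, 0.0)
        if top <= 0.0 or not any(
            table.get(v, u) == top for u in state.members[c]
        ):
            return False
    thr = summary.threshold(thr_name)
    if thr is not None:
        if admitted_strength(state, c, v, counts[c]) < thr - _EPS:
            return False
    return True


def _choose_move(
    state: CommunityState,
    v: int,
    variant: ProcessVariant,
    summary: StrengthSummary,
    exempted: set[int],
    table: SdiTable,
) -> int | None:
    """Decide the destination community for node v, or None for no move.

    For grouped nodes the current community is always an implicit candidate
    that needs no conditions; a tie that it participates in keeps the node
    in place.
    """
    own = None if state.is_solo(v) else state.labels[v]
    argmax, counts = candidate_communities(state, v)
    if own is not None:
        counts.setdefault(own, 0)
        best = max(counts.values())
        argmax = {c for c, k in counts.items() if k == best}
        if len(argmax) > 1 or own not in argmax:
            # a reallocation away is on the table: it must not gut the
            # donor community below the variant's strength bar
            donor_thr = summary.threshold(variant.donor_threshold)
            if donor_thr is not None and len(state.members[own]) > 2:
                if _departed_strength(state, own, v) < donor_thr - _EPS:
                    return None
    if not argmax:
        return None
    survivors = [
        c
        for c in sorted(argmax)
        if c == own
        or _passes_conditions(state, v, c, counts, variant, summary, exempted, table)
    ]
    if not survivors:
        return None
    if len(survivors) == 1:
        dest = survivors[0]
        return None if dest == own else dest
    # tie on edge count: higher mean SDI with the neighbours held in each
    # community wins; a residual tie leaves the label unchanged
    scored = []
    for c in survivors:
        nbrs_in_c = state.graph.adj[v] & frozenset(state.members[c])
        score = mean_sdi(table, v, nbrs_in_c) if nbrs_in_c else 0.0
        scored.append((score, c))
    best_score = max(s for s, _ in scored)
    winners = [c for s, c in scored if s == best_score]
    if len(winners) != 1:
        return None
    return None if winners[0] == own else winners[0]


def clp(
    state: CommunityState,
    variant: ProcessVariant,
    table: SdiTable,
    alpha: float,
) -> tuple[CommunityState, int]:
    """One CLP sweep over the solo nodes; returns (state, moved count).

    Community exemption and the strength quartiles are frozen at sweep
    start. In synchronous mode every decision is evaluated against the
    sweep-start state and the moves are applied together; in asynchronous
    mode (variant 1) each move takes effect immediately.
    """
    if variant.targets != "solo":
        raise ValueError(f"{variant.name} does not target solo nodes")
    summary = strength_summary(state)
    exempted = exempted_set(state, alpha) if variant.enforce_exemption else set()
    order = update_sequence(state, state.solo)
    moved = 0
    if variant.synchronous:
        moves = []
        for v in order:
            dest = _choose_move(state, v, variant, summary, exempted, table)
            if dest is not None:
                moves.append((v, dest))
        for v, dest in moves:
            apply_move(state, v, dest)
            moved += 1
    else:
        for v in order:
            if not state.is_solo(v):
                continue
            dest = _choose_move(state, v, variant, summary, exempted, table)
            if dest is not None:
                apply_move(state, v, dest)
                moved += 1
    return state, moved


def gnr(
    state: CommunityState,
    variant: ProcessVariant,
    table: SdiTable,
    alpha: float,
) -> tuple[CommunityState, int]:
    """One asynchronous GNR sweep over the grouped nodes."""
    if variant.targets != "grouped":
        raise ValueError(f"{variant.name} does not target grouped nodes")
    summary = strength_summary(state)
    exempted = exempted_set(state, alpha) if variant.enforce_exemption else set()
    order = update_sequence(state, state.grouped)
    moved = 0
    for v in order:
        if state.is_solo(v):  # may have been stranded by an earlier move
            continue
        dest = _choose_move(state, v, variant, summary, exempted, table)
        if dest is not None:
            apply_move(state, v, dest)
            moved += 1
    return state, moved


def k1_grouping(state: CommunityState) -> CommunityState:
    """Attach every degree-1 node to its sole neighbour's community."""
    g = state.graph
    for v in range(g.n):
        if g.degree(v) == 1:
            (u,) = g.adj[v]
            apply_move(state, v, state.labels[u])
    return state


def hth_sdi_grouping(state: CommunityState, table: SdiTable) -> CommunityState:
    """Reciprocal highest-SDI pairing of solo nodes.

    Solo nodes, in ascending degree then index order, join the community of
    a neighbour y when sdi(x, y) attains both x's and y's highest SDI score
    (ties broken toward the lowest-index neighbour). Pairs whose best score
    is 0 are never grouped — zero similarity is no evidence of community.
    """
    g = state.graph
    order = sorted(state.solo, key=lambda v: (g.degree(v), v))
    for x in order:
        if not state.is_solo(x) or not g.adj[x]:
            continue
        top_x = table.top.get(x, 0.0)
        if top_x <= 0.0:
            continue
        for y in sorted(g.adj[x]):
            if table.get(x, y) == top_x and table.top.get(y, 0.0) == top_x:
                apply_move(state, x, state.labels[y])
                break
    return state


def stl_clp(
    state: CommunityState, table: SdiTable, alpha: float
) -> tuple[CommunityState, int]:
    """Smallest-to-largest CLP: growth pass favouring small communities.

    Communities (size >= 2), visited in ascending size then lowest label,
    absorb every adjacent solo node that satisfies the exemption condition
    and keeps the community's strength at or above Q0. Size priority, not
    edge count, decides who claims contested solo nodes; a solo node is
    absorbed at most once per pass.
    """
    summary = strength_summary(state)
    exempted = exempted_set(state, alpha)
    order = sorted(
        (c for c, mem in state.members.items() if len(mem) >= 2),
        key=lambda c: (len(state.members[c]), c),
    )
    moved = 0
    for c in order:
        if c not in state.members or c in exempted:
            continue
        adjacent_solo = sorted(
            {
                u
                for member in state.members[c]
                for u in state.graph.adj[member]
                if state.is_solo(u)
            }
        )
        for v in adjacent_solo:
            if not state.is_solo(v):
                continue
            k_in = sum(1 for u in state.graph.adj[v] if state.labels[u] == c)
            if admitted_strength(state, c, v, k_in) >= summary.Q0 - _EPS:
                apply_move(state, v, c)
                moved += 1
    return state, moved
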