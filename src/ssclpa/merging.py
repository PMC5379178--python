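"""Community merging passes (GM 1/2/3).

Communities are visited as c_i in descending size (ties toward the lowest
label); c_i's partner c_j is the neighbouring community sharing the most
edges E(i, j). A merge requires the edge-density ratio condition

    RatioB >= factor * RatioA,   RatioA = intra_edges(c_j) / |c_j|,
                                 RatioB = E(i, j) / |c_j|,

with factor 1 (strict) by default; factor 0.5 gives a relaxed variant that
merges more aggressively. Every pass also requires that modularity not
decrease — the ratio condition alone cannot separate a genuine merge from
the absorption of a small intact community by a large one whose stray
edges happen to reach it, and without the guard such slightly
modularity-negative merges cascade on degraded clique benchmarks. The
variants differ in their remaining guards:

* GM1 — both communities need at least 4 members and neither may be
  exempted; E(i, j) ties abort the merge.
* GM2 — any sizes, neither exempted; ties abort.
* GM3 — free-for-all: exempted communities may merge; an E(i, j) tie is
  resolved toward the pair with the largest RatioB − RatioA (then lowest
  label).

The modularity guard uses the exact integer form 2·m·E(i,j) >= d_i·d_j,
so no merge is ever accepted on floating-point slack.
"""

from __future__ import annotations

from dataclasses import dataclass

from .state import CommunityState, apply_move, exempted_set

__all__ = ["MergeRatios", "MergeRecord", "merge_ratios", "modularity_delta", "gm"]


@dataclass(frozen=True)
class MergeRatios:
    ratioA: float  # average intra edges of the absorbed community c_j
    ratioB: float  # average edges between c_i and c_j
    e_ij: int


@dataclass(frozen=True)
class MergeRecord:
    """Audit record of one applied merge."""

    variant: str
    ci: int
    cj: int
    size_i: int
    size_j: int
    e_ij: int
    delta_q: float
    ci_exempt: bool
    cj_exempt: bool


def _intra_edges(state: CommunityState, c: int) -> int:
    return sum(state.intra[u] for u in state.members[c]) // 2


def _degree_sum(state: CommunityState, c: int) -> int:
    return sum(state.graph.degree(u) for u in state.members[c])


def _inter_edges(state: CommunityState, ci: int, cj: int) -> int:
    a, b = state.members[ci], state.members[cj]
    if len(a) > len(b):
        a, b = b, a
    target = state.labels[next(iter(b))]
    return sum(1 for u in a for w in state.graph.adj[u] if state.labels[w] == target)


def merge_ratios(state: CommunityState, ci: int, cj: int) -> MergeRatios:
    """Edge-density ratios for absorbing c_j into c_i (denominators |c_j|)."""
    if ci == cj:
        raise ValueError("merge_ratios requires two distinct communities")
    nj = len(state.members[cj])
    e_ij = _inter_edges(state, ci, cj)
    return MergeRatios(
        ratioA=_intra_edges(state, cj) / nj, ratioB=e_ij / nj, e_ij=e_ij
    )


def _oriented_ratios(state: CommunityState, ci: int, cj: int) -> MergeRatios:
    """Ratios with c_j taken as the smaller (absorbed) community of the pair."""
    ni, nj = len(state.members[ci]), len(state.members[cj])
    if (nj, cj) > (ni, ci):
        ci, cj = cj, ci
    return merge_ratios(state, ci, cj)


def modularity_delta(state: CommunityState, ci: int, cj: int) -> float:
    """Closed-form change in Newman modularity from merging ci and cj:
    ΔQ = e_ij/m − d_i·d_j/(2m²)."""
    if ci == cj:
        raise ValueError("distinct communities required")
    m = state.graph.m
    e_ij = _inter_edges(state, ci, cj)
    return e_ij / m - _degree_sum(state, ci) * _degree_sum(state, cj) / (2.0 * m * m)


def _delta_q_nonnegative(state: CommunityState, ci: int, cj: int, e_ij: int) -> bool:
    # exact integer comparison: e_ij/m - d_i d_j/(2 m^2) >= 0
    return 2 * state.graph.m * e_ij >= _degree_sum(state, ci) * _degree_sum(state, cj)


def _merge(state: CommunityState, ci: int, cj: int) -> int:
    """Merge two communities; the larger community's label survives
    (lowest label on a size tie). Returns the surviving label."""
    ni, nj = len(state.members[ci]), len(state.members[cj])
    if ni != nj:
        keep, absorb = (ci, cj) if ni > nj else (cj, ci)
    else:
        keep, absorb = (min(ci, cj), max(ci, cj))
    for v in sorted(state.members[absorb]):
        apply_move(state, v, keep)
    return keep


def gm(
    state: CommunityState,
    variant: str,
    alpha: float,
    ratio_factor: float = 0.5,
    log: list[MergeRecord] | None = None,
) -> tuple[CommunityState, int]:
    """One merging pass; returns (state, number of merges applied)."""
    if variant not in ("GM1", "GM2", "GM3"):
        raise ValueError(f"unknown merge variant {variant!r}")
    exempted = exempted_set(state, alpha) if variant != "GM3" else set()
    # singleton labels are solo nodes, not communities: CLP processes own
    # them, so merging never touches them on either side of a pair
    order = sorted(
        (c for c, mem in state.members.items() if len(mem) >= 2),
        key=lambda c: (-len(state.members[c]), c),
    )
    merged = 0
    for ci in order:
        if ci not in state.members or len(state.members[ci]) < 2:
            continue  # absorbed earlier in this pass
        size_i = len(state.members[ci])
        if variant != "GM3" and ci in exempted:
            continue
        if variant == "GM1" and size_i < 4:
            continue
        counts: dict[int, int] = {}
        for u in state.members[ci]:
            for w in state.graph.adj[u]:
                c = state.labels[w]
                if c != ci and len(state.members[c]) >= 2:
                    counts[c] = counts.get(c, 0) + 1
        if not counts:
            continue
        best = max(counts.values())
        cands = sorted(c for c, k in counts.items() if k == best)
        if len(cands) > 1:
            if variant != "GM3":
                continue  # tie: labels remain the same
            # GM3 resolves the tie toward the largest RatioB - RatioA
            keyed = [(_oriented_ratios(state, ci, c), c) for c in cands]
            top = max(r.ratioB - r.ratioA for r, _ in keyed)
            tied = [c for r, c in keyed if r.ratioB - r.ratioA == top]
            cj = tied[0]
        else:
            cj = cands[0]
        size_j = len(state.members[cj])
        if variant == "GM1" and size_j < 4:
            continue
        if variant != "GM3" and cj in exempted:
            continue
        ratios = _oriented_ratios(state, ci, cj)
        if ratios.ratioB + 1e-12 < ratio_factor * ratios.ratioA:
            continue
        if not _delta_q_nonnegative(state, ci, cj, ratios.e_ij):
            continue
        if log is not None:
            log.append(
                MergeRecord(
                    variant=variant,
                    ci=ci,
                    cj=cj,
                    size_i=size_i,
                    size_j=size_j,
                    e_ij=ratios.e_ij,
                    delta_q=modularity_delta(state, ci, cj),
                    ci_exempt=ci in exempted,
                    cj_exempt=cj in exempted,
                )
            )
        _merge(state, ci, cj)
        merged += 1
    return state, merged
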