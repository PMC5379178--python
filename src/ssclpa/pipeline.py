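"""Five-stage detection pipeline and the top-level :func:`detect` API.

Stage 1   unique initial labels; the SDI table is computed once.
Stage 2   initial detection: degree-1 attachment, reciprocal highest-SDI
          grouping, then CLP 1 to convergence followed by GNR 1 to
          convergence.
Stage 3   growth and first merging: cycles of {CLP 2 to convergence,
          GNR 2 to convergence, GM 1 + GNR 2, GM 2 + GNR 2}, each process
          preceded by community exemption (EC), until a full cycle changes
          nothing.
Stage 4   iterative merging: {GM 1 + GNR 2, GM 2 + GNR 2} until the
          community count stops falling.
Stage 5   relaxation: the smallest-to-largest CLP, then the progressively
          relaxed CLP 3/4 (+GNR 3/4), the free-for-all merge GM 3, and
          finally CLP 5/6 (+GNR 5). If the result is trivial (every node
          in one community) the final two blocks are rolled back to the
          checkpoint taken after GM 3 — the skip that avoids trivial
          detection on weak community structure.

The whole pipeline is deterministic: node order, update sequences and all
tie-breaks are fixed, so identical inputs give byte-identical partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO

import yaml

from .graph import Graph, Partition
from .merging import MergeRecord, gm
from .propagation import VARIANTS, clp, gnr, hth_sdi_grouping, k1_grouping, stl_clp
from .similarity import sdi_table
from .state import CommunityState
from . import metrics

logger = logging.getLogger(__name__)

__all__ = ["SsclpaConfig", "RunReport", "StageEvent", "detect", "is_trivial"]


@dataclass(frozen=True)
class SsclpaConfig:
    """Tunable parameters of the detection pipeline.

    alpha           exemption threshold: communities at strength >= alpha
                    are frozen out of propagation and merging. 0.9 exempts
                    only near-saturated communities.
    gm_ratio_factor factor f in the merge condition RatioB >= f * RatioA;
                    1.0 is the strict form, 0.5 a relaxed one that merges
                    more aggressively.
    max_sweeps      cap on every run-to-convergence loop.
    auto_fallback   roll Stage 5 back to its checkpoint when the full run
                    ends trivial.
    """

    alpha: float = 0.9
    gm_ratio_factor: float = 1.0
    max_sweeps: int = 100
    auto_fallback: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")

    @classmethod
    def from_yaml(cls, stream: IO[str] | str) -> "SsclpaConfig":
        data = yaml.safe_load(stream if isinstance(stream, str) else stream.read())
        return cls(**(data or {}))


@dataclass(frozen=True)
class StageEvent:
    stage: int
    process: str
    sweeps: int
    moves: int


@dataclass
class RunReport:
    """Outcome of one detection run."""

    partition: Partition
    trace: list[StageEvent] = field(default_factory=list)
    merge_log: list[MergeRecord] = field(default_factory=list)
    fallback_used: bool = False
    community_count: int = 0
    Q: float = 0.0
    Q_ds: float = 0.0

    def summary(self) -> dict:
        return {
            "communities": self.community_count,
            "Q": self.Q,
            "Q_ds": self.Q_ds,
            "fallback_used": self.fallback_used,
            "trace": [
                {"stage": e.stage, "process": e.process,
                 "sweeps": e.sweeps, "moves": e.moves}
                for e in self.trace
            ],
        }


def is_trivial(partition: Partition) -> bool:
    """True iff the partition places every node in a single community."""
    return len(set(partition.labels.values())) == 1


class _Runner:
    """Holds the mutable run context shared by the stage helpers."""

    def __init__(self, graph: Graph, config: SsclpaConfig):
        self.config = config
        self.state = CommunityState(graph)
        self.table = sdi_table(graph)
        self.trace: list[StageEvent] = []
        self.merge_log: list[MergeRecord] = []

    def converge(self, name: str, stage: int) -> int:
        """Run a CLP/GNR variant until a sweep moves nothing (EC re-run
        before every sweep through the alpha parameter)."""
        variant = VARIANTS[name]
        step = clp if variant.targets == "solo" else gnr
        total = 0
        for sweep in range(1, self.config.max_sweeps + 1):
            _, moved = step(self.state, variant, self.table, self.config.alpha)
            total += moved
            if moved == 0:
                break
        else:
            logger.warning("%s hit the %d-sweep cap", name, self.config.max_sweeps)
            sweep = self.config.max_sweeps
        self.trace.append(StageEvent(stage, name, sweep, total))
        return total

    def single(self, name: str, stage: int) -> int:
        variant = VARIANTS[name]
        step = clp if variant.targets == "solo" else gnr
        _, moved = step(self.state, variant, self.table, self.config.alpha)
        self.trace.append(StageEvent(stage, name, 1, moved))
        return moved

    def merge(self, name: str, stage: int) -> int:
        _, merged = gm(
            self.state,
            name,
            self.config.alpha,
            ratio_factor=self.config.gm_ratio_factor,
            log=self.merge_log,
        )
        self.trace.append(StageEvent(stage, name, 1, merged))
        return merged


def detect(graph: Graph, config: SsclpaConfig | None = None) -> RunReport:
    """Run the full five-stage detection on ``graph``."""
    if graph.n == 0:
        raise ValueError("empty graph")
    cfg = config or SsclpaConfig()
    run = _Runner(graph, cfg)
    state, table = run.state, run.table

    isolated = sum(1 for v in range(graph.n) if graph.degree(v) == 0)
    if isolated:
        logger.info("%d isolated node(s) kept as singleton communities", isolated)

    # Stage 2: initial detection
    k1_grouping(state)
    run.trace.append(StageEvent(2, "k1", 1, 0))
    hth_sdi_grouping(state, table)
    run.trace.append(StageEvent(2, "HTH", 1, 0))
    run.converge("CLP1", 2)
    run.converge("GNR1", 2)

    # Stage 3: growth + first merging, cycled until a full pass is quiet
    for _ in range(cfg.max_sweeps):
        changed = 0
        changed += run.converge("CLP2", 3)
        changed += run.converge("GNR2", 3)
        changed += run.merge("GM1", 3)
        changed += run.single("GNR2", 3)
        changed += run.merge("GM2", 3)
        changed += run.single("GNR2", 3)
        if changed == 0:
            break
    else:
        logger.warning("stage 3 hit the cycle cap")

    # Stage 4: iterative merging until the community count is stable
    for _ in range(cfg.max_sweeps):
        before = state.community_count()
        run.merge("GM1", 4)
        run.single("GNR2", 4)
        run.merge("GM2", 4)
        run.single("GNR2", 4)
        if state.community_count() == before:
            break
    else:
        logger.warning("stage 4 hit the cycle cap")

    # Stage 5: relaxation
    pre_stage5 = state.clone()
    _, moved = stl_clp(state, table, cfg.alpha)
    run.trace.append(StageEvent(5, "STL-CLP", 1, moved))
    run.converge("CLP3", 5)
    run.single("GNR3", 5)
    run.single("CLP4", 5)
    run.single("GNR4", 5)
    run.merge("GM3", 5)
    checkpoint = state.clone()
    run.single("CLP5", 5)
    run.single("GNR5", 5)
    run.single("CLP6", 5)
    run.single("GNR5", 5)

    fallback = False
    partition = state.to_partition()
    if cfg.auto_fallback and is_trivial(partition) and graph.n > 1:
        # trivial result: roll back to the checkpoint taken after GM 3
        # (skipping the final two relaxed blocks), or failing that to the
        # start of the stage. A graph that is trivial at every checkpoint
        # (a single cohesive community) keeps the full-run result.
        for snap in (checkpoint, pre_stage5):
            if len(snap.members) > 1:
                run.state = state = snap
                partition = state.to_partition()
                fallback = True
                run.trace.append(StageEvent(5, "fallback", 1, 0))
                break

    report = RunReport(
        partition=partition,
        trace=run.trace,
        merge_log=run.merge_log,
        fallback_used=fallback,
        community_count=len(set(partition.labels.values())),
    )
    if graph.m > 0:
        report.Q = metrics.modularity(graph, partition)
        report.Q_ds = metrics.modularity_density(graph, partition)
    return report
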