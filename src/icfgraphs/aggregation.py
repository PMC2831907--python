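"""Summary graphs over skeleton ensembles and connected-component reduction.

An edge enters the summary graph iff it occurred in at least ``min_count`` of
the N ensemble skeletons (the study used 20 of 100, a conservative choice);
its *reliability* is the occurrence fraction count/N, which downstream
rendering maps to edge thickness.  Splitting the summary graph into connected
components yields groups of categories that are mutually dependent within a
group and statistically independent across groups, so later analyses can run
per component.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .graphs import Edge, Skeleton

DEFAULT_SUMMARY_FRACTION = 0.2
DEFAULT_MIN_COMPONENT_SIZE = 3


@dataclass
class SummaryGraph:
    """Edge occurrence counts over an ensemble of N skeletons."""

    nodes: list[str]
    counts: dict[Edge, int]
    N: int
    min_count: int

    @property
    def edges(self) -> set[Edge]:
        return {e for e, c in self.counts.items() if c >= self.min_count}

    def reliability(self, a: str, b: str | None = None) -> float:
        e = a if b is None else Edge((a, b))
        return self.counts.get(e, 0) / self.N

    def reliabilities(self) -> dict[tuple[str, str], float]:
        return {
            tuple(sorted(e)): c / self.N
            for e, c in sorted(self.counts.items(), key=lambda kv: sorted(kv[0]))
            if c >= self.min_count
        }

    def to_skeleton(self) -> Skeleton:
        return Skeleton(list(self.nodes), set(self.edges))

    def with_min_count(self, min_count: int) -> "SummaryGraph":
        return SummaryGraph(list(self.nodes), dict(self.counts), self.N, min_count)


def fraction_to_min_count(fraction: float, N: int) -> int:
    """Convenience: inclusion threshold as ceil(fraction * N)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    return max(1, math.ceil(fraction * N))


def summarize(
    skeletons: list[Skeleton],
    min_count: int | None = None,
    fraction: float = DEFAULT_SUMMARY_FRACTION,
) -> SummaryGraph:
    """Count each edge's occurrences across the ensemble.

    ``min_count`` is the absolute inclusion threshold; when omitted it is
    derived from ``fraction`` of the ensemble size.
    """
    if not skeletons:
        raise ValueError("need at least one skeleton")
    node_set = set(skeletons[0].nodes)
    for s in skeletons[1:]:
        if set(s.nodes) != node_set:
            raise ValueError("skeletons in an ensemble must share the node set")
    N = len(skeletons)
    if min_count is None:
        min_count = fraction_to_min_count(fraction, N)
    if not 1 <= min_count <= N:
        raise ValueError("min_count must lie in 1..N")
    counts = Counter()
    for s in skeletons:
        counts.update(s.edges)
    return SummaryGraph(list(skeletons[0].nodes), dict(counts), N, int(min_count))


def connected_components(graph) -> list[list[str]]:
    """Connected components, largest first, ties by smallest member code.

    ``graph`` may be a :class:`Skeleton`, a :class:`SummaryGraph` (its
    thresholded edges) or a networkx Graph.
    """
    if isinstance(graph, SummaryGraph):
        g = graph.to_skeleton().to_networkx()
    elif isinstance(graph, Skeleton):
        g = graph.to_networkx()
    else:
        g = graph
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), c[0]))


def largest_components(
    graph,
    min_size: int = DEFAULT_MIN_COMPONENT_SIZE,
    top: int | None = 5,
) -> list[list[str]]:
    """The report view: up to ``top`` components with at least ``min_size`` nodes."""
    comps = [c for c in connected_components(graph) if len(c) >= min_size]
    return comps if top is None else comps[:top]
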