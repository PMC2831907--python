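"""Subpopulation comparison of graph ensembles.

Two subpopulations are compared through the skeletons estimated on their
resampled collections.  Dissimilarity between two skeletons is the
structural Hamming distance (SHD): the number of edge insertions or
deletions transforming one into the other, i.e. the size of the symmetric
difference of the edge sets.  The ensembles are judged *different* when the
between-collection SHD variation exceeds the variation that bootstrapping
and multiple imputation alone produce — operationalised as
``median(between-SHDs) > 95th percentile of the pooled within-SHDs``.
Characteristic edges are those highly reliable in one subpopulation's
summary graph and (near-)absent in the other's.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .aggregation import SummaryGraph, summarize
from .graphs import Skeleton, pc_skeleton
from .seeds import child_seed

DEFAULT_COMPARISON_QUANTILE = 0.95
DEFAULT_CHARACTERISTIC_HIGH = 0.5
DEFAULT_CHARACTERISTIC_LOW = 0.2


def shd(g1: Skeleton, g2: Skeleton) -> int:
    """Structural Hamming distance between two skeletons on one node set."""
    if set(g1.nodes) != set(g2.nodes):
        raise ValueError("skeletons must share the node set")
    return len(g1.edges ^ g2.edges)


@dataclass
class ComparisonReport:
    """SHD distributions, the difference decision and characteristic edges."""

    between_shds: list[int]
    within_shds_a: list[int]
    within_shds_b: list[int]
    decision: str  # "different" | "not-different"
    median_between: float
    within_quantile: float
    quantile: float
    characteristic_edges: list[tuple[tuple[str, str], float, float]]

    def to_dict(self) -> dict:
        return {
            "decision": self.decision,
            "median_between": self.median_between,
            "within_quantile": self.within_quantile,
            "quantile": self.quantile,
            "between_shds": self.between_shds,
            "within_shds_a": self.within_shds_a,
            "within_shds_b": self.within_shds_b,
            "characteristic_edges": [
                {"edge": list(e), "reliability_a": ra, "reliability_b": rb}
                for e, ra, rb in self.characteristic_edges
            ],
        }


def estimate_skeletons(
    collection,
    alpha: float = 0.05,
    max_cond_size: int = 3,
    n_perm: int = 499,
    seed: int = 0,
) -> list[Skeleton]:
    """One PC skeleton per resampled dataset of a collection."""
    out = []
    for idx, data in enumerate(collection):
        skel, _ = pc_skeleton(
            data, alpha=alpha, max_cond_size=max_cond_size,
            n_perm=n_perm, seed=child_seed(seed, "skel", idx),
        )
        out.append(skel)
    return out


def decide_difference(
    between: list[int],
    within_a: list[int],
    within_b: list[int],
    quantile: float = DEFAULT_COMPARISON_QUANTILE,
) -> tuple[str, float, float]:
    """The between- vs within-variation heuristic on SHD distributions."""
    pooled = list(within_a) + list(within_b)
    if not pooled or not between:
        raise ValueError("need non-empty SHD distributions")
    med = float(np.median(between))
    q = float(np.quantile(pooled, quantile))
    return ("different" if med > q else "not-different"), med, q


def characteristic_edges(
    summary_a: SummaryGraph,
    summary_b: SummaryGraph,
    high: float = DEFAULT_CHARACTERISTIC_HIGH,
    low: float = DEFAULT_CHARACTERISTIC_LOW,
) -> list[tuple[tuple[str, str], float, float]]:
    """Edges reliable (>= high) in one summary and rare (<= low) in the other.

    Returned as ``(edge, reliability_a, reliability_b)`` sorted by decreasing
    reliability gap, edge ties lexicographic.
    """
    if not 0.0 <= low < high <= 1.0:
        raise ValueError("need 0 <= low < high <= 1")
    if set(summary_a.nodes) != set(summary_b.nodes):
        raise ValueError("summaries must share the node set")
    pairs = set(summary_a.counts) | set(summary_b.counts)
    rows = []
    for e in pairs:
        ra = summary_a.reliability(e)
        rb = summary_b.reliability(e)
        if (ra >= high and rb <= low) or (rb >= high and ra <= low):
            rows.append((tuple(sorted(e)), ra, rb))
    return sorted(rows, key=lambda r: (-abs(r[1] - r[2]), r[0]))


def compare_subpopulations(
    collection_a,
    collection_b,
    alpha: float = 0.05,
    max_cond_size: int = 3,
    n_perm: int = 499,
    summary_fraction: float = 0.2,
    quantile: float = DEFAULT_COMPARISON_QUANTILE,
    high: float = DEFAULT_CHARACTERISTIC_HIGH,
    low: float = DEFAULT_CHARACTERISTIC_LOW,
    seed: int = 0,
    skeletons_a: list[Skeleton] | None = None,
    skeletons_b: list[Skeleton] | None = None,
) -> ComparisonReport:
    """Full subpopulation comparison of two resampled collections.

    Skeletons may be passed pre-estimated (``skeletons_a/b``) to reuse work;
    otherwise one PC skeleton per dataset is estimated with the given
    settings.  Requires at least two skeletons per collection so that the
    within-variation is defined.
    """
    if skeletons_a is None:
        skeletons_a = estimate_skeletons(
            collection_a, alpha, max_cond_size, n_perm, child_seed(seed, "A"))
    if skeletons_b is None:
        skeletons_b = estimate_skeletons(
            collection_b, alpha, max_cond_size, n_perm, child_seed(seed, "B"))
    if len(skeletons_a) < 2 or len(skeletons_b) < 2:
        raise ValueError("each collection must contribute at least 2 skeletons")

    within_a = [shd(a, b) for a, b in itertools.combinations(skeletons_a, 2)]
    within_b = [shd(a, b) for a, b in itertools.combinations(skeletons_b, 2)]
    between = [shd(a, b) for a in skeletons_a for b in skeletons_b]
    decision, med, q = decide_difference(between, within_a, within_b, quantile)
    summary_a = summarize(skeletons_a, fraction=summary_fraction)
    summary_b = summarize(skeletons_b, fraction=summary_fraction)
    chars = characteristic_edges(summary_a, summary_b, high, low)
    return ComparisonReport(between, within_a, within_b, decision, med, q,
                            quantile, chars)
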