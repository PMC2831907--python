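"""Intervention-effect bounds for binary categories on a continuous outcome.

From observational data alone the total causal effect of switching a binary
category X from 0 to 1 on the outcome is not identified — only the Markov
equivalence class (CPDAG) of the generating DAG is.  Each DAG in the class
assigns X a parent set, and under interaction-free linear structural
equations the effect under that DAG is the coefficient of X in the linear
regression of the outcome on X and those parents.  Enumerating the possible
parent sets therefore yields a *multiset* of effect estimates bounding the
true effect (the intervention-calculus / IDA approach, specialised to binary
regressors via the linear-probability assumption).

Across a resampled collection the per-category estimates are pooled and
aggregated by their unweighted mean, and categories are ranked by that mean:
category value 1 codes impairment and a higher outcome codes better health,
so the most negative mean marks the category whose improvement promises the
largest outcome gain.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphs import Cpdag, orient_cpdag, pc_skeleton
from .seeds import child_seed

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parent-set enumeration (local IDA)
# ---------------------------------------------------------------------------

def possible_parent_sets(cpdag: Cpdag, x: str) -> list[tuple[str, ...]]:
    """All parent sets of ``x`` realizable in the CPDAG's equivalence class.

    Local enumeration: candidates are pa(x) ∪ T for subsets T of the
    undirected neighbours of x such that orienting T -> x (and x -> rest)
    creates no new unshielded collider at x — every pair drawn from
    T ∪ pa(x) that involves a member of T must be adjacent.  Returned sorted,
    duplicates removed (deterministic lexicographic order).
    """
    if x not in cpdag.nodes:
        raise ValueError(f"{x!r} is not a CPDAG node")
    pa = sorted(cpdag.parents(x))
    sib = sorted(cpdag.undirected_neighbours(x))
    out: list[tuple[str, ...]] = []
    for r in range(len(sib) + 1):
        for T in itertools.combinations(sib, r):
            ok = all(
                cpdag.is_adjacent(t, u)
                for t in T
                for u in itertools.chain(T, pa)
                if u != t
            )
            if ok:
                out.append(tuple(sorted(set(pa) | set(T))))
    return sorted(set(out))


def consistent_extensions(cpdag: Cpdag):
    """Every DAG in the equivalence class, by exhaustive orientation.

    Orients each undirected edge both ways, keeping orientations that are
    acyclic, preserve the directed edges and introduce no v-structure change.
    Exponential in the number of undirected edges — a verification tool for
    small graphs, not a pipeline step.
    """
    import networkx as nx

    und = sorted(tuple(sorted(e)) for e in cpdag.undirected)
    base_vs = cpdag.v_structures()
    for bits in itertools.product((0, 1), repeat=len(und)):
        directed = set(cpdag.directed)
        directed.update(
            e if bit == 0 else e[::-1] for e, bit in zip(und, bits)
        )
        dg = nx.DiGraph()
        dg.add_nodes_from(cpdag.nodes)
        dg.add_edges_from(directed)
        if not nx.is_directed_acyclic_graph(dg):
            continue
        vs = set()
        for z in dg.nodes:
            for a, b in itertools.combinations(sorted(dg.predecessors(z)), 2):
                if not (dg.has_edge(a, b) or dg.has_edge(b, a)):
                    vs.add((a, z, b))
        if vs == base_vs:
            yield dg


# ---------------------------------------------------------------------------
# effect estimation
# ---------------------------------------------------------------------------

def _ols_x_coefficient(y: np.ndarray, x: np.ndarray, Z: np.ndarray) -> float:
    """Coefficient of x in OLS of y on [1, x, Z]; pseudo-inverse if collinear."""
    X = np.column_stack([np.ones(len(y)), x, Z])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        logger.warning("collinear adjustment set; using minimum-norm solution")
    return float(beta[1])


def effect_estimates(
    dataset,
    cpdag: Cpdag,
    x: str,
    outcome: str | pd.Series | np.ndarray = "ghp",
) -> list[float]:
    """Multiset of intervention-effect estimates of ``x`` on the outcome.

    One least-squares regression of the outcome on x plus each possible
    parent set (main effects and intercept only).  ``outcome`` is the
    dataset's own outcome column when given by name.  A zero-variance x
    yields an empty multiset with a warning.
    """
    frame = dataset.values if hasattr(dataset, "codes") else dataset
    if isinstance(outcome, str):
        if hasattr(dataset, "outcome") and dataset.outcome is not None:
            y = dataset.outcome.to_numpy(dtype=float)
        else:
            raise ValueError("dataset has no outcome column")
    else:
        y = np.asarray(outcome, dtype=float)
    xv = frame[x].to_numpy(dtype=float)
    if np.all(xv == xv[0]):
        warnings.warn(f"category {x} has zero variance; no effect estimate")
        return []
    out = []
    for P in possible_parent_sets(cpdag, x):
        Z = frame[list(P)].to_numpy(dtype=float) if P else np.empty((len(y), 0))
        out.append(_ols_x_coefficient(y, xv, Z))
    return out


# ---------------------------------------------------------------------------
# pooling and ranking over a resampled collection
# ---------------------------------------------------------------------------

@dataclass
class EffectTable:
    """Pooled effect multisets, mean aggregates and the category ranking.

    Ranking is by ascending signed mean: category 1 codes impairment and
    higher outcome codes better health, so rank 1 (most negative mean) is the
    category whose improvement is predicted to raise the outcome most.
    """

    estimates: dict[str, list[float]]
    ranking_note: str = (
        "rank 1 = most negative mean effect = largest predicted outcome "
        "gain from removing the impairment"
    )

    @property
    def means(self) -> dict[str, float]:
        return {
            c: float(np.mean(v)) if v else float("nan")
            for c, v in self.estimates.items()
        }

    @property
    def ranks(self) -> dict[str, int]:
        means = self.means
        ordered = sorted(
            means, key=lambda c: (np.isnan(means[c]), means[c], c)
        )
        return {c: r for r, c in enumerate(ordered, start=1)}

    def to_frame(self) -> pd.DataFrame:
        means, ranks = self.means, self.ranks
        rows = [
            {
                "code": c,
                "n_estimates": len(v),
                "min": float(np.min(v)) if v else np.nan,
                "mean": means[c],
                "max": float(np.max(v)) if v else np.nan,
                "rank": ranks[c],
            }
            for c, v in self.estimates.items()
        ]
        return (
            pd.DataFrame(rows)
            .sort_values("rank")
            .reset_index(drop=True)
        )

    def to_dict(self) -> dict:
        frame = self.to_frame()
        return {
            "ranking_note": self.ranking_note,
            "categories": frame.to_dict(orient="records"),
        }

    def top(self, k: int = 5) -> list[str]:
        return list(self.to_frame()["code"].head(k))


def estimate_cpdag(
    data,
    alpha: float = 0.05,
    max_cond_size: int = 3,
    n_perm: int = 499,
    seed: int = 0,
) -> Cpdag:
    """PC skeleton + orientation on one complete binary dataset."""
    skel, seps = pc_skeleton(
        data, alpha=alpha, max_cond_size=max_cond_size, n_perm=n_perm, seed=seed
    )
    return orient_cpdag(skel, seps)


def rank_categories(
    collection,
    outcome: str = "ghp",
    alpha: float = 0.05,
    max_cond_size: int = 3,
    n_perm: int = 499,
    seed: int = 0,
    cpdags: list[Cpdag] | None = None,
) -> EffectTable:
    """Pooled-mean ranking of every category over a resampled collection.

    Per dataset, a CPDAG is estimated over the categories (the outcome is
    never a PC node; it enters only through the regressions), effect
    estimates are computed for every category, and all estimates for one
    category are pooled across datasets.  Each estimate carries equal weight
    in the mean, so datasets with more ambiguous orientations contribute more
    estimates.
    """
    datasets = list(collection)
    if not datasets:
        raise ValueError("empty collection")
    codes = datasets[0].codes
    pooled: dict[str, list[float]] = {c: [] for c in codes}
    for idx, data in enumerate(datasets):
        if cpdags is not None:
            cpdag = cpdags[idx]
        else:
            cpdag = estimate_cpdag(
                data, alpha, max_cond_size, n_perm,
                seed=child_seed(seed, "cpdag", idx),
            )
        for c in codes:
            pooled[c].extend(effect_estimates(data, cpdag, c, outcome))
    return EffectTable(pooled)
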