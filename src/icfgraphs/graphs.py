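"""PC-algorithm skeleton search, v-structure orientation and Meek closure.

The skeleton of a DAG connects two nodes iff the corresponding variables are
dependent given *every* subset of the remaining variables.  The PC search
starts from the complete graph and deletes the edge X-Y as soon as some
conditioning set S with p-value above the significance level is found,
growing |S| from 0 upward over the current adjacencies of X (then of Y).
Recording the separating sets allows orientation of the unshielded colliders
(X -> Z <- Y whenever Z is not in sepset(X, Y)), and Meek's rules then
propagate to the completed partially directed acyclic graph (CPDAG)
representing the Markov equivalence class.

A d-separation oracle wrapped as a CI test makes the same machinery exact on
a known DAG, which is how the implementation is validated.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .citests import (
    DEFAULT_MAX_COND_SIZE,
    DEFAULT_N_PERM,
    CiResult,
    fisher_exact_binary,
    permutation_ci_test,
)
from .seeds import child_seed

logger = logging.getLogger(__name__)

Edge = frozenset  # unordered node pair


@dataclass
class Skeleton:
    """Undirected graph over category codes."""

    nodes: list[str]
    edges: set[Edge] = field(default_factory=set)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for e in self.edges:
            if len(e) != 2 or not e <= node_set:
                raise ValueError(f"bad edge {set(e)}")

    def has_edge(self, a: str, b: str) -> bool:
        return Edge((a, b)) in self.edges

    def adjacent(self, a: str) -> set[str]:
        return {next(iter(e - {a})) for e in self.edges if a in e}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g

    def edge_list(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.edges)


@dataclass
class Cpdag:
    """Partially directed graph of a Markov equivalence class.

    ``directed`` holds the unambiguous arrows as ordered pairs, ``undirected``
    the ambiguous edges as unordered pairs; the two sets are disjoint and the
    directed part is acyclic.
    """

    nodes: list[str]
    directed: set[tuple[str, str]] = field(default_factory=set)
    undirected: set[Edge] = field(default_factory=set)

    def __post_init__(self) -> None:
        for a, b in self.directed:
            if Edge((a, b)) in self.undirected:
                raise ValueError(f"edge {a}-{b} both directed and undirected")
        dg = nx.DiGraph(self.directed)
        if not nx.is_directed_acyclic_graph(dg):
            raise ValueError("directed part of CPDAG contains a cycle")

    def skeleton(self) -> Skeleton:
        edges = {Edge(e) for e in self.directed} | set(self.undirected)
        return Skeleton(list(self.nodes), edges)

    def parents(self, x: str) -> set[str]:
        return {a for a, b in self.directed if b == x}

    def children(self, x: str) -> set[str]:
        return {b for a, b in self.directed if a == x}

    def undirected_neighbours(self, x: str) -> set[str]:
        return {next(iter(e - {x})) for e in self.undirected if x in e}

    def is_adjacent(self, a: str, b: str) -> bool:
        return (
            Edge((a, b)) in self.undirected
            or (a, b) in self.directed
            or (b, a) in self.directed
        )

    def v_structures(self) -> set[tuple[str, str, str]]:
        """Unshielded colliders (a, z, b) with a < b and a, b non-adjacent."""
        out = set()
        for z in self.nodes:
            for a, b in itertools.combinations(sorted(self.parents(z)), 2):
                if not self.is_adjacent(a, b):
                    out.add((a, z, b))
        return out


SepsetMap = dict  # Edge -> tuple of separating nodes


# ---------------------------------------------------------------------------
# CI-test handles
# ---------------------------------------------------------------------------

def data_ci_test(
    data: pd.DataFrame,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
):
    """CI-test handle over a complete binary data frame.

    Marginal independence (empty conditioning set) uses the Fisher exact
    test; conditional independence uses the stratified permutation test.
    """
    cols = {c: data[c].to_numpy() for c in data.columns}

    def test(x: str, y: str, S: tuple) -> CiResult:
        if not S:
            return fisher_exact_binary(cols[x], cols[y])
        return permutation_ci_test(
            cols[x], cols[y], [cols[s] for s in S],
            n_perm=n_perm, seed=child_seed(seed, "ci", x, y, S),
        )

    return test


def dsep_oracle(dag: nx.DiGraph, x: str, y: str, S=()) -> bool:
    """Exact d-separation of x and y given S in a known DAG.

    Decided by reachability on the moralized ancestral subgraph induced by
    {x, y} union S (delegated to networkx).
    """
    if x in S or y in S:
        raise ValueError("x and y must not be in the conditioning set")
    return nx.is_d_separator(dag, {x}, {y}, set(S))


def oracle_ci_test(dag: nx.DiGraph):
    """CI-test handle answering from the true DAG's d-separations."""

    def test(x: str, y: str, S: tuple) -> CiResult:
        sep = dsep_oracle(dag, x, y, S)
        return CiResult(1.0 if sep else 0.0, 0.0, 0)

    return test


# ---------------------------------------------------------------------------
# PC skeleton search
# ---------------------------------------------------------------------------

def pc_skeleton(
    data,
    alpha: float = 0.05,
    max_cond_size: int = DEFAULT_MAX_COND_SIZE,
    ci_test=None,
    nodes: list[str] | None = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> tuple[Skeleton, SepsetMap]:
    """Estimate the skeleton by the PC edge-deletion sweep.

    ``data`` may be a complete binary DataFrame (``ci_test`` built from it)
    or None when an explicit ``ci_test`` handle and ``nodes`` are given.  An
    edge is deleted at the first conditioning set whose p-value exceeds
    ``alpha``; subsets at each size are scanned in lexicographic order, first
    within adj(X) minus Y, then adj(Y) minus X.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if ci_test is None:
        if data is None:
            raise ValueError("either data or ci_test must be given")
        frame = data.values if hasattr(data, "codes") else data
        nodes = list(frame.columns)
        if frame.isna().any().any():
            raise ValueError("PC requires complete data; impute first")
        ci_test = data_ci_test(frame, n_perm=n_perm, seed=seed)
    elif nodes is None:
        if data is None:
            raise ValueError("nodes must be given with an explicit ci_test")
        frame = data.values if hasattr(data, "codes") else data
        nodes = list(frame.columns)
    nodes = list(nodes)
    if len(nodes) < 2:
        raise ValueError("need at least two columns")

    adj: dict[str, set[str]] = {v: set(nodes) - {v} for v in nodes}
    sepsets: SepsetMap = {}

    for ell in range(max_cond_size + 1):
        any_candidate = False
        for x, y in _current_edges(adj):
            if y not in adj[x]:
                continue  # removed earlier in this sweep
            found = False
            tried: set[tuple] = set()
            for base in (adj[x] - {y}, adj[y] - {x}):
                if len(base) < ell:
                    continue
                any_candidate = True
                for S in itertools.combinations(sorted(base), ell):
                    if S in tried:
                        continue
                    tried.add(S)
                    res = ci_test(x, y, S)
                    p = res.p_value if isinstance(res, CiResult) else float(res)
                    if p > alpha:
                        adj[x].discard(y)
                        adj[y].discard(x)
                        sepsets[Edge((x, y))] = S
                        found = True
                        break
                if found:
                    break
        if not any_candidate and ell > 0:
            break

    edges = {Edge((x, y)) for x in nodes for y in adj[x]}
    return Skeleton(nodes, edges), sepsets


def _current_edges(adj) -> list[tuple[str, str]]:
    return sorted(
        (x, y) for x in adj for y in adj[x] if x < y
    )


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def orient_cpdag(skeleton: Skeleton, sepsets: SepsetMap) -> Cpdag:
    """Orient unshielded colliders from the sepset map, then close under Meek.

    A triple X-Z-Y with X, Y non-adjacent becomes X -> Z <- Y iff Z is not in
    sepset(X, Y).  If two colliders demand opposite directions for one edge
    (possible with sampled sepsets), the edge degrades to undirected and a
    warning is logged.
    """
    votes: set[tuple[str, str]] = set()
    for z in skeleton.nodes:
        nbrs = sorted(skeleton.adjacent(z))
        for x, y in itertools.combinations(nbrs, 2):
            if skeleton.has_edge(x, y):
                continue
            S = sepsets.get(Edge((x, y)))
            if S is None or z in S:
                continue
            votes.add((x, z))
            votes.add((y, z))

    conflicted = {Edge(e) for e in votes if (e[1], e[0]) in votes}
    if conflicted:
        logger.warning("%d edge(s) with conflicting collider orientations "
                       "left undirected", len(conflicted))
        for e in sorted(tuple(sorted(c)) for c in conflicted):
            logger.debug("conflicting collider orientations: %s-%s", *e)
    directed = {e for e in votes if Edge(e) not in conflicted}
    undirected = {e for e in skeleton.edges
                  if not any(Edge(d) == e for d in directed)}
    directed, undirected = _meek_closure(skeleton, directed, undirected)
    # with sampled sepsets inconsistent v-structures can leave a directed
    # cycle; degrade deterministically chosen cycle edges to undirected
    dg = nx.DiGraph()
    dg.add_nodes_from(skeleton.nodes)
    dg.add_edges_from(directed)
    while not nx.is_directed_acyclic_graph(dg):
        cycle = nx.find_cycle(dg)
        edge = min(cycle)
        logger.debug("directed cycle from inconsistent sepsets; "
                     "edge %s->%s left undirected", *edge)
        dg.remove_edge(*edge)
        directed.discard(tuple(edge))
        undirected.add(Edge(edge))
    return Cpdag(list(skeleton.nodes), directed, undirected)


def _meek_closure(skeleton: Skeleton, directed, undirected):
    """Apply Meek rules 1-4 to a fixpoint."""
    directed = set(directed)
    undirected = set(undirected)
    adjacent = skeleton.has_edge

    def orient(a, b) -> bool:
        e = Edge((a, b))
        if e in undirected and (b, a) not in directed:
            undirected.discard(e)
            directed.add((a, b))
            return True
        return False

    changed = True
    while changed:
        changed = False
        for e in sorted(tuple(sorted(u)) for u in undirected):
            for a, b in (e, e[::-1]):
                # R1: c -> a, a - b, c and b non-adjacent  =>  a -> b
                if any((c, a) in directed and not adjacent(c, b)
                       for c in skeleton.adjacent(a) if c != b):
                    changed |= orient(a, b)
                    break
                # R2: a -> c -> b with a - b  =>  a -> b
                if any((a, c) in directed and (c, b) in directed
                       for c in skeleton.adjacent(a) if c != b):
                    changed |= orient(a, b)
                    break
                # R3: a - c -> b, a - d -> b, c and d non-adjacent  =>  a -> b
                cands = [c for c in skeleton.adjacent(a)
                         if Edge((a, c)) in undirected and (c, b) in directed]
                if any(not adjacent(c, d)
                       for c, d in itertools.combinations(sorted(cands), 2)):
                    changed |= orient(a, b)
                    break
                # R4: a - c, c -> d, d -> b, c and b non-adjacent  =>  a -> b
                r4 = False
                for c in skeleton.adjacent(a):
                    if c == b or Edge((a, c)) not in undirected or adjacent(c, b):
                        for_c = False
                    else:
                        for_c = any((c, d) in directed and (d, b) in directed
                                    for d in skeleton.adjacent(c))
                    if for_c:
                        r4 = True
                        break
                if r4:
                    changed |= orient(a, b)
                    break
    return directed, undirected


def dag_to_cpdag(dag: nx.DiGraph) -> Cpdag:
    """Completed partially directed graph of the DAG's equivalence class.

    Orients the DAG's unshielded colliders on its skeleton and closes under
    the Meek rules; every other edge is ambiguous and stays undirected.
    """
    nodes = list(dag.nodes)
    skel = Skeleton(nodes, {Edge(e) for e in dag.edges})
    und = nx.Graph(dag.to_undirected())
    votes: set[tuple[str, str]] = set()
    for z in nodes:
        for a, b in itertools.combinations(sorted(dag.predecessors(z)), 2):
            if not und.has_edge(a, b):
                votes.add((a, z))
                votes.add((b, z))
    undirected = {e for e in skel.edges if not any(Edge(d) == e for d in votes)}
    directed, undirected = _meek_closure(skel, votes, undirected)
    return Cpdag(nodes, directed, undirected)
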