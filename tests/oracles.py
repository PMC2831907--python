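"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written from first principles (enumeration,
path tracing, closed forms) and shares no algorithmic code with the package:
these functions define what the fast implementations must agree with on
small instances.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy import stats


def fisher_p_by_enumeration(table) -> float:
    """Two-sided Fisher p-value by summing hypergeometric probabilities.

    Sums P(k) over every table with the observed margins whose probability
    does not exceed the observed table's (with a tiny relative tolerance for
    floating-point ties).
    """
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, n, c1, r1)
    obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= obs * (1 + 1e-9)].sum()))


def dsep_by_path_enumeration(dag: nx.DiGraph, x: str, y: str, S) -> bool:
    """d-separation by checking every undirected simple path for blockage."""
    Sset = set(S)
    anc = {v: nx.ancestors(dag, v) | {v} for v in dag.nodes}
    for path in nx.all_simple_paths(dag.to_undirected(), x, y):
        open_path = True
        for i in range(1, len(path) - 1):
            a, b, c = path[i - 1], path[i], path[i + 1]
            is_collider = dag.has_edge(a, b) and dag.has_edge(c, b)
            if is_collider:
                # open iff the collider is in S or has a descendant in S
                if not any(b in anc[s] for s in Sset):
                    open_path = False
                    break
            elif b in Sset:
                open_path = False
                break
        if open_path:
            return False
    return True


def path_product_effect(model, x: str, y: str) -> float:
    """Total effect in a linear-probability model: sum of path products.

    For y = "ghp" the outcome equation's weights extend each directed path
    from x to a weighted node (including the trivial path to x itself).
    """
    dag = model.dag

    def node_effect(target: str) -> float:
        if target == x:
            return 1.0
        total = 0.0
        for path in nx.all_simple_paths(dag, x, target):
            prod = 1.0
            for u, v in zip(path, path[1:]):
                prod *= model.weights[v][u]
            total += prod
        return total

    if y == "ghp":
        return sum(w * node_effect(c) for c, w in model.outcome_spec.weights.items())
    return node_effect(y)


def _colliders(dag: nx.DiGraph) -> set[tuple[str, str, str]]:
    out = set()
    und = dag.to_undirected()
    for z in dag.nodes:
        for a, b in itertools.combinations(sorted(dag.predecessors(z)), 2):
            if not und.has_edge(a, b):
                out.add((a, z, b))
    return out


def cpdag_by_class_enumeration(dag: nx.DiGraph):
    """(directed, undirected) edge sets of the equivalence class of ``dag``.

    Enumerates all 2^|E| orientations of the skeleton, keeps the acyclic ones
    with the same unshielded colliders (Markov equivalence), and marks an
    edge directed iff it has the same orientation in every member.
    """
    edges = sorted(tuple(sorted(e)) for e in dag.to_undirected().edges)
    target = _colliders(dag)
    members = []
    for bits in itertools.product((0, 1), repeat=len(edges)):
        g = nx.DiGraph()
        g.add_nodes_from(dag.nodes)
        g.add_edges_from(e if bit == 0 else e[::-1]
                         for e, bit in zip(edges, bits))
        if nx.is_directed_acyclic_graph(g) and _colliders(g) == target:
            members.append(g)
    directed, undirected = set(), set()
    for e in edges:
        orients = {("f" if g.has_edge(*e) else "b") for g in members}
        if orients == {"f"}:
            directed.add(e)
        elif orients == {"b"}:
            directed.add(e[::-1])
        else:
            undirected.add(frozenset(e))
    return directed, undirected, members


def parent_sets_by_class_enumeration(cpdag, x: str) -> list[tuple[str, ...]]:
    """Realizable parent sets of x over all consistent DAG extensions.

    Orients every undirected CPDAG edge both ways, keeping orientations that
    are acyclic and create no unshielded collider beyond those already
    present among the CPDAG's directed edges.
    """
    und = sorted(tuple(sorted(e)) for e in cpdag.undirected)
    base = nx.DiGraph()
    base.add_nodes_from(cpdag.nodes)
    base.add_edges_from(cpdag.directed)
    target = _pdag_colliders(cpdag.nodes, cpdag.directed, cpdag.undirected)
    found = set()
    for bits in itertools.product((0, 1), repeat=len(und)):
        g = base.copy()
        g.add_edges_from(e if bit == 0 else e[::-1]
                         for e, bit in zip(und, bits))
        if not nx.is_directed_acyclic_graph(g):
            continue
        if _colliders(g) != target:
            continue
        found.add(tuple(sorted(g.predecessors(x))))
    return sorted(found)


def _pdag_colliders(nodes, directed, undirected) -> set[tuple[str, str, str]]:
    """Unshielded colliders of a PDAG: pairs of directed-only parents that
    are non-adjacent (undirected edges count for adjacency, not parenthood)."""
    adj = {frozenset(e) for e in directed} | set(undirected)
    out = set()
    for z in nodes:
        pa = sorted(a for a, b in directed if b == z)
        for a, b in itertools.combinations(pa, 2):
            if frozenset((a, b)) not in adj:
                out.add((a, z, b))
    return out
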