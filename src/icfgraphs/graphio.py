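"""Graph serialization: edge-list text, DOT and GraphML."""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from .aggregation import SummaryGraph
from .graphs import Cpdag, Edge, Skeleton


def skeleton_to_edgelist(skel: Skeleton) -> str:
    lines = [f"# nodes: {' '.join(skel.nodes)}"]
    lines += [f"{a} -- {b}" for a, b in skel.edge_list()]
    return "\n".join(lines) + "\n"


def skeleton_from_edgelist(text: str) -> Skeleton:
    nodes: list[str] = []
    edges: set[Edge] = set()
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("# nodes:"):
            nodes = line.removeprefix("# nodes:").split()
        else:
            a, sep, b = line.partition(" -- ")
            if not sep:
                raise ValueError(f"bad edge line: {line!r}")
            edges.add(Edge((a.strip(), b.strip())))
    return Skeleton(nodes, edges)


def cpdag_to_edgelist(cpdag: Cpdag) -> str:
    lines = [f"# nodes: {' '.join(cpdag.nodes)}"]
    lines += [f"{a} -> {b}" for a, b in sorted(cpdag.directed)]
    lines += [f"{a} -- {b}" for a, b in
              sorted(tuple(sorted(e)) for e in cpdag.undirected)]
    return "\n".join(lines) + "\n"


def cpdag_from_edgelist(text: str) -> Cpdag:
    nodes: list[str] = []
    directed: set[tuple[str, str]] = set()
    undirected: set[Edge] = set()
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("# nodes:"):
            nodes = line.removeprefix("# nodes:").split()
        elif " -> " in line:
            a, _, b = line.partition(" -> ")
            directed.add((a.strip(), b.strip()))
        elif " -- " in line:
            a, _, b = line.partition(" -- ")
            undirected.add(Edge((a.strip(), b.strip())))
        else:
            raise ValueError(f"bad edge line: {line!r}")
    return Cpdag(nodes, directed, undirected)


def summary_to_dot(summary: SummaryGraph, scale: float = 4.0) -> str:
    """DOT rendering with edge thickness proportional to reliability."""
    lines = ["graph summary {", "  node [shape=ellipse];"]
    for node in summary.nodes:
        lines.append(f'  "{node}";')
    for (a, b), rel in summary.reliabilities().items():
        lines.append(
            f'  "{a}" -- "{b}" [penwidth={scale * rel:.2f}, '
            f'label="{rel:.2f}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def cpdag_to_dot(cpdag: Cpdag) -> str:
    lines = ["digraph cpdag {"]
    for node in cpdag.nodes:
        lines.append(f'  "{node}";')
    for a, b in sorted(cpdag.directed):
        lines.append(f'  "{a}" -> "{b}";')
    for a, b in sorted(tuple(sorted(e)) for e in cpdag.undirected):
        lines.append(f'  "{a}" -> "{b}" [dir=none];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_graphml(graph, path: str | Path) -> None:
    """GraphML export; CPDAGs become directed graphs with a ``directed``
    edge attribute distinguishing unambiguous arrows from ambiguous edges."""
    if isinstance(graph, Skeleton):
        g = graph.to_networkx()
    elif isinstance(graph, SummaryGraph):
        g = graph.to_skeleton().to_networkx()
        for (a, b), rel in graph.reliabilities().items():
            g.edges[a, b]["reliability"] = rel
    elif isinstance(graph, Cpdag):
        g = nx.DiGraph()
        g.add_nodes_from(graph.nodes)
        for a, b in sorted(graph.directed):
            g.add_edge(a, b, directed=True)
        for a, b in sorted(tuple(sorted(e)) for e in graph.undirected):
            g.add_edge(a, b, directed=False)
    else:
        g = graph
    nx.write_graphml(g, path)
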