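"""Directed acyclic causal graphs over feature names.

``CausalGraph`` wraps a :class:`networkx.DiGraph` with an explicit node
order so that topological sorts (and hence generation order in the
structural model) are deterministic: ties are broken by position in the
node list, which for the 27-tag schema is the canonical tag order.

``PDAG`` holds the partially directed output of constraint-based
discovery; ``orient_edges`` turns it into a DAG using machine-readable
domain knowledge (explicit per-edge orientations plus an optional
precedence order as fallback).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx


class CausalGraph:
    """A DAG over named features with deterministic topological order."""

    def __init__(self, nodes: Sequence[str], edges: Iterable[tuple[str, str]] = ()):
        self.nodes: list[str] = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        self._order = {n: i for i, n in enumerate(self.nodes)}
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for a, b in edges:
            if a not in self._order or b not in self._order:
                raise KeyError(f"edge ({a}, {b}) references unknown node")
            g.add_edge(a, b)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise ValueError(f"graph contains a cycle: {cyc}")
        self._g = g

    # -- queries ---------------------------------------------------------
    def _check(self, node: str) -> None:
        if node not in self._order:
            raise KeyError(f"unknown node: {node}")

    def parents(self, node: str) -> list[str]:
        self._check(node)
        return sorted(self._g.predecessors(node), key=self._order.__getitem__)

    def children(self, node: str) -> list[str]:
        self._check(node)
        return sorted(self._g.successors(node), key=self._order.__getitem__)

    def descendants(self, node: str) -> set[str]:
        self._check(node)
        return set(nx.descendants(self._g, node))

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self._g, key=self._order.__getitem__))

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._g.edges())

    def __contains__(self, node: str) -> bool:
        return node in self._order

    def __eq__(self, other) -> bool:
        return (isinstance(other, CausalGraph)
                and self.nodes == other.nodes and self.edges == other.edges)

    def __repr__(self):
        return f"CausalGraph({len(self.nodes)} nodes, {self._g.number_of_edges()} edges)"


@dataclass
class PDAG:
    """Partially directed graph: discovery output before manual orientation."""

    nodes: list[str]
    directed: set = field(default_factory=set)    # (cause, effect)
    undirected: set = field(default_factory=set)  # frozenset({a, b})

    def add_undirected(self, a: str, b: str) -> None:
        self.undirected.add(frozenset((a, b)))

    def add_directed(self, a: str, b: str) -> None:
        self.directed.add((a, b))


@dataclass
class OrientationRules:
    """Machine-readable domain knowledge for orienting undirected edges.

    ``explicit`` lists (cause, effect) pairs; ``precedence`` is an
    optional total order over features used as fallback — an uncovered
    undirected edge is oriented from the earlier to the later feature.
    """

    explicit: list[tuple[str, str]] = field(default_factory=list)
    precedence: list[str] | None = None

    def __post_init__(self):
        pairs = set(self.explicit)
        for a, b in pairs:
            if (b, a) in pairs:
                raise ValueError(f"conflicting orientation rules for edge {a}–{b}")

    def orient(self, a: str, b: str) -> tuple[str, str] | None:
        if (a, b) in self.explicit:
            return (a, b)
        if (b, a) in self.explicit:
            return (b, a)
        if self.precedence is not None and a in self.precedence and b in self.precedence:
            return (a, b) if self.precedence.index(a) < self.precedence.index(b) else (b, a)
        return None


def orient_edges(pdag: PDAG, rules: OrientationRules) -> CausalGraph:
    """Resolve every undirected edge of ``pdag`` into a DAG.

    Already-directed edges are kept as discovered.  Orienting an edge
    that would close a cycle is an error naming the cycle.
    """
    g = nx.DiGraph()
    g.add_nodes_from(pdag.nodes)
    g.add_edges_from(pdag.directed)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError(f"directed part already cyclic: {nx.find_cycle(g)}")
    order = {n: i for i, n in enumerate(pdag.nodes)}
    for pair in sorted(pdag.undirected, key=lambda p: sorted(order[x] for x in p)):
        a, b = sorted(pair, key=order.__getitem__)
        oriented = rules.orient(a, b)
        if oriented is None:
            raise ValueError(
                f"undirected edge {a}–{b} not covered by any rule or precedence order"
            )
        g.add_edge(*oriented)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise ValueError(f"orienting {oriented[0]}->{oriented[1]} creates a cycle: {cyc}")
    return CausalGraph(pdag.nodes, g.edges())


# ---------------------------------------------------------------------------
# Edge-list I/O: one "CAUSE -> EFFECT" per line; isolated nodes on their own line
# ---------------------------------------------------------------------------

def write_graph(graph: CausalGraph, path: str | Path) -> None:
    lines = []
    with_edges = {n for e in graph.edges for n in e}
    order = {n: i for i, n in enumerate(graph.nodes)}
    for a, b in sorted(graph.edges, key=lambda e: (order[e[0]], order[e[1]])):
        lines.append(f"{a} -> {b}")
    for n in graph.nodes:
        if n not in with_edges:
            lines.append(n)
    Path(path).write_text("\n".join(lines) + "\n", "utf-8")


def read_graph(path: str | Path, schema: Sequence[str] | None = None) -> CausalGraph:
    """Read an edge-list file; validates acyclicity and (optionally) a node schema."""
    nodes: list[str] = []
    edges: list[tuple[str, str]] = []

    def add_node(n: str) -> None:
        if schema is not None and n not in schema:
            raise ValueError(f"unknown node name in graph file: {n!r}")
        if n not in nodes:
            nodes.append(n)

    for raw in Path(path).read_text("utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "->" in line:
            a, b = (s.strip() for s in line.split("->", 1))
            add_node(a)
            add_node(b)
            edges.append((a, b))
        else:
            add_node(line)
    if schema is not None:
        nodes = [n for n in schema if n in nodes] + [n for n in nodes if n not in schema]
    return CausalGraph(nodes, edges)


def to_dot(graph: CausalGraph) -> str:
    """DOT export for visualization."""
    body = "\n".join(f'  "{a}" -> "{b}";' for a, b in sorted(graph.edges))
    return "digraph causal {\n" + body + "\n}\n"
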