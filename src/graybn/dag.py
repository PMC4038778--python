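"""Directed acyclic graphs over named nodes.

A :class:`DAG` is the structure half of a linear-Gaussian Bayesian network:
an ordered node list (one node per region of interest) plus a set of directed
``(parent, child)`` edges with no self-loops and no directed cycles.  Parent
sets are derivable for every node, which is what the network factorisation
``p(X) = prod_j p(X_j | parents(X_j))`` requires.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import networkx as nx

__all__ = ["DAG", "CycleError"]


class CycleError(ValueError):
    """Raised when an edge set contains a directed cycle or self-loop."""


class DAG:
    """Immutable directed acyclic graph over an ordered list of named nodes.

    Parameters
    ----------
    nodes
        Ordered node names; order fixes the column convention of every data
        matrix the graph is scored against.
    edges
        Iterable of ``(parent, child)`` name pairs.

    Raises
    ------
    CycleError
        If an edge is a self-loop or the edge set contains a directed cycle.
    ValueError
        If an edge mentions an unknown node or a node name is duplicated.
    """

    __slots__ = ("_nodes", "_edges", "_parents", "_children", "_index")

    def __init__(self, nodes: Sequence[str], edges: Iterable[tuple[str, str]] = ()):
        nodes = tuple(str(n) for n in nodes)
        if len(set(nodes)) != len(nodes):
            raise ValueError("duplicate node names")
        self._nodes = nodes
        self._index = {n: i for i, n in enumerate(nodes)}
        edge_set = set()
        for p, c in edges:
            if p not in self._index or c not in self._index:
                raise ValueError(f"edge ({p!r}, {c!r}) mentions unknown node")
            if p == c:
                raise CycleError(f"self-loop on node {p!r}")
            edge_set.add((p, c))
        self._edges = frozenset(edge_set)
        self._parents = {n: tuple() for n in nodes}
        self._children = {n: tuple() for n in nodes}
        by_child: dict[str, list[str]] = {n: [] for n in nodes}
        by_parent: dict[str, list[str]] = {n: [] for n in nodes}
        for p, c in sorted(edge_set):
            by_child[c].append(p)
            by_parent[p].append(c)
        self._parents = {n: tuple(by_child[n]) for n in nodes}
        self._children = {n: tuple(by_parent[n]) for n in nodes}
        if edge_set and not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise CycleError("edge set contains a directed cycle")

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return self._edges

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    def parents(self, node: str) -> tuple[str, ...]:
        """Parent names of *node*, sorted for determinism."""
        return self._parents[node]

    def children(self, node: str) -> tuple[str, ...]:
        return self._children[node]

    def has_edge(self, parent: str, child: str) -> bool:
        return (parent, child) in self._edges

    def __contains__(self, edge: tuple[str, str]) -> bool:
        return edge in self._edges

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DAG)
            and self._nodes == other._nodes
            and self._edges == other._edges
        )

    def __hash__(self) -> int:
        return hash((self._nodes, self._edges))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"DAG(nodes={list(self._nodes)}, edges={sorted(self._edges)})"

    # -- graph operations --------------------------------------------------

    def add_edge(self, parent: str, child: str) -> "DAG":
        """Return a new DAG with the edge added (validates acyclicity)."""
        return DAG(self._nodes, self._edges | {(parent, child)})

    def remove_edge(self, parent: str, child: str) -> "DAG":
        if (parent, child) not in self._edges:
            raise ValueError(f"edge ({parent!r}, {child!r}) not in graph")
        return DAG(self._nodes, self._edges - {(parent, child)})

    def topological_order(self) -> list[str]:
        """Deterministic topological order (ties broken by node-list order)."""
        g = self.to_networkx()
        return list(nx.lexicographical_topological_sort(g, key=self._index.__getitem__))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self._edges)
        return g

    # -- structure comparison ----------------------------------------------

    def skeleton(self) -> frozenset[frozenset[str]]:
        """Undirected edge set (adjacencies ignoring orientation)."""
        return frozenset(frozenset(e) for e in self._edges)

    def v_structures(self) -> frozenset[tuple[str, str, str]]:
        """Colliders ``a -> c <- b`` with *a*, *b* non-adjacent, as (a, c, b), a < b.

        Together with the skeleton these characterise the Markov equivalence
        class of the DAG: equivalent DAGs are indistinguishable by any
        likelihood-based score on observational Gaussian data.
        """
        out = set()
        skel = self.skeleton()
        for c in self._nodes:
            ps = self._parents[c]
            for i in range(len(ps)):
                for j in range(i + 1, len(ps)):
                    a, b = sorted((ps[i], ps[j]))
                    if frozenset((a, b)) not in skel:
                        out.add((a, c, b))
        return frozenset(out)

    def markov_equivalent(self, other: "DAG") -> bool:
        return (
            self.skeleton() == other.skeleton()
            and self.v_structures() == other.v_structures()
        )


def enumerate_dags(nodes: Sequence[str]) -> Iterator[DAG]:
    """Yield every labelled DAG on *nodes* (3 at d=2, 25 at d=3, 543 at d=4).

    Brute-force generate-and-filter over all subsets of ordered pairs;
    intended for small d only (the caller guards the explosion).
    """
    nodes = tuple(nodes)
    pairs = [(p, c) for p in nodes for c in nodes if p != c]
    for mask in range(1 << len(pairs)):
        edges = [pairs[k] for k in range(len(pairs)) if mask >> k & 1]
        try:
            yield DAG(nodes, edges)
        except CycleError:
            continue
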