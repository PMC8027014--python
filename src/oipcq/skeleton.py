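"""Undirected network skeletons and separator-set construction.

The skeleton is the working object of constraint-based structure learning:
the graph that remains after all conditional-independence tests up to the
current order. Two separator pools are defined for an edge X–Y:

* ``V_XY = ADJ(X) ∩ ADJ(Y)`` — the mid-nodes of length-2 paths, the pool
  classically used by PC-style algorithms at every order;
* ``U_XY = (ADJ(X) ∪ ADJ(Y)) \\ {X, Y}`` — the union of neighborhoods, which
  additionally covers paths of length 3 (X–Z–W–Y) when conditioning sets of
  size two are drawn from it.

Skeletons are immutable values: edge removals return a new skeleton. This is
deliberate — order independence of the quantile algorithm rests on freezing
the separator pools of an order before any removal of that order is applied.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Iterator

import networkx as nx

__all__ = ["Skeleton", "complete_skeleton"]

Edge = tuple[str, str]


def _canon(a: str, b: str) -> Edge:
    """Canonical (lexicographically sorted) form of an undirected edge."""
    if a == b:
        raise ValueError(f"self-loop on {a!r} is not a valid skeleton edge")
    return (a, b) if a < b else (b, a)


class Skeleton:
    """An undirected graph over a fixed gene set.

    Equality compares the gene *set* and the edge *set* only; neither the
    order in which genes were listed nor the order in which edges were added
    matters. Instances are immutable and hashable.
    """

    __slots__ = ("_gene_ids", "_gene_set", "_edges", "_adj")

    def __init__(self, gene_ids: Iterable[str], edges: Iterable[Edge] = ()) -> None:
        ids = tuple(gene_ids)
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            for g in ids:
                if g in seen:
                    raise ValueError(f"duplicate gene id {g!r}")
                seen.add(g)
        if any(not g for g in ids):
            raise ValueError("gene ids must be non-empty strings")
        self._gene_ids = ids
        self._gene_set = frozenset(ids)
        canon = frozenset(_canon(a, b) for a, b in edges)
        for a, b in canon:
            if a not in self._gene_set or b not in self._gene_set:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown gene")
        self._edges = canon
        adj: dict[str, set[str]] = {g: set() for g in ids}
        for a, b in canon:
            adj[a].add(b)
            adj[b].add(a)
        self._adj = {g: frozenset(n) for g, n in adj.items()}

    # -- basic accessors ---------------------------------------------------

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return self._gene_ids

    @property
    def edges(self) -> frozenset[Edge]:
        return self._edges

    @property
    def n_genes(self) -> int:
        return len(self._gene_ids)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def has_edge(self, a: str, b: str) -> bool:
        return _canon(a, b) in self._edges

    def __contains__(self, pair: Edge) -> bool:
        return _canon(*pair) in self._edges

    def __iter__(self) -> Iterator[Edge]:
        return iter(sorted(self._edges))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Skeleton):
            return NotImplemented
        return self._gene_set == other._gene_set and self._edges == other._edges

    def __hash__(self) -> int:
        return hash((self._gene_set, self._edges))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Skeleton({self.n_genes} genes, {self.n_edges} edges)"

    # -- neighborhoods and separator pools ---------------------------------

    def adjacent(self, x: str) -> frozenset[str]:
        """Neighbors ADJ(x); ``x`` itself is never a member."""
        try:
            return self._adj[x]
        except KeyError:
            raise KeyError(f"unknown gene {x!r}") from None

    def v_set(self, x: str, y: str) -> frozenset[str]:
        """Common neighbors of ``x`` and ``y`` — mid-nodes of length-2 paths."""
        if x == y:
            raise ValueError("v_set requires two distinct genes")
        return (self.adjacent(x) & self.adjacent(y)) - {x, y}

    def u_set(self, x: str, y: str) -> frozenset[str]:
        """Union of neighborhoods of ``x`` and ``y``, excluding both endpoints."""
        if x == y:
            raise ValueError("u_set requires two distinct genes")
        return (self.adjacent(x) | self.adjacent(y)) - {x, y}

    # -- derivation --------------------------------------------------------

    def remove_edges(self, edges: Iterable[Edge]) -> "Skeleton":
        """Return a new skeleton with the given edges removed (batch semantics)."""
        drop = {_canon(a, b) for a, b in edges}
        return Skeleton(self._gene_ids, self._edges - drop)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._gene_ids)
        g.add_edges_from(self._edges)
        return g


def complete_skeleton(gene_ids: Iterable[str]) -> Skeleton:
    """The complete undirected graph over ``gene_ids`` — the starting point
    of every PC-style run (all n(n−1)/2 edges present)."""
    ids = tuple(gene_ids)
    return Skeleton(ids, combinations(sorted(ids), 2))
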