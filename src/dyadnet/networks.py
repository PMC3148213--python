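"""Binary relational data containers.

Three network variants are supported:

* :class:`BipartiteNetwork` — actors × events (women × social events,
  genes × diseases, consumers × products).  The observation is an
  ``N × M`` 0/1 matrix.
* :class:`UndirectedNetwork` — a single node set, unordered edges.
* :class:`DirectedNetwork` — a single node set, ordered arcs; each
  unordered node pair forms a dyad with four possible states
  ``(x_ij, x_ji)``.

All containers are immutable after construction, use 0-based integer
indices internally and keep the user-supplied string labels for I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

import numpy as np

__all__ = [
    "BipartiteNetwork",
    "DirectedNetwork",
    "UndirectedNetwork",
]


def _check_labels(labels: Sequence[str], what: str) -> Tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(labels) < 1:
        raise ValueError(f"{what}: need at least one label")
    if len(set(labels)) != len(labels):
        raise ValueError(f"{what}: labels must be unique")
    return labels


@dataclass(frozen=True)
class BipartiteNetwork:
    """A binary bipartite network of ``N`` actors and ``M`` events.

    Parameters
    ----------
    actor_labels, event_labels
        Unique string labels; sizes define ``N`` and ``M``.
    edges
        Iterable of 0-based ``(actor_index, event_index)`` pairs.
    """

    actor_labels: Tuple[str, ...]
    event_labels: Tuple[str, ...]
    edges: frozenset = field(default_factory=frozenset)

    def __init__(self, actor_labels, event_labels, edges=()):
        object.__setattr__(self, "actor_labels", _check_labels(actor_labels, "actors"))
        object.__setattr__(self, "event_labels", _check_labels(event_labels, "events"))
        es = set()
        for i, j in edges:
            i, j = int(i), int(j)
            if not (0 <= i < self.n_actors and 0 <= j < self.n_events):
                raise ValueError(f"edge ({i},{j}) out of range")
            es.add((i, j))
        object.__setattr__(self, "edges", frozenset(es))

    @property
    def n_actors(self) -> int:
        return len(self.actor_labels)

    @property
    def n_events(self) -> int:
        return len(self.event_labels)

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_actors, self.n_events)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def x(self, i: int, j: int) -> int:
        """Observation ``x_ij`` ∈ {0, 1}."""
        return 1 if (i, j) in self.edges else 0

    def adjacency(self) -> np.ndarray:
        """Dense ``N × M`` 0/1 adjacency matrix."""
        a = np.zeros(self.shape, dtype=np.int8)
        for i, j in self.edges:
            a[i, j] = 1
        return a

    @classmethod
    def from_adjacency(cls, x, actor_labels=None, event_labels=None) -> "BipartiteNetwork":
        x = np.asarray(x)
        if x.ndim != 2:
            raise ValueError("adjacency must be 2-D")
        if not np.isin(x, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        n, m = x.shape
        if actor_labels is None:
            actor_labels = [f"a{i}" for i in range(n)]
        if event_labels is None:
            event_labels = [f"e{j}" for j in range(m)]
        edges = zip(*np.nonzero(x))
        return cls(actor_labels, event_labels, edges)

    def degrees(self) -> Tuple[np.ndarray, np.ndarray]:
        """(actor degrees, event degrees)."""
        x = self.adjacency()
        return x.sum(axis=1), x.sum(axis=0)


@dataclass(frozen=True)
class DirectedNetwork:
    """A directed unipartite network without self-loops.

    Each unordered node pair ``{i, j}`` forms a dyad whose state is the
    4-valued variable ``(x_ij, x_ji)`` ∈ {00, 10, 01, 11}.
    """

    node_labels: Tuple[str, ...]
    arcs: frozenset = field(default_factory=frozenset)

    def __init__(self, node_labels, arcs=()):
        object.__setattr__(self, "node_labels", _check_labels(node_labels, "nodes"))
        a = set()
        for i, j in arcs:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError(f"self-loop at node {i}")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"arc ({i},{j}) out of range")
            a.add((i, j))
        object.__setattr__(self, "arcs", frozenset(a))

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def x(self, i: int, j: int) -> int:
        return 1 if (i, j) in self.arcs else 0

    def dyad_state(self, i: int, j: int) -> Tuple[int, int]:
        """The 4-state dyad value ``(x_ij, x_ji)``."""
        return (self.x(i, j), self.x(j, i))

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        for i, j in self.arcs:
            a[i, j] = 1
        return a

    @classmethod
    def from_adjacency(cls, x, node_labels=None) -> "DirectedNetwork":
        x = np.asarray(x)
        if x.ndim != 2 or x.shape[0] != x.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(np.diag(x)):
            raise ValueError("self-loops not allowed")
        n = x.shape[0]
        if node_labels is None:
            node_labels = [f"n{i}" for i in range(n)]
        return cls(node_labels, zip(*np.nonzero(x)))

    def degree_vectors(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-node (in-degree, out-degree, reciprocated-degree).

        Reciprocated degree counts, for each node, the neighbours with
        which *both* arcs are present; such a mutual pair contributes
        once to each endpoint's reciprocated degree.
        """
        n = self.n_nodes
        indeg = np.zeros(n, dtype=int)
        outdeg = np.zeros(n, dtype=int)
        recdeg = np.zeros(n, dtype=int)
        for i, j in self.arcs:
            outdeg[i] += 1
            indeg[j] += 1
            if (j, i) in self.arcs:
                recdeg[i] += 1
        return indeg, outdeg, recdeg

    def mutual_pairs(self) -> set:
        """Unordered pairs {i, j} with both arcs present."""
        return {frozenset((i, j)) for i, j in self.arcs if (j, i) in self.arcs}

    def asymmetric_arcs(self) -> set:
        """Arcs (i, j) whose reverse is absent."""
        return {(i, j) for i, j in self.arcs if (j, i) not in self.arcs}


@dataclass(frozen=True)
class UndirectedNetwork:
    """An undirected unipartite network; edges are unordered pairs."""

    node_labels: Tuple[str, ...]
    edges: frozenset = field(default_factory=frozenset)

    def __init__(self, node_labels, edges=()):
        object.__setattr__(self, "node_labels", _check_labels(node_labels, "nodes"))
        es = set()
        for i, j in edges:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError(f"self-loop at node {i}")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"edge ({i},{j}) out of range")
            es.add((min(i, j), max(i, j)))
        object.__setattr__(self, "edges", frozenset(es))

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def x(self, i: int, j: int) -> int:
        return 1 if (min(i, j), max(i, j)) in self.edges else 0

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        for i, j in self.edges:
            a[i, j] = 1
            a[j, i] = 1
        return a

    def degrees(self) -> np.ndarray:
        return self.adjacency().sum(axis=1)
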