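"""Core graph data model for ontologies.

An ontology is held as a labelled directed graph: one node per class
(identifier, display label, synonym list) and one edge per parent->child
subclass/development relation.  Structure matching operates on *windowed
subgraphs*: for a generator node the subgraph contains every class reachable
within ``W`` edges travelling all-upstream (ancestors) or all-downstream
(descendants), with the induced edge set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)


class OntologyError(ValueError):
    """Malformed ontology content or an operation on absent classes."""


class ClassNotFoundError(OntologyError):
    """A class id was referenced that does not exist in the ontology."""


@dataclass
class OntoClass:
    """A single ontology class: opaque id, display label, synonym list."""

    id: str
    label: str
    synonyms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise OntologyError("class id must be non-empty")
        # synonyms: de-duplicated, never containing the label itself
        seen: set[str] = {self.label}
        cleaned: list[str] = []
        for s in self.synonyms:
            if s and s not in seen:
                cleaned.append(s)
                seen.add(s)
        self.synonyms = cleaned

    def all_names(self) -> list[str]:
        """Label first, then synonyms (the name list used for matching)."""
        return [self.label] + list(self.synonyms)


class OntologyGraph:
    """Directed graph of classes with parent->child edges.

    Tolerant of ill-formed inputs: may be disconnected, may contain cycles
    in storage.  Self-loops and duplicate edges are silently dropped on
    insertion (a debug message is logged).
    """

    def __init__(self, name: str = "") -> None:
        self.name = name
        self._classes: dict[str, OntoClass] = {}
        self._g = nx.DiGraph()

    # -- classes ----------------------------------------------------------
    def add_class(self, id: str, label: str | None = None,
                  synonyms: list[str] | None = None) -> OntoClass:
        if id in self._classes:
            raise OntologyError(f"duplicate class id: {id!r}")
        cls = OntoClass(id=id, label=label if label else id,
                        synonyms=list(synonyms or []))
        self._classes[id] = cls
        self._g.add_node(id)
        return cls

    def remove_class(self, id: str) -> None:
        if id not in self._classes:
            raise ClassNotFoundError(f"class not found: {id!r}")
        del self._classes[id]
        self._g.remove_node(id)

    def has_class(self, id: str) -> bool:
        return id in self._classes

    def get(self, id: str) -> OntoClass:
        try:
            return self._classes[id]
        except KeyError:
            raise ClassNotFoundError(f"class not found: {id!r}") from None

    @property
    def class_ids(self) -> list[str]:
        """Class ids in insertion order."""
        return list(self._classes)

    @property
    def classes(self) -> list[OntoClass]:
        return list(self._classes.values())

    # -- edges ------------------------------------------------------------
    def add_edge(self, parent: str, child: str) -> bool:
        """Add a parent->child edge; returns False for self-loops/duplicates."""
        if parent not in self._classes:
            raise ClassNotFoundError(f"class not found: {parent!r}")
        if child not in self._classes:
            raise ClassNotFoundError(f"class not found: {child!r}")
        if parent == child:
            logger.debug("dropping self-loop edge on %r", parent)
            return False
        if self._g.has_edge(parent, child):
            logger.debug("dropping duplicate edge %r -> %r", parent, child)
            return False
        self._g.add_edge(parent, child)
        return True

    def remove_edge(self, parent: str, child: str) -> None:
        self._g.remove_edge(parent, child)

    def has_edge(self, parent: str, child: str) -> bool:
        return self._g.has_edge(parent, child)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self._g.edges())

    def parents(self, id: str) -> list[str]:
        return list(self._g.predecessors(id))

    def children(self, id: str) -> list[str]:
        return list(self._g.successors(id))

    @property
    def n_classes(self) -> int:
        return len(self._classes)

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __len__(self) -> int:
        return len(self._classes)

    def __contains__(self, id: str) -> bool:
        return id in self._classes

    def copy(self, name: str | None = None) -> "OntologyGraph":
        out = OntologyGraph(name=self.name if name is None else name)
        for cls in self.classes:
            out.add_class(cls.id, cls.label, list(cls.synonyms))
        for p, c in self.edges:
            out.add_edge(p, c)
        return out

    def nx_graph(self) -> nx.DiGraph:
        """Read-only view of the underlying networkx digraph."""
        return self._g


@dataclass(frozen=True)
class Subgraph:
    """Window-``W`` subgraph around a generator node.

    ``node_order`` is deterministic: generator first, then ascending
    breadth-first distance, ties broken by lexicographic class id.
    ``distances`` holds the BFS distance (in the traversal orientation used
    during extraction) from each member to the generator.
    """

    generator: str
    members: frozenset[str]
    edges: frozenset[tuple[str, str]]
    node_order: tuple[str, ...]
    distances: dict[str, int]


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Binary adjacency matrix of a subgraph in its node order."""

    order: tuple[str, ...]
    bits: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.order)
        if self.bits.shape != (n, n):
            raise OntologyError("adjacency matrix dimension mismatch")


def extract_subgraph(onto: OntologyGraph, node: str, W: int) -> Subgraph:
    """Extract the window-``W`` subgraph centred on ``node``.

    Members are the union of descendants within ``W`` child-edges and
    ancestors within ``W`` parent-edges (two separate directed BFS sweeps;
    mixed-direction paths are not followed, so siblings are excluded at
    W=1).  Edges are those induced among the members.
    """
    if node not in onto:
        raise ClassNotFoundError(f"class not found: {node!r}")
    if W < 0:
        raise OntologyError("window length W must be >= 0")
    g = onto.nx_graph()
    down = nx.single_source_shortest_path_length(g, node, cutoff=W)
    up = nx.single_source_shortest_path_length(g.reverse(copy=False), node,
                                               cutoff=W)
    dist: dict[str, int] = dict(down)
    for k, d in up.items():
        if k not in dist or d < dist[k]:
            dist[k] = d
    members = frozenset(dist)
    others = sorted((m for m in members if m != node),
                    key=lambda m: (dist[m], m))
    order = (node, *others)
    induced = frozenset((p, c) for p, c in g.subgraph(members).edges())
    return Subgraph(generator=node, members=members, edges=induced,
                    node_order=order, distances=dist)


def adjacency_matrix(sub: Subgraph) -> AdjacencyMatrix:
    """Binary adjacency matrix of ``sub`` in its deterministic node order."""
    n = len(sub.node_order)
    idx = {m: p for p, m in enumerate(sub.node_order)}
    bits = np.zeros((n, n), dtype=np.int8)
    for p, c in sub.edges:
        bits[idx[p], idx[c]] = 1
    return AdjacencyMatrix(order=sub.node_order, bits=bits)


def shortest_path_to_generator(sub: Subgraph, node: str) -> int:
    """Minimum edge count from ``node`` to the generator within the window.

    Distances are those of the directed sweep that reached the node during
    extraction, so the value is always <= W and is 0 exactly for the
    generator itself.
    """
    try:
        return sub.distances[node]
    except KeyError:
        raise ClassNotFoundError(
            f"class not found in subgraph of {sub.generator!r}: {node!r}"
        ) from None
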