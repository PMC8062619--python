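"""Mixed directed/undirected signaling network with paired-edge bookkeeping.

Curated signaling resources (ConsensusPathDB-style aggregates) mix directed
regulatory edges with undirected physical interactions. To run directed path
searches over such a graph, every undirected edge is replaced by two directed
edges with the same endpoints and opposite orientations. The two derived
edges share a ``pair_id`` so that path-enumeration code can forbid a path
from using both of them (which would amount to traversing the same physical
interaction twice, once in each direction).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

DIRECTED = "directed"
UNDIRECTED_DERIVED = "undirected_derived"


class NetworkError(ValueError):
    """Raised when an edge list violates the network invariants."""


@dataclass(frozen=True)
class Edge:
    """A single directed edge.

    ``origin`` records whether the edge was directed in the source data or
    derived from an undirected interaction; in the latter case ``pair_id``
    links it to its oppositely oriented twin.
    """

    edge_id: int
    source: str
    target: str
    origin: str = DIRECTED
    pair_id: int | None = None


class BackgroundNetwork:
    """Immutable gene graph with adjacency indexes for path search.

    Parameters
    ----------
    nodes
        Gene identifiers; must cover every edge endpoint. Isolated nodes are
        allowed (and matter: an input gene with no edges still belongs to an
        extracted subnetwork).
    edges
        Directed :class:`Edge` records satisfying the pairing invariants.
    """

    def __init__(self, nodes: Iterable[str], edges: Iterable[Edge]):
        self.nodes: frozenset[str] = frozenset(nodes)
        self.edges: tuple[Edge, ...] = tuple(edges)
        self._validate()
        out: dict[str, list[Edge]] = {}
        und: dict[str, set[str]] = {}
        for e in self.edges:
            out.setdefault(e.source, []).append(e)
            und.setdefault(e.source, set()).add(e.target)
            und.setdefault(e.target, set()).add(e.source)
        self._out = {k: tuple(v) for k, v in out.items()}
        self._und = {k: frozenset(v) for k, v in und.items()}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_mixed(
        cls,
        directed: Sequence[tuple[str, str]],
        undirected: Sequence[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
    ) -> "BackgroundNetwork":
        """Build a network from raw directed and undirected endpoint pairs.

        Undirected pairs are expanded into two opposite directed edges
        sharing a fresh ``pair_id``. Edge and pair ids follow input order.
        """
        edges: list[Edge] = []
        eid = 0
        for s, t in directed:
            edges.append(Edge(eid, s, t, DIRECTED, None))
            eid += 1
        for pid, (s, t) in enumerate(undirected):
            if s == t:
                raise NetworkError(f"undirected self-loop on {s!r}")
            edges.append(Edge(eid, s, t, UNDIRECTED_DERIVED, pid))
            edges.append(Edge(eid + 1, t, s, UNDIRECTED_DERIVED, pid))
            eid += 2
        nodes = {s for s, _ in directed} | {t for _, t in directed}
        nodes |= {n for p in undirected for n in p}
        nodes |= set(extra_nodes)
        return cls(nodes, edges)

    # -- queries -----------------------------------------------------------

    def out_edges(self, node: str) -> tuple[Edge, ...]:
        """Directed out-edges of ``node`` (derived edges included)."""
        return self._out.get(node, ())

    def undirected_neighbors(self, node: str) -> frozenset[str]:
        """Neighbors of ``node`` ignoring edge direction."""
        return self._und.get(node, frozenset())

    def undirected_pairs(self) -> list[tuple[Edge, Edge]]:
        """The (forward, reverse) edge pairs derived from undirected edges."""
        by_pid: dict[int, list[Edge]] = {}
        for e in self.edges:
            if e.pair_id is not None:
                by_pid.setdefault(e.pair_id, []).append(e)
        return [tuple(v) for v in by_pid.values()]  # type: ignore[misc]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, node: str) -> bool:
        return node in self.nodes

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.nodes))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BackgroundNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"BackgroundNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        ids = Counter(e.edge_id for e in self.edges)
        if ids and ids.most_common(1)[0][1] > 1:
            raise NetworkError("duplicate edge_id")
        triples = Counter((e.source, e.target, e.pair_id) for e in self.edges)
        dup = [k for k, c in triples.items() if c > 1]
        if dup:
            raise NetworkError(f"duplicate (source, target, pair_id) triples: {dup[:3]}")
        by_pid: dict[int, list[Edge]] = {}
        for e in self.edges:
            if e.source == e.target:
                raise NetworkError(f"self-loop on {e.source!r}")
            if e.source not in self.nodes or e.target not in self.nodes:
                raise NetworkError(f"edge {e.edge_id} endpoint not in node set")
            if e.origin == DIRECTED:
                if e.pair_id is not None:
                    raise NetworkError(f"directed edge {e.edge_id} carries a pair_id")
            elif e.origin == UNDIRECTED_DERIVED:
                if e.pair_id is None:
                    raise NetworkError(f"derived edge {e.edge_id} lacks a pair_id")
                by_pid.setdefault(e.pair_id, []).append(e)
            else:
                raise NetworkError(f"unknown edge origin {e.origin!r}")
        for pid, pair in by_pid.items():
            if len(pair) != 2:
                raise NetworkError(f"pair_id {pid} has {len(pair)} members, expected 2")
            a, b = pair
            if (a.source, a.target) != (b.target, b.source):
                raise NetworkError(f"pair_id {pid} endpoints are not swapped")
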