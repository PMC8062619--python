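"""DFS path extraction over a mixed signaling network (pathFinder).

Starting from each gene of an input list, a depth-first search enumerates
every directed path of at most ``k`` edges in the background network.
Undirected interactions are represented as two opposite directed edges that
share a ``pair_id``; a path may use either one but never both, and a path
never revisits a node. Every node lying on any such path joins the extracted
subnetwork, so the input list is expanded with the genes on short connecting
paths. ``k = 2`` (one intermediate node) is the conventional setting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .network import BackgroundNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathFinderConfig:
    """Search parameters.

    k
        Maximum path length counted in edges (k >= 1); the zero-length path
        at the start gene is always retained so isolated inputs stay in the
        output.
    connecting_only
        If true, only paths of length >= 1 that terminate at another input
        gene contribute nodes (strict "paths connecting input genes" mode);
        input genes themselves are always kept.
    """

    k: int = 2
    connecting_only: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class PathSet:
    """All accepted paths from one start gene (or a union over starts)."""

    paths: tuple[tuple[str, ...], ...]
    node_set: frozenset[str]
    induced_edges: frozenset[int]


@dataclass(frozen=True)
class SubnetworkExtraction:
    """Union of path sets over an input gene list."""

    node_set: frozenset[str]
    paths: tuple[tuple[str, ...], ...]
    induced_edges: frozenset[int]
    density: float
    missing_inputs: tuple[str, ...]


def dfs_paths(
    network: BackgroundNetwork, start: str, config: PathFinderConfig = PathFinderConfig()
) -> PathSet:
    """Enumerate every valid directed path of <= k edges from ``start``.

    A path is a sequence of distinct nodes following directed edges, using
    at most one member of each derived edge pair. All prefixes are paths in
    their own right, including the zero-length path ``(start,)``.
    """
    if start not in network:
        raise KeyError(f"start gene {start!r} not in network")
    paths: list[tuple[str, ...]] = []
    edge_ids: set[int] = set()

    node_stack = [start]
    edge_stack: list[int] = []
    pair_used: set[int] = set()
    on_path = {start}

    def explore() -> None:
        paths.append(tuple(node_stack))
        edge_ids.update(edge_stack)
        if len(edge_stack) == config.k:
            return
        for e in network.out_edges(node_stack[-1]):
            if e.target in on_path:
                continue
            if e.pair_id is not None and e.pair_id in pair_used:
                continue
            node_stack.append(e.target)
            edge_stack.append(e.edge_id)
            on_path.add(e.target)
            if e.pair_id is not None:
                pair_used.add(e.pair_id)
            explore()
            if e.pair_id is not None:
                pair_used.discard(e.pair_id)
            on_path.discard(e.target)
            edge_stack.pop()
            node_stack.pop()

    explore()
    nodes = frozenset(n for p in paths for n in p)
    return PathSet(paths=tuple(paths), node_set=nodes, induced_edges=frozenset(edge_ids))


def extract_subnetwork(
    network: BackgroundNetwork,
    input_genes: Iterable[str],
    config: PathFinderConfig = PathFinderConfig(),
) -> SubnetworkExtraction:
    """Union of DFS path sets over all input genes present in the network.

    Input genes absent from the network are logged and skipped; it is an
    error if none are present. The reported density is
    |induced edges| / (n * (n - 1)) over the extracted node set, counting
    each derived edge pair once (one undirected interaction).
    """
    inputs = list(dict.fromkeys(input_genes))
    present = [g for g in inputs if g in network]
    missing = tuple(g for g in inputs if g not in network)
    if missing:
        logger.warning("%d input genes absent from the network: %s", len(missing), missing[:5])
    if not present:
        raise ValueError("no input gene present in the network")

    present_set = set(present)
    all_paths: list[tuple[str, ...]] = []
    nodes: set[str] = set(present)
    edge_ids: set[int] = set()
    edge_by_id = {e.edge_id: e for e in network.edges}
    for g in present:
        ps = dfs_paths(network, g, config)
        if config.connecting_only:
            kept = [p for p in ps.paths if len(p) >= 2 and p[-1] in present_set]
            all_paths.extend(kept)
            for p in kept:
                nodes.update(p)
                for a, b in zip(p, p[1:]):
                    for e in network.out_edges(a):
                        if e.target == b:
                            edge_ids.add(e.edge_id)
                            break
        else:
            all_paths.extend(ps.paths)
            nodes.update(ps.node_set)
            edge_ids.update(ps.induced_edges)

    n = len(nodes)
    if n > 1:
        pair_seen: set[int] = set()
        n_interactions = 0
        for eid in edge_ids:
            e = edge_by_id[eid]
            if e.pair_id is None:
                n_interactions += 1
            elif e.pair_id not in pair_seen:
                pair_seen.add(e.pair_id)
                n_interactions += 1
        density = n_interactions / (n * (n - 1))
    else:
        density = 0.0
    return SubnetworkExtraction(
        node_set=frozenset(nodes),
        paths=tuple(all_paths),
        induced_edges=frozenset(edge_ids),
        density=density,
        missing_inputs=missing,
    )
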