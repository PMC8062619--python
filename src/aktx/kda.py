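"""Key driver analysis: neighborhood enrichment for a target gene list.

Given a target gene list (typically a DE signature) and a background
signaling network, the procedure

1. restricts the network to the nodes within ``k_max`` steps — ignoring
   edge direction — of any target (the background sub-network, which also
   serves as the enrichment universe);
2. for every node of that sub-network and every k in 1..k_max, collects the
   node's k-step *downstream* neighborhood (directed reachability) and
   scores its overlap with the target list by a one-sided hypergeometric
   test;
3. keeps each node's best (smallest) p over k, adjusts across nodes with
   Benjamini-Hochberg, and ranks by adjusted p.

High-ranking nodes are candidate key drivers: genes whose directed
downstream neighborhoods are unexpectedly rich in targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .network import BackgroundNetwork

# Derived edge pairs need no special handling during reachability searches:
# using both members of a pair within one walk necessarily revisits a node,
# so it can never extend the reachable set.


@dataclass(frozen=True)
class KDAConfig:
    k_max: int = 3
    enrichment_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 1 <= self.k_max <= 3:
            raise ValueError("k_max must lie in [1, 3]")
        if not 0 < self.enrichment_alpha < 1:
            raise ValueError("enrichment_alpha must lie in (0, 1)")


def background_subnetwork(
    network: BackgroundNetwork, targets: Iterable[str], k: int
) -> BackgroundNetwork:
    """Sub-network induced by nodes within k undirected steps of any target.

    Edges of the original network are retained when both endpoints survive.
    """
    target_set = {t for t in targets if t in network}
    if not target_set:
        raise ValueError("no target gene present in the network")
    frontier = set(target_set)
    reached = set(target_set)
    for _ in range(k):
        nxt = set()
        for node in frontier:
            nxt |= network.undirected_neighbors(node)
        frontier = nxt - reached
        if not frontier:
            break
        reached |= frontier
    edges = [e for e in network.edges if e.source in reached and e.target in reached]
    return BackgroundNetwork(reached, edges)


def downstream_neighborhood(network: BackgroundNetwork, node: str, k: int) -> frozenset[str]:
    """Nodes reachable from ``node`` along 1..k directed edges.

    The node itself is excluded unless it is reachable through a directed
    cycle.
    """
    if node not in network:
        raise KeyError(f"node {node!r} not in network")
    frontier = {node}
    reached: set[str] = set()
    for _ in range(k):
        nxt: set[str] = set()
        for u in frontier:
            for e in network.out_edges(u):
                nxt.add(e.target)
        frontier = nxt - reached
        if not frontier:
            break
        reached |= frontier
    return frozenset(reached)


def key_driver_analysis(
    network: BackgroundNetwork,
    targets: Iterable[str],
    config: KDAConfig = KDAConfig(),
) -> pd.DataFrame:
    """Rank candidate key drivers for a target gene list.

    Returns a DataFrame indexed by node with columns ``k`` (the step count
    achieving the best p), ``downstream_size``, ``overlap``, ``p_value`` and
    ``adj_p``, ranked by adjusted p then node id. Nodes whose downstream
    neighborhood is empty at every k are skipped.
    """
    target_list = list(dict.fromkeys(targets))
    if not target_list:
        raise ValueError("empty target list")
    sub = background_subnetwork(network, target_list, config.k_max)
    universe = sub.nodes
    target_set = {t for t in target_list if t in universe}
    N = len(universe)
    K = len(target_set)

    rows = []
    for node in sorted(universe):
        best = None
        for k in range(1, config.k_max + 1):
            down = downstream_neighborhood(sub, node, k)
            n_down = len(down)
            if n_down == 0:
                continue
            overlap = len(down & target_set)
            p = float(stats.hypergeom.sf(overlap - 1, N, K, n_down))
            if best is None or p < best[3]:
                best = (k, n_down, overlap, p)
        if best is not None:
            rows.append((node, *best))
    if not rows:
        raise ValueError("no node has a nonempty downstream neighborhood")
    df = pd.DataFrame(
        rows, columns=["node", "k", "downstream_size", "overlap", "p_value"]
    ).set_index("node")
    df["adj_p"] = bh_adjust(df["p_value"])
    df = df.sort_values(["adj_p", "p_value", "node"], kind="mergesort")
    return df
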