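import numpy as np
import pandas as pd
import pytest

import aktx


@pytest.fixture(scope="session")
def default_manifest():
    return aktx.generate_panel()


@pytest.fixture(scope="session")
def small_manifest():
    return aktx.generate_panel(
        aktx.PanelConfig(n_base_endogenous=60, n_housekeeping=8, n_spike_in=4)
    )


@pytest.fixture(scope="session")
def small_run(small_manifest):
    sim = aktx.SimulationConfig(
        n_patients=10,
        n_matched_pairs=8,
        n_de_genes_response=5,
        n_de_genes_treatment=3,
        seed=7,
    )
    counts, annotations, truth = aktx.simulate_counts(small_manifest, sim)
    return counts, annotations, truth


def tiny_manifest(n_genes=4, n_housekeeping=2, conc_f=0.125):
    """Hand-sized manifest: G1..Gn endogenous, HK1..HKm, POS_F, NEG_01."""
    probes = [aktx.Probe(f"G{i + 1}", "endogenous") for i in range(n_genes)]
    probes += [aktx.Probe(f"HK{i + 1}", "housekeeping") for i in range(n_housekeeping)]
    probes.append(aktx.Probe("POS_F", "positive_control", "F", conc_f))
    probes.append(aktx.Probe("NEG_01", "negative_control"))
    return aktx.PanelManifest(tuple(probes))


def make_norm(values: pd.DataFrame, lod=(), log2=True):
    """Wrap a plain DataFrame as an already-normalized matrix (factors 1)."""
    return aktx.NormalizedMatrix(
        values=values.astype(float),
        lod_zeroed=frozenset(lod),
        scale_factors=pd.Series(1.0, index=values.columns),
        log2=log2,
    )


def random_mixed_network(rng, n_nodes_max=30):
    """Small random network with directed and undirected edges."""
    n = int(rng.integers(4, n_nodes_max + 1))
    nodes = [f"n{i}" for i in range(n)]
    directed, undirected = [], []
    seen_d, seen_u = set(), set()
    for _ in range(int(rng.integers(0, 2 * n))):
        i, j = rng.integers(n, size=2)
        if i != j and (i, j) not in seen_d:
            seen_d.add((i, j))
            directed.append((nodes[i], nodes[j]))
    for _ in range(int(rng.integers(0, n))):
        i, j = rng.integers(n, size=2)
        key = frozenset((int(i), int(j)))
        if i != j and key not in seen_u:
            seen_u.add(key)
            undirected.append((nodes[i], nodes[j]))
    return aktx.BackgroundNetwork.from_mixed(directed, undirected, extra_nodes=nodes)


def enumerate_paths_bruteforce(network, start, k):
    """Exhaustive path enumeration over raw edge records.

    Independent of the DFS implementation: scans the full edge list at every
    step and enforces the simple-path, pair and length constraints directly.
    Returns the set of node sequences.
    """
    results = set()

    def rec(nodes, edges):
        results.add(tuple(nodes))
        if len(edges) == k:
            return
        for e in network.edges:
            if e.source != nodes[-1] or e.target in nodes:
                continue
            if e.pair_id is not None and any(f.pair_id == e.pair_id for f in edges):
                continue
            rec(nodes + [e.target], edges + [e])

    rec([start], [])
    return results


def bh_bruteforce(p):
    """Step-up BH oracle: sort, scale by m/i, enforce monotonicity, cap."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    out = np.empty(m)
    out[order] = np.minimum(scaled, 1.0)
    return out
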