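"""Gene-set over-representation analysis and pathway-list comparison.

A query gene list (DE genes or an extracted subnetwork's nodes) is tested
against each set of a collection by the one-sided hypergeometric tail, with
the measured panel as universe; p-values are BH-adjusted across sets.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


def ora(
    query: Iterable[str],
    universe: Iterable[str],
    sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the universe before testing; the query must be
    a subset of the universe. Results are sorted by p-value; ``members_hit``
    lists the query genes inside each set.
    """
    uni = set(universe)
    q = set(query)
    if not uni or not q:
        raise ValueError("query and universe must be nonempty")
    if not q <= uni:
        raise ValueError(f"query contains genes outside the universe: {sorted(q - uni)[:5]}")
    N, n = len(uni), len(q)
    rows = []
    for name in sets:
        members = set(sets[name]) & uni
        K = len(members)
        hit = sorted(q & members)
        overlap = len(hit)
        p = float(stats.hypergeom.sf(overlap - 1, N, K, n)) if K else 1.0
        rows.append((name, K, overlap, p, tuple(hit)))
    df = pd.DataFrame(
        rows, columns=["set_name", "set_size", "overlap", "p_value", "members_hit"]
    ).set_index("set_name")
    df["adj_p"] = bh_adjust(df["p_value"]) if len(df) else df["p_value"]
    return df.sort_values(["p_value", "set_name"], kind="mergesort")


def overlap_pathways(
    a: pd.DataFrame, b: pd.DataFrame, alpha: float = 0.05
) -> frozenset[str]:
    """Set names significant (adj_p < alpha) in both ORA result tables."""
    sig_a = set(a.index[a["adj_p"] < alpha])
    sig_b = set(b.index[b["adj_p"] < alpha])
    return frozenset(sig_a & sig_b)
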