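"""Readers and writers for the pipeline's external formats.

Four plain-text formats are supported:

* counts TSV — header row of sample ids, first column ``gene_id``, integer
  counts;
* a simplified dialect of the nCounter per-lane RCC file, reduced to the
  ``Code_Summary`` section (``CodeClass,Name,Accession,Count`` lines);
* GMT gene-set collections (name, description, tab-separated members);
* network edge lists (``source <tab> interaction <tab> target`` with
  interaction ``directed`` or ``undirected``); undirected rows are expanded
  into paired opposite directed edges on read and collapsed back on write.

Parsers are written in-house so that every parse error carries the offending
line number.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd

from .network import BackgroundNetwork, DIRECTED, NetworkError
from .synthetic import Probe


class ParseError(ValueError):
    """Malformed input file; message carries path and line number."""

    def __init__(self, path: str | os.PathLike, line: int, message: str):
        super().__init__(f"{path}:{line}: {message}")
        self.path = str(path)
        self.line = line


# ---------------------------------------------------------------------------
# counts TSV
# ---------------------------------------------------------------------------


def read_counts_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes x samples integer count table.

    Returns a DataFrame indexed by gene_id with one column per sample.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(path, 1, "empty file")
    header = lines[0].split("\t")
    if len(header) < 2 or header[0] != "gene_id":
        raise ParseError(path, 1, "header must start with 'gene_id' and list sample ids")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise ParseError(path, 1, "duplicate sample ids in header")
    genes: list[str] = []
    rows: list[list[int]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                path, lineno, f"expected {len(header)} fields, found {len(fields)}"
            )
        gene = fields[0]
        if gene in seen:
            raise ParseError(path, lineno, f"duplicate gene_id {gene!r}")
        seen.add(gene)
        try:
            values = [int(v) for v in fields[1:]]
        except ValueError:
            raise ParseError(path, lineno, "non-integer count") from None
        if any(v < 0 for v in values):
            raise ParseError(path, lineno, "negative count")
        genes.append(gene)
        rows.append(values)
    df = pd.DataFrame(rows, index=genes, columns=samples, dtype="int64")
    df.index.name = "gene_id"
    return df


def write_counts_tsv(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a counts table readable by :func:`read_counts_tsv`."""
    out = counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# simplified RCC
# ---------------------------------------------------------------------------

_RCC_CLASS_MAP = {
    "endogenous": "endogenous",
    "housekeeping": "housekeeping",
    "spikein": "spike_in",
    "positive": "positive_control",
    "negative": "negative_control",
}


def read_rcc_like(path: str | os.PathLike) -> tuple[pd.Series, list[Probe]]:
    """Read one lane's counts from a simplified RCC file.

    Only the ``Code_Summary`` section is required; its lines are
    ``CodeClass,Name,Accession,Count``. A positive-control row named like
    ``POS_F(0.125)`` yields control label ``F``.

    Returns the per-probe counts (Series indexed by gene name) and the probe
    annotations recoverable from the section.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.strip() == "<Code_Summary>")
    except StopIteration:
        raise ParseError(path, 1, "missing <Code_Summary> section") from None
    counts: dict[str, int] = {}
    probes: list[Probe] = []
    for lineno, line in enumerate(lines[start + 1 :], start=start + 2):
        if line.strip() == "</Code_Summary>":
            break
        if not line.strip():
            continue
        fields = line.split(",")
        if len(fields) != 4:
            raise ParseError(path, lineno, "expected CodeClass,Name,Accession,Count")
        code_class, name, _accession, count_str = fields
        if code_class.strip().lower() == "codeclass":
            continue  # column header row
        cls = _RCC_CLASS_MAP.get(code_class.strip().lower())
        if cls is None:
            raise ParseError(path, lineno, f"unknown CodeClass {code_class!r}")
        try:
            count = int(count_str)
        except ValueError:
            raise ParseError(path, lineno, "non-integer count") from None
        if count < 0:
            raise ParseError(path, lineno, "negative count")
        label = None
        conc = None
        gene_id = name
        if cls == "positive_control":
            base = name.split("(", 1)[0].strip()
            if "(" in name and name.endswith(")"):
                try:
                    conc = float(name[name.index("(") + 1 : -1])
                except ValueError:
                    conc = None
            if base.upper().startswith("POS_") and len(base) >= 5:
                label = base[4].upper()
            gene_id = base
        if gene_id in counts:
            raise ParseError(path, lineno, f"duplicate probe {gene_id!r}")
        counts[gene_id] = count
        probes.append(Probe(gene_id, cls, label, conc))
    if not counts:
        raise ParseError(path, start + 1, "empty Code_Summary section")
    return pd.Series(counts, name="count"), probes


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | os.PathLike) -> dict[str, tuple[str, ...]]:
    """Read a GMT collection into ``{set_name: members}``.

    Descriptions (column 2) are parsed but not retained; duplicate members
    within a set are collapsed preserving order.
    """
    sets: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "GMT line needs name, description, >=1 member")
            name = fields[0]
            if name in sets:
                raise ParseError(path, lineno, f"duplicate gene set {name!r}")
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise ParseError(path, lineno, f"gene set {name!r} has no members")
            sets[name] = tuple(members)
    return sets


def write_gmt(sets: Mapping[str, tuple[str, ...]], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# network edge lists
# ---------------------------------------------------------------------------


def read_edge_list(path: str | os.PathLike) -> BackgroundNetwork:
    """Read a mixed edge list (``source TAB interaction TAB target``).

    Each ``undirected`` row expands into two opposite directed edges sharing
    a pair_id assigned in file order.
    """
    directed: list[tuple[str, str]] = []
    undirected: list[tuple[str, str]] = []
    isolated: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#node\t"):
                isolated.append(line.split("\t", 1)[1])
                continue
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(path, lineno, "expected source, interaction, target")
            s, kind, t = fields
            if kind == "directed":
                directed.append((s, t))
            elif kind == "undirected":
                if s == t:
                    raise ParseError(path, lineno, "undirected self-loop")
                undirected.append((s, t))
            else:
                raise ParseError(path, lineno, f"unknown interaction token {kind!r}")
    try:
        return BackgroundNetwork.from_mixed(directed, undirected, extra_nodes=isolated)
    except NetworkError as exc:
        raise ParseError(path, 1, str(exc)) from exc


def write_edge_list(network: BackgroundNetwork, path: str | os.PathLike) -> None:
    """Write the network collapsing derived edge pairs to one undirected row.

    The row order follows edge ids, with each undirected pair emitted once at
    the position of its first member, so a read/write round trip on a
    canonical file is the identity.
    """
    emitted_pairs: set[int] = set()
    touched = {e.source for e in network.edges} | {e.target for e in network.edges}
    with open(path, "w", encoding="utf-8") as fh:
        for e in network.edges:
            if e.origin == DIRECTED:
                fh.write(f"{e.source}\tdirected\t{e.target}\n")
            else:
                if e.pair_id in emitted_pairs:
                    continue
                emitted_pairs.add(e.pair_id)
                fh.write(f"{e.source}\tundirected\t{e.target}\n")
        for node in sorted(network.nodes - touched):
            fh.write(f"#node\t{node}\n")
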