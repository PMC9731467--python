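"""Core signed-network data model, file I/O and link accounting.

A survey network is a *directed* signed graph: student ``i`` nominating
student ``j`` as friend (``+1``) or enemy (``-1``) is the ordered arc
``(i, j)``.  The unit of analysis downstream is the *reciprocal*
(undirected) projection: an unordered pair ``{i, j}`` carries a sign only
when both directed nominations exist and agree.  All ``w``-style symbols in
the quality functions are plain edge counts — edges are unweighted apart
from their sign.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

from .errors import AdjacencyFormatError, UndefinedMetricError

Sign = int  # +1 or -1

_VALID_SIGNS = (-1, 1)


def _check_sign(s: int) -> int:
    if s not in _VALID_SIGNS:
        raise ValueError(f"edge sign must be -1 or +1, got {s!r}")
    return s


def ordered(i: str, j: str) -> tuple[str, str]:
    """Canonical key for an unordered node pair."""
    return (i, j) if i <= j else (j, i)


@dataclass
class DirectedSignedNetwork:
    """Directed signed graph with at most one signed arc per ordered pair.

    Parameters
    ----------
    node_ids
        Ordered list of unique node labels. Order is preserved through I/O
        and used for deterministic tie-breaking downstream.
    arcs
        Mapping ``(i, j) -> sign`` with ``sign`` in ``{-1, +1}``; no
        self-arcs.
    """

    node_ids: list[str]
    arcs: dict[tuple[str, str], Sign]

    def __post_init__(self) -> None:
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")
        nodes = set(self.node_ids)
        for (i, j), s in self.arcs.items():
            if i == j:
                raise ValueError(f"self-arc ({i},{j}) is not allowed")
            if i not in nodes or j not in nodes:
                raise ValueError(f"arc ({i},{j}) references unknown node")
            _check_sign(s)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def sign(self, i: str, j: str) -> Sign | None:
        """Sign of arc (i, j), or None if absent."""
        return self.arcs.get((i, j))

    def copy(self) -> "DirectedSignedNetwork":
        return DirectedSignedNetwork(list(self.node_ids), dict(self.arcs))

    def relabeled(self, mapping: dict[str, str]) -> "DirectedSignedNetwork":
        """Network with nodes renamed through `mapping` (a bijection)."""
        return DirectedSignedNetwork(
            [mapping[v] for v in self.node_ids],
            {(mapping[i], mapping[j]): s for (i, j), s in self.arcs.items()},
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from((i, j, {"sign": s}) for (i, j), s in self.arcs.items())
        return g


@dataclass
class UndirectedSignedNetwork:
    """Undirected signed graph; edge keys are lexicographically ordered pairs."""

    node_ids: list[str]
    edges: dict[tuple[str, str], Sign]

    def __post_init__(self) -> None:
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")
        nodes = set(self.node_ids)
        fixed = {}
        for (i, j), s in self.edges.items():
            if i == j:
                raise ValueError(f"self-edge on {i} is not allowed")
            if i not in nodes or j not in nodes:
                raise ValueError(f"edge ({i},{j}) references unknown node")
            _check_sign(s)
            fixed[ordered(i, j)] = s
        if len(fixed) != len(self.edges):
            raise ValueError("duplicate unordered pair in edges")
        self.edges = fixed

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def m_pos(self) -> int:
        """Count of positive edges (the w+ of the quality functions)."""
        return sum(1 for s in self.edges.values() if s > 0)

    @property
    def m_neg(self) -> int:
        """Count of negative edges (w-)."""
        return sum(1 for s in self.edges.values() if s < 0)

    @property
    def m_total(self) -> int:
        return len(self.edges)

    def sign(self, i: str, j: str) -> Sign | None:
        return self.edges.get(ordered(i, j))

    def adjacency(self) -> dict[str, dict[str, Sign]]:
        """Signed adjacency as nested dicts (both directions materialized)."""
        adj: dict[str, dict[str, Sign]] = {v: {} for v in self.node_ids}
        for (i, j), s in self.edges.items():
            adj[i][j] = s
            adj[j][i] = s
        return adj

    def degrees(self) -> dict[str, int]:
        deg = {v: 0 for v in self.node_ids}
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def copy(self) -> "UndirectedSignedNetwork":
        return UndirectedSignedNetwork(list(self.node_ids), dict(self.edges))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from((i, j, {"sign": s}) for (i, j), s in self.edges.items())
        return g


# ---------------------------------------------------------------------------
# Reciprocal projection
# ---------------------------------------------------------------------------


@dataclass
class DropReport:
    """Accounting of directed arcs that did not survive reciprocal projection."""

    n_oneway_pos: int = 0
    n_oneway_neg: int = 0
    n_conflicting_pairs: int = 0  # pairs with (+) one way and (-) the other

    @property
    def n_dropped_arcs(self) -> int:
        return self.n_oneway_pos + self.n_oneway_neg + 2 * self.n_conflicting_pairs

    def to_dict(self) -> dict:
        return {
            "n_oneway_pos": self.n_oneway_pos,
            "n_oneway_neg": self.n_oneway_neg,
            "n_conflicting_pairs": self.n_conflicting_pairs,
            "n_dropped_arcs": self.n_dropped_arcs,
        }


def reciprocal_projection(
    net: DirectedSignedNetwork,
) -> tuple[UndirectedSignedNetwork, DropReport]:
    """Keep only reciprocal same-sign pairs as undirected signed edges.

    A pair with arcs of opposite sign in the two directions is treated as
    non-reciprocal (both arcs dropped) and tallied separately in the report.
    Isolated nodes are retained.
    """
    edges: dict[tuple[str, str], Sign] = {}
    report = DropReport()
    seen: set[tuple[str, str]] = set()
    for (i, j), s in net.arcs.items():
        key = ordered(i, j)
        if key in seen:
            continue
        seen.add(key)
        rev = net.arcs.get((j, i))
        if rev is None:
            if s > 0:
                report.n_oneway_pos += 1
            else:
                report.n_oneway_neg += 1
        elif rev == s:
            edges[key] = s
        else:
            report.n_conflicting_pairs += 1
    return UndirectedSignedNetwork(list(net.node_ids), edges), report


def bidirectionalize(net: UndirectedSignedNetwork) -> DirectedSignedNetwork:
    """Expand every undirected edge into its two reciprocal arcs."""
    arcs: dict[tuple[str, str], Sign] = {}
    for (i, j), s in net.edges.items():
        arcs[(i, j)] = s
        arcs[(j, i)] = s
    return DirectedSignedNetwork(list(net.node_ids), arcs)


# ---------------------------------------------------------------------------
# Degree summary (Table-2-style accounting)
# ---------------------------------------------------------------------------


def truncate1(x: float) -> float:
    """Floor-truncate to one decimal (2.465 -> 2.4, never 2.5).

    A tiny epsilon guards against values like 5.6999999999 that are exactly
    5.7 in rational arithmetic.
    """
    return math.floor(x * 10 + 1e-9) / 10


@dataclass
class DegreeSummary:
    """Per-network link accounting: mean reciprocal degrees and negative share.

    ``mean_pos_degree`` is <k>+ = 2 m+ / n, ``mean_neg_degree`` is <k>- =
    2 m- / n, and ``neg_fraction_pct`` is 100 m- / (m+ + m-), ``None``
    (undefined) on an edgeless network.  ``mode`` records whether the values
    are raw or floor-truncated to one decimal, the convention used when
    reproducing published summary tables.
    """

    n_nodes: int
    mean_pos_degree: float
    mean_neg_degree: float
    neg_fraction_pct: float | None
    mode: str  # "raw" | "truncated-1dp"

    @property
    def neg_fraction_defined(self) -> bool:
        return self.neg_fraction_pct is not None


def degree_summary(net: UndirectedSignedNetwork, truncate: bool = False) -> DegreeSummary:
    if net.n_nodes < 1:
        raise ValueError("degree summary requires at least one node")
    n = net.n_nodes
    m_pos, m_neg = net.m_pos, net.m_neg
    k_pos = 2.0 * m_pos / n
    k_neg = 2.0 * m_neg / n
    total = m_pos + m_neg
    pct = 100.0 * m_neg / total if total > 0 else None
    if truncate:
        k_pos = truncate1(k_pos)
        k_neg = truncate1(k_neg)
        pct = truncate1(pct) if pct is not None else None
    return DegreeSummary(n, k_pos, k_neg, pct, "truncated-1dp" if truncate else "raw")


def subnetwork_by_sign(net: UndirectedSignedNetwork, sign: Sign) -> UndirectedSignedNetwork:
    """Same node set, only the edges of the requested sign."""
    _check_sign(sign)
    return UndirectedSignedNetwork(
        list(net.node_ids), {e: s for e, s in net.edges.items() if s == sign}
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _sniff_delimiter(line: str) -> str:
    counts = {d: line.count(d) for d in (",", ";", "\t")}
    return max(counts, key=counts.get) if max(counts.values()) > 0 else ","


def _is_numeric(cell: str) -> bool:
    try:
        float(cell.strip())
        return True
    except ValueError:
        return False


def _parse_cell(cell: str) -> int | None:
    try:
        v = float(cell.strip())
    except ValueError:
        return None
    if v not in (-1.0, 0.0, 1.0) or v != int(v):
        return None
    return int(v)


def read_signed_adjacency(path) -> DirectedSignedNetwork:
    """Read a square signed adjacency matrix CSV into a directed network.

    The first row and/or first column may carry node labels; if absent,
    nodes are named by 0-based index. The delimiter is auto-detected among
    comma, semicolon and tab. Entries must lie in {-1, 0, 1} with a zero
    diagonal.
    """
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first:
            raise AdjacencyFormatError("empty file")
        delim = _sniff_delimiter(first)
        fh.seek(0)
        rows = [row for row in csv.reader(fh, delimiter=delim) if any(c.strip() for c in row)]

    # Header row/label column present iff their cells are non-numeric strings;
    # numeric-but-invalid entries stay in the body so they error with position.
    has_header_row = any(not _is_numeric(c) for c in rows[0][1:])
    body = rows[1:] if has_header_row else rows
    has_label_col = any(not _is_numeric(r[0]) for r in body)

    if has_header_row:
        labels = [c.strip() for c in (rows[0][1:] if has_label_col else rows[0])]
    elif has_label_col:
        labels = [r[0].strip() for r in body]
    else:
        labels = [str(k) for k in range(len(body))]

    n = len(body)
    if len(labels) != n:
        raise AdjacencyFormatError(
            f"label count ({len(labels)}) does not match row count ({n})"
        )
    arcs: dict[tuple[str, str], Sign] = {}
    for r, row in enumerate(body):
        vals = row[1:] if has_label_col else row
        if len(vals) != n:
            raise AdjacencyFormatError(
                f"non-square matrix: row {r} has {len(vals)} entries, expected {n}"
            )
        for c, cell in enumerate(vals):
            v = _parse_cell(cell)
            if v is None:
                raise AdjacencyFormatError(
                    f"entry at row {r}, column {c} is {cell.strip()!r}; must be -1, 0 or 1"
                )
            if r == c:
                if v != 0:
                    raise AdjacencyFormatError(
                        f"nonzero diagonal entry at row {r}, column {c}"
                    )
                continue
            if v != 0:
                arcs[(labels[r], labels[c])] = v
    return DirectedSignedNetwork(labels, arcs)


def write_signed_adjacency(net: DirectedSignedNetwork, path) -> None:
    """Write the directed network as a labeled square adjacency CSV."""
    idx = {v: k for k, v in enumerate(net.node_ids)}
    n = net.n_nodes
    mat = [[0] * n for _ in range(n)]
    for (i, j), s in net.arcs.items():
        mat[idx[i]][idx[j]] = s
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([""] + list(net.node_ids))
        for v, row in zip(net.node_ids, mat):
            w.writerow([v] + row)


def read_signed_edgelist(path) -> DirectedSignedNetwork:
    """Read a TSV with header columns ``source  target  sign`` (directed arcs)."""
    nodes: list[str] = []
    seen: set[str] = set()
    arcs: dict[tuple[str, str], Sign] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"source", "target", "sign"}
        if not required <= set(reader.fieldnames or ()):
            raise AdjacencyFormatError(
                f"edge list must have columns {sorted(required)}, got {reader.fieldnames}"
            )
        for row in reader:
            i, j = row["source"].strip(), row["target"].strip()
            s = _parse_cell(row["sign"])
            if s not in _VALID_SIGNS:
                raise AdjacencyFormatError(f"sign {row['sign']!r} on arc ({i},{j})")
            for v in (i, j):
                if v not in seen:
                    seen.add(v)
                    nodes.append(v)
            arcs[(i, j)] = s
    return DirectedSignedNetwork(nodes, arcs)


def write_signed_edgelist(net: DirectedSignedNetwork, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["source", "target", "sign"])
        for (i, j), s in net.arcs.items():
            w.writerow([i, j, s])
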