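"""Edge-list I/O and interaction-matrix construction.

A gene interaction network arrives as a tab-separated edge list
(source gene, target gene, edge frequency in [0, 1], optional direction).
Directions are discarded: antiparallel duplicates collapse to a single
undirected edge carrying the maximum of their frequencies, and self-loops
are dropped.  The interaction (adjacency) matrix M is the symmetric 0/1
matrix with zero diagonal over the lexicographically sorted node set.

Edges can be subdivided into frequency quartiles M1 (lowest) .. M4
(highest), plus the full set ALL; each quartile subnetwork keeps only the
nodes incident to at least one of its edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse

logger = logging.getLogger("rmtnet")

GROUP_LABELS = ("M1", "M2", "M3", "M4", "ALL")


class EdgeListError(ValueError):
    """Malformed or invalid edge-list content."""


@dataclass(frozen=True)
class EdgeRecord:
    """One line of an edge list: a (possibly directed) gene pair."""

    source: str
    target: str
    frequency: float
    direction: str | None = None  # parsed if present, ignored downstream


@dataclass
class GeneNetwork:
    """Undirected, deduplicated, frequency-weighted gene network.

    ``edges`` maps each unordered pair (stored as a sorted tuple) to its
    edge frequency.  ``nodes`` is the sorted list of distinct endpoints.
    """

    nodes: list[str]
    edges: dict[tuple[str, str], float]

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    def validate(self) -> None:
        node_set = set(self.nodes)
        for (u, v) in self.edges:
            if u == v:
                raise EdgeListError(f"self-loop survived: {u}")
            if (u, v) != tuple(sorted((u, v))):
                raise EdgeListError(f"edge pair not canonical: {(u, v)}")
            if u not in node_set or v not in node_set:
                raise EdgeListError(f"edge endpoint missing from nodes: {(u, v)}")


@dataclass
class InteractionMatrix:
    """Symmetric 0/1 matrix M with zero diagonal (M_ii = 0)."""

    entries: np.ndarray
    node_index: dict[str, int]

    @property
    def size(self) -> int:
        return self.entries.shape[0]


@dataclass
class SubnetworkGroup:
    """One frequency quartile (M1..M4) or the full edge set (ALL)."""

    label: str
    frequency_range: tuple[float, float]
    edges: dict[tuple[str, str], float]
    incident_nodes: list[str] = field(default_factory=list)

    def to_network(self) -> GeneNetwork:
        return GeneNetwork(nodes=list(self.incident_nodes), edges=dict(self.edges))


# ---------------------------------------------------------------------------
# reading


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_edge_list(path: str | Path) -> list[EdgeRecord]:
    """Read a tab-separated edge list.

    Lines starting with ``#`` are comments; a header row is auto-detected
    by a non-numeric third field.  Each data line needs at least three
    fields: source, target, frequency (in [0, 1]); a fourth field, if
    present, is kept as the (ignored) direction flag.
    """
    path = Path(path)
    records: list[EdgeRecord] = []
    header_skipped = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise EdgeListError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if not _looks_numeric(fields[2]):
                if not records and not header_skipped:
                    header_skipped = True
                    continue
                raise EdgeListError(
                    f"{path.name}:{lineno}: non-numeric frequency {fields[2]!r}"
                )
            freq = float(fields[2])
            if not 0.0 <= freq <= 1.0:
                raise EdgeListError(
                    f"{path.name}:{lineno}: frequency {freq} outside [0, 1]"
                )
            direction = fields[3] if len(fields) > 3 and fields[3] else None
            records.append(EdgeRecord(fields[0], fields[1], freq, direction))
    return records


# ---------------------------------------------------------------------------
# network construction


def build_network(records: Iterable[EdgeRecord]) -> GeneNetwork:
    """Collapse records to an undirected network.

    Self-loops are dropped; duplicate unordered pairs keep the maximum
    frequency (the strongest inference evidence).  Nodes are the sorted
    distinct endpoints of the surviving edges.
    """
    edges: dict[tuple[str, str], float] = {}
    n_self = n_dup = 0
    for rec in records:
        if rec.source == rec.target:
            n_self += 1
            continue
        key = tuple(sorted((rec.source, rec.target)))
        if key in edges:
            n_dup += 1
            edges[key] = max(edges[key], rec.frequency)
        else:
            edges[key] = rec.frequency
    if n_self or n_dup:
        logger.info(
            "build_network: removed %d self-loop(s), merged %d duplicate pair(s)",
            n_self, n_dup,
        )
    nodes = sorted({n for pair in edges for n in pair})
    return GeneNetwork(nodes=nodes, edges=edges)


def build_interaction_matrix(net: GeneNetwork) -> InteractionMatrix:
    """Dense symmetric 0/1 matrix over the sorted node order."""
    index = {name: i for i, name in enumerate(net.nodes)}
    n = len(index)
    m = np.zeros((n, n), dtype=np.float64)
    for (u, v) in net.edges:
        i, j = index[u], index[v]
        m[i, j] = 1.0
        m[j, i] = 1.0
    return InteractionMatrix(entries=m, node_index=index)


# ---------------------------------------------------------------------------
# quartile subdivision


def split_by_frequency_quartiles(net: GeneNetwork) -> list[SubnetworkGroup]:
    """Split edges into frequency quartiles M1..M4 plus ALL.

    Edges are sorted ascending by (frequency, node pair) — the pair is a
    deterministic tie-break — and cut into four contiguous blocks of equal
    size (remainder r < 4 gives one extra edge to each of the first r
    blocks).  Each group's node universe is its incident nodes only.
    """
    if net.edge_count < 4:
        raise EdgeListError("too few edges to subdivide (need >= 4)")
    order = sorted(net.edges.items(), key=lambda kv: (kv[1], kv[0]))
    e = len(order)
    base, rem = divmod(e, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    groups: list[SubnetworkGroup] = []
    start = 0
    for i, sz in enumerate(sizes):
        chunk = order[start:start + sz]
        start += sz
        freqs = [f for _, f in chunk]
        groups.append(_make_group(f"M{i + 1}", dict(chunk), (min(freqs), max(freqs))))
    all_freqs = [f for _, f in order]
    groups.append(_make_group("ALL", dict(order), (min(all_freqs), max(all_freqs))))
    return groups


def _make_group(label: str, edges: dict[tuple[str, str], float],
                frange: tuple[float, float]) -> SubnetworkGroup:
    incident = sorted({n for pair in edges for n in pair})
    return SubnetworkGroup(label=label, frequency_range=frange,
                           edges=edges, incident_nodes=incident)


# ---------------------------------------------------------------------------
# export


def write_edge_list(net: GeneNetwork, path: str | Path) -> None:
    """Write the TSV dialect ``read_edge_list`` reads."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# source\ttarget\tfrequency\n")
        for (u, v), f in sorted(net.edges.items()):
            fh.write(f"{u}\t{v}\t{f:.6g}\n")


def export_matrix_market(mat: InteractionMatrix, path: str | Path) -> None:
    """Adjacency as Matrix Market coordinate, symmetric pattern."""
    coo = scipy.sparse.coo_matrix(np.tril(mat.entries))
    scipy.io.mmwrite(str(path), coo, field="pattern", symmetry="symmetric")


def export_node_index(mat: InteractionMatrix, path: str | Path) -> None:
    """Two-column TSV: gene ID, 0-based row index."""
    with Path(path).open("w") as fh:
        for name, idx in sorted(mat.node_index.items(), key=lambda kv: kv[1]):
            fh.write(f"{name}\t{idx}\n")
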