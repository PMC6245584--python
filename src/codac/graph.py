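"""Bipartite graph data model.

A tripartite association problem is decomposed into bipartite layers: an
annotation layer X–Z (e.g. GO term ↔ protein), a membership layer Y–Z
(e.g. domain ↔ protein), and the sparse target layer X–Y whose enrichment
is the point of the method.  This module holds the unweighted bipartite
graph container, its 0/1 biadjacency matrix, and the redundancy clustering
of the shared Z side.

Identifier comparison is exact, case-sensitive string equality; whitespace
normalisation is an I/O concern (see :mod:`codac.io`).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

from .errors import ValidationError

__all__ = [
    "Bigraph",
    "BiadjacencyMatrix",
    "ClusterMap",
    "build_biadjacency",
    "cluster_common_items",
    "identity_cluster_map",
]


def _ordered_vocab(items: Iterable[str], what: str) -> tuple[str, ...]:
    items = tuple(items)
    if len(set(items)) != len(items):
        seen, dups = set(), []
        for it in items:
            if it in seen:
                dups.append(it)
            seen.add(it)
        raise ValidationError(f"duplicate {what} identifiers: {sorted(set(dups))[:5]}")
    return items


@dataclass(frozen=True)
class Bigraph:
    """An unweighted bipartite graph with ordered vocabularies on both sides.

    Parameters
    ----------
    left_items, right_items
        Ordered identifier vocabularies.  Items may be isolated (degree 0).
    edges
        Set of ``(left, right)`` identifier pairs; duplicates collapse since
        edges are stored as a frozenset.
    """

    left_items: tuple[str, ...]
    right_items: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "left_items", _ordered_vocab(self.left_items, "left"))
        object.__setattr__(self, "right_items", _ordered_vocab(self.right_items, "right"))
        object.__setattr__(self, "edges", frozenset(self.edges))
        left, right = set(self.left_items), set(self.right_items)
        for l, r in self.edges:
            if l not in left:
                raise ValidationError(f"edge endpoint {l!r} missing from left vocabulary")
            if r not in right:
                raise ValidationError(f"edge endpoint {r!r} missing from right vocabulary")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        left_items: Iterable[str] | None = None,
        right_items: Iterable[str] | None = None,
    ) -> "Bigraph":
        """Build a bigraph from an edge list.

        Vocabularies default to the lexicographically sorted identifiers seen
        in the edges, so matrix layouts are reproducible across runs.
        """
        edges = frozenset((str(l), str(r)) for l, r in edges)
        if left_items is None:
            left_items = sorted({l for l, _ in edges})
        if right_items is None:
            right_items = sorted({r for _, r in edges})
        return cls(tuple(left_items), tuple(right_items), edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def left_neighbours(self) -> dict[str, set[str]]:
        """Neighbour sets in Z, keyed by left item (isolated items included)."""
        nbrs: dict[str, set[str]] = {l: set() for l in self.left_items}
        for l, r in self.edges:
            nbrs[l].add(r)
        return nbrs

    def left_degrees(self) -> dict[str, int]:
        deg = dict.fromkeys(self.left_items, 0)
        for l, _ in self.edges:
            deg[l] += 1
        return deg

    def right_degrees(self) -> dict[str, int]:
        deg = dict.fromkeys(self.right_items, 0)
        for _, r in self.edges:
            deg[r] += 1
        return deg


@dataclass(frozen=True)
class BiadjacencyMatrix:
    """0/1 sparse biadjacency matrix with recorded row/column orders."""

    rows: tuple[str, ...]
    cols: tuple[str, ...]
    values: sparse.csr_matrix = field(compare=False)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match vocabularies "
                f"({len(self.rows)}×{len(self.cols)})"
            )

    def to_edges(self) -> frozenset[tuple[str, str]]:
        """Recover the edge set (round-trips with :func:`build_biadjacency`)."""
        coo = self.values.tocoo()
        return frozenset((self.rows[i], self.cols[j]) for i, j in zip(coo.row, coo.col))


@dataclass(frozen=True)
class ClusterMap:
    """Total map from Z-item identifiers to cluster identifiers (CIDs)."""

    mapping: Mapping[str, str]

    def cid(self, z: str) -> str:
        try:
            return self.mapping[z]
        except KeyError:
            raise ValidationError(
                f"Z item {z!r} has no cluster assignment (cluster map must be total)"
            ) from None


def identity_cluster_map(graphs: Iterable[Bigraph]) -> ClusterMap:
    """Singleton clustering: every Z item is its own cluster."""
    mapping: dict[str, str] = {}
    for g in graphs:
        for z in g.right_items:
            mapping[z] = z
    return ClusterMap(mapping)


def build_biadjacency(g: Bigraph, col_order: Iterable[str] | None = None) -> BiadjacencyMatrix:
    """Encode a bigraph as a 0/1 sparse matrix, rows in left order.

    ``col_order`` lets the X–Z and Y–Z layers share one Z column order (a
    precondition of the cosine product); it must cover every right endpoint
    referenced by an edge of ``g``.  Columns absent from ``g`` are all-zero.
    """
    cols = tuple(col_order) if col_order is not None else g.right_items
    col_index = {c: j for j, c in enumerate(cols)}
    if len(col_index) != len(cols):
        raise ValidationError("duplicate identifiers in col_order")
    row_index = {r: i for i, r in enumerate(g.left_items)}
    ii, jj = [], []
    for l, r in g.edges:
        if r not in col_index:
            raise ValidationError(f"edge endpoint {r!r} missing from col_order")
        ii.append(row_index[l])
        jj.append(col_index[r])
    values = sparse.csr_matrix(
        (np.ones(len(ii)), (ii, jj)), shape=(len(g.left_items), len(cols))
    )
    return BiadjacencyMatrix(rows=g.left_items, cols=cols, values=values)


def cluster_common_items(g1: Bigraph, g2: Bigraph, cm: ClusterMap) -> tuple[Bigraph, Bigraph]:
    """Collapse redundant Z items of both layers into cluster identifiers.

    Every edge ``(x, z)`` / ``(y, z)`` is rewritten to ``(x, CID(z))`` /
    ``(y, CID(z))`` and duplicates merge, producing the reduced graphs that
    feed the similarity stage.  Cluster membership must be total over the Z
    items of both graphs.  Collapsing can only shrink the graphs, and it can
    create common-neighbour overlap that the raw identifiers hid (two
    identical proteins annotated in different sources).
    """

    def _reduce(g: Bigraph) -> Bigraph:
        cids = sorted({cm.cid(z) for z in g.right_items})
        edges = {(l, cm.cid(r)) for l, r in g.edges}
        return Bigraph(g.left_items, tuple(cids), frozenset(edges))

    return _reduce(g1), _reduce(g2)


def common_neighbour_counts(g1: Bigraph, g2: Bigraph) -> dict[tuple[str, str], int]:
    """|N(x) ∩ N(y)| for every (x, y) pair with at least one shared Z item.

    Brute-force set arithmetic; intended for oracles and per-pair count
    tables at desk scale, not for the scoring path.
    """
    by_z: dict[str, list[str]] = defaultdict(list)
    for l, r in g1.edges:
        by_z[r].append(l)
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for y, z in g2.edges:
        for x in by_z.get(z, ()):
            counts[(x, y)] += 1
    return dict(counts)
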