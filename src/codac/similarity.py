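"""Cosine neighbourhood similarity and multi-dataset consensus.

For one evidence dataset the X–Z and Y–Z biadjacency matrices M1, M2 are
row-normalised to U1, U2 and the sparse product ``C = U1 @ U2.T`` gives, for
every (x, y) pair, the cosine of their 0/1 neighbourhood vectors::

    C[x, y] = |N(x) ∩ N(y)| / sqrt(deg(x) · deg(y))

Several evidence datasets (curated vs. electronically annotated sources,
structure- vs. sequence-derived) are then merged as a weighted average into
a consensus matrix; a pair absent from a dataset contributes a zero score
for that dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .errors import ValidationError
from .graph import BiadjacencyMatrix

__all__ = [
    "DatasetSimilarity",
    "ConsensusSimilarity",
    "row_normalize",
    "cosine_similarity",
    "consensus",
]


@dataclass(frozen=True)
class DatasetSimilarity:
    """Sparse X×Y cosine score matrix from a single evidence dataset."""

    dataset_id: str
    rows: tuple[str, ...]
    cols: tuple[str, ...]
    values: sparse.csr_matrix = field(compare=False)

    def score(self, x: str, y: str) -> float:
        i, j = self.rows.index(x), self.cols.index(y)
        return float(self.values[i, j])

    def items(self) -> Iterable[tuple[str, str, float]]:
        """Yield (x, y, score) over stored (nonzero) entries."""
        coo = self.values.tocoo()
        for i, j, v in zip(coo.row, coo.col, coo.data):
            yield self.rows[i], self.cols[j], float(v)

    def to_dict(self) -> dict[tuple[str, str], float]:
        return {(x, y): v for x, y, v in self.items()}


@dataclass(frozen=True)
class ConsensusSimilarity:
    """Weighted-average similarity over the union vocabularies of datasets."""

    rows: tuple[str, ...]
    cols: tuple[str, ...]
    values: sparse.csr_matrix = field(compare=False)
    weights: Mapping[str, float] = field(default_factory=dict)

    def items(self) -> Iterable[tuple[str, str, float]]:
        coo = self.values.tocoo()
        for i, j, v in zip(coo.row, coo.col, coo.data):
            yield self.rows[i], self.cols[j], float(v)

    def to_dict(self) -> dict[tuple[str, str], float]:
        return {(x, y): v for x, y, v in self.items()}


def row_normalize(m: BiadjacencyMatrix | sparse.spmatrix) -> sparse.csr_matrix:
    """Scale every nonzero row to unit Euclidean norm; zero rows stay zero.

    Zero-degree items therefore score zero against everything rather than
    propagating NaNs.
    """
    values = m.values if isinstance(m, BiadjacencyMatrix) else m
    csr = sparse.csr_matrix(values, dtype=np.float64, copy=True)
    norms = np.sqrt(np.asarray(csr.multiply(csr).sum(axis=1)).ravel())
    scale = np.divide(1.0, norms, out=np.zeros_like(norms), where=norms > 0)
    return sparse.diags(scale) @ csr


def cosine_similarity(
    m1: BiadjacencyMatrix, m2: BiadjacencyMatrix, dataset_id: str = ""
) -> DatasetSimilarity:
    """Cosine similarity of every X row of ``m1`` against every Y row of ``m2``.

    Both matrices must share an identical Z column vocabulary and order.
    The result is sparse: pairs without a common neighbour are simply not
    stored, so the dense |X|×|Y| product is never materialised.
    """
    if m1.cols != m2.cols:
        raise ValidationError("biadjacency matrices do not share a Z column order")
    u1 = row_normalize(m1)
    u2 = row_normalize(m2)
    c = sparse.csr_matrix(u1 @ u2.T)
    c.eliminate_zeros()
    return DatasetSimilarity(dataset_id=dataset_id, rows=m1.rows, cols=m2.rows, values=c)


def consensus(
    sims: Sequence[DatasetSimilarity], weights: Mapping[str, float]
) -> ConsensusSimilarity:
    """Weighted average of per-dataset scores over union vocabularies.

    ``CS(x, y) = Σ_d w_d · C_d(x, y) / Σ_d w_d`` with ``C_d(x, y) = 0`` when
    the pair is absent from dataset *d*.  Dividing by the full weight sum
    (a true average, not an average over datasets with data) keeps that
    zero-fill semantics literal, and makes the result invariant under
    uniform weight rescaling.
    """
    if not sims:
        raise ValidationError("consensus requires at least one dataset similarity")
    for s in sims:
        if s.dataset_id not in weights:
            raise ValidationError(f"no weight for dataset {s.dataset_id!r}")
        if not weights[s.dataset_id] > 0:
            raise ValidationError(
                f"weight for dataset {s.dataset_id!r} must be positive, got "
                f"{weights[s.dataset_id]!r}"
            )
    rows = tuple(sorted(set().union(*(s.rows for s in sims))))
    cols = tuple(sorted(set().union(*(s.cols for s in sims))))
    row_index = {r: i for i, r in enumerate(rows)}
    col_index = {c: j for j, c in enumerate(cols)}
    total_w = float(sum(weights[s.dataset_id] for s in sims))
    acc = sparse.csr_matrix((len(rows), len(cols)), dtype=np.float64)
    for s in sims:
        coo = s.values.tocoo()
        ii = np.fromiter((row_index[s.rows[i]] for i in coo.row), dtype=np.int64, count=coo.nnz)
        jj = np.fromiter((col_index[s.cols[j]] for j in coo.col), dtype=np.int64, count=coo.nnz)
        lifted = sparse.csr_matrix((coo.data, (ii, jj)), shape=(len(rows), len(cols)))
        acc = acc + (weights[s.dataset_id] / total_w) * lifted
    acc = sparse.csr_matrix(acc)
    acc.eliminate_zeros()
    return ConsensusSimilarity(rows=rows, cols=cols, values=acc, weights=dict(weights))
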