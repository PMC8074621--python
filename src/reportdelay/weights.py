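"""Spatial weight matrices: queen contiguity, k-nearest-neighbour and
same-district schemes.

Weights are binary and stored sparsely.  Queen and same-district graphs are
symmetric by construction; kNN graphs need not be.  Rows are aligned with
the unit ids passed in, and the diagonal is always zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from shapely import STRtree

logger = logging.getLogger(__name__)


@dataclass
class SpatialWeights:
    """Binary neighbourhood structure over a fixed list of units."""

    ids: np.ndarray
    matrix: sp.csr_matrix
    scheme: str
    symmetric: bool = field(default=True)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def to_edge_frame(self) -> pd.DataFrame:
        coo = self.matrix.tocoo()
        return pd.DataFrame(
            {"id_from": self.ids[coo.row], "id_to": self.ids[coo.col]}
        )


def _finalize(ids, rows, cols, n, scheme, symmetric) -> SpatialWeights:
    data = np.ones(len(rows), dtype=np.int8)
    mat = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    mat.sum_duplicates()
    mat.data[:] = 1
    w = SpatialWeights(np.asarray(ids), mat, scheme, symmetric)
    isolated = int((w.row_sums() == 0).sum())
    if isolated:
        logger.warning("%s weights: %d units have no neighbours", scheme, isolated)
    return w


def queen_weights(polygons, ids=None) -> SpatialWeights:
    """Queen contiguity: units are neighbours iff their polygons share at
    least one boundary point (corner touches count)."""
    geoms = list(polygons)
    n = len(geoms)
    if n < 2:
        raise ValueError("queen weights need at least 2 polygons")
    if ids is None:
        ids = np.arange(n)
    tree = STRtree(geoms)
    q_from, q_to = tree.query(geoms, predicate="touches")
    keep = q_from != q_to
    return _finalize(ids, q_from[keep], q_to[keep], n, "queen", True)


def knn_weights(coords, k: int, ids=None) -> SpatialWeights:
    """k-nearest-neighbour weights in planar Euclidean distance.

    Every row has exactly k ones.  Distance ties (common when many events
    share a district-centroid location) are broken by the smallest unit id,
    making the graph deterministic.
    """
    pts = np.asarray(coords, dtype=float)
    n = len(pts)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points {n}")
    if ids is None:
        ids = np.arange(n)
    id_rank = np.argsort(np.argsort(np.asarray(ids), kind="stable"), kind="stable")
    rows = np.repeat(np.arange(n), k)
    cols = np.empty(n * k, dtype=np.int64)
    # exact lexicographic (distance, id) ordering per row; O(n^2) but the
    # event tables this runs on are a few thousand rows
    chunk = max(1, int(2e7 // max(n, 1)))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = ((pts[start:stop, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        d2[np.arange(stop - start), np.arange(start, stop)] = np.inf
        for i in range(start, stop):
            order = np.lexsort((id_rank, d2[i - start]))
            cols[i * k : (i + 1) * k] = order[:k]
    return _finalize(ids, rows, cols, n, f"knn({k})", False)


def same_district_weights(district_ids, ids=None) -> SpatialWeights:
    """All pairs of distinct events in the same district are neighbours
    (block-diagonal complete graphs).  Singleton districts yield zero rows
    with a warning."""
    labels = np.asarray(district_ids)
    n = len(labels)
    if ids is None:
        ids = np.arange(n)
    rows, cols = [], []
    for _, idx in pd.Series(np.arange(n)).groupby(pd.Series(labels)):
        g = idx.to_numpy()
        if len(g) < 2:
            continue
        r = np.repeat(g, len(g))
        c = np.tile(g, len(g))
        keep = r != c
        rows.append(r[keep])
        cols.append(c[keep])
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
    else:
        rows = cols = np.empty(0, dtype=int)
    return _finalize(ids, rows, cols, n, "same_district", True)
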