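"""Two-dimensional hierarchical clustering of the gene x sample matrix.

Rows (genes) are z-scored, distances default to 1 - Pearson correlation and
linkage to average (UPGMA), the standard recipe behind expression heatmaps.
Leaf order is made fully deterministic: at every merge the child subtree
with fewer leaves comes first, ties broken by the lexicographically
smallest member id.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import DataError, GeneMatrix

__all__ = ["ClusterResult", "hierarchical_cluster", "cluster_2d", "linkage_to_json"]


@dataclass
class ClusterResult:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    dropped_rows: list[str]


def _standardize_rows(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    sd = values.std(axis=1, ddof=1)
    dropped = list(values.index[(sd == 0) | sd.isna()])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance rows before clustering",
            stacklevel=3,
        )
        values = values.drop(index=dropped)
        sd = sd.drop(index=dropped)
    z = values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)
    return z, dropped


def _deterministic_leaf_order(Z: np.ndarray, ids: list[str]) -> list[str]:
    """Leaves of a linkage tree: smaller subtree first, ties by smallest id."""
    n = len(ids)

    def describe(node: int) -> tuple[list[str], int, str]:
        if node < n:
            return [ids[node]], 1, ids[node]
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        la, ca, ma = describe(a)
        lb, cb, mb = describe(b)
        if (ca, ma) <= (cb, mb):
            return la + lb, ca + cb, min(ma, mb)
        return lb + la, ca + cb, min(ma, mb)

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * n + 100))
    try:
        leaves, _, _ = describe(2 * n - 2) if n > 1 else ([ids[0]], 1, ids[0])
    finally:
        sys.setrecursionlimit(old)
    return leaves


def hierarchical_cluster(
    values: pd.DataFrame,
    metric: str = "correlation",
    linkage: str = "average",
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of the rows of ``values``.

    Returns the scipy linkage matrix and the deterministic leaf order of
    the row ids.
    """
    if values.shape[0] < 2:
        raise DataError("clustering needs at least 2 items")
    D = pdist(values.to_numpy(dtype=float), metric=metric)
    if not np.all(np.isfinite(D)):
        raise DataError(
            "non-finite distances; correlation distance requires rows with variance"
        )
    Z = hierarchy.linkage(D, method=linkage)
    return Z, _deterministic_leaf_order(Z, list(values.index))


def cluster_2d(
    m: GeneMatrix,
    metric: str = "correlation",
    linkage: str = "average",
    standardize: bool = True,
) -> ClusterResult:
    """Cluster genes (rows) and samples (columns) of an expression matrix."""
    values = m.values
    dropped: list[str] = []
    if standardize:
        values, dropped = _standardize_rows(values)
    row_Z, row_order = hierarchical_cluster(values, metric=metric, linkage=linkage)
    col_Z, col_order = hierarchical_cluster(values.T, metric=metric, linkage=linkage)
    return ClusterResult(
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_Z,
        col_linkage=col_Z,
        dropped_rows=dropped,
    )


def linkage_to_json(Z: np.ndarray, ids: list[str], path: str | Path | None = None):
    """Serialize a linkage tree as a merge list.

    Each entry is ``[left, right, height, n_leaves]`` where leaves are ids
    and internal nodes are ``"node<i>"`` in merge order.
    """
    n = len(ids)

    def name(node: int) -> str:
        return ids[node] if node < n else f"node{node - n}"

    merges = [
        [name(int(a)), name(int(b)), float(h), int(c)] for a, b, h, c in Z
    ]
    if path is not None:
        Path(path).write_text(json.dumps({"leaves": ids, "merges": merges}, indent=1))
    return merges
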