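"""Probe-level normalization and probe-set summarization.

This module provides the two workhorse steps of RMA-style preprocessing on
already log2-transformed intensities:

* :func:`quantile_normalize` — force every sample (column) onto the common
  reference distribution (the row-wise mean of the sorted columns).
* :func:`median_polish_summarize` — per probe set, fit the additive model
  ``value ~ overall + probe effect + sample effect`` by Tukey median polish
  and report ``overall + sample effect`` as the gene-level expression.

Background correction of raw intensities is deliberately not implemented:
inputs are assumed to be log2 scale already, and everything downstream
depends only on normalized log2 values.

:func:`summarize_probe_subset` re-summarizes a gene from a subset of its
probes (e.g. 5' vs 3' probes), the check used to detect cross-hybridization
between paralogous transcripts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DataError, GeneMatrix, ProbeMatrix

__all__ = [
    "quantile_normalize",
    "median_polish",
    "median_polish_summarize",
    "summarize_probe_subset",
]

_MP_TOL = 1e-6
_MP_MAX_ITER = 20


def quantile_normalize(m: ProbeMatrix) -> ProbeMatrix:
    """Quantile-normalize columns to their common mean distribution.

    After normalization every column's sorted value vector equals the
    row-wise mean of the sorted input columns.  Ties within a column receive
    the mean of the reference values at their (tied) rank positions, which
    keeps the transform deterministic and order-independent.
    """
    X = m.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise DataError("quantile normalization needs at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise DataError("probe matrix contains non-finite values")

    n = X.shape[0]
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.take_along_axis(X, order, axis=0).mean(axis=1)

    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        vals = np.empty(n)
        vals[order[:, j]] = ref
        uniq, inv = np.unique(col, return_inverse=True)
        if len(uniq) < n:  # average reference values over tied ranks
            sums = np.bincount(inv, weights=vals)
            counts = np.bincount(inv)
            vals = (sums / counts)[inv]
        out[:, j] = vals

    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ProbeMatrix(values=values, probe_to_gene=m.probe_to_gene.copy())


def _median_polish_batch(
    X: np.ndarray, tol: float = _MP_TOL, max_iter: int = _MP_MAX_ITER
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Median polish of a stack of matrices, shape (g, rows, cols).

    Sweeps rows then columns (rows first), re-centering the effect vectors
    after every sweep; even-count medians use the midpoint.  Stops when the
    summed absolute residual changes by less than ``tol`` (relatively) for
    every matrix in the stack, or after ``max_iter`` sweeps.

    Returns (overall, row_effects, col_effects, residuals).
    """
    g = X.shape[0]
    t = np.zeros(g)
    row = np.zeros((g, X.shape[1]))
    col = np.zeros((g, X.shape[2]))
    R = np.array(X, dtype=float, copy=True)
    prev = np.abs(R).sum(axis=(1, 2))
    # each matrix in the stack is frozen at its own convergence point, so a
    # batched polish is exactly the polish of every block alone
    active = np.ones(g, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        frozen = ~active
        snap = (t[frozen], row[frozen], col[frozen], R[frozen]) if frozen.any() else None
        rd = np.median(R, axis=2, keepdims=True)
        R -= rd
        row += rd[:, :, 0]
        d = np.median(col, axis=1)
        col -= d[:, None]
        t += d
        cd = np.median(R, axis=1, keepdims=True)
        R -= cd
        col += cd[:, 0, :]
        d = np.median(row, axis=1)
        row -= d[:, None]
        t += d
        if snap is not None:
            t[frozen], row[frozen], col[frozen], R[frozen] = snap
        tot = np.abs(R).sum(axis=(1, 2))
        converged = np.abs(prev - tot) <= tol * np.maximum(tot, 1.0)
        active &= ~converged
        prev = tot
    return t, row, col, R


def median_polish(block: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Median polish of a single probes x samples matrix.

    Returns (overall, probe_effects, sample_effects, residuals); the
    summarized per-sample expression is ``overall + sample_effects``.
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or block.size == 0:
        raise DataError("median polish needs a non-empty 2-D matrix")
    t, row, col, R = _median_polish_batch(block[None, :, :])
    return float(t[0]), row[0], col[0], R[0]


def median_polish_summarize(m: ProbeMatrix) -> GeneMatrix:
    """Summarize every probe set to gene-level expression by median polish.

    Genes are processed in first-appearance order of their probes; genes
    with identical probe counts are polished as one vectorized stack, which
    gives results identical to polishing each block alone.
    """
    blocks = m.gene_blocks()
    if not blocks:
        raise DataError("probe map contains no genes")
    X = m.values.to_numpy(dtype=float)

    by_size: dict[int, list[str]] = {}
    for gene, idx in blocks.items():
        by_size.setdefault(len(idx), []).append(gene)

    summaries: dict[str, np.ndarray] = {}
    for size, genes in by_size.items():
        idx = np.stack([blocks[g] for g in genes])  # (g, size)
        t, _row, col, _R = _median_polish_batch(X[idx])
        fitted = t[:, None] + col
        for i, g in enumerate(genes):
            summaries[g] = fitted[i]

    gene_order = m.gene_ids()
    values = pd.DataFrame(
        np.vstack([summaries[g] for g in gene_order]),
        index=gene_order,
        columns=m.values.columns,
    )
    return GeneMatrix(values=values)


def summarize_probe_subset(
    m: ProbeMatrix, gene_id: str, probe_subset: list[str]
) -> pd.Series:
    """Median-polish summary of one gene restricted to a probe subset.

    Used to compare e.g. 5' versus 3' probe subsets of a gene whose probe
    set is suspected of cross-hybridizing with a paralog: subsets that
    disagree on differential expression indicate an off-target signal.
    """
    if len(probe_subset) == 0:
        raise DataError("probe_subset is empty")
    members = set(m.probe_to_gene.index[m.probe_to_gene == gene_id])
    if not members:
        raise DataError(f"gene {gene_id!r} has no probes in the map")
    outside = [p for p in probe_subset if p not in members]
    if outside:
        raise DataError(f"probes not in gene {gene_id!r}: {outside}")
    block = m.values.loc[list(probe_subset)].to_numpy(dtype=float)
    t, _row, col, _R = _median_polish_batch(block[None, :, :])
    return pd.Series(t[0] + col[0], index=m.values.columns, name=gene_id)
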