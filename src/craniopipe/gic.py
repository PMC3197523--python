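"""Gene Information Content: probe-coherence scoring with a permutation null.

The GIC of a gene is the fraction of probe-level variance explained by the
first singular value of its (row-centered) probes x samples block:

    GIC = s1^2 / sum_i si^2

A gene whose probes all track one shared expression pattern is rank-1 after
centering and scores near 1; a gene whose probes are unrelated noise scores
near the top-eigenvalue share of a Wishart matrix, well below 1 for blocks
of a few probes or more.

Significance is calibrated by permuting the probe -> probe-set map: probes
are reassigned to probe sets uniformly at random while preserving every
set's probe count, the GIC of every permuted set is computed, all permuted
scores are pooled, and the cutoff is a high percentile (by default the
99th) of the pooled null.  Genes at or below the cutoff are removed before
downstream analysis; the survivors are ranked by GIC and the top K kept.

Notes on conventions (the source analyses leave these open):

* rows are mean-centered before the SVD, so per-probe affinity offsets do
  not inflate the first singular value;
* percentiles use linear interpolation between order statistics, applied
  identically to observed and permuted scores;
* single-probe genes score 1.0 by construction (their coherence is
  vacuous) and are excluded from top-K selection by default;
* an all-constant block has zero total variance and is scored 0.0 and
  flagged degenerate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .containers import ProbeMatrix

__all__ = [
    "gic_score",
    "score_genes",
    "permutation_cutoff",
    "rank_and_select",
    "gic_filter",
    "PermutationNull",
]

logger = logging.getLogger(__name__)

_ZERO_TOL = 1e-300  # total variance at or below this counts as degenerate


class ParameterError(ValueError):
    pass


def gic_score(block) -> float:
    """GIC of a single probes x samples block.

    Rows are centered across samples; returns ``s1^2 / sum(si^2)`` from the
    SVD of the centered block.  A single-probe gene returns 1.0; an
    all-constant (zero total variance) block returns 0.0.
    """
    X = np.asarray(getattr(block, "values", block), dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 2:
        raise ParameterError("block must be 2-D with >=1 probe and >=2 samples")
    C = X - X.mean(axis=1, keepdims=True)
    total = float((C * C).sum())
    if total <= _ZERO_TOL:
        return 0.0
    if X.shape[0] == 1:
        return 1.0
    s = np.linalg.svd(C, compute_uv=False)
    s2 = s * s
    return float(s2[0] / s2.sum())


def _batch_gic(X: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """GIC for a stack of equal-sized blocks.

    ``X`` is the full probes x samples array, ``idx`` an integer array of
    shape (n_genes, block_size) selecting each gene's probe rows.  Uses the
    eigendecomposition of each block's probe Gram matrix, which for k << n
    samples is much cheaper than an SVD per block.
    """
    B = X[idx]  # (g, k, n)
    B = B - B.mean(axis=2, keepdims=True)
    G = np.einsum("gkn,gln->gkl", B, B, optimize=True)
    w = np.linalg.eigvalsh(G)
    w = np.clip(w, 0.0, None)
    total = w.sum(axis=1)
    degenerate = total <= _ZERO_TOL
    safe = np.where(degenerate, 1.0, total)
    gic = np.where(degenerate, 0.0, w[:, -1] / safe)
    return gic, degenerate


def _grouped_scores(
    X: np.ndarray, genes: list[str], blocks: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Scores for arbitrary-size blocks by batching genes of equal size."""
    gic = np.empty(len(genes))
    degen = np.zeros(len(genes), dtype=bool)
    by_size: dict[int, list[int]] = {}
    for i, g in enumerate(genes):
        by_size.setdefault(len(blocks[g]), []).append(i)
    for size, members in by_size.items():
        idx = np.stack([blocks[genes[i]] for i in members])
        s, d = _batch_gic(X, idx)
        gic[members] = s
        degen[members] = d
    return gic, degen


def score_genes(m: ProbeMatrix) -> pd.DataFrame:
    """Observed GIC for every gene in a probe matrix.

    Returns a DataFrame indexed by gene_id with columns ``gic``,
    ``n_probes`` and ``degenerate``.
    """
    blocks = m.gene_blocks()
    genes = list(blocks)
    X = m.values.to_numpy(dtype=float)
    gic, degen = _grouped_scores(X, genes, blocks)
    return pd.DataFrame(
        {
            "gic": gic,
            "n_probes": [len(blocks[g]) for g in genes],
            "degenerate": degen,
        },
        index=pd.Index(genes, name="gene_id"),
    )


@dataclass
class PermutationNull:
    """Pooled permutation null of GIC scores and its percentile cutoff."""

    n_permutations: int
    cutoff: float
    permuted_scores: np.ndarray
    seed: int
    percentile: float = 99.0

    def summary(self) -> dict:
        return {
            "n_permutations": int(self.n_permutations),
            "cutoff": float(self.cutoff),
            "percentile": float(self.percentile),
            "n_scores": int(self.permuted_scores.size),
            "seed": int(self.seed),
        }


def permutation_cutoff(
    m: ProbeMatrix,
    n_permutations: int = 1000,
    seed: int = 0,
    percentile: float = 99.0,
    _permute: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> PermutationNull:
    """Permutation null for GIC: shuffle the probe -> probe-set map.

    Each permutation reassigns probes to probe sets uniformly at random
    while preserving every set's probe count, scores all permuted sets, and
    pools the scores across permutations; the cutoff is the ``percentile``
    (linear-interpolation) quantile of the pooled null.

    ``_permute`` is a test hook replacing the random permutation; pass
    ``lambda rng, n: np.arange(n)`` to force the identity permutation.
    """
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    blocks = m.gene_blocks()
    if len(blocks) < 2:
        raise ParameterError("permutation null needs at least 2 genes")
    rng = np.random.default_rng(seed)
    permute = _permute or (lambda r, n: r.permutation(n))

    X = m.values.to_numpy(dtype=float)
    sizes = [len(v) for v in blocks.values()]
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    # template: genes grouped by size, holding slice positions into the
    # permuted probe order, so each permutation reuses the same batching
    by_size: dict[int, list[int]] = {}
    for i, s in enumerate(sizes):
        by_size.setdefault(s, []).append(i)
    templates = {
        s: np.stack([np.arange(bounds[i], bounds[i + 1]) for i in members])
        for s, members in by_size.items()
    }

    n_probes = X.shape[0]
    pooled = []
    for _ in range(n_permutations):
        p = permute(rng, n_probes)
        for size, tmpl in templates.items():
            scores, _ = _batch_gic(X, p[tmpl])
            pooled.append(scores)
    permuted = np.concatenate(pooled)
    cutoff = float(np.percentile(permuted, percentile))
    return PermutationNull(
        n_permutations=n_permutations,
        cutoff=cutoff,
        permuted_scores=permuted,
        seed=seed,
        percentile=percentile,
    )


def rank_and_select(
    results: pd.DataFrame,
    k: int,
    cutoff: float,
    include_single_probe: bool = False,
) -> pd.DataFrame:
    """Rank genes by GIC and keep the top ``k`` that pass the cutoff.

    ``results`` is the frame from :func:`score_genes`.  Adds columns
    ``rank`` (1..n over all genes, GIC descending, ties broken by gene id),
    ``passes_cutoff`` (gic strictly above the cutoff) and ``selected``.
    Single-probe genes score 1.0 vacuously and are excluded from selection
    unless ``include_single_probe`` is set.
    """
    if k <= 0:
        raise ParameterError("k must be positive")
    out = results.copy()
    # GIC descending, ties by gene id ascending (lexsort: last key is primary)
    perm = np.lexsort((out.index.to_numpy(), -out["gic"].to_numpy()))
    ranks = np.empty(len(out), dtype=int)
    ranks[perm] = np.arange(1, len(out) + 1)
    out["rank"] = ranks
    out["passes_cutoff"] = out["gic"] > cutoff
    eligible = out["passes_cutoff"] & ~out["degenerate"]
    if not include_single_probe:
        eligible &= out["n_probes"] > 1
    n_eligible = int(eligible.sum())
    if k > n_eligible:
        logger.warning(
            "requested top %d genes but only %d pass the cutoff; keeping all", k, n_eligible
        )
        k = n_eligible
    ranked = out[eligible].sort_values("rank")
    selected = set(ranked.index[:k])
    out["selected"] = [g in selected for g in out.index]
    return out.sort_values("rank")


def gic_filter(
    m: ProbeMatrix,
    n_permutations: int = 1000,
    top_k: int = 2000,
    seed: int = 0,
    percentile: float = 99.0,
    include_single_probe: bool = False,
) -> tuple[pd.DataFrame, PermutationNull]:
    """Score, calibrate and select in one call; the usual entry point."""
    null = permutation_cutoff(m, n_permutations=n_permutations, seed=seed, percentile=percentile)
    table = rank_and_select(
        score_genes(m), top_k, null.cutoff, include_single_probe=include_single_probe
    )
    return table, null
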