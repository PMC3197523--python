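"""Gene-set over-representation analysis (ORA) against GMT collections.

For a query gene list and each gene set, the one-sided Fisher exact test on
the 2x2 table (overlap, query-only, set-only, rest of universe) — exactly
the hypergeometric upper tail P(X >= overlap).  The ``ease`` mode applies
the EASE-score convention of subtracting one from the overlap cell before
computing, a deliberately conservative variant popularized by DAVID.

The universe defaults to all genes on the platform under study and should
match the population the query was drawn from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import DataError
from .diffexpr import bh_adjust

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "overrepresentation"]


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """Parse a GMT file: name TAB description TAB member TAB member ..."""
    out: dict[str, tuple[str, set[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataError(f"malformed GMT line: {line[:60]!r}")
        name, description, members = parts[0], parts[1], parts[2:]
        out[name] = (description, {m for m in members if m})
    return out


def write_gmt(sets: dict[str, tuple[str, set[str]]], path: str | Path) -> None:
    lines = [
        "\t".join([name, desc] + sorted(members))
        for name, (desc, members) in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    @classmethod
    def from_gmt(
        cls,
        path: str | Path,
        universe: set[str],
        min_size: int = 2,
        max_size: int | None = None,
    ) -> "GeneSetCollection":
        """Load a GMT and keep sets whose in-universe size is in range."""
        raw = read_gmt(path)
        sets = {}
        for name, (_desc, members) in raw.items():
            inside = members & universe
            if len(inside) < min_size:
                continue
            if max_size is not None and len(inside) > max_size:
                continue
            sets[name] = inside
        return cls(sets=sets, universe=set(universe))


def overrepresentation(
    query: set[str],
    collection: GeneSetCollection,
    mode: str = "fisher",
) -> pd.DataFrame:
    """One-sided over-representation test of ``query`` against every set.

    Returns a table sorted by p then set name, with columns set_name,
    overlap, set_size, query_size, universe_size, p, p_adj (BH across
    sets).  ``mode="ease"`` subtracts one from the overlap cell.
    """
    if mode not in ("fisher", "ease"):
        raise DataError(f"unknown mode {mode!r}")
    universe = collection.universe
    if not universe:
        raise DataError("empty universe")
    if not query:
        raise DataError("empty query")
    outside = set(query) - universe
    if outside:
        warnings.warn(
            f"dropping {len(outside)} query genes outside the universe", stacklevel=2
        )
    q = set(query) & universe
    if not q:
        raise DataError("no query genes inside the universe")

    M, N = len(universe), len(q)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        K = len(members)
        k = len(members & q)
        k_eff = max(k - 1, 0) if mode == "ease" else k
        # hypergeometric upper tail P(X >= k_eff)
        p = float(hypergeom.sf(k_eff - 1, M, K, N)) if k_eff > 0 else 1.0
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": K,
                "query_size": N,
                "universe_size": M,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
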