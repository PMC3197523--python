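"""Effect-size filtering and three-way Venn partition of flagged genes.

A gene is *flagged* for a contrast when its change is both significant
(raw moderated p < 0.05) and large (|percent change| strictly > 50).  The
flagged sets of the three case-vs-control contrasts are partitioned into
the seven disjoint Venn regions:

    m1 = coronal & metopic & sagittal       (shared by all three)
    m2 = (coronal & metopic) - sagittal
    m3 = (coronal & sagittal) - metopic
    m4 = (metopic & sagittal) - coronal
    m5 = coronal only
    m6 = metopic only
    m7 = sagittal only

m2 is pinned to the coronal-metopic pair; the remaining two-way regions
follow in contrast-name order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DataError
from .diffexpr import lfc_to_pct

__all__ = ["flag_genes", "venn_partition", "shared_table", "VennPartition"]

REGION_NAMES = ("m1", "m2", "m3", "m4", "m5", "m6", "m7")


def flag_genes(
    de_tables: dict[str, pd.DataFrame],
    sig_threshold: float | None = None,
    large_threshold: float | None = None,
) -> dict[str, set[str]]:
    """Per-contrast sets of genes that are both significant and large.

    All tables must cover the same gene universe.  By default the flag is
    ``sig AND large`` as already computed by the differential-expression
    step; passing thresholds recomputes the flags from the ``p`` and
    ``pct_change`` columns (p strictly below, |% change| strictly above).
    """
    universes = {name: frozenset(t.index) for name, t in de_tables.items()}
    first = next(iter(universes.values()), frozenset())
    for name, u in universes.items():
        if u != first:
            raise DataError(f"contrast {name!r} covers a different gene universe")
    out: dict[str, set[str]] = {}
    for name, t in de_tables.items():
        if sig_threshold is None and large_threshold is None:
            mask = (t["sig"] & t["large"]).to_numpy()
        else:
            sig = t["p"].to_numpy() < (sig_threshold if sig_threshold is not None else 0.05)
            large = np.abs(t["pct_change"].to_numpy()) > (
                large_threshold if large_threshold is not None else 50.0
            )
            mask = sig & large
        out[name] = set(t.index[mask])
    return out


@dataclass
class VennPartition:
    """The seven disjoint regions of the coronal/metopic/sagittal Venn."""

    regions: dict[str, set[str]]

    def __post_init__(self) -> None:
        if set(self.regions) != set(REGION_NAMES):
            raise DataError(f"expected regions {REGION_NAMES}")
        all_ids = [g for s in self.regions.values() for g in s]
        if len(all_ids) != len(set(all_ids)):
            raise DataError("Venn regions are not disjoint")

    def __getitem__(self, region: str) -> set[str]:
        return self.regions[region]

    def sizes(self) -> dict[str, int]:
        return {r: len(self.regions[r]) for r in REGION_NAMES}

    def union(self) -> set[str]:
        return set().union(*self.regions.values())

    def contrast_totals(self) -> dict[str, int]:
        """Per-contrast flagged totals, each a sum of four covering regions."""
        r = self.regions
        return {
            "coronal": len(r["m1"] | r["m2"] | r["m3"] | r["m5"]),
            "metopic": len(r["m1"] | r["m2"] | r["m4"] | r["m6"]),
            "sagittal": len(r["m1"] | r["m3"] | r["m4"] | r["m7"]),
        }

    def to_dict(self) -> dict[str, list[str]]:
        return {r: sorted(self.regions[r]) for r in REGION_NAMES}


def venn_partition(
    coronal: set[str], metopic: set[str], sagittal: set[str]
) -> VennPartition:
    """Partition three flagged gene sets into Venn regions m1-m7."""
    c, m, s = set(coronal), set(metopic), set(sagittal)
    return VennPartition(
        regions={
            "m1": c & m & s,
            "m2": (c & m) - s,
            "m3": (c & s) - m,
            "m4": (m & s) - c,
            "m5": c - m - s,
            "m6": m - c - s,
            "m7": s - c - m,
        }
    )


def _fmt(lfc: float) -> str:
    return f"{lfc:.2f} ({lfc_to_pct(lfc, rounded=True)})"


def shared_table(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    flagged_a: set[str],
    flagged_b: set[str],
) -> pd.DataFrame:
    """Genes flagged in both contrasts, with both effect sizes.

    Sorted by the first contrast's log2 fold change, descending.  The
    ``label_*`` columns carry the conventional "lfc (%)" rendering.
    """
    shared = sorted(flagged_a & flagged_b)
    rows = []
    for g in shared:
        la = float(de_a.loc[g, "lfc"])
        lb = float(de_b.loc[g, "lfc"])
        rows.append(
            {
                "gene_id": g,
                "lfc_a": la,
                "pct_a": int(lfc_to_pct(la, rounded=True)),
                "lfc_b": lb,
                "pct_b": int(lfc_to_pct(lb, rounded=True)),
                "label_a": _fmt(la),
                "label_b": _fmt(lb),
            }
        )
    cols = ["gene_id", "lfc_a", "pct_a", "lfc_b", "pct_b", "label_a", "label_b"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values("lfc_a", ascending=False, kind="stable").reset_index(drop=True)
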