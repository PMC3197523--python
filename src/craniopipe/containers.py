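"""In-memory containers and tab-delimited IO for probe- and gene-level expression.

Two matrices flow through the pipeline:

* :class:`ProbeMatrix` — log2 probe intensities, probes x samples, together
  with the probe -> gene (probe-set) map.
* :class:`GeneMatrix` — probe-set-summarized log2 expression, genes x samples.

Everything is stored in pandas so that row/column identity travels with the
numbers.  All on-disk formats are plain tab-delimited text: the probe matrix
(header = sample ids, first column = probe id), a two-column probe map
(probe_id, gene_id) and a sample annotation table with columns
``sample_id, group, age_months, sex, batch``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "CASE_GROUPS",
    "ANNOTATION_COLUMNS",
    "ProbeMatrix",
    "GeneMatrix",
    "read_annotation",
    "write_annotation",
    "validate_annotation",
]

#: The four study arms; ``control`` is always the reference level.
GROUPS: tuple[str, ...] = ("control", "coronal", "metopic", "sagittal")
CASE_GROUPS: tuple[str, ...] = ("coronal", "metopic", "sagittal")
ANNOTATION_COLUMNS: tuple[str, ...] = ("sample_id", "group", "age_months", "sex", "batch")


class DataError(ValueError):
    """Malformed input data (bad map, missing column, non-finite value ...)."""


@dataclass
class ProbeMatrix:
    """Probe-level log2 intensities plus the probe-set map.

    Parameters
    ----------
    values
        probes x samples DataFrame; the index holds probe ids.
    probe_to_gene
        Series mapping probe_id -> gene_id.  Every probe in ``values`` must
        map to exactly one gene.
    """

    values: pd.DataFrame
    probe_to_gene: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise DataError("duplicate probe ids in probe matrix")
        if self.probe_to_gene.index.has_duplicates:
            raise DataError("a probe maps to more than one gene")
        missing = self.values.index.difference(self.probe_to_gene.index)
        if len(missing):
            raise DataError(f"probes missing from probe map: {list(missing[:5])} ...")
        # keep the map aligned to the matrix rows
        self.probe_to_gene = self.probe_to_gene.reindex(self.values.index)

    # -- basic views -------------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_ids(self) -> list[str]:
        """Gene ids in first-appearance order of their probes."""
        return list(dict.fromkeys(self.probe_to_gene.tolist()))

    def gene_blocks(self) -> dict[str, np.ndarray]:
        """Map gene_id -> integer row positions of its probes."""
        pos = pd.Series(np.arange(self.n_probes), index=self.values.index)
        out: dict[str, np.ndarray] = {}
        for gene, probes in self.probe_to_gene.groupby(self.probe_to_gene, sort=False):
            out[str(gene)] = pos.loc[probes.index].to_numpy()
        return out

    def block(self, gene_id: str) -> pd.DataFrame:
        """The probes x samples sub-matrix for one gene."""
        probes = self.probe_to_gene.index[self.probe_to_gene == gene_id]
        if len(probes) == 0:
            raise DataError(f"gene {gene_id!r} has no probes in the map")
        return self.values.loc[probes]

    # -- IO ----------------------------------------------------------------
    def to_tsv(self, probes_path: str | Path, map_path: str | Path) -> None:
        self.values.rename_axis("probe_id").to_csv(probes_path, sep="\t")
        self.probe_to_gene.rename("gene_id").rename_axis("probe_id").to_csv(
            map_path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, probes_path: str | Path, map_path: str | Path) -> "ProbeMatrix":
        values = pd.read_csv(probes_path, sep="\t", index_col=0)
        pmap = pd.read_csv(map_path, sep="\t", index_col=0)["gene_id"].astype(str)
        return cls(values=values, probe_to_gene=pmap)


@dataclass
class GeneMatrix:
    """Probe-set (gene)-level summarized log2 expression, genes x samples."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise DataError("duplicate gene ids in gene matrix")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, path: str | Path) -> None:
        self.values.rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneMatrix":
        return cls(values=pd.read_csv(path, sep="\t", index_col=0))


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check the sample table and return it with canonical dtypes.

    Raises :class:`DataError` naming the first missing column.
    """
    for col in ANNOTATION_COLUMNS:
        if col not in annotation.columns:
            raise DataError(f"annotation is missing required column {col!r}")
    bad = set(annotation["group"]) - set(GROUPS)
    if bad:
        raise DataError(f"unknown group labels in annotation: {sorted(bad)}")
    out = annotation.copy()
    out["sample_id"] = out["sample_id"].astype(str)
    out["age_months"] = out["age_months"].astype(int)
    out["sex"] = out["sex"].astype(int)  # 0 = female, 1 = male
    out["batch"] = out["batch"].astype(str)
    return out


def read_annotation(path: str | Path) -> pd.DataFrame:
    return validate_annotation(pd.read_csv(path, sep="\t"))


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    validate_annotation(annotation).to_csv(path, sep="\t", index=False)
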