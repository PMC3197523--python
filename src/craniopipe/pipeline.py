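"""End-to-end orchestration: normalize -> GIC -> DE -> sets -> cluster -> enrich.

A :class:`PipelineConfig` (optionally loaded from YAML) points at the input
files and carries every stage's parameters.  :func:`run_pipeline` executes
the stages in order, writes each artifact as tab-delimited text or JSON
into the output directory, and finishes with a machine-readable manifest
(parameters, seeds, library versions, per-stage row counts and a sha256 of
every output).  Reruns with the same config and inputs are byte-identical
for every deterministic stage.

On a stage failure the partial outputs are moved under ``failed/`` inside
the run directory and a :class:`PipelineError` naming the stage is raised.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import cluster_2d, linkage_to_json
from .containers import GeneMatrix, ProbeMatrix, read_annotation
from .diffexpr import DEFAULT_CONTRASTS, ModelSpec, de_analysis, parse_contrasts
from .enrich import GeneSetCollection, overrepresentation
from .gic import gic_filter
from .normalize import median_polish_summarize, quantile_normalize
from .setops import flag_genes, shared_table, venn_partition

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    # inputs
    probes: str = ""
    probe_map: str = ""
    annotation: str = ""
    gmt: str | None = None
    # GIC stage
    n_permutations: int = 1000
    top_k: int = 2000
    seed: int = 0
    gic_percentile: float = 99.0
    # DE stage
    contrasts: str = ",".join(":".join(c) for c in DEFAULT_CONTRASTS)
    batch_mode: str = "gls"
    sig_threshold: float = 0.05
    large_threshold: float = 50.0
    # clustering
    cluster_metric: str = "correlation"
    cluster_linkage: str = "average"
    # enrichment
    enrich_mode: str = "fisher"
    enrich_min_size: int = 2
    enrich_max_size: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and return the manifest (also written to manifest.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "libraries": {"numpy": np.__version__, "pandas": pd.__version__},
        "config": asdict(config),
        "stages": {},
    }
    stage = "load"
    try:
        annotation = read_annotation(config.annotation)
        probes = ProbeMatrix.from_tsv(config.probes, config.probe_map)
        manifest["stages"]["load"] = {
            "n_probes": probes.n_probes,
            "n_samples": probes.n_samples,
            "n_genes": len(probes.gene_ids()),
        }

        stage = "normalize"
        normalized = quantile_normalize(probes)
        genes = median_polish_summarize(normalized)
        genes.to_tsv(out / "genes.tsv")
        manifest["stages"]["normalize"] = {"n_genes": len(genes.gene_ids)}

        stage = "gic"
        # GIC consumes the quantile-normalized probe matrix, pre-summarization
        table, null = gic_filter(
            normalized,
            n_permutations=config.n_permutations,
            top_k=config.top_k,
            seed=config.seed,
            percentile=config.gic_percentile,
        )
        table.to_csv(out / "gic.tsv", sep="\t")
        (out / "gic_null.json").write_text(json.dumps(null.summary(), indent=1))
        selected = list(table.index[table["selected"]])
        manifest["stages"]["gic"] = {
            "cutoff": null.cutoff,
            "n_passing": int(table["passes_cutoff"].sum()),
            "n_selected": len(selected),
        }

        stage = "diffexpr"
        spec = ModelSpec(
            contrasts=parse_contrasts(config.contrasts),
            batch_mode=config.batch_mode,
            sig_threshold=config.sig_threshold,
            large_threshold=config.large_threshold,
        )
        top = GeneMatrix(values=genes.values.loc[selected])
        de = de_analysis(top, annotation, spec)
        for name, t in de.items():
            t.to_csv(out / f"de_{name}.tsv", sep="\t")
        manifest["stages"]["diffexpr"] = {
            "contrasts": sorted(de),
            "n_genes": len(top.gene_ids),
        }

        stage = "setops"
        case_names = ["coronal_control", "metopic_control", "sagittal_control"]
        missing = [n for n in case_names if n not in de]
        if missing:
            raise ValueError(f"Venn partition needs contrasts {missing}")
        flagged = flag_genes({n: de[n] for n in case_names})
        venn = venn_partition(
            flagged["coronal_control"],
            flagged["metopic_control"],
            flagged["sagittal_control"],
        )
        (out / "venn.json").write_text(
            json.dumps(
                {"regions": venn.to_dict(), "totals": venn.contrast_totals()}, indent=1
            )
        )
        if {"coronal_sagittal", "metopic_sagittal"} <= set(de):
            fl = flag_genes(
                {n: de[n] for n in ("coronal_sagittal", "metopic_sagittal")}
            )
            shared = shared_table(
                de["coronal_sagittal"],
                de["metopic_sagittal"],
                fl["coronal_sagittal"],
                fl["metopic_sagittal"],
            )
            shared.to_csv(out / "shared_vs_sagittal.tsv", sep="\t", index=False)
        manifest["stages"]["setops"] = {"venn_sizes": venn.sizes()}

        stage = "cluster"
        result = cluster_2d(
            top, metric=config.cluster_metric, linkage=config.cluster_linkage
        )
        (out / "row_order.txt").write_text("\n".join(result.row_order) + "\n")
        (out / "col_order.txt").write_text("\n".join(result.col_order) + "\n")
        linkage_to_json(result.row_linkage, result.row_order, out / "row_linkage.json")
        linkage_to_json(result.col_linkage, result.col_order, out / "col_linkage.json")
        manifest["stages"]["cluster"] = {
            "n_rows": len(result.row_order),
            "n_dropped": len(result.dropped_rows),
        }

        if config.gmt:
            stage = "enrich"
            collection = GeneSetCollection.from_gmt(
                config.gmt,
                universe=set(genes.gene_ids),
                min_size=config.enrich_min_size,
                max_size=config.enrich_max_size,
            )
            enr = overrepresentation(set(selected), collection, mode=config.enrich_mode)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["enrich"] = {
                "n_sets": len(enr),
                "n_significant": int((enr["p"] < 0.01).sum()),
            }
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for f in out.iterdir():
            if f.is_file():
                shutil.move(str(f), failed / f.name)
        raise PipelineError(stage, exc) from exc

    manifest["outputs"] = {
        f.name: _sha256(f) for f in sorted(out.iterdir()) if f.is_file()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
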