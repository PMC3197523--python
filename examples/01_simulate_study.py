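"""Simulate a probe-level four-arm expression study.

Builds the study's sample layout (50 controls, 100 sagittal, 50 coronal,
49 metopic cases, with realistic age/sex structure and processing batches)
and generates probe-level log2 intensities for a handful of genes with
planted fold changes.
"""

import numpy as np

from craniopipe import (
    PlantedGene,
    StudyDesign,
    generate_design,
    generate_probe_data,
    planted_genes,
)

design = StudyDesign(seed=1)
annotation = generate_design(design)
print(annotation.groupby("group")["age_months"].agg(["count", "mean", "min", "max"]))

genes = [
    PlantedGene(
        gene_id="FGF7like",
        n_probes=9,
        coherence=0.95,
        lfc_by_contrast={"coronal": 1.01, "metopic": 0.91, "sagittal": 0.91},
    )
] + planted_genes(50, np.random.default_rng(2), coherence=0.9)

probes = generate_probe_data(annotation, genes, seed=3)
print(f"\nprobe matrix: {probes.n_probes} probes x {probes.n_samples} samples")
print(f"genes: {len(probes.gene_ids())} (first: {probes.gene_ids()[:3]})")
# Each probe row tracks its gene's latent signal in proportion to the
# gene's coherence; the planted log2 fold changes sit on the case groups.
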