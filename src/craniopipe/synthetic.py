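"""Synthetic probe-level datasets with the structure the analysis assumes.

The generator emulates a four-arm osteoblast expression study (control and
three single-suture craniosynostosis groups: sagittal, coronal, metopic) on a
whole-transcript array where each gene is interrogated by several probes.

For a planted gene *g* and sample *s* a latent gene-level signal is drawn

    z_gs = baseline + lfc(group(s)) + beta_age * age_s + beta_sex * sex_s
           + batch_effect(batch(s)) + N(0, sample_sd^2)

and probe *p* observes

    y_pgs = z_gs * sqrt(coherence) * a_p + N(0, noise_sd^2) * sqrt(1 - coherence)

with per-probe affinities a_p ~ N(1, affinity_sd^2) fixed per gene.  The
``coherence`` parameter therefore controls the share of probe-level variance
driven by the shared gene signal: coherent genes have probes that move in
lock-step (high GIC), incoherent genes look like unrelated probes.

Defaults reproduce the study design: group sizes 50/100/50/49
(control/sagittal/coronal/metopic), age ranges and male fractions per the
study's demographic table, batches assigned round-robin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import CASE_GROUPS, GROUPS, ProbeMatrix, validate_annotation

__all__ = [
    "StudyDesign",
    "PlantedGene",
    "DesignError",
    "generate_design",
    "generate_probe_data",
    "planted_genes",
    "background_genes",
]

# Demographic defaults: (age range in months, fraction male) per group.
_AGE_RANGE = {
    "control": (1, 120),
    "coronal": (4, 24),
    "metopic": (3, 19),
    "sagittal": (2, 28),
}
_MALE_FRACTION = {
    "control": 35 / 50,
    "coronal": 18 / 50,
    "metopic": 36 / 49,
    "sagittal": 77 / 100,
}


class DesignError(ValueError):
    """Invalid study design or generator parameters."""


@dataclass(frozen=True)
class StudyDesign:
    """Sample-level layout of a simulated study.

    All counts must be >= 2; ages are integer months, drawn uniformly within
    each group's (min, max) range; sex is Bernoulli at the group's male
    fraction; batches (processing dates) are assigned round-robin.
    """

    n_control: int = 50
    n_sagittal: int = 100
    n_coronal: int = 50
    n_metopic: int = 49
    age_range_by_group: dict = field(default_factory=lambda: dict(_AGE_RANGE))
    sex_proportion_by_group: dict = field(default_factory=lambda: dict(_MALE_FRACTION))
    n_batches: int = 8
    seed: int = 0

    def group_sizes(self) -> dict[str, int]:
        return {
            "control": self.n_control,
            "coronal": self.n_coronal,
            "metopic": self.n_metopic,
            "sagittal": self.n_sagittal,
        }

    def validate(self) -> None:
        for g, n in self.group_sizes().items():
            if n < 2:
                raise DesignError(f"group {g!r} needs at least 2 samples, got {n}")
        if self.n_batches < 1:
            raise DesignError("n_batches must be >= 1")
        for g in GROUPS:
            lo, hi = self.age_range_by_group[g]
            if lo < 1 or hi < lo:
                raise DesignError(f"bad age range for {g!r}: ({lo}, {hi})")
            frac = self.sex_proportion_by_group[g]
            if not 0.0 <= frac <= 1.0:
                raise DesignError(f"sex fraction for {g!r} outside [0, 1]: {frac}")


@dataclass(frozen=True)
class PlantedGene:
    """One simulated gene and the effects planted into it.

    ``coherence`` in [0, 1] is the share of probe variance carried by the
    shared gene-level signal; ``lfc_by_contrast`` maps a case group name to
    its planted log2 fold change versus control.
    """

    gene_id: str
    n_probes: int = 8
    coherence: float = 0.95
    lfc_by_contrast: dict = field(default_factory=dict)
    batch_sd: float = 0.3
    noise_sd: float = 0.5
    sample_sd: float = 0.5
    baseline: float = 7.0

    def validate(self) -> None:
        if self.n_probes < 1:
            raise DesignError(f"{self.gene_id}: n_probes must be >= 1")
        if not 0.0 <= self.coherence <= 1.0:
            raise DesignError(f"{self.gene_id}: coherence outside [0, 1]")
        if self.noise_sd <= 0:
            raise DesignError(f"{self.gene_id}: noise_sd must be > 0")
        unknown = set(self.lfc_by_contrast) - set(CASE_GROUPS)
        if unknown:
            raise DesignError(f"{self.gene_id}: unknown contrast groups {sorted(unknown)}")


def generate_design(design: StudyDesign) -> pd.DataFrame:
    """Draw the sample annotation table for a :class:`StudyDesign`.

    Returns one row per sample with columns sample_id, group, age_months,
    sex (0 = female, 1 = male) and batch; deterministic given ``design.seed``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    rows = []
    i = 0
    for group in GROUPS:  # fixed group order: control, coronal, metopic, sagittal
        n = design.group_sizes()[group]
        lo, hi = design.age_range_by_group[group]
        ages = rng.integers(lo, hi + 1, size=n)
        sexes = (rng.random(n) < design.sex_proportion_by_group[group]).astype(int)
        for k in range(n):
            rows.append(
                {
                    "sample_id": f"S{i + 1:03d}",
                    "group": group,
                    "age_months": int(ages[k]),
                    "sex": int(sexes[k]),
                    "batch": f"B{i % design.n_batches + 1}",
                }
            )
            i += 1
    return validate_annotation(pd.DataFrame(rows))


def generate_probe_data(
    annotation: pd.DataFrame,
    genes: list[PlantedGene],
    seed: int,
    *,
    beta_age: float = 0.002,
    beta_sex: float = 0.1,
    affinity_sd: float = 0.2,
) -> ProbeMatrix:
    """Simulate the probe x sample log2 intensity matrix for planted genes.

    Parameters
    ----------
    annotation
        Sample table from :func:`generate_design` (or the same format).
    genes
        Planted genes; ids must be distinct.
    seed
        Seed for all randomness in this call.
    beta_age, beta_sex
        Confounder effect sizes shared by all genes (log2 per month, log2).
    affinity_sd
        Spread of the per-probe multiplicative affinities a_p ~ N(1, sd^2).
    """
    annotation = validate_annotation(annotation)
    if len(annotation) == 0:
        raise DesignError("annotation is empty")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise DesignError("planted gene ids are not distinct")
    for g in genes:
        g.validate()

    rng = np.random.default_rng(seed)
    n_samples = len(annotation)
    age = annotation["age_months"].to_numpy(float)
    sex = annotation["sex"].to_numpy(float)
    batches = annotation["batch"].to_numpy()
    batch_levels, batch_idx = np.unique(batches, return_inverse=True)

    blocks, probe_ids, gene_of_probe = [], [], []
    for g in genes:
        lfc = np.zeros(n_samples)
        for grp, value in g.lfc_by_contrast.items():
            lfc[annotation["group"].to_numpy() == grp] = value
        batch_eff = rng.normal(0.0, g.batch_sd, size=len(batch_levels))
        z = (
            g.baseline
            + lfc
            + beta_age * age
            + beta_sex * sex
            + batch_eff[batch_idx]
            + rng.normal(0.0, g.sample_sd, size=n_samples)
        )
        a = rng.normal(1.0, affinity_sd, size=g.n_probes)
        noise = rng.normal(0.0, g.noise_sd, size=(g.n_probes, n_samples))
        c = g.coherence
        block = np.sqrt(c) * a[:, None] * z[None, :] + np.sqrt(1.0 - c) * noise
        blocks.append(block)
        probe_ids.extend(f"{g.gene_id}_p{j + 1}" for j in range(g.n_probes))
        gene_of_probe.extend([g.gene_id] * g.n_probes)

    values = pd.DataFrame(
        np.vstack(blocks), index=probe_ids, columns=annotation["sample_id"].tolist()
    )
    pmap = pd.Series(gene_of_probe, index=probe_ids, name="gene_id")
    return ProbeMatrix(values=values, probe_to_gene=pmap)


def planted_genes(
    n: int,
    rng: np.random.Generator,
    *,
    prefix: str = "G",
    coherence: float = 0.95,
    lfc_by_contrast: dict | None = None,
    n_probes: tuple[int, int] = (4, 26),
    **kwargs,
) -> list[PlantedGene]:
    """Convenience factory: ``n`` genes with probe counts uniform in a range."""
    counts = rng.integers(n_probes[0], n_probes[1] + 1, size=n)
    return [
        PlantedGene(
            gene_id=f"{prefix}{i + 1:05d}",
            n_probes=int(counts[i]),
            coherence=coherence,
            lfc_by_contrast=dict(lfc_by_contrast or {}),
            **kwargs,
        )
        for i in range(n)
    ]


def background_genes(n: int, rng: np.random.Generator, **kwargs) -> list[PlantedGene]:
    """Null genes: no planted fold change, probes are pure independent noise."""
    kwargs.setdefault("coherence", 0.0)
    kwargs.setdefault("prefix", "N")
    return planted_genes(n, rng, lfc_by_contrast={}, **kwargs)


def simulate_from_config(cfg: dict, seed: int):
    """Build (annotation, ProbeMatrix) from a flat config mapping.

    Recognized keys::

        design:               # StudyDesign fields (group sizes, n_batches ...)
        genes:
          n_background: 200   # incoherent null genes
          n_coherent: 100     # coherent genes without planted effects
          coherence: 0.9      # coherence of the n_coherent genes
          planted:            # explicit genes with planted fold changes
            - gene_id: FGF7like
              n_probes: 9
              coherence: 0.95
              lfc: {coronal: 1.01, metopic: 0.91, sagittal: 0.91}
    """
    design = StudyDesign(**{**cfg.get("design", {}), "seed": seed})
    annotation = generate_design(design)
    gcfg = cfg.get("genes", {})
    rng = np.random.default_rng(seed + 1)
    genes: list[PlantedGene] = []
    for entry in gcfg.get("planted", []):
        entry = dict(entry)
        entry["lfc_by_contrast"] = entry.pop("lfc", {})
        genes.append(PlantedGene(**entry))
    genes += planted_genes(
        int(gcfg.get("n_coherent", 0)),
        rng,
        prefix="G",
        coherence=float(gcfg.get("coherence", 0.9)),
    )
    genes += background_genes(int(gcfg.get("n_background", 0)), rng)
    probes = generate_probe_data(annotation, genes, seed=seed + 2)
    return annotation, probes
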