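import numpy as np
import pandas as pd
import pytest

from craniopipe.containers import ProbeMatrix, validate_annotation
from craniopipe.synthetic import StudyDesign, generate_design


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_design():
    return StudyDesign(
        n_control=12, n_sagittal=12, n_coronal=12, n_metopic=12, n_batches=4, seed=7
    )


@pytest.fixture
def small_annotation(small_design):
    return generate_design(small_design)


def make_probe_matrix(values, gene_sizes, sample_ids=None):
    """Assemble a ProbeMatrix from a raw array and per-gene probe counts."""
    values = np.asarray(values, dtype=float)
    assert values.shape[0] == sum(gene_sizes.values())
    probe_ids, gene_of = [], []
    for gene, k in gene_sizes.items():
        probe_ids.extend(f"{gene}_p{i}" for i in range(k))
        gene_of.extend([gene] * k)
    cols = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=probe_ids, columns=cols)
    return ProbeMatrix(values=df, probe_to_gene=pd.Series(gene_of, index=probe_ids))


@pytest.fixture
def iid_probe_matrix(rng):
    """60 probes over 10 genes of 6 probes, iid Gaussian, 20 samples."""
    sizes = {f"g{i}": 6 for i in range(10)}
    return make_probe_matrix(rng.normal(size=(60, 20)), sizes)
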