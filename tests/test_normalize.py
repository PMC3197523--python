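"""Quantile normalization and median-polish summarization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from craniopipe.containers import DataError
from craniopipe.normalize import (
    median_polish,
    median_polish_summarize,
    quantile_normalize,
    summarize_probe_subset,
)

from conftest import make_probe_matrix


class TestQuantileNormalize:
    def test_hand_example(self):
        # mean of sorted columns [1,2,3] and [3,4,5] is [2,3,4]
        m = make_probe_matrix(np.array([[1.0, 3.0], [2.0, 4.0], [3.0, 5.0]]), {"g": 3})
        out = quantile_normalize(m).values.to_numpy()
        assert np.allclose(out[:, 0], [2, 3, 4])
        assert np.allclose(out[:, 1], [2, 3, 4])

    def test_identical_columns_are_fixed_point(self):
        col = np.array([5.0, 1.0, 3.0])
        m = make_probe_matrix(np.column_stack([col, col, col]), {"g": 3})
        assert np.allclose(quantile_normalize(m).values.to_numpy(), m.values.to_numpy())

    def test_ties_get_mean_of_reference_ranks(self):
        # tied values 1,1 occupy ranks 0 and 1 -> both get mean(ref[0], ref[1])
        m = make_probe_matrix(np.array([[1.0, 10.0], [1.0, 20.0], [2.0, 30.0]]), {"g": 3})
        out = quantile_normalize(m).values.to_numpy()
        ref = np.array([5.5, 10.5, 16.0])
        assert np.allclose(out[:, 0], [8.0, 8.0, 16.0])
        assert np.allclose(out[:, 1], ref)

    def test_rejects_nonfinite(self):
        m = make_probe_matrix(np.array([[1.0, np.nan], [2.0, 4.0]]), {"g": 2})
        with pytest.raises(DataError):
            quantile_normalize(m)

    @settings(max_examples=25, deadline=None)
    @given(
        arrays(
            np.float64,
            (6, 4),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
            unique=True,  # tie-averaging makes ties only approximately idempotent
        )
    )
    def test_idempotent_with_equal_column_means(self, x):
        m = make_probe_matrix(x, {"g": 6})
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-10)
        means = once.values.mean(axis=0)
        assert np.allclose(means, means.iloc[0], atol=1e-10)


class TestMedianPolish:
    def test_single_probe_gene_passes_through(self):
        m = make_probe_matrix(np.array([[3.0, 5.0, 4.0]]), {"g": 1})
        out = median_polish_summarize(m)
        assert np.allclose(out.values.loc["g"], [3.0, 5.0, 4.0])

    def test_probe_offsets_fully_absorbed(self):
        # rows are column-constant offsets -> identical summaries per sample
        m = make_probe_matrix(np.array([[1.0] * 4, [5.0] * 4, [9.0] * 4]), {"g": 3})
        out = median_polish_summarize(m).values.loc["g"].to_numpy()
        assert np.allclose(out, out[0])

    def test_additive_truth_robust_to_outlier(self):
        # 3x4 additive table (overall 5, rows [-1,0,1], cols [0,1,2,3]) with
        # one corrupted cell; sample-effect differences must match the truth
        rows = np.array([-1.0, 0.0, 1.0])
        cols = np.array([0.0, 1.0, 2.0, 3.0])
        X = 5.0 + rows[:, None] + cols[None, :]
        X[0, 0] += 10.0
        _t, _row, col_eff, _r = median_polish(X)
        assert np.allclose(col_eff - col_eff[0], cols - cols[0], atol=1e-9)

    def test_additive_matrix_recovered_in_two_sweeps(self, rng):
        rows = rng.normal(size=6)
        cols = rng.normal(size=9)
        X = 2.0 + rows[:, None] + cols[None, :]
        t, row_eff, col_eff, resid = median_polish(X)
        assert np.allclose(resid, 0.0, atol=1e-12)
        assert np.allclose((t + col_eff) - (t + col_eff)[0], cols - cols[0], atol=1e-12)

    def test_summary_invariant_to_probe_row_order(self, rng):
        X = rng.normal(size=(7, 10))
        m1 = make_probe_matrix(X, {"g": 7})
        m2 = make_probe_matrix(X[::-1], {"g": 7})
        a = median_polish_summarize(m1).values.loc["g"]
        b = median_polish_summarize(m2).values.loc["g"]
        assert np.allclose(a, b, atol=1e-12)

    def test_batched_summarization_matches_single_gene(self, rng):
        X = rng.normal(size=(12, 8))
        m = make_probe_matrix(X, {"a": 5, "b": 4, "c": 3})
        out = median_polish_summarize(m)
        for gene in ("a", "b", "c"):
            t, _row, col, _r = median_polish(m.block(gene).to_numpy())
            assert np.allclose(out.values.loc[gene], t + col, atol=1e-12)


class TestProbeSubset:
    def test_full_subset_equals_summarize(self, iid_probe_matrix):
        probes = [p for p in iid_probe_matrix.probe_ids if p.startswith("g3_")]
        sub = summarize_probe_subset(iid_probe_matrix, "g3", probes)
        full = median_polish_summarize(iid_probe_matrix).values.loc["g3"]
        assert np.allclose(sub, full, atol=1e-12)

    def test_single_probe_subset_is_that_probe(self, iid_probe_matrix):
        sub = summarize_probe_subset(iid_probe_matrix, "g0", ["g0_p2"])
        assert np.allclose(sub, iid_probe_matrix.values.loc["g0_p2"])

    def test_probe_outside_gene_rejected(self, iid_probe_matrix):
        with pytest.raises(DataError):
            summarize_probe_subset(iid_probe_matrix, "g0", ["g1_p0"])
        with pytest.raises(DataError):
            summarize_probe_subset(iid_probe_matrix, "g0", [])

    def test_cross_hybridizing_gene_detected_by_subset_summaries(self, rng):
        # one gene whose 3' probes carry an off-target case signal while its
        # 5' probes do not: the subset summaries must disagree on DE
        from scipy import stats

        n_per = 30
        group = np.array(["control"] * n_per + ["coronal"] * n_per)
        effect = (group == "coronal") * 1.0
        z_true = rng.normal(scale=0.3, size=2 * n_per)  # on-target signal, no DE
        z_cross = z_true + effect  # cross-hybridizing signal
        probes = []
        for _ in range(3):  # 5' probes: on-target only
            probes.append(z_true + rng.normal(scale=0.2, size=2 * n_per))
        for _ in range(3):  # 3' probes: contaminated
            probes.append(z_cross + rng.normal(scale=0.2, size=2 * n_per))
        m = make_probe_matrix(np.array(probes), {"kgf": 6})
        five = summarize_probe_subset(m, "kgf", ["kgf_p0", "kgf_p1", "kgf_p2"])
        three = summarize_probe_subset(m, "kgf", ["kgf_p3", "kgf_p4", "kgf_p5"])

        lfc5 = five[group == "coronal"].mean() - five[group == "control"].mean()
        _t, p3 = stats.ttest_ind(three[group == "coronal"], three[group == "control"])
        assert p3 < 0.05
        assert abs(lfc5) < 0.1
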