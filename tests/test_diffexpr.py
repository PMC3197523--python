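"""Linear models, empirical-Bayes moderation, BH and effect-size arithmetic."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from craniopipe.containers import DataError, GeneMatrix
from craniopipe.diffexpr import (
    ModelError,
    ModelSpec,
    bh_adjust,
    de_analysis,
    fit_gene_models,
    lfc_to_pct,
    moderate_variances,
    parse_contrasts,
)
from craniopipe.normalize import median_polish_summarize
from craniopipe.synthetic import (
    PlantedGene,
    StudyDesign,
    generate_design,
    generate_probe_data,
    planted_genes,
)


def _noiseless_dataset(annotation, lfc_map, n_genes=12, seed=0):
    """Deterministic expression: coherence 1, unit affinities, no scatter."""
    genes = [
        PlantedGene(
            gene_id=f"G{i}",
            n_probes=4,
            coherence=1.0,
            lfc_by_contrast=dict(lfc_map),
            batch_sd=0.0,
            sample_sd=0.0,
        )
        for i in range(n_genes)
    ]
    pm = generate_probe_data(annotation, genes, seed=seed, affinity_sd=0.0)
    return median_polish_summarize(pm)


class TestFitGeneModels:
    def test_noiseless_planted_lfc_recovered_exactly(self, small_annotation):
        gm = _noiseless_dataset(small_annotation, {"coronal": 1.17})
        fit = fit_gene_models(gm, small_annotation, ModelSpec(batch_mode="fixed"))
        lfc, _ = fit.contrast(("coronal", "control"))
        assert np.allclose(lfc, 1.17, atol=1e-8)

    def test_contrast_antisymmetry_exact(self, small_annotation):
        gm = _noiseless_dataset(small_annotation, {"coronal": 0.8, "metopic": 0.3})
        fit = fit_gene_models(gm, small_annotation, ModelSpec())
        ab, _ = fit.contrast(("coronal", "metopic"))
        ba, _ = fit.contrast(("metopic", "coronal"))
        assert np.array_equal(ab.to_numpy(), -ba.to_numpy())

    def test_permuted_labels_give_null_coefficients(self, rng):
        ann = generate_design(
            StudyDesign(n_control=25, n_sagittal=25, n_coronal=25, n_metopic=25, seed=4)
        )
        genes = planted_genes(60, rng, coherence=0.9, lfc_by_contrast={"coronal": 1.0})
        pm = generate_probe_data(ann, genes, seed=5)
        gm = median_polish_summarize(pm)
        shuffled = ann.copy()
        shuffled["group"] = rng.permutation(shuffled["group"].to_numpy())
        fit = fit_gene_models(gm, shuffled, ModelSpec(batch_mode="fixed"))
        lfc, use = fit.contrast(("coronal", "control"))
        se = use * np.sqrt(fit.s2.to_numpy())
        assert np.mean(np.abs(lfc.to_numpy()) < 3 * se) > 0.95

    def test_age_adjustment_removes_confounding(self, rng):
        # cases much older than controls, age effect planted, zero true lfc:
        # the adjusted fit is unbiased while the unadjusted group-mean
        # difference equals the analytic omitted-variable bias
        ann = generate_design(
            StudyDesign(
                n_control=30,
                n_coronal=30,
                n_metopic=2,
                n_sagittal=2,
                age_range_by_group={
                    "control": (1, 24),
                    "coronal": (60, 120),
                    "metopic": (1, 24),
                    "sagittal": (1, 24),
                },
                seed=6,
            )
        )
        beta_age = 0.01
        genes = [
            PlantedGene(
                gene_id=f"G{i}", n_probes=4, coherence=1.0, batch_sd=0.0, sample_sd=0.0
            )
            for i in range(12)
        ]
        pm = generate_probe_data(
            ann, genes, seed=7, beta_age=beta_age, beta_sex=0.0, affinity_sd=0.0
        )
        gm = median_polish_summarize(pm)
        fit = fit_gene_models(gm, ann, ModelSpec(batch_mode="fixed"))
        adjusted, _ = fit.contrast(("coronal", "control"))
        assert np.allclose(adjusted, 0.0, atol=1e-8)

        # analytic bias of the model that omits age
        grp = ann["group"].to_numpy()
        in_model = (grp == "control") | (grp == "coronal")
        age = ann["age_months"].to_numpy(float)[in_model]
        case = (grp[in_model] == "coronal").astype(float)
        expected_bias = beta_age * (age[case == 1].mean() - age[case == 0].mean())
        y = gm.values.to_numpy()[0][in_model]
        naive = y[case == 1].mean() - y[case == 0].mean()
        assert naive == pytest.approx(expected_bias, abs=1e-8)
        assert abs(naive) > 0.3  # the confounding is material

    def test_rank_deficient_design_names_columns(self, small_annotation):
        ann = small_annotation.copy()
        ann["sex"] = 1  # constant -> collinear with the intercept
        gm = _noiseless_dataset(small_annotation, {})
        with pytest.raises(ModelError, match="sex"):
            fit_gene_models(gm, ann, ModelSpec(batch_mode="fixed"))

    def test_gls_and_fixed_batch_modes_agree_on_balanced_design(self, rng):
        ann = generate_design(
            StudyDesign(n_control=24, n_sagittal=24, n_coronal=24, n_metopic=24,
                        n_batches=6, seed=8)
        )
        genes = planted_genes(
            40, rng, coherence=0.9, lfc_by_contrast={"coronal": 0.8}, batch_sd=0.4
        )
        pm = generate_probe_data(ann, genes, seed=9)
        gm = median_polish_summarize(pm)
        gls = fit_gene_models(gm, ann, ModelSpec(batch_mode="gls"))
        fixed = fit_gene_models(gm, ann, ModelSpec(batch_mode="fixed"))
        a, _ = gls.contrast(("coronal", "control"))
        b, _ = fixed.contrast(("coronal", "control"))
        assert gls.rho is not None and gls.rho > 0.05  # batch effect was detected
        assert np.corrcoef(a, b)[0, 1] > 0.99
        assert np.max(np.abs(a - b)) < 0.1


class TestModerateVariances:
    def test_identical_variances_collapse_to_common(self):
        post, d0, s0 = moderate_variances(np.full(50, 0.36), df=12)
        assert d0 == np.inf
        assert s0 == pytest.approx(0.36)
        assert np.allclose(post, 0.36)

    def test_widely_dispersed_variances_barely_shrink(self, rng):
        s2 = np.exp(rng.normal(0.0, 3.0, size=2000))
        post, d0, _ = moderate_variances(s2, df=30)
        assert d0 < 1.0
        rel = np.abs(post - s2) / s2
        assert np.median(rel) < 0.1

    def test_hyperparameter_recovery_from_known_prior(self, rng):
        # s2_g ~ s0^2 * d0 / chisq(d0), observed through chisq(df) sampling
        d0_true, s0_true, df = 4.0, 0.25, 20.0
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=5000)
        s2 = sigma2 * rng.chisquare(df, size=5000) / df
        _post, d0, s0 = moderate_variances(s2, df=df)
        assert d0 == pytest.approx(d0_true, abs=1.0)
        assert s0 == pytest.approx(s0_true, rel=0.10)

    def test_matches_limma_squeezevar(self, rng, tmp_path):
        s2 = (0.3 * rng.chisquare(8, size=300) / 8).round(10)
        path = tmp_path / "s2.txt"
        path.write_text("\n".join(f"{v:.10f}" for v in s2))
        script = (
            "suppressMessages(library(limma));"
            f"x <- scan('{path}', quiet=TRUE);"
            "f <- squeezeVar(x, df=8);"
            "cat(f$df.prior, f$var.prior, f$var.post[1:10], sep='\\n')"
        )
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ref = [float(v) for v in res.stdout.split()]
        post, d0, s0 = moderate_variances(s2, df=8)
        assert d0 == pytest.approx(ref[0], rel=1e-4)
        assert s0 == pytest.approx(ref[1], rel=1e-4)
        assert np.allclose(post[:10], ref[2:], rtol=1e-4)

    def test_requires_enough_genes(self):
        with pytest.raises(DataError):
            moderate_variances(np.ones(5), df=10)


class TestBhAdjust:
    def test_step_up_hand_oracle(self):
        # min over j>=i of p(j)*n/j: all four collapse to 0.04
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_saturated_inputs(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_order_preserved(self, rng):
        p = rng.uniform(size=40)
        adj = bh_adjust(p)
        perm = rng.permutation(40)
        assert np.allclose(adj[perm], bh_adjust(p[perm]))

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])


class TestLfcToPct:
    @pytest.mark.parametrize(
        "lfc,pct",
        [(0.0, 0), (1.0, 100), (-1.0, -100), (0.5, 41), (-0.5, -41)],
    )
    def test_signed_transform(self, lfc, pct):
        assert lfc_to_pct(lfc, rounded=True) == pct

    def test_unrounded_value_is_exact(self):
        assert lfc_to_pct(1.0) == pytest.approx(100.0, abs=1e-12)
        assert lfc_to_pct(-2.0) == pytest.approx(-300.0, abs=1e-12)

    def test_rounding_symmetric_in_sign(self):
        lfc = np.log2(2.5)  # exactly +150%
        assert lfc_to_pct(lfc, rounded=True) == 150
        assert lfc_to_pct(-lfc, rounded=True) == -150

    def test_rejects_nonfinite(self):
        with pytest.raises(DataError):
            lfc_to_pct(np.inf)


class TestDeAnalysis:
    def test_tables_have_consistent_flags(self, small_annotation, rng):
        genes = planted_genes(
            30, rng, coherence=0.9, lfc_by_contrast={"coronal": 1.2}
        )
        pm = generate_probe_data(small_annotation, genes, seed=10)
        gm = median_polish_summarize(pm)
        tables = de_analysis(gm, small_annotation, ModelSpec(batch_mode="fixed"))
        assert set(tables) == {
            "coronal_control", "metopic_control", "sagittal_control", "all_control",
            "coronal_metopic", "coronal_sagittal", "metopic_sagittal",
        }
        t = tables["coronal_control"]
        assert np.all(t["p_adj"] >= t["p"] - 1e-15)
        assert np.array_equal(t["sig"], t["p"] < 0.05)
        assert np.array_equal(t["large"], np.abs(t["pct_change"]) > 50)
        # a strong planted effect at n=12/group is overwhelmingly detected
        assert t["sig"].mean() > 0.8

    def test_parse_contrasts(self):
        assert parse_contrasts("coronal:control, all:control") == (
            ("coronal", "control"),
            ("all", "control"),
        )
        with pytest.raises(ModelError):
            parse_contrasts("coronal")
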