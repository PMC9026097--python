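"""Moderated t, BH adjustment, DEG calling, and PC treatment vectors."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from modscape.diffexpr import (
    DEGCriteria,
    EBayesParams,
    bh_adjust,
    call_degs,
    estimate_prior,
    fc_scatter_stats,
    fit_moderated_t,
    max_abs_fc,
    pc_treatment_vectors,
    read_de_tsv,
    write_de_tsv,
)
from modscape.io import ExpressionMatrix
from modscape.synthio import SimParams, simulate_experiment


def random_matrix(n=200, seed=0, sd=0.3):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.normal(7, 1, size=n)[:, None] + rng.normal(0, sd, size=(n, 6)),
        index=pd.Index([f"g{i}" for i in range(n)], name="gene"),
        columns=list("abcdef"),
    )
    return ExpressionMatrix(df)


class TestModeratedT:
    def test_identical_group_means_give_zero_t(self):
        m = random_matrix(50, seed=1)
        data = m.data.copy()
        data.loc["g0", ["a", "b", "c"]] = [1.0, 2.0, 3.0]
        data.loc["g0", ["d", "e", "f"]] = [3.0, 1.0, 2.0]
        de, _ = fit_moderated_t(ExpressionMatrix(data), ["a", "b", "c"], ["d", "e", "f"])
        assert de.loc["g0", "t"] == pytest.approx(0.0)
        assert de.loc["g0", "p"] == pytest.approx(1.0)

    def test_infinite_prior_df_limit(self):
        m = random_matrix(100, seed=2)
        prior = EBayesParams(d0=1e6, s0_sq=0.09, residual_df=4)
        de, _ = fit_moderated_t(m, ["a", "b", "c"], ["d", "e", "f"], prior=prior)
        expected = de["log2fc"] / (0.3 * np.sqrt(2.0 / 3.0))
        assert np.allclose(de["t"], expected)

    def test_zero_prior_df_equals_ordinary_t(self):
        m = random_matrix(150, seed=3)
        prior = EBayesParams(d0=0.0, s0_sq=1.0, residual_df=4)
        de, _ = fit_moderated_t(m, ["a", "b", "c"], ["d", "e", "f"], prior=prior)
        a = m.data[["a", "b", "c"]].to_numpy()
        b = m.data[["d", "e", "f"]].to_numpy()
        t_ref, p_ref = stats.ttest_ind(a, b, axis=1, equal_var=True)
        assert np.allclose(de["t"], t_ref)
        assert np.allclose(de["p"], p_ref)

    def test_null_p_values_uniform(self, null_experiment):
        _, m, _ = null_experiment
        de, _ = fit_moderated_t(m, m.samples_in_group("IDMF"), m.samples_in_group("CTL"))
        frac = (de["p"] < 0.05).mean()
        assert 0.04 <= frac <= 0.06
        assert stats.kstest(de["p"], "uniform").pvalue > 0.01

    def test_prior_recovery_from_generating_values(self):
        """(d0, s0^2) recovered within 20% when variances follow the prior."""
        rng = np.random.default_rng(11)
        n, d0_true, s0_true, d = 10_000, 5.0, 0.04, 4
        sig2 = d0_true * s0_true / rng.chisquare(d0_true, size=n)
        s2 = sig2 * rng.chisquare(d, size=n) / d
        d0_hat, s0_hat = estimate_prior(s2, d)
        assert abs(d0_hat - d0_true) / d0_true < 0.2
        assert abs(s0_hat - s0_true) / s0_true < 0.2

    def test_all_zero_variance_rejected(self):
        df = pd.DataFrame(
            np.tile([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0]], (5, 1)),
            index=[f"g{i}" for i in range(5)],
            columns=list("abcdef"),
        )
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_moderated_t(ExpressionMatrix(df), ["a", "b", "c"], ["d", "e", "f"])

    def test_matches_limma_oracle(self, tmp_path):
        """Independent oracle: R limma lmFit/eBayes on the same fixture."""
        rng = np.random.default_rng(7)
        n = 300
        sig2 = 4.0 * 0.05 / rng.chisquare(4.0, size=n)
        X = rng.normal(0, 1, size=(n, 6)) * np.sqrt(sig2)[:, None] + 7
        xfile = tmp_path / "x.tsv"
        np.savetxt(xfile, X, delimiter="\t")
        out = tmp_path / "limma.tsv"
        r_code = textwrap.dedent(
            f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.table("{xfile}", sep="\\t"))
            design <- cbind(Intercept=1, Trt=c(1,1,1,0,0,0))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],
                              d0=fit$df.prior, s0=fit$s2.prior)
            write.table(out, "{out}", sep="\\t", row.names=FALSE, quote=FALSE)
            """
        )
        subprocess.run(["Rscript", "-e", r_code], check=True, capture_output=True)
        lim = pd.read_csv(out, sep="\t")
        em = ExpressionMatrix(
            pd.DataFrame(X, index=[f"g{i}" for i in range(n)], columns=list("abcdef"))
        )
        de, prior = fit_moderated_t(em, ["a", "b", "c"], ["d", "e", "f"])
        assert prior.d0 == pytest.approx(lim["d0"][0], rel=1e-6)
        assert prior.s0_sq == pytest.approx(lim["s0"][0], rel=1e-6)
        assert np.allclose(de["t"], lim["t"], atol=1e-10)
        assert np.allclose(de["p"], lim["p"], atol=1e-10)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
        # a second hand case with a genuine gradient
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.9])
        expected = np.array([0.005, 0.02, 0.05125, 0.05125, 0.9])
        assert np.allclose(bh_adjust(p), expected)

    def test_fdr_at_least_p_and_matches_statsmodels(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=500)
        fdr = bh_adjust(p)
        assert (fdr >= p - 1e-12).all()
        from statsmodels.stats.multitest import multipletests

        _, sm_fdr, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(fdr, sm_fdr)

    def test_ties_share_adjusted_value(self):
        fdr = bh_adjust([0.02, 0.02, 0.5])
        assert fdr[0] == fdr[1]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestCallDegs:
    def test_boundary_fc_excluded(self, de_table_factory):
        de = de_table_factory([np.log2(1.25), 1.0], p=[0.04, 0.01])
        de["fdr"] = de["p"]
        up, down = call_degs(de)
        assert de.index[0] not in up  # fc == 1.25 exactly: strict '>'
        assert de.index[1] in up

    def test_down_deg(self, de_table_factory):
        de = de_table_factory([-1.0], p=[0.01])
        de["fdr"] = de["p"]
        up, down = call_degs(de)
        assert list(down) == [de.index[0]]

    def test_planted_recall(self, planted_experiment):
        params, m, truth = planted_experiment
        de, _ = fit_moderated_t(m, m.samples_in_group("IDMF"), m.samples_in_group("CTL"))
        up, down = call_degs(de, DEGCriteria(), "lenient")
        called = set(up) | set(down)
        planted = set(truth.planted_deg_sets["IDMF"])
        recall = len(called & planted) / len(planted)
        assert recall >= 0.9

    def test_stringent_uses_fdr(self, de_table_factory):
        de = de_table_factory([1.0], p=[0.01])
        de["fdr"] = [0.2]
        up, _ = call_degs(de, mode="stringent")
        assert up == []


class TestSummaries:
    def test_max_abs_fc(self, de_table_factory):
        d1 = de_table_factory([0.5, 0.0])
        d2 = de_table_factory([-1.0, 0.0])
        d3 = de_table_factory([0.2, 0.0])
        score = max_abs_fc([d1, d2, d3])
        assert score.iloc[0] == pytest.approx(1.0)
        assert score.iloc[1] == pytest.approx(0.0)
        assert max_abs_fc([d1]).equals(d1["log2fc"].abs().rename("max_abs_log2fc"))

    def test_max_abs_fc_universe_mismatch(self, de_table_factory):
        d1 = de_table_factory([0.5], genes=["a"])
        d2 = de_table_factory([0.5], genes=["b"])
        with pytest.raises(ValueError):
            max_abs_fc([d1, d2])

    def test_pc_arrows_zero_for_identical_treatment(self):
        rng = np.random.default_rng(17)
        base = rng.normal(7, 1, size=(300, 3))
        data = np.concatenate([base, base], axis=1)
        df = pd.DataFrame(
            data,
            index=[f"g{i}" for i in range(300)],
            columns=["CTL-1", "CTL-2", "CTL-3", "TRT-1", "TRT-2", "TRT-3"],
        )
        groups = {c: c.split("-")[0] for c in df.columns}
        arrows = pc_treatment_vectors(ExpressionMatrix(df, groups))
        assert arrows["TRT"]["length"] == pytest.approx(0.0, abs=1e-8)

    def test_planted_strong_effect_gives_longer_arrow(self):
        p = SimParams(
            n_genes=2000,
            effect_fraction_per_group={"MMF": 0.01, "DRF": 0.01, "IDMF": 0.15},
            seed=21,
        )
        m, _ = simulate_experiment(p)
        arrows = pc_treatment_vectors(m)
        assert arrows["IDMF"]["length"] > arrows["MMF"]["length"]

    def test_fc_scatter_identity_and_construction(self, planted_experiment):
        _, m, _ = planted_experiment
        de, _ = fit_moderated_t(m, m.samples_in_group("DRF"), m.samples_in_group("CTL"))
        r, _ = fc_scatter_stats(de, de)
        assert r == pytest.approx(1.0)

    def test_fc_scatter_independent_nulls_near_zero(self):
        # two fully independent null experiments over the same gene universe
        null = {"MMF": 0.0, "DRF": 0.0, "IDMF": 0.0}
        m1, _ = simulate_experiment(
            SimParams(n_genes=5000, effect_fraction_per_group=null, seed=41)
        )
        m2, _ = simulate_experiment(
            SimParams(n_genes=5000, effect_fraction_per_group=null, seed=42)
        )
        de_a, _ = fit_moderated_t(m1, m1.samples_in_group("MMF"), m1.samples_in_group("CTL"))
        de_b, _ = fit_moderated_t(m2, m2.samples_in_group("DRF"), m2.samples_in_group("CTL"))
        r, _ = fc_scatter_stats(de_a, de_b)
        assert abs(r) < 0.05

    def test_fc_scatter_shared_planted_effects_correlate(self):
        # the same genes perturbed in two groups -> strongly correlated FC vectors
        p = SimParams(n_genes=3000, seed=43)
        m, truth = simulate_experiment(p)
        shared = list(truth.planted_deg_sets["IDMF"])
        data = m.data.copy()
        signs = pd.Series(truth.planted_deg_sets["IDMF"])
        for s in m.samples_in_group("MMF"):
            data.loc[shared, s] += signs * p.effect_size_log2
        m2 = ExpressionMatrix(data, m.groups)
        de_a, _ = fit_moderated_t(m2, m2.samples_in_group("MMF"), m2.samples_in_group("CTL"))
        de_b, _ = fit_moderated_t(m2, m2.samples_in_group("IDMF"), m2.samples_in_group("CTL"))
        r, _ = fc_scatter_stats(de_a, de_b)
        assert r > 0.5

    def test_de_table_round_trip(self, tmp_path, planted_experiment):
        _, m, _ = planted_experiment
        de, _ = fit_moderated_t(
            ExpressionMatrix(m.data.iloc[:100], m.groups),
            m.samples_in_group("MMF"),
            m.samples_in_group("CTL"),
        )
        path = tmp_path / "de.tsv"
        write_de_tsv(de, path)
        back = read_de_tsv(path)
        assert np.allclose(back["t"], de["t"])
        assert back["detected"].all()
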