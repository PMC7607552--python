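"""Moderated t, p-value adjustment, DEG calling, Fisher ORA."""

import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import latentsim as ls


def _two_group_data(n_per=10, g=50, effect=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per, g))
    X[n_per:, :5] += effect
    labels = ["A"] * n_per + ["B"] * n_per
    return X, labels


class TestModeratedTTest:
    def test_equal_means_give_zero_logfc(self):
        X = np.zeros((8, 3))
        X[:, 1] = np.tile([0.0, 1.0], 4)  # same values in both groups
        labels = ["A", "A", "B", "B"] * 2
        de = ls.moderated_ttest(X, labels)
        assert de.table.logFC.iloc[1] == pytest.approx(0.0)
        assert de.table.p_value.iloc[1] == pytest.approx(1.0, abs=1e-6)

    def test_d0_zero_reduces_to_ordinary_pooled_t(self):
        """Brute-force oracle: scipy's pooled two-sample t."""
        X, labels = _two_group_data(n_per=7, g=40, effect=0.8, seed=1)
        de = ls.moderated_ttest(X, labels, d0=0)
        g = np.asarray(labels)
        expected = stats.ttest_ind(X[g == "B"], X[g == "A"], equal_var=True)
        np.testing.assert_allclose(de.table.t_moderated, expected.statistic,
                                   atol=1e-10)
        np.testing.assert_allclose(de.table.t_moderated, de.table.t_ordinary,
                                   atol=1e-10)
        np.testing.assert_allclose(de.table.p_value, expected.pvalue, atol=1e-10)

    def test_d0_infinite_orders_by_logfc(self):
        X, labels = _two_group_data(n_per=6, g=30, effect=0.5, seed=2)
        de = ls.moderated_ttest(X, labels, d0=np.inf)
        order_t = np.argsort(np.abs(de.table.t_moderated.to_numpy()))
        order_fc = np.argsort(np.abs(de.table.logFC.to_numpy()))
        np.testing.assert_array_equal(order_t, order_fc)

    def test_small_group_rejected(self):
        X = np.random.default_rng(0).normal(size=(3, 5))
        with pytest.raises(ValueError, match=">= 2"):
            ls.moderated_ttest(X, ["A", "B", "B"])

    def test_three_levels_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 5))
        with pytest.raises(ValueError, match="2 groups"):
            ls.moderated_ttest(X, ["A", "A", "B", "B", "C", "C"])

    def test_zero_variance_gene_handled(self):
        X, labels = _two_group_data(n_per=5, g=10, seed=3)
        X[:, 0] = 0.7  # identical everywhere: no variance, no difference
        de = ls.moderated_ttest(X, labels)
        assert np.isfinite(de.table.t_moderated.iloc[0])
        assert de.table.logFC.iloc[0] == 0.0

    def test_null_pvalues_uniform(self):
        """On null data (no group effect) moderated p-values are ~U(0,1):
        KS at alpha=0.01 accepted in a majority of 10 seeds."""
        accepted = 0
        for seed in range(10):
            X, labels = _two_group_data(n_per=25, g=1000, effect=0.0, seed=seed)
            de = ls.moderated_ttest(X, labels)
            if stats.kstest(de.table.p_value, "uniform").pvalue > 0.01:
                accepted += 1
        assert accepted > 5

    def test_matches_limma_ebayes(self, tmp_path):
        """Independent oracle: limma lmFit + eBayes on the same matrix."""
        X, labels = _two_group_data(n_per=8, g=60, effect=1.0, seed=4)
        # per-gene scale heterogeneity so the variance prior is well identified
        X = X * np.random.default_rng(7).lognormal(0, 0.5, size=X.shape[1])
        de = ls.moderated_ttest(X, labels)
        mat = tmp_path / "m.tsv"
        np.savetxt(mat, X.T, delimiter="\t")  # genes x samples
        groups = ",".join("1" if l == "B" else "0" for l in labels)
        script = tmp_path / "eb.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.table("{mat}", sep="\\t"))
            design <- cbind(Intercept=1, Group=c({groups}))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[, "Group"], p=fit$p.value[, "Group"],
                              lfc=fit$coefficients[, "Group"])
            write.table(out, "{tmp_path / 'out.tsv'}", sep="\\t", row.names=FALSE)
            cat(fit$df.prior, fit$s2.prior, sep="\\n")
        """))
        proc = subprocess.run(["Rscript", str(script)], check=True,
                              capture_output=True, text=True)
        d0_r, s02_r = (float(v) for v in proc.stdout.split())
        import pandas as pd
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        assert de.d0 == pytest.approx(d0_r, rel=1e-4)
        assert de.s0_squared == pytest.approx(s02_r, rel=1e-4)
        np.testing.assert_allclose(de.table.logFC, ref.lfc, atol=1e-8)
        np.testing.assert_allclose(de.table.t_moderated, ref.t, rtol=1e-5)
        np.testing.assert_allclose(de.table.p_value, ref.p, rtol=1e-4)


class TestAdjustPvalues:
    def test_bh_hand_check(self):
        np.testing.assert_allclose(
            ls.adjust_pvalues([0.01, 0.02, 0.03], "BH"), [0.03, 0.03, 0.03])

    def test_bonferroni_with_explicit_m(self):
        np.testing.assert_allclose(ls.adjust_pvalues([0.5], "bonferroni", m=1), [0.5])
        np.testing.assert_allclose(ls.adjust_pvalues([0.01], "bonferroni", m=100), [1.0])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50),
           st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_bh_equals_stepup_definition(self, p, _seed):
        p = np.asarray(p)
        got = ls.adjust_pvalues(p, "BH")
        m = p.size
        order = np.argsort(p, kind="stable")
        expected = np.empty(m)
        for rank_pos, i in enumerate(order):
            js = np.arange(rank_pos, m)
            expected[i] = min(1.0, (m * p[order][js] / (js + 1)).min())
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        p = np.random.default_rng(0).random(200)
        np.testing.assert_allclose(ls.adjust_pvalues(p, "BH"),
                                   multipletests(p, method="fdr_bh")[1], atol=1e-12)
        np.testing.assert_allclose(ls.adjust_pvalues(p, "bonferroni"),
                                   multipletests(p, method="bonferroni")[1], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ls.adjust_pvalues([0.5, 1.2], "BH")


class TestCallDegs:
    def test_fdr_fc_requires_both_conditions(self):
        X, labels = _two_group_data(n_per=10, g=20, effect=0.4, seed=5)
        de = ls.moderated_ttest(X, labels)
        # significant p but small fold change must not be called
        de.table.loc[:, "p_value"] = 1e-6
        de.table.loc[:, "logFC"] = 0.5
        assert ls.call_degs(de, scheme="fdr_fc") == set()
        de.table.loc[0, "logFC"] = 1.5
        assert ls.call_degs(de, scheme="fdr_fc") == {de.table.gene.iloc[0]}

    def test_unknown_scheme_rejected(self):
        X, labels = _two_group_data(seed=6)
        de = ls.moderated_ttest(X, labels)
        with pytest.raises(ValueError, match="scheme"):
            ls.call_degs(de, scheme="fancy")

    def test_recall_and_fdr_on_synthetic_truth(self):
        """30 large-effect genes: recall >= 0.8 at empirical FDR <= 0.1,
        aggregated over 10 seeds (Bonferroni calling)."""
        tp = fp = fn = 0
        for seed in range(10):
            comp, truth = ls.generate_compendium(
                ls.SyntheticSpec(n_experiments=1, samples_per_experiment=100,
                                 group_effect=3.0, seed=seed))
            labels = [truth.group_of[s] for s in comp.sample_ids]
            de = ls.moderated_ttest(comp, labels)
            degs = ls.call_degs(de, scheme="bonferroni")
            true_set = set(truth.differential_genes)
            tp += len(degs & true_set)
            fp += len(degs - true_set)
            fn += len(true_set - degs)
        assert tp / (tp + fn) >= 0.8
        assert fp / max(tp + fp, 1) <= 0.1

    def test_null_data_yields_no_degs(self):
        counts = []
        for seed in range(5):
            comp, truth = ls.generate_compendium(
                ls.SyntheticSpec(n_experiments=1, samples_per_experiment=60,
                                 group_effect=0.0, seed=100 + seed))
            labels = [truth.group_of[s] for s in comp.sample_ids]
            de = ls.moderated_ttest(comp, labels)
            counts.append(len(ls.call_degs(de, scheme="bonferroni")))
        assert np.median(counts) == 0


class TestOraFisher:
    def test_matches_enumerated_hypergeometric_tail(self):
        """Background 100, 10 DEGs, set of 10 with 5 DEG members: p equals
        the enumerated tail P(X >= 5)."""
        background = [f"g{i}" for i in range(100)]
        degs = set(background[:10])
        gene_set = background[5:15]  # overlap of 5
        res = ls.ora_fisher(degs, {"s": gene_set}, background)
        p = res.table.set_index("set").loc["s", "p"]
        expected = sum(stats.hypergeom.pmf(x, 100, 10, 10) for x in range(5, 11))
        assert p == pytest.approx(expected, abs=1e-12)
        fisher = stats.fisher_exact([[5, 5], [5, 85]], alternative="greater")[1]
        assert p == pytest.approx(fisher, abs=1e-12)

    def test_disjoint_set_never_beats_overlapping(self):
        background = [f"g{i}" for i in range(50)]
        degs = set(background[:8])
        res = ls.ora_fisher(degs, {"hit": background[:10], "miss": background[20:30]},
                            background)
        t = res.table.set_index("set")
        assert t.loc["miss", "p"] >= t.loc["hit", "p"]

    def test_degenerate_all_degs(self):
        background = [f"g{i}" for i in range(20)]
        res = ls.ora_fisher(set(background), {"s": background[:5]}, background)
        assert res.table.p.iloc[0] == pytest.approx(1.0)
        assert res.table.overlap.iloc[0] == 5

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ls.ora_fisher(set(), {}, set())

    def test_degs_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            ls.ora_fisher({"x"}, {}, {"a", "b"})

    def test_enriched_flag_threshold(self):
        background = [f"g{i}" for i in range(200)]
        degs = set(background[:20])
        sets = {"strong": background[:20],
                **{f"r{i}": background[50 + 10 * i:60 + 10 * i] for i in range(5)}}
        res = ls.ora_fisher(degs, sets, background)
        t = res.table.set_index("set")
        assert bool(t.loc["strong", "enriched"])
        assert (t.loc[t.index != "strong", "q"] >= 0.02).all()


class TestExperimentVsSampleLevelDegs:
    def test_experiment_level_preserves_de_signal(self, strong_vae, strong_comp,
                                                  strong_truth):
        """Over 20 simulated experiments from a strong two-group template,
        experiment-level simulation yields more Bonferroni DEGs than
        sample-level simulation with random group assignment (median 0)."""
        from conftest import template_group_labels
        n_exp, n_smp = [], []
        for seed in range(20):
            sim = ls.simulate_experiments(strong_vae, strong_comp, 1, seed=seed)
            labels = template_group_labels(sim.records[0], strong_truth)
            de = ls.moderated_ttest(sim.values, labels)
            n_exp.append(len(ls.call_degs(de, scheme="bonferroni")))
            rnd = ls.simulate_samples(strong_vae, len(labels), seed=1000 + seed)
            de2 = ls.moderated_ttest(rnd.values, labels)
            n_smp.append(len(ls.call_degs(de2, scheme="bonferroni")))
        assert np.median(n_exp) > np.median(n_smp)
        assert np.median(n_smp) == 0
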