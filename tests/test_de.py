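"""Differential-expression stage: size factors, dispersion, Wald/BH, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mbwsim.de import (
    bh_adjust,
    estimate_dispersion,
    pathway_summary,
    regulator_table,
    rpkm,
    segregation_binomial,
    size_factors,
    wald_test,
)
from mbwsim.transcriptome import (
    EffectPreset,
    PanelConfig,
    build_panel,
    generate_counts,
)


def groups_3v3():
    idx = [f"wt_{j}" for j in (1, 2, 3)] + [f"rnai_{j}" for j in (1, 2, 3)]
    return pd.Series(["wild_type"] * 3 + ["rnai"] * 3, index=idx, name="group")


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 5], "s2": [10, 20, 5]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_sample_gets_doubled_factor(self):
        rng = np.random.default_rng(2)
        base = rng.integers(5, 500, size=50)
        counts = pd.DataFrame({"s1": base, "s2": 2 * base})
        f = size_factors(counts)
        assert f["s2"] / f["s1"] == pytest.approx(2.0)

    def test_single_gene_matrix(self):
        counts = pd.DataFrame({"s1": [10], "s2": [40]})
        f = size_factors(counts)
        assert f["s2"] / f["s1"] == pytest.approx(4.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(rng.integers(1, 1000, size=(200, 4)),
                              columns=list("abcd"))
        f0 = size_factors(counts)
        scaled = counts.copy()
        scaled["c"] = scaled["c"] * 7
        f1 = size_factors(scaled)
        # factors are defined relative to the geometric-mean reference, so
        # equivariance shows up in the between-sample ratios
        assert f1["c"] / f1["a"] == pytest.approx(7.0 * f0["c"] / f0["a"])
        assert f1["b"] / f1["a"] == pytest.approx(f0["b"] / f0["a"])

    def test_fallback_to_totals_when_no_common_gene(self, caplog):
        counts = pd.DataFrame({"s1": [10, 0], "s2": [0, 10]})
        with caplog.at_level("WARNING"):
            f = size_factors(counts)
        assert "falling back" in caplog.text
        assert np.allclose(f, 1.0)  # equal totals


class TestEstimateDispersion:
    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.poisson(500.0, size=(300, 200)))
        groups = pd.Series(["wild_type"] * 100 + ["rnai"] * 100,
                           index=counts.columns)
        alpha = estimate_dispersion(counts, groups)
        assert float(np.median(alpha)) <= 0.01

    def test_constant_counts_give_zero_raw_dispersion(self):
        counts = pd.DataFrame({"s1": [7, 9], "s2": [7, 9], "s3": [7, 9],
                               "s4": [7, 9], "s5": [7, 9], "s6": [7, 9]})
        counts.columns = groups_3v3().index
        alpha = estimate_dispersion(counts, groups_3v3(), shrinkage_weight=0.0)
        assert (alpha == 0).all()

    def test_nb_dispersion_recovery(self):
        # alpha = 0.2 truth, 50 per group: shrunken median inside [0.1, 0.3]
        truth = 0.2
        rng = np.random.default_rng(12)
        size = 1 / truth
        mu = 300.0
        counts = pd.DataFrame(
            rng.negative_binomial(size, size / (size + mu), size=(500, 100)))
        groups = pd.Series(["wild_type"] * 50 + ["rnai"] * 50, index=counts.columns)
        alpha = estimate_dispersion(counts, groups)
        assert 0.1 <= float(np.median(alpha)) <= 0.3

    def test_all_zero_gene_excluded(self):
        counts = pd.DataFrame(np.vstack([np.zeros(6), np.full(6, 50)]),
                              columns=groups_3v3().index).astype(int)
        alpha = estimate_dispersion(counts, groups_3v3())
        assert np.isnan(alpha.iloc[0])
        assert np.isfinite(alpha.iloc[1])


class TestBenjaminiHochberg:
    def brute_force(self, p):
        # literal step-up: padj_(i) = min_{j>=i} m p_(j) / j
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        for rank_idx in range(m):
            candidates = [p[order[j]] * m / (j + 1) for j in range(rank_idx, m)]
            adj[order[rank_idx]] = min(1.0, min(candidates))
        return adj

    def test_worked_example(self):
        padj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(padj, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(100)
        for _ in range(1000):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), self.brute_force(p), atol=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(101)
        p = rng.uniform(0, 1, size=500)
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), expected, atol=1e-12)

    def test_nan_passthrough(self):
        padj = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(padj[1])
        assert padj[0] == pytest.approx(0.02)

    def test_monotone_in_p_order(self):
        rng = np.random.default_rng(102)
        p = rng.uniform(0, 1, 200)
        padj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-12).all()


class TestWaldTest:
    def test_identical_groups_have_zero_log2fc(self):
        rng = np.random.default_rng(3)
        col = rng.integers(10, 1000, size=100)
        counts = pd.DataFrame(np.tile(col[:, None], (1, 6)),
                              columns=groups_3v3().index)
        de = wald_test(counts, groups_3v3())
        assert np.allclose(de["log2FC"], 0.0)

    def test_scale_invariance_of_log2fc(self, fig5c_panel):
        cm = generate_counts(fig5c_panel, seed=9)
        de0 = wald_test(cm.counts, cm.groups)
        scaled = cm.counts.copy()
        scaled.iloc[:, 2] = scaled.iloc[:, 2] * 5
        de1 = wald_test(scaled, cm.groups)
        # exact for genes expressed in both groups (no pseudocount involved)
        expressed = (cm.counts.T.groupby(cm.groups).sum() > 0).all(axis=0)
        assert np.allclose(de0.loc[expressed, "log2FC"],
                           de1.loc[expressed, "log2FC"], atol=1e-10)

    def test_null_simulation_controls_fdr(self):
        panel = build_panel(PanelConfig(effects=EffectPreset.null()))
        fractions = []
        for seed in range(20):
            cm = generate_counts(panel, n_per_group=3, alpha=0.05, seed=seed)
            de = wald_test(cm.counts, cm.groups)
            fractions.append(de["significant"].mean())
        assert float(np.mean(fractions)) <= 0.05

    def test_all_zero_gene_flagged_not_tested(self):
        counts = pd.DataFrame(
            np.vstack([np.zeros(6), np.full(6, 200), np.full(6, 80)]),
            columns=groups_3v3().index).astype(int)
        de = wald_test(counts, groups_3v3())
        assert np.isnan(de["pvalue"].iloc[0])
        assert not de["significant"].iloc[0]

    def test_significance_rule(self, fig5c_panel):
        cm = generate_counts(fig5c_panel, seed=2)
        de = wald_test(cm.counts, cm.groups)
        called = de["significant"]
        rule = (de["log2FC"].abs() >= 1.0) & (de["padj"] < 0.05)
        assert (called == rule.fillna(False)).all()
        assert (de["padj"].dropna() >= de["pvalue"].dropna() - 1e-15).all()

    def test_planted_fold_change_recovery(self, fig5c_panel):
        # planted folds {1.5, 2.5, 3, 4, 19, 29}: median recovered within 20%
        probes = {"CHS_1": 1.5, "REG_bHLH1": 2.5, "REG_MYB5a": 3.0, "DFR_1": 4.0,
                  "REG_RTO1": 19.0, "REG_RTO2": 29.0}
        assert set(probes) <= set(fig5c_panel.gene_ids)
        recovered = {g: [] for g in probes}
        for seed in range(50):
            cm = generate_counts(fig5c_panel, n_per_group=3, alpha=0.05, seed=seed)
            de = wald_test(cm.counts, cm.groups)
            for g in probes:
                recovered[g].append(2.0 ** abs(de.loc[g, "log2FC"]))
        for g, truth in probes.items():
            med = float(np.median(recovered[g]))
            assert med == pytest.approx(truth, rel=0.2), g


class TestRpkm:
    def test_formula_identity(self):
        counts = pd.DataFrame({"s": [1000]}, index=["g"])
        # pad the library to 1e7 total reads
        counts.loc["rest"] = [10_000_000 - 1000]
        lengths = pd.Series({"g": 2000.0, "rest": 1000.0})
        out = rpkm(counts, lengths)
        assert out.loc["g", "s"] == pytest.approx(50.0)

    def test_zero_count_zero_rpkm(self):
        counts = pd.DataFrame({"s": [0, 100]}, index=["a", "b"])
        lengths = pd.Series({"a": 1000.0, "b": 1000.0})
        assert rpkm(counts, lengths).loc["a", "s"] == 0.0

    def test_depth_homogeneity(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame({"s1": rng.integers(1, 100, 20)})
        counts["s2"] = counts["s1"] * 2  # doubled depth at doubled counts
        lengths = pd.Series(np.full(20, 1500.0), index=counts.index)
        out = rpkm(counts, lengths)
        assert np.allclose(out["s1"], out["s2"])

    def test_zero_depth_rejected(self):
        counts = pd.DataFrame({"s": [0, 0]})
        lengths = pd.Series([100.0, 100.0])
        with pytest.raises(ValueError, match="zero-depth"):
            rpkm(counts, lengths)


@pytest.fixture(scope="module")
def fig5c_de(fig5c_panel):
    cm = generate_counts(fig5c_panel, n_per_group=3, alpha=0.05, seed=1)
    return wald_test(cm.counts, cm.groups)


class TestStudySummaries:
    def test_lbg_coordinate_downregulation(self, fig5c_de, fig5c_panel):
        summary = pathway_summary(fig5c_de, fig5c_panel).set_index("enzyme_class")
        for cls_name in ("DFR", "ANS", "UF3GT"):
            assert summary.loc[cls_name, "all_copies_down"]
            assert summary.loc[cls_name, "dichotomy_call"] == "LBG-like coordinate-down"

    def test_ebg_mixed_response(self, fig5c_de, fig5c_panel):
        summary = pathway_summary(fig5c_de, fig5c_panel).set_index("enzyme_class")
        for cls_name in ("CHS", "CHI", "F3H"):
            assert summary.loc[cls_name, "dichotomy_call"] == "EBG-like mixed"

    def test_null_panel_has_no_lbg_like_class(self):
        panel = build_panel(PanelConfig(effects=EffectPreset.null()))
        cm = generate_counts(panel, seed=0)
        de = wald_test(cm.counts, cm.groups)
        summary = pathway_summary(de, panel)
        assert not summary["all_copies_down"].any()

    def test_regulator_table_ordering(self, fig5c_de, fig5c_panel):
        table = regulator_table(fig5c_de, fig5c_panel).set_index("subrole")
        activators = [table.loc[s, "fold_down"] for s in ("MYB5a", "bHLH1", "bHLH2")]
        repressors = [table.loc[s, "fold_down"] for s in ("RTO1", "RTO2")]
        assert min(repressors) > max(activators)

    def test_null_regulator_folds_near_one(self):
        panel = build_panel(PanelConfig(effects=EffectPreset.null()))
        cm = generate_counts(panel, seed=3)
        de = wald_test(cm.counts, cm.groups)
        table = regulator_table(de, panel)
        assert np.allclose(table["fold_down"], 1.0, atol=0.5)


class TestSegregation:
    def test_three_to_one_modal_count(self):
        result = segregation_binomial(8, 6, ratio=(3, 1))
        assert result.modal_count == 6
        assert result.expected_count == pytest.approx(6.0)

    def test_observed_modal_outcome_has_p_one(self):
        # 6 of 8 is the most likely 3:1 outcome, so every outcome's pmf
        # is <= pmf(6) and the minimum-likelihood two-sided p sums to 1
        result = segregation_binomial(8, 6, ratio=(3, 1))
        assert result.p_two_sided == pytest.approx(1.0)

    def test_all_dominant_one_to_one(self):
        result = segregation_binomial(4, 4, ratio=(1, 1))
        assert result.pmf[4] == pytest.approx(0.0625)

    def test_matches_exact_binomial_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            n = int(rng.integers(2, 30))
            k = int(rng.integers(0, n + 1))
            r = int(rng.integers(1, 5))
            ours = segregation_binomial(n, k, ratio=(r, 1)).p_two_sided
            oracle = stats.binomtest(k, n, r / (r + 1), alternative="two-sided").pvalue
            assert ours == pytest.approx(oracle, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            segregation_binomial(0, 0)
        with pytest.raises(ValueError):
            segregation_binomial(8, 9)
        with pytest.raises(ValueError):
            segregation_binomial(8, 6, ratio=(3, 2))
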