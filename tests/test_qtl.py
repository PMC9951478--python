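import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import tqtlkit as tk
from tqtlkit.qtl import cis_window_variants


class TestGrm:
    def test_identical_samples_share_diagonal_entry(self, geno_factory):
        dos = np.array([[0, 1, 2], [0, 1, 2], [2, 1, 0], [1, 2, 0]], dtype=float)
        grm = tk.compute_grm(geno_factory(dos))
        assert grm[0, 1] == pytest.approx(grm[0, 0])
        assert grm[0, 1] == pytest.approx(grm[1, 1])

    def test_diagonal_mean_is_one(self, small_sim):
        grm = tk.compute_grm(small_sim.genotypes)
        assert np.diag(grm).mean() == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(grm, grm.T, atol=1e-12)

    def test_hand_computed_example(self, geno_factory):
        dos = np.array(
            [[0, 2, 1], [1, 1, 1], [2, 0, 0], [1, 1, 2]], dtype=float
        )
        x = (dos - dos.mean(axis=0)) / dos.std(axis=0)
        expected = x @ x.T / 3
        np.testing.assert_allclose(tk.compute_grm(geno_factory(dos)), expected,
                                   atol=1e-12)

    def test_all_monomorphic_rejected(self, geno_factory):
        with pytest.raises(ValueError, match="polymorphic"):
            tk.compute_grm(geno_factory(np.ones((4, 3))))


class TestCisWindow:
    def test_gene_window_from_tss(self, geno_factory, pheno_factory):
        geno = geno_factory(np.zeros((4, 5)), positions=[100, 5000, 10_000,
                                                         110_001, 120_000])
        pm = pheno_factory(np.zeros((1, 4)), geno.sample_ids, tss=[10_000])
        idx = cis_window_variants(geno, pm.features.iloc[0], 100_000)
        assert list(idx) == [0, 1, 2]  # 110_001 is 100_001 bp away

    def test_intron_distance_zero_inside_interval(self, geno_factory):
        geno = geno_factory(np.zeros((2, 3)), positions=[500, 1500, 3000])
        feature = pd.Series(
            {"id": "c:i", "kind": "intron", "chrom": "chr1",
             "start": 1000, "end": 2000}
        )
        idx = cis_window_variants(geno, feature, 400)
        # 1500 inside (dist 0); 500 at dist 501; 3000 at dist 1000
        assert list(idx) == [1]


class TestOlsScan:
    def test_noiseless_phenotype_recovers_beta_two(self, geno_factory,
                                                   pheno_factory):
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.4, size=(50, 6)).astype(float)
        geno = geno_factory(dos)
        y = 2.0 * dos[:, 2]
        pm = pheno_factory(y[None, :], geno.sample_ids, tss=[3000])
        recs = tk.cis_scan(geno, pm, None, maf_min=0.0)
        hit = recs.set_index("variant_id").loc["v2"]
        assert hit["beta"] == pytest.approx(2.0, abs=1e-10)
        assert hit["p"] < 1e-200

    def test_matches_statsmodels_on_fuzzed_instances(self, geno_factory,
                                                     pheno_factory):
        rng = np.random.default_rng(42)
        n = 60
        for trial in range(20):
            n_var = int(rng.integers(2, 8))
            dos = rng.binomial(2, rng.uniform(0.2, 0.8), size=(n, n_var)).astype(float)
            cov_data = rng.normal(size=(n, 2))
            y = rng.normal(size=n) + dos[:, 0] * rng.normal() \
                + cov_data @ rng.normal(size=2)
            geno = geno_factory(dos)
            cov = tk.CovariateMatrix(
                pd.DataFrame(cov_data, index=geno.sample_ids,
                             columns=["c1", "c2"])
            )
            pm = pheno_factory(y[None, :], geno.sample_ids, tss=[1000])
            recs = tk.cis_scan(geno, pm, cov, maf_min=0.0).set_index("variant_id")
            for j in range(n_var):
                if dos[:, j].std() == 0:
                    continue
                design = sm.add_constant(np.column_stack([cov_data, dos[:, j]]))
                fit = sm.OLS(y, design).fit()
                row = recs.loc[f"v{j}"]
                assert row["beta"] == pytest.approx(fit.params[-1], abs=1e-8)
                assert row["se"] == pytest.approx(fit.bse[-1], abs=1e-8)
                assert row["p"] == pytest.approx(fit.pvalues[-1], abs=1e-8)

    def test_maf_filter_is_strict_and_pooled(self, geno_factory, pheno_factory):
        dos = np.zeros((20, 2))
        dos[:2, 0] = 1.0           # alt freq 0.05 -> excluded at maf_min=0.05
        dos[:8, 1] = 1.0           # alt freq 0.2 -> kept
        geno = geno_factory(dos)
        pm = pheno_factory(np.random.default_rng(1).normal(size=(1, 20)),
                           geno.sample_ids, tss=[1500])
        recs = tk.cis_scan(geno, pm, None, maf_min=0.05)
        assert list(recs["variant_id"]) == ["v1"]

    def test_missing_dosages_mean_imputed(self, geno_factory, pheno_factory):
        rng = np.random.default_rng(2)
        dos = rng.binomial(2, 0.5, size=(40, 1)).astype(float)
        y = dos[:, 0] + rng.normal(0, 0.1, 40)
        dos_missing = dos.copy()
        dos_missing[:5, 0] = np.nan
        geno = geno_factory(dos_missing)
        pm = pheno_factory(y[None, :], geno.sample_ids)
        recs = tk.cis_scan(geno, pm, None, maf_min=0.0)
        imputed = dos_missing[:, 0].copy()
        imputed[:5] = np.nanmean(dos_missing[:, 0])
        fit = sm.OLS(y, sm.add_constant(imputed)).fit()
        assert recs.loc[0, "beta"] == pytest.approx(fit.params[-1], abs=1e-10)


class TestLmmScan:
    def test_identity_grm_reduces_to_ols(self, geno_factory, pheno_factory):
        rng = np.random.default_rng(11)
        n = 45
        dos = rng.binomial(2, 0.4, size=(n, 5)).astype(float)
        cov_data = rng.normal(size=(n, 1))
        y = dos[:, 1] * 0.6 + cov_data[:, 0] + rng.normal(size=n)
        geno = geno_factory(dos)
        cov = tk.CovariateMatrix(
            pd.DataFrame(cov_data, index=geno.sample_ids, columns=["c1"])
        )
        pm = pheno_factory(y[None, :], geno.sample_ids, tss=[3000])
        ols = tk.cis_scan(geno, pm, cov, maf_min=0.0, model="ols")
        lmm = tk.cis_scan(geno, pm, cov, maf_min=0.0, model="lmm",
                          grm=np.eye(n))
        merged = ols.merge(lmm, on="variant_id", suffixes=("_ols", "_lmm"))
        np.testing.assert_allclose(merged["p_ols"], merged["p_lmm"], atol=1e-6)
        np.testing.assert_allclose(merged["beta_ols"], merged["beta_lmm"],
                                   atol=1e-6)

    def test_lmm_runs_with_structured_grm(self, small_sim):
        geno = small_sim.genotypes
        qn = tk.two_stage_quantile_normalize(small_sim.expression.phenotypes)
        one_gene = qn.subset([qn.features["id"].iloc[0]])
        recs = tk.cis_scan(geno, one_gene, None, model="lmm")
        assert len(recs) > 0
        assert recs["p"].between(0, 1).all()


class TestHierarchicalFdr:
    def _records(self, pvals_by_feature):
        rows = []
        for fid, ps in pvals_by_feature.items():
            for i, p in enumerate(ps):
                rows.append({"feature_id": fid, "variant_id": f"{fid}_v{i + 1}",
                             "p": p})
        return pd.DataFrame(rows)

    def test_worked_example_with_bh_step_up(self):
        recs = self._records(
            {"G1": [0.0005, 0.04, 0.8], "G2": [0.3, 0.6], "G3": [0.004, 0.01]}
        )
        feat, out = tk.hierarchical_fdr(recs, alpha=0.05)
        feat = feat.set_index("feature_id")
        assert feat.loc["G1", "min_P_prime"] == pytest.approx(0.0015)
        assert feat.loc["G2", "min_P_prime"] == pytest.approx(0.6)
        assert feat.loc["G3", "min_P_prime"] == pytest.approx(0.008)
        assert feat.loc["G1", "P_double_prime"] == pytest.approx(0.0045)
        assert feat.loc["G2", "P_double_prime"] == pytest.approx(0.6)
        assert feat.loc["G3", "P_double_prime"] == pytest.approx(0.012)
        assert set(feat.index[feat["significant"]]) == {"G1", "G3"}
        assert feat["snp_threshold"].iloc[0] == pytest.approx(0.008)
        sig = out.loc[out["significant"], "variant_id"]
        assert set(sig) == {"G1_v1", "G3_v1"}

    def test_all_ones_nothing_significant(self):
        recs = self._records({"G1": [1.0, 1.0], "G2": [1.0]})
        feat, out = tk.hierarchical_fdr(recs)
        assert not feat["significant"].any()
        assert not out["significant"].any()

    def test_single_feature_single_variant(self):
        recs = self._records({"G1": [0.01]})
        feat, out = tk.hierarchical_fdr(recs, alpha=0.05)
        assert feat.loc[0, "min_P_prime"] == pytest.approx(0.01)
        assert feat.loc[0, "P_double_prime"] == pytest.approx(0.01)
        assert bool(feat.loc[0, "significant"])
        assert feat.loc[0, "snp_threshold"] == pytest.approx(0.01)
        assert bool(out.loc[0, "significant"])

    def test_every_significant_feature_has_a_significant_variant(self):
        rng = np.random.default_rng(3)
        pvals = {
            f"G{i}": rng.uniform(1e-6, 1.0, size=rng.integers(2, 12))
            for i in range(30)
        }
        feat, out = tk.hierarchical_fdr(self._records(pvals))
        sig_features = set(feat.loc[feat["significant"], "feature_id"])
        with_sig_variant = set(out.loc[out["significant"], "feature_id"])
        assert sig_features <= with_sig_variant

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            tk.hierarchical_fdr(pd.DataFrame(columns=["feature_id", "p"]))


class TestConditionalScan:
    def _simulated_gene(self, seed, beta=1.2):
        rng = np.random.default_rng(seed)
        n = 120
        dos = rng.binomial(2, 0.4, size=(n, 12)).astype(float)
        y = beta * dos[:, 4] + rng.normal(size=n)
        return dos, y

    def test_conditioning_on_causal_variant_removes_signal(self, geno_factory,
                                                           pheno_factory):
        dos, y = self._simulated_gene(1)
        geno = geno_factory(dos)
        pm = pheno_factory(y[None, :], geno.sample_ids, tss=[6000])
        flags, recs = tk.conditional_scan(
            geno, pm, None, {"g0": ["v4"]}, original_threshold=1e-4,
            maf_min=0.0,
        )
        assert not flags["g0"]

    def test_conditioning_on_unlinked_variant_keeps_signal(self, geno_factory,
                                                           pheno_factory):
        dos, y = self._simulated_gene(2)
        geno = geno_factory(dos)
        pm = pheno_factory(y[None, :], geno.sample_ids, tss=[6000])
        flags, _ = tk.conditional_scan(
            geno, pm, None, {"g0": ["v11"]}, original_threshold=1e-4,
            maf_min=0.0,
        )
        assert flags["g0"]

    def test_empty_conditioning_matches_unconditioned_scan(self, geno_factory,
                                                           pheno_factory):
        dos, y = self._simulated_gene(3)
        geno = geno_factory(dos)
        pm = pheno_factory(y[None, :], geno.sample_ids, tss=[6000])
        plain = tk.cis_scan(geno, pm, None, maf_min=0.0)
        _, cond = tk.conditional_scan(geno, pm, None, {},
                                      original_threshold=1e-4, maf_min=0.0)
        np.testing.assert_allclose(cond["p"].to_numpy(), plain["p"].to_numpy(),
                                   atol=1e-10)

    def test_absent_conditioning_variant_dropped(self, geno_factory,
                                                 pheno_factory):
        dos, y = self._simulated_gene(4)
        geno = geno_factory(dos)
        pm = pheno_factory(y[None, :], geno.sample_ids, tss=[6000])
        flags, _ = tk.conditional_scan(
            geno, pm, None, {"g0": ["not_a_variant"]},
            original_threshold=1e-4, maf_min=0.0,
        )
        assert flags["g0"]  # nothing actually conditioned out
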