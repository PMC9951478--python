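import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tqtlkit as tk
from tqtlkit.normalize import rank_to_normal


def brute_force_expression_keep(counts, tpm, t):
    keep = []
    for fid in counts.index:
        n_with_reads = int((counts.loc[fid] > t.expr_min_reads).sum())
        if n_with_reads >= t.expr_min_individuals and tpm.loc[fid].mean() > t.expr_min_mean_tpm:
            keep.append(fid)
    return keep


def brute_force_splicing_keep(jc, cmap, t):
    keep = []
    totals = {}
    for clu in cmap.unique():
        totals[clu] = jc.loc[cmap[cmap == clu].index].sum(axis=0)
    for iid in jc.index:
        tot = totals[cmap[iid]]
        cluster_ok = (
            int((tot >= t.cluster_min_reads).sum()) >= t.cluster_min_individuals
            and int((tot == 0).sum()) < t.cluster_max_zero_individuals
        )
        intron_ok = int((jc.loc[iid] == 0).sum()) <= t.intron_max_zero_individuals
        if cluster_ok and intron_ok:
            keep.append(iid)
    return keep


class TestExpressionFilter:
    def _mats(self, counts):
        counts = pd.DataFrame(counts)
        tpm = counts / 10.0
        return counts, tpm

    def test_nineteen_supporting_samples_is_too_few(self):
        counts = pd.DataFrame(
            np.where(np.arange(162) < 19, 100, 0)[None, :], index=["g1"]
        )
        tpm = pd.DataFrame(np.full((1, 162), 2.0), index=["g1"])
        assert tk.filter_expression_features(counts, tpm) == []

    def test_mean_tpm_threshold_is_strict(self):
        counts = pd.DataFrame(np.full((1, 162), 100), index=["g1"])
        tpm = pd.DataFrame(np.full((1, 162), 0.1), index=["g1"])
        assert tk.filter_expression_features(counts, tpm) == []
        tpm_ok = tpm + 1e-6
        assert tk.filter_expression_features(counts, tpm_ok) == ["g1"]

    def test_read_threshold_is_strict(self):
        # exactly 5 reads never counts as support (> 5 required)
        counts = pd.DataFrame(np.full((1, 162), 5), index=["g1"])
        tpm = pd.DataFrame(np.full((1, 162), 2.0), index=["g1"])
        assert tk.filter_expression_features(counts, tpm) == []

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(17)
        counts = pd.DataFrame(
            rng.poisson(6, size=(60, 162)),
            index=[f"g{i}" for i in range(60)],
        )
        tpm = pd.DataFrame(
            rng.gamma(0.5, 0.4, size=(60, 162)),
            index=counts.index, columns=counts.columns,
        )
        t = tk.FilterThresholds()
        assert tk.filter_expression_features(counts, tpm, t) == \
            brute_force_expression_keep(counts, tpm, t)

    def test_biotype_restriction(self):
        counts = pd.DataFrame(np.full((2, 162), 100), index=["g1", "g2"])
        tpm = pd.DataFrame(np.full((2, 162), 2.0), index=["g1", "g2"])
        biotypes = pd.Series({"g1": "protein_coding", "g2": "pseudogene"})
        assert tk.filter_expression_features(counts, tpm, biotypes=biotypes) == ["g1"]


class TestSplicingFilter:
    def test_six_zero_read_individuals_excludes_intron(self):
        n = 162
        jc = pd.DataFrame(
            {f"s{i}": [0 if i < 6 else 50, 50] for i in range(n)},
            index=["c1:i1", "c1:i2"],
        )
        cmap = pd.Series({"c1:i1": "c1", "c1:i2": "c1"})
        kept = tk.filter_splicing_features(jc, cmap)
        assert kept == ["c1:i2"]

    def test_cluster_support_in_99_individuals_is_too_few(self):
        n = 162
        reads = [30 if i < 99 else 0 for i in range(n)]
        jc = pd.DataFrame(
            {f"s{i}": [reads[i], reads[i]] for i in range(n)},
            index=["c1:i1", "c1:i2"],
        )
        cmap = pd.Series({"c1:i1": "c1", "c1:i2": "c1"})
        assert tk.filter_splicing_features(jc, cmap) == []

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(23)
        introns, cmap = [], {}
        rows = []
        for c in range(12):
            for m in range(3):
                iid = f"c{c}:i{m}"
                introns.append(iid)
                cmap[iid] = f"c{c}"
                rows.append(rng.poisson(rng.uniform(2, 40), size=162))
        jc = pd.DataFrame(np.vstack(rows), index=introns)
        cmap = pd.Series(cmap)
        t = tk.FilterThresholds()
        assert tk.filter_splicing_features(jc, cmap, t) == \
            brute_force_splicing_keep(jc, cmap, t)

    def test_intron_without_cluster_rejected(self):
        jc = pd.DataFrame(np.ones((1, 10)), index=["orphan"])
        with pytest.raises(ValueError, match="cluster"):
            tk.filter_splicing_features(jc, pd.Series(dtype=object))


class TestQuantileNormalize:
    def test_three_sample_feature_hand_values(self):
        out = rank_to_normal(np.array([[5.0, 1.0, 9.0]]), axis=1)
        np.testing.assert_allclose(
            out[0], [0.0, stats.norm.ppf(1 / 6), stats.norm.ppf(5 / 6)],
            atol=1e-6,
        )
        assert out[0][1] == pytest.approx(-0.9674, abs=1e-4)

    @staticmethod
    def _latin_square_values(n, seed):
        """Tie-free matrix: every feature holds each within-sample rank once."""
        rng = np.random.default_rng(seed)
        ranks = (np.arange(n)[:, None] + np.arange(n)[None, :]) % n
        spread = np.sort(rng.gamma(2.0, 1.0, size=n))
        return spread[ranks]

    def test_every_feature_shares_the_same_quantile_vector(self, pheno_factory):
        values = self._latin_square_values(24, seed=3)
        pm = pheno_factory(values, [f"s{i}" for i in range(24)])
        qn = tk.two_stage_quantile_normalize(pm)
        sorted_rows = np.sort(qn.values.to_numpy(), axis=1)
        for row in sorted_rows[1:]:
            np.testing.assert_allclose(row, sorted_rows[0], atol=1e-12)

    def test_sample_permutation_equivariance(self, pheno_factory):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(10, 20))
        samples = [f"s{i}" for i in range(20)]
        pm = pheno_factory(values, samples)
        qn = tk.two_stage_quantile_normalize(pm).values.to_numpy()
        perm = rng.permutation(20)
        pm2 = pheno_factory(values[:, perm], samples)
        qn2 = tk.two_stage_quantile_normalize(pm2).values.to_numpy()
        np.testing.assert_allclose(qn2, qn[:, perm], atol=1e-12)

    def test_constant_feature_flagged_and_zeroed(self, pheno_factory):
        values = np.vstack([np.full(10, 3.0), np.arange(10, dtype=float)])
        pm = pheno_factory(values, [f"s{i}" for i in range(10)])
        qn = tk.two_stage_quantile_normalize(pm)
        assert qn.constant_features == ["g0"]
        np.testing.assert_allclose(qn.values.loc["g0"], 0.0, atol=1e-12)

    def test_per_feature_mean_near_zero(self, pheno_factory):
        values = self._latin_square_values(30, seed=5)
        pm = pheno_factory(values, [f"s{i}" for i in range(30)])
        qn = tk.two_stage_quantile_normalize(pm)
        assert np.abs(qn.values.to_numpy().mean(axis=1)).max() < 1e-8


class TestHiddenFactors:
    def test_rank_one_matrix_recovers_generating_vector(self, pheno_factory):
        rng = np.random.default_rng(6)
        sample_vec = rng.normal(size=40)
        loadings = rng.normal(size=25)
        pm = pheno_factory(np.outer(loadings, sample_vec),
                           [f"s{i}" for i in range(40)])
        pc1 = tk.infer_hidden_factors(pm, 1).data["PC1"]
        assert abs(np.corrcoef(pc1, sample_vec)[0, 1]) > 0.999

    def test_factors_orthogonal(self, pheno_factory):
        rng = np.random.default_rng(7)
        pm = pheno_factory(rng.normal(size=(30, 12)), [f"s{i}" for i in range(12)])
        scores = tk.infer_hidden_factors(pm, 11).data.to_numpy()
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_sign_convention_deterministic(self, pheno_factory):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(20, 15))
        pm = pheno_factory(values, [f"s{i}" for i in range(15)])
        a = tk.infer_hidden_factors(pm, 3).data
        b = tk.infer_hidden_factors(pm, 3).data
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("bad_k", [0, -1, 100])
    def test_invalid_k_rejected(self, pheno_factory, bad_k):
        pm = pheno_factory(np.random.default_rng(0).normal(size=(10, 8)),
                           [f"s{i}" for i in range(8)])
        with pytest.raises(ValueError):
            tk.infer_hidden_factors(pm, bad_k)


class TestFactorGridSearch:
    def test_ties_resolve_to_smallest_k(self, pheno_factory):
        pm = pheno_factory(np.random.default_rng(1).normal(size=(10, 8)),
                           [f"s{i}" for i in range(8)])
        chosen, counts = tk.select_factor_count(pm, [0, 1, 2, 3], lambda f: 5)
        assert chosen == 0
        assert set(counts) == {0, 1, 2, 3}

    def test_singleton_zero_grid_skips_scanning(self, pheno_factory):
        pm = pheno_factory(np.random.default_rng(1).normal(size=(10, 8)),
                           [f"s{i}" for i in range(8)])
        calls = []
        chosen, _ = tk.select_factor_count(pm, [0], lambda f: calls.append(1) or 0)
        assert chosen == 0 and calls == []

    def test_empty_grid_rejected(self, pheno_factory):
        pm = pheno_factory(np.random.default_rng(1).normal(size=(10, 8)),
                           [f"s{i}" for i in range(8)])
        with pytest.raises(ValueError, match="empty"):
            tk.select_factor_count(pm, [], lambda f: 0)

    def test_latent_confounder_not_harmful(self, small_sim):
        """Adjusting for one inferred factor never loses discoveries on a
        cohort whose expression carries a genome-wide latent factor."""
        qn = tk.two_stage_quantile_normalize(small_sim.expression.phenotypes)
        measured = small_sim.covariates.data[["sex", "age"]]

        def discoveries(factors):
            cov = (
                tk.CovariateMatrix(measured.join(factors.data))
                if factors is not None else tk.CovariateMatrix(measured.copy())
            )
            recs = tk.cis_scan(small_sim.genotypes, qn, cov)
            feat, _ = tk.hierarchical_fdr(recs)
            return int(feat["significant"].sum())

        chosen, counts = tk.select_factor_count(qn, [0, 1], discoveries)
        assert counts[1] >= counts[0]
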