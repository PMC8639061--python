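import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from aqtlkit.io_preprocess import GenotypeMatrix, GwasSummary
from aqtlkit.qtl import (
    bh_fdr,
    cis_pairs,
    compare_qtl_strength,
    dense_locus_scan,
    empirical_genewise_p,
    fit_qtl,
    genewise_minp,
    genewise_scan,
    genotype_pcs,
    scan_qtl,
    select_gwas_variants,
    trans_pairs,
    trans_threshold,
    two_proportion_ztest,
)


def _geno(dosages, chrom=None, pos=None):
    m, n = dosages.shape
    ids = [f"v{i}" for i in range(m)]
    coords = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else [100 + 10 * i for i in range(m)],
        },
        index=ids,
    )
    return GenotypeMatrix(
        pd.DataFrame(dosages, index=ids, columns=[f"s{j}" for j in range(n)]), coords
    )


@pytest.fixture()
def geno20(rng):
    return _geno(rng.binomial(2, 0.3, size=(20, 100)).astype(float))


class TestGenotypePCs:
    def test_scores_orthonormal(self, geno20):
        pcs = genotype_pcs(geno20, 5)
        gram = pcs.to_numpy().T @ pcs.to_numpy()
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)

    def test_duplicated_variant_loads_pc1(self, rng):
        base = rng.binomial(2, 0.4, size=100).astype(float)
        noise = rng.binomial(2, 0.4, size=(4, 100)).astype(float)
        geno = _geno(np.vstack([base, base, noise]))
        pcs = genotype_pcs(geno, 2)
        z = (base - base.mean()) / base.std()
        r = np.corrcoef(pcs["PC1"], z)[0, 1]
        assert abs(r) > 0.9

    def test_variance_matches_eigendecomposition(self, rng):
        X = rng.normal(size=(5, 12))  # 5 variants, 12 samples
        geno = _geno((X - X.min()) / np.ptp(X) * 2)
        Xs = geno.dosages.to_numpy().T
        Xs = (Xs - Xs.mean(axis=0)) / Xs.std(axis=0)
        evals = np.linalg.eigvalsh(Xs.T @ Xs)[::-1]
        _, S, _ = np.linalg.svd(Xs)
        np.testing.assert_allclose(S[:5] ** 2, evals[:5], atol=1e-8)


class TestPairSelection:
    def test_gwas_cutoff_filter(self):
        tbl = pd.DataFrame(
            {
                "variant_id": ["a", "b", "c"],
                "chrom": ["1"] * 3,
                "pos": [1, 2, 3],
                "beta": [0.0, 0.0, 0.0],
                "se": [1.0] * 3,
                "p": [1e-9, 5e-8, 1e-7],
            }
        )
        gwas = GwasSummary(tbl)
        assert select_gwas_variants(gwas, 5e-8) == ["a", "b"]
        assert select_gwas_variants(gwas, 1.0) == ["a", "b", "c"]

    def test_cis_window_boundary_inclusive(self):
        vc = pd.DataFrame({"chrom": ["1", "1", "2"], "pos": [2_000_000, 3_000_001, 2_000_000]},
                          index=["va", "vb", "vc"])
        gc = pd.DataFrame({"chrom": ["1"], "tss": [1_000_000]}, index=["G"])
        pairs = cis_pairs(vc, gc, window=1_000_000)
        assert set(pairs["variant_id"]) == {"va"}  # exactly 1 Mb in; 1 Mb + 1 out

    def test_cis_matches_brute_force(self, rng):
        vc = pd.DataFrame(
            {"chrom": rng.choice(["1", "2"], 50), "pos": rng.integers(1, 5_000_000, 50)},
            index=[f"v{i}" for i in range(50)],
        )
        gc = pd.DataFrame(
            {"chrom": rng.choice(["1", "2"], 10), "tss": rng.integers(1, 5_000_000, 10)},
            index=[f"g{i}" for i in range(10)],
        )
        pairs = set(map(tuple, cis_pairs(vc, gc, 500_000).to_numpy()))
        expected = {
            (v, g)
            for v in vc.index
            for g in gc.index
            if vc.at[v, "chrom"] == gc.at[g, "chrom"]
            and abs(vc.at[v, "pos"] - gc.at[g, "tss"]) <= 500_000
        }
        assert pairs == expected

    def test_trans_excludes_cis(self):
        vc = pd.DataFrame({"chrom": ["1", "1"], "pos": [1_000_100, 900_000_000]},
                          index=["near", "far"])
        gc = pd.DataFrame({"chrom": ["1", "1"], "tss": [1_000_000, 500_000_000]},
                          index=["M1", "M2"])
        pairs = set(map(tuple, trans_pairs(vc, ["M1", "M2"], gc).to_numpy()))
        assert ("near", "M1") not in pairs
        assert ("far", "M1") in pairs and ("near", "M2") in pairs


class TestFitQtl:
    def test_exact_linear_trait(self):
        rng = np.random.default_rng(1)
        g = pd.Series(rng.binomial(2, 0.4, 50).astype(float),
                      index=[f"s{i}" for i in range(50)], name="v")
        y = (2.0 * g).rename("gene")
        res = fit_qtl(g, y)
        assert res.beta == pytest.approx(2.0)
        assert res.p < 1e-200

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 40
        g = pd.Series(rng.binomial(2, 0.3, n).astype(float),
                      index=[f"s{i}" for i in range(n)], name="v")
        y = pd.Series(rng.normal(size=n), index=g.index, name="gene")
        cov = pd.DataFrame({"age": rng.uniform(20, 70, n), "pc1": rng.normal(size=n)},
                           index=g.index)
        res = fit_qtl(g, y, cov)
        X = sm.add_constant(pd.concat([g, cov], axis=1))
        fit = sm.OLS(y, X).fit()
        assert res.beta == pytest.approx(fit.params["v"], abs=1e-10)
        assert res.se == pytest.approx(fit.bse["v"], abs=1e-10)
        assert res.p == pytest.approx(fit.pvalues["v"], abs=1e-10)

    def test_null_p_uniform(self, rng):
        n = 200
        y = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)], name="g")
        ps = []
        for _ in range(500):
            g = pd.Series(rng.binomial(2, 0.3, n).astype(float), index=y.index, name="v")
            ps.append(fit_qtl(g, y).p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_constant_dosage_p_one(self):
        g = pd.Series(np.ones(30), index=[f"s{i}" for i in range(30)], name="v")
        y = pd.Series(np.random.default_rng(0).normal(size=30), index=g.index, name="gene")
        assert fit_qtl(g, y).p == 1.0

    def test_scan_agrees_with_single_fits(self, geno20, rng):
        traits = pd.DataFrame(
            rng.normal(size=(3, 100)), index=["gA", "gB", "gC"],
            columns=geno20.sample_ids,
        )
        cov = pd.DataFrame({"age": rng.uniform(20, 70, 100)}, index=geno20.sample_ids)
        pairs = pd.DataFrame(
            [(v, g) for g in traits.index for v in list(geno20.variant_ids)[:5]],
            columns=["variant_id", "gene"],
        )
        scan = scan_qtl(geno20, traits, pairs, cov).set_index(["variant_id", "gene"])
        for (v, g), row in scan.iterrows():
            single = fit_qtl(geno20.dosages.loc[v], traits.loc[g], cov)
            assert row["beta"] == pytest.approx(single.beta, abs=1e-10)
            assert row["p"] == pytest.approx(single.p, abs=1e-10)


class TestGenewise:
    def test_minp_and_positional_tiebreak(self):
        assocs = pd.DataFrame(
            {
                "variant_id": ["v1", "v2", "v3"],
                "gene": ["G"] * 3,
                "p": [0.01, 0.01, 0.5],
            }
        )
        vc = pd.DataFrame({"chrom": ["1"] * 3, "pos": [300, 100, 200]},
                          index=["v1", "v2", "v3"])
        gw = genewise_minp(assocs, vc)
        assert gw.iloc[0]["min_p"] == 0.01
        assert gw.iloc[0]["lead_variant"] == "v2"  # smaller position wins the tie
        assert gw.iloc[0]["n"] == 3

    def test_qk_floor_when_observed_beats_all_sims(self, rng):
        n = 120
        block = pd.DataFrame(
            rng.binomial(2, 0.3, size=(3, n)).astype(float),
            index=["v0", "v1", "v2"], columns=[f"s{i}" for i in range(n)],
        )
        y = pd.Series(2.0 * block.loc["v0"] + 0.01 * rng.normal(size=n),
                      index=block.columns)
        q, null = empirical_genewise_p(block, y, None, n_sim=200, seed=0)
        assert q == pytest.approx(1.0 / 201.0)

    def test_single_variant_qk_close_to_p(self, rng):
        n = 150
        block = pd.DataFrame(
            rng.binomial(2, 0.4, size=(1, n)).astype(float),
            index=["v0"], columns=[f"s{i}" for i in range(n)],
        )
        y = pd.Series(rng.normal(size=n), index=block.columns)
        from aqtlkit.qtl import fit_qtl

        p_obs = fit_qtl(block.loc["v0"], y.rename("g")).p
        q, _ = empirical_genewise_p(block, y, None, n_sim=2000, seed=1)
        assert abs(q - p_obs) < 0.06

    def test_ld_identical_vs_independent_variants(self, rng):
        """Perfect LD → q ≈ p; independent variants → q ≈ Sidak."""
        n = 300
        base = rng.binomial(2, 0.4, n).astype(float)
        ld_block = pd.DataFrame(
            np.tile(base, (10, 1)), index=[f"v{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(n)],
        )
        indep_block = pd.DataFrame(
            rng.binomial(2, 0.4, size=(10, n)).astype(float),
            index=[f"v{i}" for i in range(10)], columns=ld_block.columns,
        )
        y = pd.Series(rng.normal(size=n), index=ld_block.columns)
        p_obs = fit_qtl(ld_block.iloc[0], y.rename("g")).p
        q_ld, _ = empirical_genewise_p(ld_block, y, None, n_sim=2000, seed=2)
        assert abs(q_ld - p_obs) < 0.07
        p_min = scan_qtl(
            _geno(indep_block.to_numpy()), pd.DataFrame([y.to_numpy()], index=["g"], columns=y.index),
            pd.DataFrame([(f"v{i}", "g") for i in range(10)], columns=["variant_id", "gene"]),
        )["p"].min()
        q_ind, _ = empirical_genewise_p(indep_block, y, None, n_sim=2000, seed=3)
        sidak = 1 - (1 - p_min) ** 10
        assert abs(q_ind - sidak) < 0.1

    def test_joint_permutation_preserves_ld(self, rng):
        X = rng.binomial(2, 0.3, size=(5, 200)).astype(float)
        perm = rng.permutation(200)
        np.testing.assert_allclose(np.corrcoef(X), np.corrcoef(X[:, perm]), atol=1e-12)

    def test_nsim_too_small_error(self, rng):
        block = pd.DataFrame(rng.binomial(2, 0.3, size=(2, 50)).astype(float),
                             columns=[f"s{i}" for i in range(50)], index=["a", "b"])
        y = pd.Series(rng.normal(size=50), index=block.columns)
        with pytest.raises(ValueError):
            empirical_genewise_p(block, y, None, n_sim=50)


class TestBH:
    def test_brute_force_oracle(self, rng):
        for _ in range(50):
            q = rng.uniform(size=rng.integers(1, 30))
            adj, sig = bh_fdr(q, 0.05)
            K = len(q)
            # brute-force step-up enumeration
            order = np.argsort(q)
            expected = np.empty(K)
            prev = 1.0
            for rank in range(K, 0, -1):
                i = order[rank - 1]
                prev = min(prev, q[i] * K / rank)
                expected[i] = prev
            np.testing.assert_allclose(adj, expected)
            assert (sig == (adj <= 0.05)).all()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        q = rng.uniform(size=100)
        adj, sig = bh_fdr(q, 0.05)
        reject, padj, _, _ = multipletests(q, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adj, padj)
        assert (sig == reject).all()

    def test_trivial_cases(self):
        adj, sig = bh_fdr(np.full(10, 0.001), 0.05)
        assert sig.all()
        adj, sig = bh_fdr(np.array([0.04]), 0.05)
        assert sig.all()


class TestTransThreshold:
    def test_nan_when_nothing_passes(self):
        gw = pd.DataFrame({"gene": ["a"], "q": [0.9], "significant": [False]})
        assert np.isnan(trans_threshold(np.linspace(0, 1, 100), gw))

    def test_inverts_null_cdf_at_largest_passing_q(self):
        null = np.linspace(0.001, 1.0, 1000)
        gw = pd.DataFrame(
            {"gene": ["a", "b", "c"], "q": [0.01, 0.03, 0.8],
             "significant": [True, True, False]}
        )
        thr = trans_threshold(null, gw)
        assert thr == pytest.approx(np.quantile(null, 0.03))


class TestCompareStrength:
    def test_identical_p_gives_zero_proportion(self):
        df = pd.DataFrame({"variant_id": ["v"], "gene": ["g"], "p": [0.1]})
        out = compare_qtl_strength(df, df)
        assert out["prop_aqtl_stronger"] == 0.0

    def test_two_proportion_z_matches_textbook(self):
        z, p = two_proportion_ztest(20, 100, 72, 100)
        p1, p2, pool = 0.2, 0.72, 0.46
        se = np.sqrt(pool * (1 - pool) * (1 / 100 + 1 / 100))
        assert z == pytest.approx((p1 - p2) / se)
        assert z < 0 and p < 1e-10

    def test_z_sign_flips_when_swapped(self):
        z1, _ = two_proportion_ztest(20, 100, 72, 100)
        z2, _ = two_proportion_ztest(72, 100, 20, 100)
        assert z1 == pytest.approx(-z2)

    def test_by_mode_proportions(self):
        e = pd.DataFrame(
            {"variant_id": ["v1", "v2"], "gene": ["g1", "g2"],
             "p": [0.1, 0.1], "mode": ["cis", "trans"]}
        )
        a = pd.DataFrame(
            {"variant_id": ["v1", "v2"], "gene": ["g1", "g2"],
             "p": [0.5, 0.01], "mode": ["cis", "trans"]}
        )
        out = compare_qtl_strength(e, a)
        assert out["by_mode"] == {"cis": 0.0, "trans": 1.0}


class TestDenseScan:
    def test_window_and_gwas_independence(self, rng):
        n = 80
        d = rng.binomial(2, 0.3, size=(6, n)).astype(float)
        geno = _geno(d, pos=[100, 200_000, 400_000, 600_000, 800_000, 5_000_000])
        tbl = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(6)],
                "chrom": ["1"] * 6,
                "pos": geno.variant_coords["pos"].to_numpy(),
                "beta": np.zeros(6),
                "se": np.ones(6),
                "p": [1.0, 1.0, 1e-9, 1.0, 1.0, 1.0],
            }
        )
        gwas = GwasSummary(tbl)
        traits = pd.DataFrame(rng.normal(size=(2, n)), index=["gA", "gB"],
                              columns=geno.sample_ids)
        out = dense_locus_scan(gwas, geno, traits, "v2", window=1_000_000)
        # all variants within +-500 kb of v2 enter, including p = 1 ones
        assert set(out["variant_id"]) == {"v0", "v1", "v2", "v3", "v4"}
        assert set(out["gene"]) == {"gA", "gB"}


class TestGenewiseScanIntegration:
    def test_planted_effects_detected(self, small_sim):
        from aqtlkit.activity import zscale

        geno = small_sim["geno"]
        truth = small_sim["truth"]
        z = zscale(small_sim["expr"])
        pcs = genotype_pcs(geno, 3)
        cov = small_sim["pheno"].table[["age"]].join(pcs)
        coords = small_sim["expr"].gene_coords
        reg_ids = list(truth.activities.index)
        pairs = cis_pairs(geno.variant_coords, coords.loc[reg_ids])
        assoc, gw = genewise_scan(geno, z.values, pairs, cov, n_sim=500, seed=0)
        eqtl_genes = set(truth.effects.loc[truth.effects["type"] == "eqtl", "gene"])
        sig = set(gw.loc[gw["significant"], "gene"])
        assert eqtl_genes <= sig
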