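import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr

from aqtlkit.activity import (
    ActivityMatrix,
    Regulon,
    activity_scores,
    infer_activities,
    network_to_interactome,
    pleiotropy_correction,
    regulons_from_tsv,
    regulons_to_tsv,
    zscale,
)
from aqtlkit.io_preprocess import ExpressionMatrix
from aqtlkit.network import CoexpressionNetwork


def _em(arr, ids=None, unit="log2tpm"):
    arr = np.asarray(arr, dtype=float)
    ids = ids or [f"g{i}" for i in range(arr.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(arr, index=ids, columns=[f"s{j}" for j in range(arr.shape[1])]),
        unit,
    )


class TestInteractome:
    def test_modes_and_likelihoods(self):
        r = np.random.default_rng(0)
        x = r.normal(size=100)
        expr = _em([x, -x + 0.01 * r.normal(size=100), 0.5 * x + r.normal(size=100)],
                   ids=["R", "T1", "T2"])
        net = CoexpressionNetwork(
            pd.DataFrame(
                [("R", "T1", 0.9, 10), ("R", "T2", 0.45, 10)],
                columns=["regulator", "target", "mi", "support"],
            ),
            10, 0.1, 1e-3,
        )
        regulons = network_to_interactome(net, expr)
        assert len(regulons) == 1
        reg = regulons[0]
        i1 = reg.targets.index("T1")
        assert reg.mode[i1] == pytest.approx(-1.0, abs=0.02)
        assert reg.likelihood[i1] == 1.0  # top-MI target
        # brute-force Spearman check
        i2 = reg.targets.index("T2")
        assert reg.mode[i2] == pytest.approx(
            spearmanr(x, expr.values.loc["T2"]).statistic, abs=1e-12
        )
        assert reg.likelihood[i2] == pytest.approx(0.5)

    def test_missing_targets_dropped_and_empty_regulon_omitted(self):
        expr = _em(np.random.default_rng(1).normal(size=(2, 50)), ids=["R", "T1"])
        net = CoexpressionNetwork(
            pd.DataFrame(
                [("R", "T1", 0.5, 5), ("R", "GONE", 0.9, 5), ("R2", "GONE", 0.4, 5)],
                columns=["regulator", "target", "mi", "support"],
            ),
            10, 0.1, 1e-3,
        )
        regulons = network_to_interactome(net, expr)
        assert len(regulons) == 1
        assert regulons[0].targets == ["T1"]

    def test_tsv_round_trip(self, tmp_path):
        reg = Regulon("R", ["a", "b"], np.array([0.5, -1.0]), np.array([1.0, 0.25]))
        path = tmp_path / "reg.tsv"
        regulons_to_tsv([reg], path)
        back = regulons_from_tsv(path)
        assert back[0].targets == ["a", "b"]
        np.testing.assert_allclose(back[0].mode, reg.mode)


class TestZscale:
    def test_mean_zero_sd_one(self, rng):
        z = zscale(_em(rng.normal(3, 5, size=(20, 60))))
        arr = z.values.to_numpy()
        np.testing.assert_allclose(arr.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(arr.std(axis=1), 1, atol=1e-10)
        assert z.unit == "zscore"

    def test_small_example_population_sd(self):
        z = zscale(_em([[1.0, 2.0, 3.0]]))
        sd = np.std([1, 2, 3])  # ddof=0
        np.testing.assert_allclose(z.values.to_numpy().ravel(), [-1 / sd, 0, 1 / sd])

    def test_constant_gene_zeroed(self):
        z = zscale(_em([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(z.values.to_numpy()[0], 0)


def _null_z(n_genes, n_samples, seed):
    r = np.random.default_rng(seed)
    return zscale(_em(r.normal(size=(n_genes, n_samples))))


class TestActivityScores:
    def test_min_target_threshold_boundary(self):
        z = _null_z(60, 40, 2)
        genes = list(z.gene_ids)
        r24 = Regulon("A", genes[:24], np.ones(24), np.ones(24))
        r25 = Regulon("B", genes[:25], np.ones(25), np.ones(25))
        act = activity_scores(z, [r24, r25], min_targets=25)
        assert "A" not in act.nes.index
        assert "B" in act.nes.index

    def test_sign_antisymmetry(self):
        z = _null_z(50, 30, 3)
        genes = list(z.gene_ids)[:30]
        w = np.random.default_rng(4).uniform(0.3, 1.0, 30)
        m = np.random.default_rng(5).choice([-1.0, 1.0], 30) * 0.8
        a1 = activity_scores(z, [Regulon("R", genes, m, w)], min_targets=10)
        a2 = activity_scores(z, [Regulon("R", genes, -m, w)], min_targets=10)
        np.testing.assert_allclose(a1.nes.to_numpy(), -a2.nes.to_numpy())

    def test_likelihood_scale_invariance(self):
        z = _null_z(50, 30, 6)
        genes = list(z.gene_ids)[:30]
        m = np.full(30, 0.9)
        a1 = activity_scores(z, [Regulon("R", genes, m, np.full(30, 1.0))], min_targets=10)
        a2 = activity_scores(z, [Regulon("R", genes, m, np.full(30, 0.5))], min_targets=10)
        np.testing.assert_allclose(a1.nes.to_numpy(), a2.nes.to_numpy(), atol=1e-12)

    def test_invariant_under_monotone_transform_of_z(self):
        z = _null_z(50, 30, 7)
        genes = list(z.gene_ids)[:28]
        reg = [Regulon("R", genes, np.ones(28), np.ones(28))]
        a1 = activity_scores(z, reg, min_targets=10)
        warped = ExpressionMatrix(z.values * 3 + np.tanh(z.values), "zscore")
        a2 = activity_scores(warped, reg, min_targets=10)
        np.testing.assert_allclose(a1.nes.to_numpy(), a2.nes.to_numpy())

    def test_null_calibration_small(self):
        # gene panel much larger than the regulons and mixed mode signs:
        # the within-sample rank constraint then leaves sd(NES) near 1
        z = _null_z(600, 400, 8)
        genes = list(z.gene_ids)
        r = np.random.default_rng(80)
        regs = [
            Regulon("R1", genes[:40], r.choice([-1.0, 1.0], 40), np.ones(40)),
            Regulon("R2", genes[40:140], r.choice([-1.0, 1.0], 100), np.ones(100)),
        ]
        act = activity_scores(z, regs, min_targets=25)
        for reg in act.nes.index:
            assert abs(act.nes.loc[reg].mean()) < 0.12
            assert 0.85 < act.nes.loc[reg].std() < 1.15

    def test_empty_regulon_set_errors(self):
        with pytest.raises(ValueError):
            activity_scores(_null_z(10, 10, 9), [])

    def test_recovers_true_activity(self, small_sim):
        truth = small_sim["truth"]
        regs = [
            Regulon(r, grp["target"].tolist(), grp["mode"].to_numpy(),
                    grp["weight"].to_numpy())
            for r, grp in truth.network.groupby("regulator")
        ]
        act = activity_scores(zscale(small_sim["expr"]), regs, min_targets=25)
        for r in act.nes.index:
            c = pearsonr(act.nes.loc[r], truth.activities.loc[r])[0]
            assert c >= 0.7


class TestPleiotropyCorrection:
    def test_disjoint_regulons_unchanged(self):
        z = _null_z(120, 50, 10)
        genes = list(z.gene_ids)
        regs = [
            Regulon("A", genes[:40], np.ones(40), np.ones(40)),
            Regulon("B", genes[40:80], np.ones(40), np.ones(40)),
        ]
        act = activity_scores(z, regs, min_targets=25)
        out = pleiotropy_correction(act, regs, z, min_common=25, alpha=0.5)
        pd.testing.assert_frame_equal(out.nes, act.nes)

    def test_alpha_one_is_identity(self):
        z = _null_z(120, 50, 11)
        genes = list(z.gene_ids)
        regs = [
            Regulon("A", genes[:60], np.ones(60), np.ones(60)),
            Regulon("B", genes[20:60], np.ones(40), np.ones(40)),  # nested in A
        ]
        act = activity_scores(z, regs, min_targets=25)
        out = pleiotropy_correction(act, regs, z, min_common=25, alpha=1.0)
        pd.testing.assert_frame_equal(out.nes, act.nes)

    def test_shadowed_regulator_shrinks(self):
        # A drives the signal; B's regulon is a subset of A's plus unique
        # null targets, so B's apparent activity is borrowed from A
        r = np.random.default_rng(12)
        n = 200
        a = r.normal(size=n)
        rows = {}
        shared = []
        for i in range(40):
            rows[f"sh{i}"] = 0.9 * a + 0.4 * r.normal(size=n)
            shared.append(f"sh{i}")
        unique_b = []
        for i in range(20):
            rows[f"ub{i}"] = r.normal(size=n)
            unique_b.append(f"ub{i}")
        for i in range(60):
            rows[f"bg{i}"] = r.normal(size=n)
        z = zscale(
            ExpressionMatrix(
                pd.DataFrame(rows).T.set_axis([f"s{j}" for j in range(n)], axis=1),
                "log2tpm",
            )
        )
        regA = Regulon("A", shared, np.ones(40), np.ones(40))
        regB = Regulon("B", shared[:30] + unique_b, np.ones(50), np.ones(50))
        act = activity_scores(z, [regA, regB], min_targets=25)
        out = pleiotropy_correction(act, [regA, regB], z, min_common=25, alpha=0.5)
        dominated = act.nes.loc["A"].abs() > act.nes.loc["B"].abs()
        # B's borrowed signal shrinks on average where A dominates
        assert out.nes.loc["B", dominated].abs().mean() < act.nes.loc["B", dominated].abs().mean()
        # exact blend contract: corrected = a*orig + (1-a)*unique-target score
        from scipy.stats import norm, rankdata

        u = norm.ppf((np.apply_along_axis(rankdata, 0, z.values.to_numpy()) - 0.5) / len(z.gene_ids))
        u = pd.DataFrame(u, index=z.gene_ids, columns=z.sample_ids)
        uniq = [t for t in regB.targets if t not in regA.targets]
        unique_score = u.loc[uniq].sum(axis=0) / np.sqrt(len(uniq))
        expected = 0.5 * act.nes.loc["B"] + 0.5 * unique_score
        np.testing.assert_allclose(
            out.nes.loc["B", dominated], expected[dominated], atol=1e-10
        )
        # samples where B dominates are untouched
        np.testing.assert_allclose(
            out.nes.loc["B", ~dominated], act.nes.loc["B", ~dominated], atol=1e-12
        )

    def test_bad_alpha_errors(self):
        z = _null_z(30, 10, 13)
        reg = [Regulon("A", list(z.gene_ids)[:25], np.ones(25), np.ones(25))]
        act = activity_scores(z, reg, min_targets=25)
        with pytest.raises(ValueError):
            pleiotropy_correction(act, reg, z, alpha=1.5)


class TestInferActivities:
    def test_cross_dataset_missing_targets_dropped(self, small_sim):
        truth = small_sim["truth"]
        regs = [
            Regulon(r, grp["target"].tolist(), grp["mode"].to_numpy(),
                    grp["weight"].to_numpy())
            for r, grp in truth.network.groupby("regulator")
        ]
        expr = small_sim["expr"]
        # drop 20% of genes to emulate a different platform
        keep = [g for i, g in enumerate(expr.gene_ids) if i % 5 != 0]
        sub = ExpressionMatrix(expr.values.loc[keep], "log2tpm")
        act = infer_activities(sub, regs, min_targets=15)
        assert act.nes.shape[1] == expr.values.shape[1]
        assert len(act.nes.index) >= 4
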