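import numpy as np
import pandas as pd
import pytest
from scipy import stats

from msntx import synthetic, transcriptomics as tx
from msntx.exceptions import ConfigError, DegenerateInputError


class TestPls1:
    def test_single_signal_gene_dominates(self, rng):
        # limit case: many regions per noise gene so contamination vanishes
        R = 600
        X = rng.normal(size=(R, 5))
        y = (X[:, 3] - X[:, 3].mean()) / X[:, 3].std(ddof=1)
        res = tx.pls1(X, y)
        assert np.argmax(np.abs(res.weights.to_numpy())) == 3
        assert res.explained_variance >= 0.99

    def test_weights_collinear_with_xty(self, rng):
        X = rng.normal(size=(20, 50))
        y = rng.normal(size=20)
        res = tx.pls1(X, y)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        oracle = Xs.T @ (y - y.mean())
        oracle /= np.linalg.norm(oracle)
        cosine = abs(res.weights.to_numpy() @ oracle)
        assert cosine >= 1 - 1e-10

    def test_explained_variance_is_squared_correlation(self, rng):
        X = rng.normal(size=(25, 40))
        y = rng.normal(size=25)
        res = tx.pls1(X, y)
        r = np.corrcoef(res.scores.to_numpy(), y)[0, 1]
        assert res.explained_variance == pytest.approx(r**2, abs=1e-12)

    def test_sign_convention(self, rng):
        X = rng.normal(size=(25, 40))
        y = rng.normal(size=25)
        a = tx.pls1(X, y)
        b = tx.pls1(X, -y)
        assert np.corrcoef(a.scores, y)[0, 1] >= 0
        assert np.corrcoef(b.scores, -y)[0, 1] >= 0
        np.testing.assert_allclose(a.scores, -b.scores, atol=1e-10)
        assert a.explained_variance == pytest.approx(b.explained_variance)

    def test_zero_variance_response_rejected(self, rng):
        with pytest.raises(DegenerateInputError):
            tx.pls1(rng.normal(size=(10, 5)), np.ones(10))

    def test_region_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            tx.pls1(rng.normal(size=(10, 5)), np.ones(9))


class TestPlsPermutation:
    def test_self_association_significant(self, rng):
        X = rng.normal(size=(30, 20))
        y = tx.pls1(X, rng.normal(size=30)).scores.to_numpy()
        p = tx.pls_permutation_p(X, y, n_perm=500, mode="shuffle", seed=1)
        assert p <= 0.01

    def test_min_permutations_enforced(self, rng):
        with pytest.raises(ConfigError):
            tx.pls_permutation_p(
                rng.normal(size=(10, 5)), rng.normal(size=10), n_perm=50, mode="shuffle"
            )

    def test_deterministic(self, rng):
        X = rng.normal(size=(15, 10))
        y = rng.normal(size=15)
        p1 = tx.pls_permutation_p(X, y, n_perm=200, mode="shuffle", seed=3)
        p2 = tx.pls_permutation_p(X, y, n_perm=200, mode="shuffle", seed=3)
        assert p1 == p2

    def test_spin_mode_needs_coordinates(self, rng):
        with pytest.raises(ConfigError):
            tx.pls_permutation_p(
                rng.normal(size=(10, 5)), rng.normal(size=10), n_perm=100, mode="spin"
            )


class TestBootstrapGeneZ:
    def test_planted_gradient_gene_high_z(self, parcellation_left):
        target = np.linspace(-2, 2, len(parcellation_left))
        expr, truth = synthetic.simulate_expression(
            parcellation_left, target, n_genes=40, frac_pos=0.025, frac_neg=0,
            noise_sd=0.15, beta_scale=2.0, seed=4,
        )
        table = tx.bootstrap_gene_z(expr, target, B=300, seed=0)
        (planted,) = truth.associated_genes
        assert table.loc[planted, "z"] > 5

    def test_noise_genes_mostly_below_threshold(self, parcellation_left):
        target = np.linspace(-2, 2, len(parcellation_left))
        expr, _ = synthetic.simulate_expression(
            parcellation_left, target, n_genes=60, frac_pos=0, frac_neg=0, seed=8
        )
        table = tx.bootstrap_gene_z(expr, target, B=300, seed=0)
        assert (table["z"].abs() < 5).mean() >= 0.95

    def test_response_negation_flips_z(self, rng):
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        a = tx.bootstrap_gene_z(X, y, B=100, seed=2)
        b = tx.bootstrap_gene_z(X, -y, B=100, seed=2)
        merged = a.join(b, lsuffix="_a", rsuffix="_b")
        np.testing.assert_allclose(merged["z_a"], -merged["z_b"], atol=1e-8)

    def test_zero_se_gives_signed_infinity(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=15)
        X = np.column_stack([y, y])  # weights identical in every resample
        with pytest.warns(UserWarning, match="zero bootstrap SE"):
            table = tx.bootstrap_gene_z(X, y, B=50, seed=1)
        assert np.isinf(table["z"]).all()
        assert (table["z"] > 0).all()

    def test_se_shrinks_with_region_count(self):
        ses = []
        for R in (50, 200):
            rng = np.random.default_rng(10)
            grad = np.linspace(-1, 1, R)
            X = grad[:, None] + 0.5 * rng.normal(size=(R, 15))
            table = tx.bootstrap_gene_z(X, grad, B=200, seed=3)
            ses.append(table["se"].median())
        assert ses[1] < ses[0]


class TestThresholdGeneLists:
    def test_basic_split(self):
        z = pd.Series({"g1": 6.1, "g2": -5.2, "g3": 0.3})
        pos, neg = tx.threshold_gene_lists(z)
        assert pos == ["g1"]
        assert neg == ["g2"]

    def test_threshold_is_strict(self):
        z = pd.Series({"g1": 5.0, "g2": -5.0})
        pos, neg = tx.threshold_gene_lists(z)
        assert pos == [] and neg == []

    def test_all_null_empty(self):
        z = pd.Series({"g1": 1.0, "g2": -2.0})
        assert tx.threshold_gene_lists(z) == ([], [])

    def test_sorted_by_abs_z(self):
        z = pd.Series({"a": 5.5, "b": 8.0, "c": 6.0, "d": -9.0, "e": -5.5})
        pos, neg = tx.threshold_gene_lists(z)
        assert pos == ["b", "c", "a"]
        assert neg == ["d", "e"]


class TestSpinTest:
    def test_identical_maps(self, parcellation_left):
        xyz = synthetic.centroids(parcellation_left)
        a = np.linspace(0, 1, len(xyz))
        rho, p = tx.spin_test(a, a, xyz, n_rot=199, seed=0)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_permutations_preserve_multiset(self, parcellation_left):
        xyz = synthetic.centroids(parcellation_left)
        perms = tx.generate_spins(xyz, n_rot=20, seed=1)
        a = np.arange(len(xyz), dtype=float)
        for perm in perms:
            assert sorted(a[perm]) == sorted(a)

    def test_mirrored_rotations_stay_within_hemisphere(self, parcellation_small):
        xyz = synthetic.centroids(parcellation_small)
        hemi = parcellation_small["hemisphere"].to_numpy()
        perms = tx.generate_spins(xyz, n_rot=10, seed=2, hemispheres=hemi)
        for perm in perms:
            assert (hemi[perm] == hemi).all()

    def test_joint_rotation_exchangeability(self, parcellation_left):
        xyz = synthetic.centroids(parcellation_left)
        rng = np.random.default_rng(3)
        a = rng.normal(size=len(xyz))
        b = rng.normal(size=len(xyz))
        rho0 = stats.spearmanr(a, b).statistic
        perms = tx.generate_spins(xyz, n_rot=5, seed=4)
        for perm in perms:
            rho = stats.spearmanr(a[perm], b[perm]).statistic
            assert rho == pytest.approx(rho0, abs=1e-12)

    def test_constant_map_rejected(self, parcellation_left):
        xyz = synthetic.centroids(parcellation_left)
        with pytest.raises(DegenerateInputError):
            tx.spin_test(np.ones(len(xyz)), np.arange(len(xyz)), xyz, n_rot=10)


class TestIshGeneScreen:
    def test_monotone_transform_significant(self, expression_with_gradient, parcellation_left):
        expr, _, target = expression_with_gradient
        xyz = synthetic.centroids(parcellation_left)
        expr = expr.copy()
        expr["GMONO"] = np.exp(stats.rankdata(target))  # monotone in the t-map
        res = tx.ish_gene_screen(expr, target, ["GMONO", "G00050"], xyz, n_rot=199, seed=0)
        assert res.loc["GMONO", "rho"] == pytest.approx(1.0)
        assert bool(res.loc["GMONO", "significant"])

    def test_planted_genes_recovered_with_sign(self, expression_with_gradient, parcellation_left):
        expr, truth, target = expression_with_gradient
        xyz = synthetic.centroids(parcellation_left)
        genes = list(truth.associated_genes)
        res = tx.ish_gene_screen(expr, target, genes, xyz, n_rot=99, seed=0)
        signs = np.sign([truth.associated_genes[g] for g in genes])
        agree = (np.sign(res.loc[genes, "rho"].to_numpy()) == signs).mean()
        assert agree >= 0.9

    def test_disjoint_list_rejected(self, expression_with_gradient, parcellation_left):
        expr, _, target = expression_with_gradient
        xyz = synthetic.centroids(parcellation_left)
        with pytest.raises(ValueError):
            tx.ish_gene_screen(expr, target, ["NOPE1", "NOPE2"], xyz, n_rot=99)


class TestDgeWeightCorrelation:
    def test_noiseless_positive_slope(self):
        weights = pd.Series({f"g{i}": w for i, w in enumerate(np.linspace(-1, 1, 20))})
        dge = pd.DataFrame(
            {"gene": weights.index, "log2fc": 2.0 * weights.to_numpy() + 5.0}
        )  # all positive log2fc, perfectly rank-aligned
        res = tx.dge_weight_correlation(weights, weights, dge, n_perm=200, seed=0)
        assert res["rho"] == pytest.approx(1.0)
        assert res["p_perm"] < 0.05

    def test_small_overlap_flagged(self):
        weights = pd.Series({"g1": 0.5, "g2": -0.1, "g3": 0.2})
        dge = pd.DataFrame({"gene": ["g1", "g2", "g3"], "log2fc": [1.0, 2.0, 3.0]})
        res = tx.dge_weight_correlation(weights, weights, dge, n_perm=100, seed=0)
        assert res["flag"] == "insufficient overlap"
        assert res["p_perm"] is None

    def test_downregulated_direction(self):
        weights = pd.Series({f"g{i}": float(i) for i in range(10)})
        dge = pd.DataFrame({"gene": weights.index, "log2fc": -np.ones(10)})
        res = tx.dge_weight_correlation(
            weights, weights, dge, direction="upregulated", n_perm=100, seed=0
        )
        assert res["n_overlap"] == 0
        res = tx.dge_weight_correlation(
            weights, weights, dge, direction="downregulated", n_perm=100, seed=0
        )
        assert res["n_overlap"] == 10

    def test_null_p_roughly_uniform(self, rng):
        background = pd.Series(rng.normal(size=200), index=[f"g{i}" for i in range(200)])
        ps = []
        for rep in range(40):
            chosen = rng.choice(200, size=20, replace=False)
            weights = background.iloc[chosen]
            dge = pd.DataFrame(
                {"gene": weights.index, "log2fc": np.abs(rng.normal(size=20)) + 0.1}
            )
            res = tx.dge_weight_correlation(weights, background, dge, n_perm=200, seed=rep)
            ps.append(res["p_perm"])
        assert 0.25 < np.mean(ps) < 0.75


class TestBhFdr:
    def test_single_p(self):
        np.testing.assert_allclose(tx.bh_fdr(np.array([0.03])), [0.03])

    def test_hand_evaluated_step_up(self):
        q = tx.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(tx.bh_fdr(np.ones(5)), np.ones(5))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(50)
        q = tx.bh_fdr(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            tx.bh_fdr(np.array([0.5, 1.5]))
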