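"""PCA/PC-selection, Chebyshev PC clustering, PLS-DA + VIP, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from cyberphenom import integrate
from cyberphenom.popgen import DistanceMatrix


def random_matrix(rng, n=8, p=5):
    return pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"v{j}" for j in range(p)],
    )


class TestPca:
    def test_rank_one_data_pc1_100(self):
        direction = np.array([1.0, 2.0, -1.0])
        X = pd.DataFrame(np.outer(np.arange(6, dtype=float), direction))
        res = integrate.pca(X, scale=False)
        assert res.explained_pct[0] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        res = integrate.pca(random_matrix(rng, n=10, p=4))
        assert res.explained_pct.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.diff(res.explained_pct) <= 1e-9)

    def test_matches_covariance_eigen_oracle(self):
        """Scores and percentages equal a direct covariance
        eigendecomposition (up to component sign)."""
        rng = np.random.default_rng(1)
        X = random_matrix(rng, n=5, p=4)
        res = integrate.pca(X, center=True, scale=False)
        Xc = X - X.mean(axis=0)
        cov = np.cov(Xc.to_numpy().T, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert res.explained_pct == pytest.approx(100 * evals[:4] / evals.sum(), abs=1e-8)
        oracle_scores = Xc.to_numpy() @ evecs
        for k in range(res.scores.shape[1]):
            got = res.scores.iloc[:, k].to_numpy()
            assert np.allclose(got, oracle_scores[:, k], atol=1e-8) or np.allclose(
                got, -oracle_scores[:, k], atol=1e-8
            )

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(2)
        res = integrate.pca(random_matrix(rng, n=12, p=6))
        gram = res.scores.to_numpy().T @ res.scores.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-9

    def test_constant_column_dropped_when_scaling(self):
        rng = np.random.default_rng(3)
        X = random_matrix(rng)
        X["const"] = 1.0
        res = integrate.pca(X, scale=True)
        assert res.dropped_columns == ["const"]
        assert "const" not in res.loadings.index

    def test_missing_values_rejected(self):
        X = random_matrix(np.random.default_rng(4))
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            integrate.pca(X)


class TestSelectPcs:
    def test_cumulative_sum_example(self):
        res = integrate.PcaResult(
            scores=pd.DataFrame(), loadings=pd.DataFrame(),
            explained_pct=np.array([60.0, 25.0, 10.0, 5.0]),
        )
        assert integrate.select_pcs(res, 0.90) == 3

    def test_threshold_one_returns_all(self):
        res = integrate.PcaResult(
            scores=pd.DataFrame(), loadings=pd.DataFrame(),
            explained_pct=np.array([60.0, 25.0, 10.0, 5.0]),
        )
        assert integrate.select_pcs(res, 1.0) == 4

    def test_invalid_threshold(self):
        res = integrate.PcaResult(pd.DataFrame(), pd.DataFrame(), np.array([100.0]))
        with pytest.raises(ValueError):
            integrate.select_pcs(res, 0.0)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 9999), thr=st.floats(0.05, 1.0))
    def test_matches_bruteforce_scan(self, seed, thr):
        rng = np.random.default_rng(seed)
        res = integrate.pca(random_matrix(rng, n=9, p=6))
        k = integrate.select_pcs(res, thr)
        cum = np.cumsum(res.explained_pct) / 100
        brute = next((i + 1 for i in range(len(cum)) if cum[i] >= thr - 1e-12), len(cum))
        assert k == brute


class TestPcCluster:
    def test_duplicate_strains_merge_first_at_zero(self):
        rng = np.random.default_rng(5)
        X = random_matrix(rng, n=5, p=4)
        X.loc["s1"] = X.loc["s0"]
        tree = integrate.pc_cluster(X, B=100, seed=0)
        first = tree.linkage[0]
        assert first[2] == pytest.approx(0.0, abs=1e-12)
        merged = tree.clusters[len(X)]
        assert merged == frozenset({"s0", "s1"})

    def test_tree_matches_hand_agglomeration(self):
        """Average-linkage merges on Chebyshev distances of the selected
        PC scores equal an independent scipy linkage run."""
        rng = np.random.default_rng(6)
        X = random_matrix(rng, n=4, p=3)
        tree = integrate.pc_cluster(X, ccr_threshold=1.0, B=100, seed=0)
        res = integrate.pca(X)
        k = integrate.select_pcs(res, 1.0)
        Z = hierarchy.linkage(pdist(res.scores.iloc[:, :k], metric="chebyshev"), "average")
        assert np.allclose(tree.linkage[:, 2], Z[:, 2])

    def test_strain_order_permutation_invariance(self):
        rng = np.random.default_rng(7)
        X = random_matrix(rng, n=6, p=4)
        t1 = integrate.pc_cluster(X, B=100, seed=0)
        perm = X.sample(frac=1, random_state=1)
        t2 = integrate.pc_cluster(perm, B=100, seed=0)
        sets1 = set(t1.clusters.values())
        sets2 = set(t2.clusters.values())
        assert sets1 == sets2


class TestPlsda:
    def test_single_informative_column(self):
        rng = np.random.default_rng(8)
        X = random_matrix(rng, n=20, p=6)
        y = np.array(["a"] * 10 + ["b"] * 10)
        X.iloc[10:, 2] += 3.0
        model = integrate.plsda(X, y, ncomp=2)
        w1 = np.abs(model.x_weights[:, 0])
        assert np.argmax(w1) == 2
        t1 = model.x_scores[:, 0]
        assert np.sign(t1[:10].mean()) != np.sign(t1[10:].mean())

    def test_explained_variance_bounded(self):
        rng = np.random.default_rng(9)
        X = random_matrix(rng, n=15, p=8)
        y = np.array(["a", "b"] * 7 + ["a"])
        model = integrate.plsda(X, y, ncomp=3)
        assert np.all(model.explained_x_pct <= 100 + 1e-9)
        assert model.explained_x_pct.sum() <= 100 + 1e-9

    def test_component1_weights_proportional_to_covariance(self):
        """Balanced two-class PLS: first-component weights are
        proportional to each column's covariance with the class
        indicator."""
        rng = np.random.default_rng(10)
        X = random_matrix(rng, n=16, p=5)
        y = np.array(["a"] * 8 + ["b"] * 8)
        model = integrate.plsda(X, y, ncomp=1)
        Xs = (X - X.mean()) / X.std(ddof=1)
        ind = (y == "b").astype(float)
        cov = Xs.to_numpy().T @ (ind - ind.mean())
        w = model.x_weights[:, 0]
        ratio = cov / np.linalg.norm(cov)
        assert np.allclose(np.abs(w), np.abs(ratio), atol=1e-8)

    def test_ncomp_truncated_to_rank(self):
        rng = np.random.default_rng(11)
        X = random_matrix(rng, n=4, p=6)
        model = integrate.plsda(X, ["a", "a", "b", "b"], ncomp=10)
        assert model.x_weights.shape[1] == 3

    def test_single_class_rejected(self):
        X = random_matrix(np.random.default_rng(12))
        with pytest.raises(ValueError):
            integrate.plsda(X, ["a"] * len(X))


class TestVip:
    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 9999), p=st.integers(3, 8))
    def test_normalization_identity(self, seed, p):
        """mean(VIP^2) = 1 for every fitted model."""
        rng = np.random.default_rng(seed)
        X = random_matrix(rng, n=14, p=p)
        y = np.array(["a", "b"] * 7)
        model = integrate.plsda(X, y, ncomp=2)
        v = integrate.vip(model)
        assert (v**2).mean() == pytest.approx(1.0, abs=1e-9)

    def test_informative_variable_flagged(self):
        rng = np.random.default_rng(13)
        X = random_matrix(rng, n=30, p=10)
        y = np.array(["a"] * 15 + ["b"] * 15)
        X.iloc[15:, 4] += 2.0
        v = integrate.vip(integrate.plsda(X, y, ncomp=2))
        assert v.idxmax() == "v4" and v.max() > 1.0

    def test_one_component_closed_form(self):
        """Single-component VIP reduces to sqrt(p) |w_j| / ||w||."""
        rng = np.random.default_rng(14)
        X = random_matrix(rng, n=12, p=6)
        y = np.array(["a", "b"] * 6)
        model = integrate.plsda(X, y, ncomp=1)
        v = integrate.vip(model)
        w = model.x_weights[:, 0]
        expected = np.sqrt(len(w)) * np.abs(w) / np.linalg.norm(w)
        assert np.allclose(v.to_numpy(), expected, atol=1e-10)


class TestGpCorrelation:
    def make_dist(self, n, rng):
        a = rng.random((n, n))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0)
        return DistanceMatrix(labels=[f"s{i}" for i in range(n)], values=d)

    def test_constant_profile_raises(self):
        rng = np.random.default_rng(15)
        dist = self.make_dist(4, rng)
        traits = random_matrix(rng, n=4, p=5)
        traits.loc["s2"] = 1.0
        with pytest.raises(ValueError, match="s2"):
            integrate.gp_correlation(dist, traits)

    def test_hand_computed_pearson(self):
        rng = np.random.default_rng(16)
        dist = self.make_dist(4, rng)
        traits = random_matrix(rng, n=4, p=6)
        gp = integrate.gp_correlation(dist, traits)
        ds, rs = [], []
        for i in range(4):
            for j in range(i + 1, 4):
                ds.append(dist.values[i, j])
                rs.append(stats.pearsonr(traits.iloc[i], traits.iloc[j])[0])
        r, p = stats.pearsonr(ds, rs)
        assert gp.r == pytest.approx(r, abs=1e-12)
        assert gp.p_value == pytest.approx(p, abs=1e-12)
        assert len(gp.pairs) == 6

    def test_joint_affine_transform_invariance(self):
        rng = np.random.default_rng(17)
        dist = self.make_dist(5, rng)
        traits = random_matrix(rng, n=5, p=6)
        g1 = integrate.gp_correlation(dist, traits)
        g2 = integrate.gp_correlation(dist, traits * 3.5 + 11.0)
        assert g2.r == pytest.approx(g1.r, abs=1e-12)
        assert np.allclose(g1.pairs["trait_r"], g2.pairs["trait_r"])

    def test_lineage_structured_traits_give_negative_r(self):
        """Traits built as linear images of a latent genotype coordinate:
        genetically close strains have similar profiles, so distance and
        profile correlation anticorrelate."""
        neg = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            latent = rng.normal(size=8)
            d = np.abs(latent[:, None] - latent[None, :])
            dist = DistanceMatrix(labels=[f"s{i}" for i in range(8)], values=d)
            basis = rng.normal(size=(2, 10))
            profiles = np.outer(latent, basis[0]) + basis[1] + rng.normal(0, 0.05, (8, 10))
            traits = pd.DataFrame(profiles, index=dist.labels)
            neg += integrate.gp_correlation(dist, traits).r < 0
        assert neg == 10


class TestChiSquare:
    def test_proportional_table_zero(self):
        chi2, df, p = integrate.chi_square_2x2([[10, 10], [20, 20]])
        assert chi2 == pytest.approx(0.0) and df == 1 and p == pytest.approx(1.0)

    def test_symmetric_table_zero(self):
        chi2, _, _ = integrate.chi_square_2x2([[5, 5], [5, 5]])
        assert chi2 == pytest.approx(0.0)

    def test_study_layout_table_matches_formula(self):
        """All 9 diploids euploid, 4 of 11 triploids aneuploid: chi2 equals
        the direct sum over cells, with and without Yates."""
        tab = np.array([[9, 0], [7, 4]], dtype=float)
        n = tab.sum()
        exp = np.outer(tab.sum(1), tab.sum(0)) / n
        plain = ((tab - exp) ** 2 / exp).sum()
        yates = ((np.abs(tab - exp) - 0.5).clip(0) ** 2 / exp).sum()
        chi2, _, _ = integrate.chi_square_2x2(tab)
        chi2_y, _, _ = integrate.chi_square_2x2(tab, correction=True)
        assert chi2 == pytest.approx(plain, abs=1e-12)
        assert chi2_y == pytest.approx(yates, abs=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(
        a=st.integers(1, 30), b=st.integers(1, 30),
        c=st.integers(1, 30), d=st.integers(1, 30),
    )
    def test_closed_form_identity(self, a, b, c, d):
        """Uncorrected chi2 equals n(ad-bc)^2 / product of margins."""
        chi2, _, _ = integrate.chi_square_2x2([[a, b], [c, d]])
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(closed, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            integrate.chi_square_2x2([[0, 0], [5, 5]])
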