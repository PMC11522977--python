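"""Network matrices, module detection, eigengenes, classes and hub calling."""

import numpy as np
import pandas as pd
import pytest

from cutinet import coexpression as cx
from cutinet.containers import ConfigurationError


def brute_force_tom(A):
    """O(n^3) triple-loop evaluation of the topological overlap formula."""
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    k = A.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n))
            tom[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return tom


class TestBicor:
    def test_self_and_negation(self, rng):
        x = rng.normal(size=(1, 20))
        X = np.vstack([x, -x])
        cor = cx.bicor_matrix(X)
        assert cor[0, 0] == pytest.approx(1.0)
        assert cor[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_close_to_pearson_without_outliers(self, rng):
        z = rng.normal(size=72)
        x = z + 0.5 * rng.normal(size=72)
        y = z + 0.5 * rng.normal(size=72)
        X = np.vstack([x, y])
        b = cx.bicor_matrix(X)[0, 1]
        p = np.corrcoef(X)[0, 1]
        assert abs(b - p) < 0.05

    def test_robust_to_gross_outlier(self, rng):
        z = rng.normal(size=72)
        x = z + 0.3 * rng.normal(size=72)
        y = z + 0.3 * rng.normal(size=72)
        pearson_clean = np.corrcoef(x, y)[0, 1]
        xo, yo = x.copy(), y.copy()
        xo[0], yo[0] = 40.0, -40.0  # one wildly discordant sample
        pearson_dirty = np.corrcoef(xo, yo)[0, 1]
        bicor_dirty = cx.bicor_matrix(np.vstack([xo, yo]))[0, 1]
        assert abs(bicor_dirty - pearson_clean) < abs(pearson_dirty - pearson_clean)

    def test_constant_row_fallback(self, rng):
        X = np.vstack([np.ones(10), rng.normal(size=10)])
        cor = cx.bicor_matrix(X)
        assert np.isfinite(cor).all()

    def test_too_few_samples(self):
        with pytest.raises(ConfigurationError):
            cx.bicor_matrix(np.ones((2, 3)))


class TestSoftAdjacency:
    def test_extremes_and_forced_value(self):
        cor = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, -0.9], [0.0, -0.9, 1.0]])
        adj = cx.soft_adjacency(cor, beta=16)
        assert adj[0, 0] == 1.0
        assert adj[0, 2] == 0.0
        assert adj[0, 1] == pytest.approx(0.5**16)
        assert adj[1, 2] == pytest.approx(0.9**16)  # unsigned

    def test_invalid_beta(self):
        with pytest.raises(ConfigurationError):
            cx.soft_adjacency(np.eye(2), beta=0.5)


class TestTopologicalOverlap:
    def test_fully_connected_triangle(self):
        A = np.ones((3, 3))
        tom = cx.topological_overlap(A)
        # (sum_u a_iu a_uj + a_ij) / (min(k) + 1 - a_ij) = (1 + 1)/(2 + 1 - 1)
        assert tom[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(tom), 1.0)

    def test_isolated_node(self, rng):
        A = np.abs(rng.normal(size=(4, 4)))
        A = (A + A.T) / 10
        A[3, :] = A[:, 3] = 0.0
        tom = cx.topological_overlap(A)
        assert np.allclose(tom[3, :3], 0.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(3):
            A = np.abs(rng.normal(size=(8, 8)))
            A = (A + A.T) / (2 * A.max())
            np.fill_diagonal(A, 0.0)
            assert np.abs(cx.topological_overlap(A) - brute_force_tom(A)).max() < 1e-12

    def test_asymmetric_rejected(self):
        A = np.array([[0.0, 0.5], [0.2, 0.0]])
        with pytest.raises(ConfigurationError):
            cx.topological_overlap(A)


def planted_expression(rng, sizes=(60, 50, 40), n_noise=100, r=0.8):
    blocks = []
    truth = []
    for mi, size in enumerate(sizes, start=1):
        latent = rng.normal(size=72)
        blocks.append(
            np.sqrt(r) * latent + np.sqrt(1 - r) * rng.normal(size=(size, 72))
        )
        truth += [mi] * size
    blocks.append(rng.normal(size=(n_noise, 72)))
    truth += [0] * n_noise
    X = np.vstack(blocks)
    X = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
    return X, np.array(truth)


class TestDetectModules:
    def test_planted_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, truth = planted_expression(rng)
            tom = cx.topological_overlap(cx.soft_adjacency(cx.bicor_matrix(X)))
            labels, _ = cx.detect_modules(tom, expr_std=X)
            assert len(np.unique(labels[labels > 0])) == 3
            aris.append(adjusted_rand_score(truth, labels))
        assert np.mean(aris) >= 0.9

    def test_identical_latents_merged(self):
        rng = np.random.default_rng(1)
        latent = rng.normal(size=72)
        r = 0.8
        X = np.vstack(
            [
                np.sqrt(r) * latent + np.sqrt(1 - r) * rng.normal(size=(40, 72)),
                np.sqrt(r) * latent + np.sqrt(1 - r) * rng.normal(size=(40, 72)),
                rng.normal(size=(60, 72)),
            ]
        )
        X = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        tom = cx.topological_overlap(cx.soft_adjacency(cx.bicor_matrix(X)))
        labels, _ = cx.detect_modules(tom, expr_std=X)
        assert len(np.unique(labels[:80])) == 1  # one merged module

    def test_pure_noise_mostly_unclustered(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(300, 72))
            X = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
            tom = cx.topological_overlap(cx.soft_adjacency(cx.bicor_matrix(X)))
            labels, _ = cx.detect_modules(tom, expr_std=X)
            assert (labels == 0).mean() >= 0.9

    def test_min_module_size_validated(self):
        with pytest.raises(ConfigurationError):
            cx.detect_modules(np.eye(10), min_module_size=2)

    def test_label_counts_partition(self):
        rng = np.random.default_rng(3)
        X, _ = planted_expression(rng)
        tom = cx.topological_overlap(cx.soft_adjacency(cx.bicor_matrix(X)))
        labels, _ = cx.detect_modules(tom, expr_std=X)
        assert (labels == 0).sum() + (labels > 0).sum() == len(labels)


class TestEigengenes:
    def test_identical_profiles(self, rng):
        profile = rng.normal(size=12)
        profile = (profile - profile.mean()) / profile.std(ddof=1)
        X = np.tile(profile, (5, 1))
        eig = cx.module_eigengenes(X, np.ones(5, dtype=int))
        v = eig.loc[1].to_numpy()
        assert np.linalg.norm(v) == pytest.approx(1.0)
        assert abs(np.corrcoef(v, profile)[0, 1]) == pytest.approx(1.0)

    def test_sign_convention(self, rng):
        X = rng.normal(size=(20, 30))
        X = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        eig = cx.module_eigengenes(X, np.ones(20, dtype=int))
        cors = [np.corrcoef(X[i], eig.loc[1])[0, 1] for i in range(20)]
        assert np.mean(cors) >= 0

    def test_two_gene_closed_form(self):
        """2 x n block: the eigengene matches the analytic leading right
        singular vector computed from the 2x2 Gram matrix."""
        rng = np.random.default_rng(2)
        M = rng.normal(size=(2, 6))
        eig = cx.module_eigengenes(M, np.ones(2, dtype=int)).loc[1].to_numpy()
        G = M @ M.T  # 2x2
        a, b, c = G[0, 0], G[0, 1], G[1, 1]
        lam = (a + c) / 2 + np.sqrt(((a - c) / 2) ** 2 + b**2)
        u = np.array([b, lam - a])
        u /= np.linalg.norm(u)
        v = M.T @ u
        v /= np.linalg.norm(v)
        assert min(np.abs(eig - v).max(), np.abs(eig + v).max()) < 1e-10

    def test_eigengene_maximality(self, rng):
        """No unit-norm sample profile explains more member variance than the
        eigengene (checked against the full SVD spectrum)."""
        X = rng.normal(size=(15, 10))
        eig = cx.module_eigengenes(X, np.ones(15, dtype=int)).loc[1].to_numpy()
        explained = np.linalg.norm(X @ eig) ** 2
        s = np.linalg.svd(X, compute_uv=False)
        assert explained == pytest.approx(s[0] ** 2, rel=1e-10)

    def test_singleton_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            cx.module_eigengenes(rng.normal(size=(3, 8)), np.array([1, 2, 2]))


class TestClassifyModules:
    def _eig_pair(self, r, rng):
        z = rng.normal(size=(2, 2000))
        a = z[0]
        b = r * z[0] + np.sqrt(1 - r**2) * z[1]
        return pd.DataFrame([a / np.linalg.norm(a), b / np.linalg.norm(b)],
                            index=[1, 2])

    def test_correlated_above_half_same_class(self, rng):
        classes = cx.classify_modules(self._eig_pair(0.6, rng))
        assert classes[1] == classes[2]

    def test_below_half_different_classes(self, rng):
        classes = cx.classify_modules(self._eig_pair(0.4, rng))
        assert classes[1] != classes[2]

    def test_single_module_single_class(self, rng):
        eig = pd.DataFrame([rng.normal(size=10)], index=[1])
        assert cx.classify_modules(eig) == {1: 1}


class TestHubGenes:
    def _fixture(self, rng, n=100):
        latent = rng.normal(size=72)
        X = np.sqrt(0.85) * latent + np.sqrt(0.15) * rng.normal(size=(n, 72))
        X = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        labels = np.ones(n, dtype=int)
        tom = cx.topological_overlap(cx.soft_adjacency(cx.bicor_matrix(X)))
        eig = cx.module_eigengenes(X, labels)
        trait = np.column_stack([latent + rng.normal(size=72),
                                 rng.normal(size=72)])
        return X, labels, eig, tom, trait

    def test_quota_and_cutoff_grid(self, rng):
        X, labels, eig, tom, trait = self._fixture(rng)
        hub, cutoffs, diag = cx.identify_hub_genes(X, labels, eig, tom, trait)
        cutoff, n_hub = cutoffs[1]
        assert cutoff in set(np.round(cx.CUTOFF_GRID, 2))
        assert n_hub == hub.sum()
        # chosen cutoff minimizes |fraction - 5%| (direct re-evaluation oracle)
        k = tom[np.ix_(np.arange(100), np.arange(100))].sum(1) - 1
        crit1 = k > k.mean()
        ec = np.array([np.corrcoef(X[i], eig.loc[1])[0, 1] for i in range(100)])
        crit2 = np.abs(ec) > 0.8
        tc = np.max(np.abs(np.array(
            [[np.corrcoef(X[i], trait[:, j])[0, 1] for j in range(2)]
             for i in range(100)])), axis=1)
        best = min(
            ((abs((crit1 & crit2 & (tc > c)).mean() - 0.05), -c) for c in cx.CUTOFF_GRID)
        )
        assert cutoff == pytest.approx(-best[1])

    def test_low_eigengene_correlation_excluded(self, rng):
        X, labels, eig, tom, trait = self._fixture(rng)
        hub, _, diag = cx.identify_hub_genes(X, labels, eig, tom, trait,
                                             eigen_cor_min=0.8)
        assert not hub[np.abs(diag["eigengene_cor"].to_numpy()) <= 0.8].any()

    def test_identical_genes_yield_no_hubs(self):
        profile = np.linspace(-1, 1, 72)
        X = np.tile(profile, (30, 1))
        X = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        labels = np.ones(30, dtype=int)
        tom = cx.topological_overlap(cx.soft_adjacency(cx.bicor_matrix(X)))
        eig = cx.module_eigengenes(X, labels)
        trait = np.column_stack([profile, profile])
        hub, _, _ = cx.identify_hub_genes(X, labels, eig, tom, trait)
        assert hub.sum() == 0  # nobody is strictly above the mean connectivity

    def test_monotone_in_eigen_cor_threshold(self, rng):
        X, labels, eig, tom, trait = self._fixture(rng)
        loose, _, _ = cx.identify_hub_genes(X, labels, eig, tom, trait,
                                            eigen_cor_min=0.7)
        tight, _, _ = cx.identify_hub_genes(X, labels, eig, tom, trait,
                                            eigen_cor_min=0.9)
        assert set(np.flatnonzero(tight)) <= set(np.flatnonzero(loose))

    def test_missing_traits_rejected(self, rng):
        X, labels, eig, tom, _ = self._fixture(rng)
        with pytest.raises(ConfigurationError):
            cx.identify_hub_genes(X, labels, eig, tom, None)


class TestEstimator:
    def test_sklearn_interface(self, rng):
        X, truth = planted_expression(rng, sizes=(40, 30), n_noise=50)
        est = cx.CoexpressionModules(min_module_size=20)
        labels = est.fit_predict(X.T)
        assert labels.shape == (120,)
        assert est.tom_.shape == (120, 120)
        params = est.get_params()
        assert params["beta"] == 16.0
        est.set_params(beta=6.0)
        assert est.beta == 6.0
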