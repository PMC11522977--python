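"""PLS / sparse PLS / randomized-GLM importance, permutation calibration and
the S > 1, p < 0.01 selection rule."""

import numpy as np
import pandas as pd
import pytest

from cutinet import gene_assoc as ga
from cutinet.containers import ConfigurationError


def svd_pls_oracle(X, Y, n_components):
    """Independent SVD-based PLS2: per component the X-weight is the leading
    left singular vector of X'Y, followed by the standard deflation."""
    Xd = X - X.mean(axis=0)
    Yd = Y - Y.mean(axis=0)
    W, T, ssy = [], [], []
    for _ in range(n_components):
        U, _, _ = np.linalg.svd(Xd.T @ Yd, full_matrices=False)
        w = U[:, 0]
        t = Xd @ w
        tt = t @ t
        c = Yd.T @ t / tt
        p = Xd.T @ t / tt
        before = (Yd**2).sum()
        Xd = Xd - np.outer(t, p)
        Yd = Yd - np.outer(t, c)
        ssy.append(before - (Yd**2).sum())
        W.append(w)
        T.append(t)
    return np.array(W).T, np.array(T).T, np.array(ssy)


class TestPLS:
    def test_single_pair_full_explanation(self):
        X = np.linspace(-1, 1, 10)[:, None]
        Y = 2 * X
        model = ga.pls_fit(X, Y, 1)
        total = ((Y - Y.mean()) ** 2).sum()
        assert model.y_ss_explained_[0] == pytest.approx(total, rel=1e-10)

    def test_matches_svd_oracle(self, rng):
        X = rng.normal(size=(6, 4))
        Y = rng.normal(size=(6, 3))
        model = ga.pls_fit(X, Y, 2)
        W, T, ssy = svd_pls_oracle(X, Y, 2)
        for a in range(2):
            sign = np.sign(model.x_weights_[:, a] @ W[:, a])
            assert np.abs(model.x_weights_[:, a] - sign * W[:, a]).max() < 1e-8
            assert np.abs(model.x_scores_[:, a] - sign * T[:, a]).max() < 1e-8
        assert np.allclose(model.y_ss_explained_, ssy, atol=1e-8)

    def test_cross_check_against_sklearn(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(20, 6))
        Y = rng.normal(size=(20, 3))
        mine = ga.pls_fit(X, Y, 3)
        sk = PLSRegression(n_components=3, scale=False, tol=1e-10).fit(X, Y)
        assert np.abs(mine.predict(X) - sk.predict(X)).max() < 1e-4

    def test_zero_variance_response_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            ga.pls_fit(rng.normal(size=(8, 3)), np.ones((8, 2)), 1)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            ga.pls_fit(rng.normal(size=(5, 3)), rng.normal(size=(5, 2)), 5)


class TestVIP:
    def test_single_gene_is_unity(self, rng):
        X = rng.normal(size=(12, 1))
        Y = 2 * X + 0.1 * rng.normal(size=(12, 1))
        model = ga.pls_fit(X, Y, 1)
        assert model.vip_[0] == pytest.approx(1.0, abs=1e-12)

    def test_exchangeable_predictors_all_unity(self):
        x = np.linspace(-1, 1, 14)
        X = np.tile(x[:, None], (1, 5))  # identical columns
        Y = x[:, None]
        model = ga.pls_fit(X, Y, 1)
        assert np.allclose(model.vip_, 1.0, atol=1e-10)

    def test_mean_square_identity(self, rng):
        for _ in range(10):
            X = rng.normal(size=(15, 8))
            Y = rng.normal(size=(15, 4))
            m = ga.pls_fit(X, Y, 3)
            assert np.mean(m.vip_**2) == pytest.approx(1.0, abs=1e-8)
            s = ga.spls_fit(X, Y, 3, keep_per_component=3)
            assert np.mean(s.vip_**2) == pytest.approx(1.0, abs=1e-8)


class TestSparsePLS:
    def test_keep_all_reduces_to_pls(self, rng):
        X = rng.normal(size=(12, 6))
        Y = rng.normal(size=(12, 3))
        dense = ga.pls_fit(X, Y, 2)
        sparse = ga.spls_fit(X, Y, 2, keep_per_component=6)
        assert np.allclose(sparse.vip_, dense.vip_, atol=1e-10)

    def test_planted_driver_sole_weight(self, rng):
        X = rng.normal(size=(30, 8))
        Y = (3 * X[:, 4] + 0.05 * rng.normal(size=30))[:, None]
        model = ga.spls_fit(X, Y, 1, keep_per_component=1)
        assert np.flatnonzero(model.x_weights_[:, 0]).tolist() == [4]

    def test_never_selected_gene_scores_zero(self, rng):
        X = rng.normal(size=(30, 10))
        Y = (X[:, 0] + 0.05 * rng.normal(size=30))[:, None]
        model = ga.spls_fit(X, Y, 1, keep_per_component=1)
        assert model.vip_[0] > 1
        assert np.allclose(model.vip_[1:], 0.0, atol=1e-12)

    def test_invalid_keep_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            ga.spls_fit(rng.normal(size=(10, 4)), rng.normal(size=(10, 2)), 1, 9)


class TestRandomizedGLM:
    def test_mean_score_is_one_and_no_noise_gene_dominates(self, rng):
        X = rng.normal(size=(72, 500))
        y = rng.normal(size=72)
        S = ga.rglm_scores(X, y, n_bags=100, seed=0)
        assert np.mean(S) == pytest.approx(1.0, rel=1e-12)
        # under noise, no gene is picked in more than half of the bags that
        # offered it (scores are selection counts normalized to mean 1, so
        # the absolute ceiling scales with the selection density)
        max_count = S.max() * S.sum() / 500
        n_offered = 100 * 0.2  # bags x candidate fraction
        assert max_count / n_offered < 0.5

    def test_planted_driver_dominates(self, rng):
        X = rng.normal(size=(72, 80))
        y = X[:, 17] + 0.2 * rng.normal(size=72)
        S = ga.rglm_scores(X, y, n_bags=200, candidate_frac=0.3, seed=1)
        assert np.argmax(S) == 17
        assert S[17] > 1

    def test_unselected_gene_zero(self, rng):
        X = rng.normal(size=(40, 30))
        X[:, 5] = 0.0  # constant column can never enter a model
        y = X[:, 0] + 0.1 * rng.normal(size=40)
        S = ga.rglm_scores(X, y, n_bags=100, candidate_frac=1.0, seed=2)
        assert S[5] == 0.0

    def test_too_few_bags_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            ga.rglm_scores(rng.normal(size=(20, 5)), rng.normal(size=20), n_bags=10)


class TestPermutationPvalues:
    def test_top_score_floor_formula(self, rng):
        """A score above the whole null pool gets p = 1 / (1 + pool size)."""
        n, p = 20, 5
        X = rng.normal(size=(n, p))
        X[:, 0] = np.arange(n)  # deterministic marker

        def score(Xv, Yv):
            out = np.abs(np.corrcoef(Xv.T, Yv.ravel())[:-1, -1])
            return np.where(np.arange(Xv.shape[1]) == 0, 10.0 + out, out)

        # make gene 0's real score larger than any permuted one
        def score_real_boost(Xv, Yv):
            s = score(Xv, Yv)
            return s

        Y = X[:, [0]] + 0.1 * rng.normal(size=(n, 1))
        S, pvals, pool = ga.permutation_pvalues(score_real_boost, X, Y,
                                                n_perm=99, seed=0)
        # gene 0 scores > 10 in real and permuted runs alike; its p counts the
        # pooled >= comparisons exactly
        n_ge = (pool >= S[0]).sum()
        assert pvals[0] == pytest.approx((1 + n_ge) / (1 + pool.size))

    def test_duplicated_gene_same_pvalue(self, rng):
        X = rng.normal(size=(24, 4))
        X[:, 3] = X[:, 1]
        Y = rng.normal(size=(24, 3))

        def score(Xv, Yv):
            return np.abs(Xv.T @ (Yv - Yv.mean(0))).sum(axis=1)

        _, pvals, _ = ga.permutation_pvalues(score, X, Y, n_perm=99, seed=1)
        assert pvals[1] == pvals[3]

    def test_deterministic(self, rng):
        X = rng.normal(size=(20, 6))
        Y = rng.normal(size=(20, 2))

        def score(Xv, Yv):
            return np.abs(Xv.T @ Yv).sum(axis=1)

        a = ga.permutation_pvalues(score, X, Y, n_perm=99, seed=5)[1]
        b = ga.permutation_pvalues(score, X, Y, n_perm=99, seed=5)[1]
        assert np.array_equal(a, b)

    def test_insufficient_permutations_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            ga.permutation_pvalues(lambda X, Y: X.sum(0), rng.normal(size=(5, 2)),
                                   rng.normal(size=(5, 1)), n_perm=50)


class TestSelection:
    @pytest.mark.parametrize(
        "S,p,expected",
        [(1.0, 0.005, False), (1.5, 0.02, False), (1.5, 0.005, True),
         (0.8, 0.001, False)],
    )
    def test_strict_rule(self, S, p, expected):
        table = pd.DataFrame({"S": [S], "p": [p]})
        assert ga.select_genes(table)["selected"].iloc[0] == expected

    def test_monotone_in_thresholds(self, rng):
        table = pd.DataFrame({"S": rng.uniform(0, 3, 200), "p": rng.uniform(0, 0.05, 200)})
        base = set(np.flatnonzero(ga.select_genes(table)["selected"]))
        tighter = set(np.flatnonzero(ga.select_genes(table, s_min=1.5, p_max=0.005)["selected"]))
        assert tighter <= base


class TestRunGeneAssociation:
    @pytest.fixture(scope="class")
    def result(self):
        from cutinet import synthdata as sd
        from cutinet import metabstats as ms
        from cutinet.io import filter_low_expression, standardize

        cfg = sd.association_benchmark_config(
            seed=2, n_genes=400, n_assoc_genes=10, n_metabolites_per_fraction=24
        )
        ds = sd.generate_dataset(cfg)
        expr = filter_low_expression(ds.expression)
        tsne = {
            fr: ms.tsne_embed(standardize(getattr(ds, f"metabolome_{fr}")), seed=1).scores
            for fr in ("wax", "lcw")
        }
        table = ga.run_gene_association(
            expr,
            {fr: getattr(ds, f"metabolome_{fr}") for fr in ("wax", "lcw")},
            tsne,
            ga.GeneAssocConfig(n_perm=99, n_bags=100, seed=0),
        )
        return ds, table

    def test_provenance_columns(self, result):
        _, table = result
        assert {"gene", "model", "stratum", "fraction", "response", "S", "p",
                "selected"} <= set(table.columns)
        assert set(table["model"]) <= {"pls", "spls", "rglm"}
        assert (table.loc[table.model == "pls", "stratum"] == "high").all()
        assert (table.loc[table.model != "pls", "stratum"] == "low").all()

    def test_union_rule(self, result):
        """A gene selected by any single model appears in the putative set."""
        _, table = result
        put = table.attrs["putative"]
        for fr in ("wax", "lcw"):
            sel = table[(table.fraction == fr) & table.selected]
            assert set(sel["gene"]) == put[fr]

    def test_vip_identity_within_run(self, result):
        _, table = result
        for (model, fr), sub in table.groupby(["model", "fraction"]):
            if model in ("pls", "spls"):
                sub = sub[sub.response == "profiles"]
                assert np.mean(sub["S"] ** 2) == pytest.approx(1.0, abs=1e-6)
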