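"""Gene-to-metabolite association by multivariate importance scoring.

Three models produce a per-gene importance score S on a common scale where
S > 1 means above-average contribution:

* multi-response PLS (NIPALS PLS2) on the highly expressed stratum
  (mean FPKM > 100), S = VIP (variable importance in projection; the squared
  scores average to exactly 1 over genes);
* sparse PLS on the low stratum: per-component X-weights are soft-thresholded
  so a fixed number of genes stay active, then renormalized (VIP again);
* a randomized-GLM ensemble on the low stratum: many bootstrap bags, each
  fitting a forward-selected (AIC) linear model on a random candidate subset
  of genes against the leading metabolome tSNE component (the single-value
  response that captures the major metabolome variation); S is the gene's
  selection frequency normalized to mean 1.  Forward selection is capped at
  5 terms: with looser caps every bag fills its quota whether or not signal
  exists, which removes the contrast between real and permuted data that the
  mean-1 normalization relies on.

Each score is calibrated by a permutation test: the sample order of the
response block is permuted jointly (preserving its internal covariance while
severing the X-Y link), all scores are recomputed, and the null pool across
genes and permutations yields p = (1 + #{S_B >= S}) / (1 + pool size).
A gene is selected when S > 1 and p < 0.01; per fraction the putative set is
the union over the three models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold

from .containers import ConfigurationError, OmicsMatrix
from .io import standardize, stratify_by_expression

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PLS / sparse PLS
# ---------------------------------------------------------------------------

class PLSImportance(BaseEstimator, RegressorMixin):
    """Multi-response PLS (NIPALS) with VIP importance.

    ``fit(X, Y)`` expects samples x genes and samples x metabolites arrays
    (already standardized upstream; the estimator re-centers defensively).
    Fitted attributes: ``x_weights_`` (p x A, unit columns), ``x_scores_``,
    ``y_ss_explained_`` (Y sum of squares captured per component) and
    ``vip_``.
    """

    def __init__(self, n_components: int = 2, max_iter: int = 500, tol: float = 1e-12):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol

    # subclass hook
    def _threshold(self, w: np.ndarray) -> np.ndarray:
        return w

    def fit(self, X, Y):
        X = np.array(X, dtype=float)
        Y = np.array(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, p = X.shape
        if self.n_components > min(n - 1, p):
            raise ConfigurationError("n_components exceeds min(n_samples - 1, n_genes)")
        if np.allclose(Y.var(axis=0), 0):
            raise ConfigurationError("response block has zero variance")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xd = X - self.x_mean_
        Yd = Y - self.y_mean_

        W = np.zeros((p, self.n_components))
        P = np.zeros((p, self.n_components))
        C = np.zeros((Y.shape[1], self.n_components))
        T = np.zeros((n, self.n_components))
        ssy = np.zeros(self.n_components)
        for a in range(self.n_components):
            u = Yd[:, int(np.argmax(Yd.var(axis=0)))]
            if np.allclose(u, 0):
                W, P, C, T, ssy = W[:, :a], P[:, :a], C[:, :a], T[:, :a], ssy[:a]
                break
            w = np.zeros(p)
            for _ in range(self.max_iter):
                w_new = Xd.T @ u
                norm = np.linalg.norm(w_new)
                if norm == 0:
                    break
                w_new = self._threshold(w_new / norm)
                w_new /= np.linalg.norm(w_new)
                t = Xd @ w_new
                tt = t @ t
                if tt == 0:
                    break
                c = Yd.T @ t / tt
                u_new = Yd @ c / (c @ c)
                if np.linalg.norm(w_new - w) < self.tol:
                    w = w_new
                    break
                w, u = w_new, u_new
            t = Xd @ w
            tt = t @ t
            if tt == 0:
                W, P, C, T, ssy = W[:, :a], P[:, :a], C[:, :a], T[:, :a], ssy[:a]
                break
            c = Yd.T @ t / tt
            p_load = Xd.T @ t / tt
            before = float((Yd**2).sum())
            Xd = Xd - np.outer(t, p_load)
            Yd = Yd - np.outer(t, c)
            ssy[a] = before - float((Yd**2).sum())
            W[:, a], P[:, a], C[:, a], T[:, a] = w, p_load, c, t

        self.x_weights_, self.x_loadings_, self.y_loadings_, self.x_scores_ = W, P, C, T
        self.y_ss_explained_ = ssy
        self.n_components_ = W.shape[1]
        self.vip_ = vip_scores(self)
        return self

    def _coef(self, n_comp: int | None = None) -> np.ndarray:
        a = self.n_components_ if n_comp is None else n_comp
        W, P, C = self.x_weights_[:, :a], self.x_loadings_[:, :a], self.y_loadings_[:, :a]
        if a == 0:
            return np.zeros((W.shape[0], C.shape[0]))
        return W @ np.linalg.pinv(P.T @ W) @ C.T

    def predict(self, X, n_components: int | None = None):
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean_) @ self._coef(n_components) + self.y_mean_


class SparsePLSImportance(PLSImportance):
    """Sparse PLS: per component only ``keep_per_component`` genes keep a
    nonzero (soft-thresholded) weight; reduces to PLS when keep = p."""

    def __init__(
        self,
        n_components: int = 2,
        keep_per_component: int = 10,
        max_iter: int = 500,
        tol: float = 1e-12,
    ):
        super().__init__(n_components=n_components, max_iter=max_iter, tol=tol)
        self.keep_per_component = keep_per_component

    def fit(self, X, Y):
        p = np.asarray(X).shape[1]
        if not 1 <= self.keep_per_component <= p:
            raise ConfigurationError("keep_per_component must be in 1..n_genes")
        return super().fit(X, Y)

    def _threshold(self, w: np.ndarray) -> np.ndarray:
        keep = self.keep_per_component
        if keep >= w.size:
            return w
        mags = np.abs(w)
        lam = np.partition(mags, -keep - 1)[-keep - 1]
        out = np.sign(w) * np.maximum(mags - lam, 0.0)
        if not out.any():  # all-tied degenerate case
            out = np.where(mags >= mags.max(), w, 0.0)
        return out


def pls_fit(X, Y, n_components: int) -> PLSImportance:
    return PLSImportance(n_components=n_components).fit(X, Y)


def spls_fit(X, Y, n_components: int, keep_per_component: int) -> SparsePLSImportance:
    return SparsePLSImportance(
        n_components=n_components, keep_per_component=keep_per_component
    ).fit(X, Y)


def vip_scores(model: PLSImportance) -> np.ndarray:
    """VIP_j = sqrt(p * sum_a SSY_a w_aj^2 / sum_a SSY_a).

    With unit-norm weight columns the squared scores average to exactly 1
    over genes, which grounds the S > 1 selection convention.
    """
    W = model.x_weights_
    ssy = model.y_ss_explained_
    p = W.shape[0]
    total = ssy.sum()
    if total <= 0 or W.shape[1] == 0:
        return np.ones(p)
    return np.sqrt(p * (W**2 @ ssy) / total)


def choose_n_components(
    X,
    Y,
    max_components: int = 10,
    cv_folds: int = 5,
    seed: int = 0,
    keep_per_component: int | None = None,
) -> int:
    """Pick the component count minimizing 5-fold cross-validated Y
    prediction error (PRESS); smallest count wins ties."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    amax = min(max_components, n - 1 - (n // cv_folds), X.shape[1])
    amax = max(amax, 1)
    press = np.zeros(amax)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for train, test in kf.split(X):
        if keep_per_component is None:
            model = PLSImportance(n_components=amax)
        else:
            model = SparsePLSImportance(
                n_components=amax, keep_per_component=keep_per_component
            )
        model.fit(X[train], Y[train])
        for a in range(1, amax + 1):
            resid = Y[test] - model.predict(X[test], n_components=min(a, model.n_components_))
            press[a - 1] += float((resid**2).sum())
    return int(np.argmin(press)) + 1


# ---------------------------------------------------------------------------
# randomized GLM ensemble
# ---------------------------------------------------------------------------

class RandomizedGLM(BaseEstimator):
    """Bootstrap ensemble of forward-selected linear models.

    Each bag draws a bootstrap sample and a random candidate subset of
    ``ceil(candidate_frac * p)`` genes, then adds genes greedily while the
    AIC improves (at most ``max_terms`` terms).  A gene's importance is its
    final-model selection count normalized so the mean score over genes is 1.
    """

    def __init__(
        self,
        n_bags: int = 500,
        candidate_frac: float = 0.2,
        max_terms: int = 10,
        seed: int = 0,
    ):
        self.n_bags = n_bags
        self.candidate_frac = candidate_frac
        self.max_terms = max_terms
        self.seed = seed

    def fit(self, X, y):
        if self.n_bags < 100:
            raise ConfigurationError("n_bags must be >= 100")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        q = max(1, int(np.ceil(self.candidate_frac * p)))
        rng = np.random.default_rng(self.seed)
        counts = np.zeros(p)
        for _ in range(self.n_bags):
            idx = rng.integers(0, n, size=n)
            cand = rng.choice(p, size=q, replace=False)
            active = self._forward_select(X[idx][:, cand], y[idx])
            counts[cand[active]] += 1
        total = counts.sum()
        if total == 0:
            raise ConfigurationError("no bag selected any gene")
        self.counts_ = counts
        self.importances_ = counts * p / total
        return self

    def _forward_select(self, Xb: np.ndarray, yb: np.ndarray) -> list[int]:
        n, q = Xb.shape
        Q = Xb - Xb.mean(axis=0)
        r = yb - yb.mean()
        rss = float(r @ r)
        if rss == 0:
            return []
        aic = n * np.log(rss / n) + 2.0
        active: list[int] = []
        remaining = np.ones(q, dtype=bool)
        for _ in range(min(self.max_terms, q)):
            norms = (Q**2).sum(axis=0)
            proj = Q.T @ r
            with np.errstate(divide="ignore", invalid="ignore"):
                reduction = np.where(norms > 1e-12, proj**2 / norms, 0.0)
            reduction[~remaining] = -np.inf
            j = int(np.argmax(reduction))
            red = reduction[j]
            if not np.isfinite(red) or red <= 0 or red >= rss:
                break
            new_rss = rss - red
            new_aic = n * np.log(new_rss / n) + 2.0 * (len(active) + 2)
            if new_aic >= aic:
                break
            qj = Q[:, j] / np.sqrt(norms[j])
            r = r - (qj @ r) * qj
            Q = Q - np.outer(qj, qj @ Q)
            remaining[j] = False
            active.append(j)
            rss, aic = new_rss, new_aic
        return active


def rglm_scores(
    X, y, n_bags: int = 500, candidate_frac: float = 0.2, seed: int = 0,
    max_terms: int = 10,
) -> np.ndarray:
    return RandomizedGLM(n_bags, candidate_frac, max_terms, seed).fit(X, y).importances_


# ---------------------------------------------------------------------------
# permutation calibration and selection
# ---------------------------------------------------------------------------

def permutation_pvalues(score_fn, X, Y, n_perm: int = 199, seed: int = 0):
    """Pooled permutation p-values for a per-gene score function.

    ``score_fn(X, Y)`` must return one score per gene.  Returns
    ``(scores, pvalues, null_pool)``.
    """
    if n_perm < 99:
        raise ConfigurationError("n_perm must be >= 99 to resolve p < 0.01")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    scores = np.asarray(score_fn(X, Y if Y.shape[1] > 1 else Y[:, 0]), dtype=float)
    rng = np.random.default_rng(seed)
    pool = np.empty((n_perm, scores.size))
    n = Y.shape[0]
    for b in range(n_perm):
        perm = rng.permutation(n)
        Yp = Y[perm]
        pool[b] = score_fn(X, Yp if Yp.shape[1] > 1 else Yp[:, 0])
    flat = np.sort(pool.ravel())
    n_ge = flat.size - np.searchsorted(flat, scores, side="left")
    p = (1.0 + n_ge) / (1.0 + flat.size)
    return scores, p, flat


def select_genes(table: pd.DataFrame, s_min: float = 1.0, p_max: float = 0.01) -> pd.DataFrame:
    """Apply the strict S > s_min and p < p_max rule."""
    out = table.copy()
    out["selected"] = (out["S"] > s_min) & (out["p"] < p_max)
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class GeneAssocConfig:
    fpkm_threshold: float = 100.0
    n_perm: int = 199
    s_min: float = 1.0
    p_max: float = 0.01
    max_components: int = 10
    cv_folds: int = 5
    keep_frac: float = 0.1
    n_bags: int = 500
    candidate_frac: float = 0.2
    max_terms: int = 5
    rglm_components: int = 1
    seed: int = 0


def run_gene_association(
    expr: OmicsMatrix,
    metabolomes: dict[str, OmicsMatrix],
    tsne_scores: dict[str, pd.DataFrame],
    config: GeneAssocConfig | None = None,
) -> pd.DataFrame:
    """Full gene-to-metabolite stage across strata, models and fractions.

    ``expr`` is the filtered raw-FPKM matrix; ``metabolomes`` maps fraction
    name -> raw metabolite matrix; ``tsne_scores`` maps fraction -> samples x
    2 tSNE coordinates.  Returns a long table (gene, model, stratum,
    fraction, response, S, p, selected); the per-fraction putative union is
    stored in ``table.attrs["putative"]``.
    """
    config = config or GeneAssocConfig()
    high, low = stratify_by_expression(expr, config.fpkm_threshold)
    strata = {}
    for name, stratum in (("high", high), ("low", low)):
        if stratum.n_features == 0:
            logger.warning("stratum %r is empty; its models are skipped", name)
            strata[name] = None
        else:
            std = standardize(stratum)
            strata[name] = (std.feature_ids, std.values.T)  # samples x genes

    seed_seq = np.random.SeedSequence(config.seed)
    seeds = iter(s.generate_state(1)[0] % (2**31) for s in seed_seq.spawn(64))

    rows = []
    putative: dict[str, set[str]] = {}
    for fraction, metab in metabolomes.items():
        Y = standardize(metab).values.T  # samples x metabolites
        putative[fraction] = set()

        if strata["high"] is not None:
            genes, X = strata["high"]
            a = choose_n_components(X, Y, config.max_components, config.cv_folds, next(seeds))
            fn = lambda Xv, Yv, a=a: PLSImportance(n_components=a).fit(Xv, Yv).vip_
            S, p, _ = permutation_pvalues(fn, X, Y, config.n_perm, next(seeds))
            rows.append(_frame(genes, "pls", "high", fraction, "profiles", S, p))
        if strata["low"] is not None:
            genes, X = strata["low"]
            keep = max(1, int(np.ceil(config.keep_frac * X.shape[1])))
            a = choose_n_components(
                X, Y, config.max_components, config.cv_folds, next(seeds),
                keep_per_component=keep,
            )
            fn = lambda Xv, Yv, a=a, k=keep: SparsePLSImportance(
                n_components=a, keep_per_component=k
            ).fit(Xv, Yv).vip_
            S, p, _ = permutation_pvalues(fn, X, Y, config.n_perm, next(seeds))
            rows.append(_frame(genes, "spls", "low", fraction, "profiles", S, p))

            for comp in tsne_scores[fraction].columns[: config.rglm_components]:
                y = tsne_scores[fraction][comp].to_numpy()
                bag_seed = next(seeds)
                fn = lambda Xv, yv, s=bag_seed: rglm_scores(
                    Xv, yv, config.n_bags, config.candidate_frac, s, config.max_terms
                )
                S, p, _ = permutation_pvalues(fn, X, y, config.n_perm, next(seeds))
                rows.append(_frame(genes, "rglm", "low", fraction, str(comp), S, p))

    table = select_genes(pd.concat(rows, ignore_index=True), config.s_min, config.p_max)
    for fraction in metabolomes:
        sel = table[(table["fraction"] == fraction) & table["selected"]]
        putative[fraction] = set(sel["gene"])
    table.attrs["putative"] = putative
    return table


def _frame(genes, model, stratum, fraction, response, S, p) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": genes,
            "model": model,
            "stratum": stratum,
            "fraction": fraction,
            "response": response,
            "S": S,
            "p": p,
        }
    )
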