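"""Cluster-to-metabolome association by leave-one-covariate-out random forest.

A random-forest regression predicts each metabolome tSNE component from the
module eigengenes plus (a capped number of) unclustered genes.  For every
predictor, a reduced forest without it is refit; the performance drop is
measured by three metrics (predictive R2, RMSE, MAPE), a paired bootstrap
over samples turns each drop into a one-sided p-value, p-values are BH
corrected across predictors per metric, and a predictor counts as associated
with a fraction when at least two metrics are significant for at least one
response component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from statsmodels.stats.multitest import multipletests

from .containers import ConfigurationError

METRICS = ("r2", "rmse", "mape")


@dataclass
class RFMetrics:
    r2: float
    rmse: float
    mape: float


def regression_metrics(actual, predicted) -> RFMetrics:
    """Predictive R2 (1 - SSE/TSS), RMSE and mean absolute percentage error.

    The MAPE denominator is guarded at ``1e-8 * max|actual|`` because tSNE
    coordinates can sit arbitrarily close to zero.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1 or a.size < 2:
        raise ConfigurationError("actual/predicted must be equal-length vectors, n >= 2")
    sse = float(((a - p) ** 2).sum())
    tss = float(((a - a.mean()) ** 2).sum())
    if tss == 0:
        raise ConfigurationError("actual values are constant (TSS = 0)")
    eps = 1e-8 * np.abs(a).max()
    mape = float(np.mean(100.0 * np.abs(p - a) / np.maximum(np.abs(a), eps)))
    return RFMetrics(1.0 - sse / tss, float(np.sqrt(sse / a.size)), mape)


def rf_fit_oob(
    predictors: np.ndarray,
    response: np.ndarray,
    n_trees: int = 1000,
    seed: int = 0,
    max_features: float | int = 1.0 / 3.0,
) -> np.ndarray:
    """Out-of-bag predictions of a random-forest regression.

    Every sample is predicted only by trees whose bootstrap did not contain
    it; deterministic for a fixed seed.  ``max_features`` may be a fraction
    of the predictor count or an absolute integer; leave-one-covariate-out
    comparisons must pass the same absolute value to the full and reduced
    fits, otherwise the reduced forest is handicapped by a smaller split
    subset rather than by the missing predictor.
    """
    X = np.asarray(predictors, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ConfigurationError("predictors must be a samples x p matrix with p >= 1")
    if X.shape[0] < 10:
        raise ConfigurationError("need >= 10 samples")
    if isinstance(max_features, int):
        mtry = min(max_features, X.shape[1])
    else:
        mtry = max(1, int(np.ceil(max_features * X.shape[1])))
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        rf.fit(X, y)
    if any("oob" in str(w.message).lower() for w in caught):
        raise ConfigurationError(
            "some samples have no out-of-bag trees; increase n_trees"
        )
    return rf.oob_prediction_


class LocoForestImportance(BaseEstimator):
    """Leave-one-covariate-out forest importance with paired-bootstrap p-values.

    ``fit(X, Y)`` takes samples x p predictors and samples x k response
    components.  Fitted attributes: ``delta_`` (p x k x 3 performance drops),
    ``pvalues_``, ``qvalues_`` (BH across predictors, per metric and
    component) and ``selected_`` (>= 2 significant metrics on >= 1 component).
    """

    def __init__(
        self,
        n_trees: int = 1000,
        n_boot: int = 4000,
        alpha: float = 0.01,
        seed: int = 0,
    ):
        self.n_trees = n_trees
        self.n_boot = n_boot
        self.alpha = alpha
        self.seed = seed

    def fit(self, X, Y):
        if self.n_boot < 50:
            raise ConfigurationError("n_boot must be >= 50 (p-value resolution)")
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, p = X.shape
        k = Y.shape[1]
        rng = np.random.default_rng(self.seed)
        boot_idx = rng.integers(0, n, size=(self.n_boot, n))

        delta = np.zeros((p, k, 3))
        pvals = np.ones((p, k, 3))
        mtry = max(1, int(np.ceil(p / 3.0)))  # shared by full and reduced fits
        for c in range(k):
            y = Y[:, c]
            full_oob = rf_fit_oob(X, y, self.n_trees, seed=self.seed, max_features=mtry)
            for j in range(p):
                reduced = np.delete(X, j, axis=1)
                red_oob = rf_fit_oob(
                    reduced, y, self.n_trees, seed=self.seed, max_features=mtry
                )
                delta[j, c] = self._delta(y, full_oob, red_oob)
                pvals[j, c] = self._bootstrap_p(y, full_oob, red_oob, boot_idx)

        qvals = np.ones_like(pvals)
        for c in range(k):
            for mi in range(3):
                qvals[:, c, mi] = multipletests(pvals[:, c, mi], method="fdr_bh")[1]
        n_sig = (qvals < self.alpha).sum(axis=2)  # p x k
        self.delta_ = delta
        self.pvalues_ = pvals
        self.qvalues_ = qvals
        self.n_significant_ = n_sig.max(axis=1)
        self.selected_ = self.n_significant_ >= 2
        return self

    @staticmethod
    def _delta(y, full_oob, red_oob) -> np.ndarray:
        mf = regression_metrics(y, full_oob)
        mr = regression_metrics(y, red_oob)
        # harmful direction is positive: R2 falls, errors rise
        return np.array([mf.r2 - mr.r2, mr.rmse - mf.rmse, mr.mape - mf.mape])

    @staticmethod
    def _bootstrap_p(y, full_oob, red_oob, boot_idx) -> np.ndarray:
        """Vectorized paired bootstrap: p = (1 + #{delta* <= 0}) / (n_boot + 1).

        The bootstrap must be fine enough that the post-BH floor
        ``n_predictors / (n_boot + 1)`` stays below alpha, hence the large
        default resample count.
        """
        n_boot, n = boot_idx.shape
        yb = y[boot_idx]
        tss = ((yb - yb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        sq_full = ((y - full_oob) ** 2)[boot_idx].sum(axis=1)
        sq_red = ((y - red_oob) ** 2)[boot_idx].sum(axis=1)
        valid = tss > 0
        d_r2 = np.where(valid, (sq_red - sq_full) / np.where(valid, tss, 1.0), 0.0)
        d_rmse = np.sqrt(sq_red / n) - np.sqrt(sq_full / n)
        eps = 1e-8 * np.abs(yb).max(axis=1, keepdims=True)
        denom = np.maximum(np.abs(yb), eps)
        d_mape = 100.0 * (
            (np.abs(y - red_oob)[boot_idx] / denom).mean(axis=1)
            - (np.abs(y - full_oob)[boot_idx] / denom).mean(axis=1)
        )
        count_nonpos = np.array(
            [(d_r2 <= 0).sum(), (d_rmse <= 0).sum(), (d_mape <= 0).sum()], dtype=float
        )
        count_nonpos += (~valid).sum()
        return (1.0 + count_nonpos) / (n_boot + 1.0)


def cluster_importance(
    predictors: pd.DataFrame,
    responses: dict[str, pd.DataFrame],
    n_trees: int = 1000,
    n_boot: int = 4000,
    alpha: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Associate every predictor with each metabolome fraction.

    ``predictors``: samples x p DataFrame (eigengenes + unclustered genes,
    centered/scaled); ``responses``: fraction name -> samples x k tSNE
    scores.  Returns a long table with one row per predictor x fraction x
    component x metric plus per-predictor selection flags and the combined
    ``associated_fraction`` label (lcw / wax / both / none).
    """
    rows = []
    selected: dict[str, set[str]] = {name: set() for name in responses}
    Xs = (predictors - predictors.mean()) / predictors.std(ddof=1)
    for fraction, Y in responses.items():
        est = LocoForestImportance(n_trees, n_boot, alpha, seed).fit(
            Xs.to_numpy(), Y.to_numpy()
        )
        for j, pred in enumerate(predictors.columns):
            if est.selected_[j]:
                selected[fraction].add(pred)
            for c in range(Y.shape[1]):
                for mi, metric in enumerate(METRICS):
                    rows.append(
                        {
                            "predictor": pred,
                            "fraction": fraction,
                            "component": Y.columns[c],
                            "metric": metric,
                            "delta": est.delta_[j, c, mi],
                            "p": est.pvalues_[j, c, mi],
                            "q": est.qvalues_[j, c, mi],
                        }
                    )
    table = pd.DataFrame(rows)
    frac_names = list(responses)
    labels = {}
    for pred in predictors.columns:
        hits = [f for f in frac_names if pred in selected[f]]
        if len(hits) == len(frac_names) and len(frac_names) > 1:
            labels[pred] = "both"
        elif hits:
            labels[pred] = hits[0]
        else:
            labels[pred] = "none"
    table["associated_fraction"] = table["predictor"].map(labels)
    table.attrs["selected"] = {f: sorted(s) for f, s in selected.items()}
    table.attrs["association"] = labels
    return table
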