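"""Metabolome statistics: variance partitioning and low-dimensional embeddings.

Variance partitioning uses sequential (type-I) ANOVA with the term order
genotype -> organ -> genotype x organ; in the balanced design used here the
factors are orthogonal, so the partial R-squared values do not depend on the
order.  Embeddings follow the standard two-step recipe: PCA on standardized
features, then tSNE of the samples computed on the full PC score matrix.
The tSNE coordinates double as single-value response variables for the
downstream association models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .containers import ConfigurationError, OmicsMatrix

ANOVA_TERMS = ("genotype", "organ", "interaction")


@dataclass
class EmbeddingResult:
    scores: pd.DataFrame  # samples x components
    method: str
    explained_variance: np.ndarray | None = None
    seed: int | None = None


def anova_partition(y, metadata: pd.DataFrame) -> pd.Series:
    """Type-I ANOVA partial R-squared for genotype, organ and interaction.

    Returns a Series with ``partial_R2_{term}`` shares (summing to 1 with the
    residual) and ``p_{term}`` F-test p-values.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(y, dtype=float),
            "genotype": metadata["genotype"].to_numpy(),
            "organ": metadata["organ"].to_numpy(),
        }
    )
    if df["genotype"].nunique() < 2 or df["organ"].nunique() < 2:
        raise ConfigurationError("each factor needs >= 2 levels")
    cross = pd.crosstab(df["genotype"], df["organ"])
    if (cross == 0).any().any():
        raise ConfigurationError("genotype and organ are aliased (empty cells)")
    model = ols("y ~ C(genotype) + C(organ) + C(genotype):C(organ)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    ss = table["sum_sq"].to_numpy()
    total = ss.sum()
    if total == 0:
        raise ConfigurationError("response has zero variance")
    out = {}
    for term, row in zip(ANOVA_TERMS, table.index[:3]):
        out[f"partial_R2_{term}"] = float(table.loc[row, "sum_sq"] / total)
        out[f"p_{term}"] = float(table.loc[row, "PR(>F)"])
    out["partial_R2_residual"] = float(table.loc["Residual", "sum_sq"] / total)
    return pd.Series(out)


def class_abundance(metab: OmicsMatrix) -> pd.DataFrame:
    """Per-class abundance = sum of member metabolite concentrations per
    sample (classes x samples)."""
    if metab.feature_meta is None or "class" not in metab.feature_meta.columns:
        raise ConfigurationError("metabolite matrix lacks class annotation")
    cls = metab.feature_meta.loc[metab.feature_ids, "class"]
    return metab.data.groupby(cls.to_numpy()).sum()


def anova_partition_by_class(metab: OmicsMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """Class-level variance partitioning, one row per metabolite class."""
    abundance = class_abundance(metab)
    rows = {}
    for cname, y in abundance.iterrows():
        rows[cname] = anova_partition(y.to_numpy(), metadata)
    out = pd.DataFrame(rows).T
    out.index.name = "class"
    return out


# ---------------------------------------------------------------------------
# Tukey HSD with compact letter display
# ---------------------------------------------------------------------------

def tukey_hsd(y, groups, alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey HSD with a compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``.
    Returns one row per group (in first-appearance order) with columns
    ``group``, ``n``, ``mean``, ``letters``.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ConfigurationError("need >= 2 groups")
    samples = [y[groups == g] for g in labels]
    for g, s in zip(labels, samples):
        if len(s) < 2:
            raise ConfigurationError(f"group {g!r} has < 2 observations")
    res = sps.tukey_hsd(*samples)
    k = len(labels)
    significant = [
        (i, j) for i in range(k) for j in range(i + 1, k)
        if res.pvalue[i, j] < alpha
    ]
    letters = _compact_letter_display(k, significant)
    return pd.DataFrame(
        {
            "group": labels,
            "n": [len(s) for s in samples],
            "mean": [float(np.mean(s)) for s in samples],
            "letters": letters,
        }
    )


def _compact_letter_display(k: int, significant: list[tuple[int, int]]) -> list[str]:
    """Insert-and-absorb algorithm: columns are letters; a significant pair
    may never share a column.  Deterministic, ties broken by group order."""
    columns: list[set[int]] = [set(range(k))]
    for i, j in significant:
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            a, b = col - {j}, col - {i}
            for new in (a, b):
                if not any(new <= other for other in columns):
                    columns.append(new)
        columns = [c for c in columns if not any(c < other for other in columns)]
    # order columns by smallest member for a stable letter assignment
    columns.sort(key=lambda c: sorted(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = []
    for g in range(k):
        out.append("".join(alphabet[ci] for ci, c in enumerate(columns) if g in c))
    return out


def tukey_letters_by_class(
    metab: OmicsMatrix, metadata: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Genotype comparisons within each organ for each metabolite class."""
    abundance = class_abundance(metab)
    records = []
    for cname, y in abundance.iterrows():
        vals = y.to_numpy()
        for organ in dict.fromkeys(metadata["organ"]):
            mask = (metadata["organ"] == organ).to_numpy()
            table = tukey_hsd(vals[mask], metadata["genotype"].to_numpy()[mask], alpha)
            for _, row in table.iterrows():
                records.append(
                    {
                        "class": cname,
                        "organ": organ,
                        "genotype": row["group"],
                        "mean": row["mean"],
                        "letters": row["letters"],
                    }
                )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

def pca_embed(m: OmicsMatrix) -> EmbeddingResult:
    """PCA of samples from a standardized features x samples matrix.

    Keeps all components; explained variances are nonincreasing and sum to
    the total variance.  Deterministic up to per-PC sign (sklearn's
    deterministic sign convention is applied).
    """
    X = m.values.T  # samples x features
    if X.shape[0] < 2:
        raise ConfigurationError("PCA needs >= 2 samples")
    k = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    df = pd.DataFrame(
        scores, index=m.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return EmbeddingResult(df, "pca", explained_variance=pca.explained_variance_.copy())


def tsne_embed(
    m: OmicsMatrix, perplexity: float = 10.0, seed: int = 0, max_iter: int = 1000
) -> EmbeddingResult:
    """2-D tSNE of samples computed on the full PC score matrix.

    The embedding is deterministic for a fixed seed (exact-gradient tSNE
    with PCA initialization).
    """
    n = m.n_samples
    feasible = (n - 1) / 3.0
    if perplexity >= feasible:
        raise ConfigurationError(
            f"perplexity {perplexity} too large for n={n}; must be < {feasible:.2f}"
        )
    pcs = pca_embed(m).scores.to_numpy()
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        method="exact",
        max_iter=max_iter,
    )
    emb = tsne.fit_transform(pcs)
    df = pd.DataFrame(emb, index=m.sample_ids, columns=["tSNE1", "tSNE2"])
    return EmbeddingResult(df, "tsne", seed=seed)
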