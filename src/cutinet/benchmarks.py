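"""Self-contained evaluation protocols on synthetic data with known truth.

Each function generates its dataset, runs the relevant pipeline stages and
returns scalar quality metrics.  They are used both by the test suite and by
the acceptance script, so the protocol (problem sizes, analysis parameters)
is fixed here in one place; docs/methods.md records the choices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthdata as sd
from . import metabstats as ms
from . import coexpression as cx
from . import cluster_rf as crf
from . import gene_assoc as ga
from . import integrate
from .io import filter_low_expression, standardize

FRACTIONS = ("wax", "lcw")


def _tsne_scores(ds: sd.SyntheticDataset, seed: int) -> dict[str, pd.DataFrame]:
    return {
        fr: ms.tsne_embed(standardize(getattr(ds, f"metabolome_{fr}")), seed=seed).scores
        for fr in FRACTIONS
    }


def variance_partition_check(n_seeds: int = 20, seed: int = 0) -> dict:
    """Median wax-class organ and genotype partial R2 under the default
    generator, per seed; reports the across-seed medians and extremes."""
    organ, genotype = [], []
    for s in range(n_seeds):
        ds_cfg = sd.default_config(seed=seed + s)
        ds = sd.generate_dataset(ds_cfg)
        tab = ms.anova_partition_by_class(ds.metabolome_wax, ds.metadata)
        organ.append(float(np.median(tab["partial_R2_organ"])))
        genotype.append(float(np.median(tab["partial_R2_genotype"])))
    return {
        "organ_median": float(np.median(organ)),
        "organ_min": min(organ),
        "organ_max": max(organ),
        "genotype_median": float(np.median(genotype)),
        "genotype_max": max(genotype),
        "n_seeds": n_seeds,
    }


def module_recovery(n_seeds: int = 10, seed: int = 0) -> dict:
    """Adjusted Rand index of detected vs planted modules (3 modules among
    2000 genes) and the clustered + unclustered bookkeeping identity."""
    from sklearn.metrics import adjusted_rand_score

    aris = []
    bookkeeping_ok = True
    for s in range(n_seeds):
        ds = sd.generate_dataset(sd.default_config(seed=seed + s))
        expr = standardize(filter_low_expression(ds.expression))
        mset, _ = cx.fit_module_set(expr)
        truth = np.array([ds.truth.module_membership[g] for g in expr.feature_ids])
        aris.append(float(adjusted_rand_score(truth, mset.labels.to_numpy())))
        counts_sum = int((mset.labels != 0).sum() + (mset.labels == 0).sum())
        bookkeeping_ok &= counts_sum == expr.n_features
    return {
        "ari_mean": float(np.mean(aris)),
        "ari_min": min(aris),
        "bookkeeping_ok": bookkeeping_ok,
        "n_seeds": n_seeds,
    }


def null_calibration(seed: int = 0, n_perm: int = 199, n_bags: int = 100) -> dict:
    """Fraction of genes with permutation p < 0.01 per model on a global-null
    dataset (no gene-metabolite links, expression independent of metabolome)."""
    ds = sd.generate_dataset(sd.null_config(seed=seed))
    expr = filter_low_expression(ds.expression)
    tsne = _tsne_scores(ds, seed=1)
    cfg = ga.GeneAssocConfig(n_perm=n_perm, n_bags=n_bags, seed=seed + 1)
    table = ga.run_gene_association(
        expr, {fr: getattr(ds, f"metabolome_{fr}") for fr in FRACTIONS}, tsne, cfg
    )
    out = {"n_genes": expr.n_features}
    for model in ("pls", "spls", "rglm"):
        sub = table[table.model == model]
        out[f"{model}_p_rate"] = float((sub.p < 0.01).mean())
        out[f"{model}_select_rate"] = float(
            sub.groupby(["gene", "fraction"])["selected"].any().mean()
        )
    return out


def rf_noise_selection_rate(
    n_replicates: int = 100, seed: int = 0, n_trees: int = 100, n_boot: int = 4000
) -> dict:
    """How often the cluster-RF stage flags a pure-noise predictor among 20
    (three informative predictors drive the response)."""
    hits = 0
    n = 72
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        X = rng.normal(size=(n, 20))
        y = X[:, 0] + 0.8 * X[:, 1] + 0.5 * X[:, 2] + 0.5 * rng.normal(size=n)
        est = crf.LocoForestImportance(
            n_trees=n_trees, n_boot=n_boot, alpha=0.01, seed=seed + r
        ).fit(X, y)
        hits += bool(est.selected_[19])
    return {"rate": hits / n_replicates, "n_replicates": n_replicates}


def association_recovery(seed: int = 0, n_perm: int = 199, n_bags: int = 150) -> dict:
    """Sensitivity and false-discovery proportion of the putative-gene union
    on the association benchmark (40 planted genes per fraction among 2000)."""
    ds = sd.generate_dataset(sd.association_benchmark_config(seed=seed))
    expr = filter_low_expression(ds.expression)
    tsne = _tsne_scores(ds, seed=1)
    cfg = ga.GeneAssocConfig(n_perm=n_perm, n_bags=n_bags, seed=seed + 1)
    table = ga.run_gene_association(
        expr, {fr: getattr(ds, f"metabolome_{fr}") for fr in FRACTIONS}, tsne, cfg
    )
    put = table.attrs["putative"]
    tp = sel = truth_n = 0
    for fr in FRACTIONS:
        truth = getattr(ds.truth, f"assoc_genes_{fr}")
        tp += len(put[fr] & truth)
        sel += len(put[fr])
        truth_n += len(truth)
    return {
        "sensitivity": tp / truth_n,
        "fdp": (sel - tp) / max(sel, 1),
        "n_genes": expr.n_features,
        "n_planted": truth_n,
    }


def network_recovery(
    seed: int = 0,
    n_perm: int = 99,
    n_bags: int = 150,
    n_trees: int = 800,
    n_boot: int = 8000,
    n_loco_genes: int = 5,
) -> dict:
    """End-to-end run on the network benchmark: module detection, cluster-RF
    association, gene association and network integration; reports the
    fraction of planted both-fraction genes recovered as network nodes."""
    ds = sd.generate_dataset(sd.network_benchmark_config(seed=seed))
    expr = filter_low_expression(ds.expression)
    expr_std = standardize(expr)
    tsne = _tsne_scores(ds, seed=1)
    trait = np.hstack([tsne[fr].to_numpy() for fr in FRACTIONS])
    mset, est = cx.fit_module_set(expr_std, trait_scores=trait)

    cols = {
        f"cluster_{m}": mset.eigengenes.loc[m].to_numpy()
        for m in range(1, mset.n_modules + 1)
    }
    unclustered = [g for g in mset.labels.index if mset.labels[g] == 0]
    sub = expr_std.data.loc[unclustered]
    for g in sub.var(axis=1).sort_values(ascending=False).index[:n_loco_genes]:
        cols[str(g)] = expr_std.data.loc[g].to_numpy()
    predictors = pd.DataFrame(cols, index=expr_std.sample_ids)
    rf_table = crf.cluster_importance(
        predictors,
        {fr: tsne[fr] for fr in FRACTIONS},
        n_trees=n_trees,
        n_boot=n_boot,
        seed=seed + 7,
    )
    selected_clusters = {
        fr: {
            int(p.split("_")[1])
            for p in rf_table.attrs["selected"][fr]
            if p.startswith("cluster_")
        }
        for fr in FRACTIONS
    }
    cfg = ga.GeneAssocConfig(n_perm=n_perm, n_bags=n_bags, seed=seed + 3)
    table = ga.run_gene_association(
        expr, {fr: getattr(ds, f"metabolome_{fr}") for fr in FRACTIONS}, tsne, cfg
    )
    networks = integrate.build_network(
        table.attrs["putative"], mset, selected_clusters, est.tom_, expr_std.feature_ids
    )
    nodes = set().union(*[set(G.nodes) for G in networks.values()])
    both = {
        g for g in ds.truth.categories()["both"] if ds.truth.module_membership[g] > 0
    }
    return {
        "sensitivity": len(nodes & both) / max(len(both), 1),
        "n_planted_both": len(both),
        "n_nodes": {cat: G.number_of_nodes() for cat, G in networks.items()},
        "clusters_selected": {fr: sorted(s) for fr, s in selected_clusters.items()},
    }
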