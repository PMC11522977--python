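"""Intersection of the two pipelines into gene networks, plus enrichment.

The cluster pipeline nominates metabolome-associated co-expression clusters;
the multi-omics pipeline nominates putative genes.  A network node must pass
both: the gene is putative for a fraction AND resides in a cluster selected
for that fraction.  Genes split into three disjoint categories (lcw-only,
wax-only, both) and edges connect within-cluster pairs whose topological
overlap reaches the cluster's upper quantile.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import ConfigurationError
from .coexpression import ModuleSet

logger = logging.getLogger(__name__)

CATEGORIES = ("lcw", "wax", "both")


def classify_associations(lcw_set, wax_set) -> dict[str, set[str]]:
    """Disjoint categories: lcw-only, wax-only, both."""
    L, W = set(lcw_set), set(wax_set)
    return {"lcw": L - W, "wax": W - L, "both": L & W}


def build_network(
    putative: dict[str, set[str]],
    module_set: ModuleSet,
    cluster_selected: dict[str, set[int]],
    tom: np.ndarray,
    gene_index: list[str],
    edge_quantile: float = 0.95,
) -> dict[str, nx.Graph]:
    """One weighted co-expression network per association category.

    ``putative`` maps fraction -> putative gene set; ``cluster_selected``
    maps fraction -> cluster ids selected by the cluster-RF stage.  A gene
    in category "both" needs its cluster selected for both fractions; edges
    join within-cluster node pairs whose TOM is at or above the
    ``edge_quantile`` of that cluster's full within-cluster TOM distribution
    (ties included).
    """
    categories = classify_associations(putative.get("lcw", set()), putative.get("wax", set()))
    idx_of = {g: i for i, g in enumerate(gene_index)}
    labels = module_set.labels
    hub = module_set.hub_flags
    networks: dict[str, nx.Graph] = {}
    for cat in CATEGORIES:
        required = ("lcw", "wax") if cat == "both" else (cat,)
        nodes = []
        for g in sorted(categories[cat]):
            if g not in labels.index:
                continue
            cluster = int(labels.loc[g])
            if cluster == 0:
                continue
            if all(cluster in cluster_selected.get(f, set()) for f in required):
                nodes.append(g)
        G = nx.Graph(category=cat)
        for g in nodes:
            cluster = int(labels.loc[g])
            G.add_node(
                g,
                cluster=cluster,
                cls=int(module_set.class_of.get(cluster, 0)),
                is_hub=bool(hub.loc[g]) if hub is not None else False,
                category=cat,
            )
        # edges within clusters, thresholded on the cluster TOM quantile
        by_cluster: dict[int, list[str]] = {}
        for g in nodes:
            by_cluster.setdefault(int(labels.loc[g]), []).append(g)
        for cluster, members in by_cluster.items():
            cluster_genes = [g for g in labels.index[labels == cluster] if g in idx_of]
            cidx = [idx_of[g] for g in cluster_genes]
            block = tom[np.ix_(cidx, cidx)]
            off = block[np.triu_indices(len(cidx), 1)]
            if off.size == 0:
                continue
            thresh = float(np.quantile(off, edge_quantile))
            for i, gi in enumerate(members):
                for gj in members[i + 1 :]:
                    w = float(tom[idx_of[gi], idx_of[gj]])
                    if w >= thresh:
                        G.add_edge(gi, gj, weight=w)
        if G.number_of_nodes() == 0:
            logger.warning("category %r network is empty", cat)
        networks[cat] = G
    return networks


def network_tables(networks: dict[str, nx.Graph]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten category networks into node and edge tables."""
    node_rows, edge_rows = [], []
    for cat, G in networks.items():
        for g, attrs in sorted(G.nodes(data=True)):
            node_rows.append({"gene": g, **{k: v for k, v in attrs.items()}})
        for a, b, attrs in sorted(G.edges(data=True)):
            edge_rows.append(
                {"category": cat, "source": a, "target": b, "weight": attrs["weight"]}
            )
    cols_nodes = ["gene", "cluster", "cls", "is_hub", "category"]
    nodes = pd.DataFrame(node_rows, columns=cols_nodes)
    edges = pd.DataFrame(edge_rows, columns=["category", "source", "target", "weight"])
    return nodes, edges


def write_graphml(networks: dict[str, nx.Graph], out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    for cat, G in networks.items():
        nx.write_graphml(G, out / f"network_{cat}.graphml")


def fisher_enrichment(
    selected,
    background,
    annotation: dict[str, set[str]],
    alpha: float = 0.05,
    min_term_size: int = 3,
) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric tail) term enrichment with BH control.

    ``selected`` must be a subset of ``background``; terms with fewer than
    ``min_term_size`` background genes are skipped.
    """
    selected, background = set(selected), set(background)
    if not selected <= background:
        raise ConfigurationError("selected genes must be a subset of the background")
    N, n = len(background), len(selected)
    term_genes: dict[str, set[str]] = {}
    for gene in background:
        for term in annotation.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)
    rows = []
    for term in sorted(term_genes):
        K = len(term_genes[term])
        if K < min_term_size:
            continue
        k = len(term_genes[term] & selected)
        p = float(hypergeom.sf(k - 1, N, K, n))
        denom = (K - k) * (n - k)
        odds = (k * (N - K - n + k)) / denom if denom > 0 else np.inf
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "odds_ratio": odds, "p": p})
    table = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "odds_ratio", "p"])
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = table["q"] < alpha
    else:
        table["q"] = []
        table["significant"] = []
    return table
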