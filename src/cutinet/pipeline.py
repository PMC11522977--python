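"""End-to-end pipeline orchestration with resumable stages and a manifest.

Stage order: simulate/load -> preprocess -> metabstats -> coexpress ->
cluster_assoc -> gene_assoc -> integrate -> enrich.  Every stage writes its
outputs before the next starts, so a failure leaves completed stages intact
and ``--from STAGE`` can resume from on-disk intermediates.  The manifest
records the config echo, package version, per-stage output checksums and
headline counts; it contains nothing volatile, so two runs with the same
config and seed produce byte-identical manifests and tables (wall-clock
timings go to the log only).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ConfigurationError
from . import io as dataio
from . import synthdata
from . import metabstats
from . import coexpression
from . import cluster_rf
from . import gene_assoc as ga
from . import integrate

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "preprocess",
    "metabstats",
    "coexpress",
    "cluster_assoc",
    "gene_assoc",
    "integrate",
    "enrich",
)

FRACTIONS = ("wax", "lcw")


@dataclass
class RunConfig:
    """Validated run configuration; every stochastic stage has an explicit
    seed derived from the single top-level ``seed``."""

    seed: int
    simulate: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # alternative to simulate
    filter_min_fraction: float = 0.5
    fpkm_threshold: float = 100.0
    tsne_perplexity: float = 10.0
    beta: float = 16.0
    min_module_size: int = 30
    deep_split: int = 2
    merge_cut_height: float = 0.25
    cut_fraction: float = 0.99
    r_min: float = 0.5
    target_frac: float = 0.05
    eigen_cor_min: float = 0.8
    n_trees: int = 1000
    n_boot: int = 4000
    rf_alpha: float = 0.01
    max_loco_genes: int = 30
    n_perm: int = 199
    n_bags: int = 500
    candidate_frac: float = 0.2
    keep_frac: float = 0.1
    max_components: int = 10
    s_min: float = 1.0
    p_max: float = 0.01
    edge_quantile: float = 0.95
    enrich_alpha: float = 0.05
    min_term_size: int = 3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("config must specify an integer seed")
        for name, lo, hi in (
            ("filter_min_fraction", 0.0, 1.0),
            ("edge_quantile", 0.0, 1.0),
            ("p_max", 0.0, 1.0),
            ("rf_alpha", 0.0, 1.0),
            ("enrich_alpha", 0.0, 1.0),
            ("keep_frac", 0.0, 1.0),
            ("candidate_frac", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigurationError(f"{name}={v} outside [{lo}, {hi}]")
        if not self.simulate and not self.inputs:
            raise ConfigurationError("config needs either a 'simulate' or an 'inputs' block")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ConfigurationError("config must specify an integer seed")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        children = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        return int(children[STAGES.index(stage)].generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRun:
    """Holds in-memory state across stages plus the output directory."""

    def __init__(self, config: RunConfig, out_dir):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.state: dict = {}
        self.manifest: dict = {
            "version": __version__,
            "config": dataclasses.asdict(config),
            "stages": {},
            "counts": {},
        }

    # -- helpers -------------------------------------------------------------
    def _record(self, stage: str, paths: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            p.name: _sha256(p) for p in sorted(paths, key=lambda q: q.name)
        }

    def _write_table(self, df: pd.DataFrame, name: str, index=False, header_comment=None):
        path = self.out / name
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, sep="\t", index=index)
        return path

    # -- stages --------------------------------------------------------------
    def stage_simulate(self):
        cfg = self.config
        if cfg.inputs:
            st = self.state
            st["metadata"] = dataio.load_metadata(cfg.inputs["metadata"])
            st["expression"] = dataio.load_matrix(cfg.inputs["expression"], "expression")
            for fr in FRACTIONS:
                m = dataio.load_matrix(cfg.inputs[f"metabolome_{fr}"], "metabolite")
                classes_path = cfg.inputs.get(f"metabolite_classes_{fr}")
                if classes_path:
                    m.feature_meta = pd.read_csv(classes_path, sep="\t", index_col=0)
                st[f"metab_{fr}"] = m
            st["annotation"] = (
                dataio.load_annotation(cfg.inputs["annotation"])
                if "annotation" in cfg.inputs
                else None
            )
            st["truth"] = None
            self._record("simulate", [])
            return
        params = dict(cfg.simulate)
        params.setdefault("seed", cfg.stage_seed("simulate"))
        design = synthdata.DesignConfig(**params)
        ds = synthdata.generate_dataset(design)
        data_dir = self.out / "data"
        synthdata.write_dataset(ds, data_dir)
        self.state.update(
            metadata=ds.metadata,
            expression=ds.expression,
            metab_wax=ds.metabolome_wax,
            metab_lcw=ds.metabolome_lcw,
            truth=ds.truth,
            annotation=ds.annotation,
        )
        self._record("simulate", sorted(data_dir.iterdir()))
        self.manifest["counts"]["n_samples"] = len(ds.metadata)
        self.manifest["counts"]["n_genes_input"] = ds.expression.n_features

    def load_simulate(self):
        data_dir = self.out / "data"
        if self.config.inputs:
            return self.stage_simulate()
        ds = synthdata.load_dataset(data_dir)
        self.state.update(
            metadata=ds.metadata,
            expression=ds.expression,
            metab_wax=ds.metabolome_wax,
            metab_lcw=ds.metabolome_lcw,
            truth=ds.truth,
            annotation=ds.annotation,
        )

    def stage_preprocess(self):
        st = self.state
        matrices = [st["expression"], st["metab_wax"], st["metab_lcw"]]
        (expr, wax, lcw), md = dataio.align_samples(matrices, st["metadata"])
        wax.feature_meta = st["metab_wax"].feature_meta
        lcw.feature_meta = st["metab_lcw"].feature_meta
        st.update(metadata=md, metab_wax=wax, metab_lcw=lcw)
        filtered = dataio.filter_low_expression(expr, self.config.filter_min_fraction)
        st["expr_filtered"] = filtered
        paths = [self.out / "expression_filtered.tsv"]
        dataio.write_matrix(filtered, paths[0])
        high, low = dataio.stratify_by_expression(filtered, self.config.fpkm_threshold)
        strata = pd.DataFrame(
            {
                "gene": filtered.feature_ids,
                "stratum": ["high" if g in set(high.feature_ids) else "low"
                            for g in filtered.feature_ids],
            }
        )
        paths.append(self._write_table(strata, "strata.tsv"))
        self._record("preprocess", paths)
        self.manifest["counts"]["n_genes_filtered"] = filtered.n_features

    def load_preprocess(self):
        st = self.state
        st["expr_filtered"] = dataio.load_matrix(
            self.out / "expression_filtered.tsv", "expression"
        )

    def stage_metabstats(self):
        st = self.state
        cfg = self.config
        paths = []
        seed = cfg.stage_seed("metabstats")
        st["tsne"] = {}
        for fr in FRACTIONS:
            metab = st[f"metab_{fr}"]
            anova = metabstats.anova_partition_by_class(metab, st["metadata"])
            paths.append(self._write_table(anova, f"anova_{fr}.tsv", index=True))
            tukey = metabstats.tukey_letters_by_class(metab, st["metadata"])
            paths.append(self._write_table(tukey, f"tukey_{fr}.tsv"))
            std = dataio.standardize(metab)
            pca = metabstats.pca_embed(std)
            paths.append(self._write_table(pca.scores, f"pca_{fr}.tsv", index=True))
            tsne = metabstats.tsne_embed(std, cfg.tsne_perplexity, seed=seed)
            st["tsne"][fr] = tsne.scores
            paths.append(
                self._write_table(
                    tsne.scores, f"tsne_{fr}.tsv", index=True, header_comment=f"seed={seed}"
                )
            )
        self._record("metabstats", paths)

    def load_metabstats(self):
        self.state["tsne"] = {
            fr: pd.read_csv(self.out / f"tsne_{fr}.tsv", sep="\t", index_col=0, comment="#")
            for fr in FRACTIONS
        }

    def _trait_matrix(self) -> np.ndarray:
        return np.hstack([self.state["tsne"][fr].to_numpy() for fr in FRACTIONS])

    def stage_coexpress(self):
        st = self.state
        cfg = self.config
        expr_std = dataio.standardize(st["expr_filtered"])
        st["expr_std"] = expr_std
        mset, est = coexpression.fit_module_set(
            expr_std,
            trait_scores=self._trait_matrix(),
            target_frac=cfg.target_frac,
            eigen_cor_min=cfg.eigen_cor_min,
            beta=cfg.beta,
            min_module_size=cfg.min_module_size,
            deep_split=cfg.deep_split,
            merge_cut_height=cfg.merge_cut_height,
            cut_fraction=cfg.cut_fraction,
            r_min=cfg.r_min,
        )
        st["module_set"] = mset
        st["tom"] = est.tom_
        np.save(self.out / "tom.npy", est.tom_)
        modules = pd.DataFrame(
            {
                "gene": mset.labels.index,
                "cluster": mset.labels.to_numpy(),
                "class": [mset.class_of.get(int(m), 0) for m in mset.labels],
                "is_hub": (
                    mset.hub_flags.to_numpy()
                    if mset.hub_flags is not None
                    else np.zeros(len(mset.labels), dtype=bool)
                ),
            }
        )
        if mset.diagnostics is not None:
            modules["eigengene_cor"] = mset.diagnostics["eigengene_cor"].to_numpy()
            modules["connectivity"] = mset.diagnostics["connectivity"].to_numpy()
        paths = [self._write_table(modules, "modules.tsv")]
        eig = mset.eigengenes.copy()
        eig.index.name = "cluster"
        paths.append(self._write_table(eig, "eigengenes.tsv", index=True))
        cutoffs = pd.DataFrame(
            [
                {"cluster": m, "cutoff": c, "n_hub": n}
                for m, (c, n) in sorted(mset.cutoffs.items())
            ],
            columns=["cluster", "cutoff", "n_hub"],
        )
        paths.append(self._write_table(cutoffs, "hub_cutoffs.tsv"))
        self._record("coexpress", paths)
        counts = self.manifest["counts"]
        counts["n_clusters"] = mset.n_modules
        counts["n_unclustered"] = int((mset.labels == 0).sum())
        counts["n_clustered"] = int((mset.labels != 0).sum())
        counts["n_hub_genes"] = (
            int(mset.hub_flags.sum()) if mset.hub_flags is not None else 0
        )

    def load_coexpress(self):
        st = self.state
        st["expr_std"] = dataio.standardize(st["expr_filtered"])
        modules = pd.read_csv(self.out / "modules.tsv", sep="\t")
        labels = pd.Series(
            modules["cluster"].to_numpy(), index=modules["gene"], name="module"
        )
        eig = pd.read_csv(self.out / "eigengenes.tsv", sep="\t", index_col=0)
        class_of = dict(zip(modules["cluster"], modules["class"]))
        class_of.pop(0, None)
        mset = coexpression.ModuleSet(
            labels, eig, {int(k): int(v) for k, v in class_of.items()}, np.empty((0, 4))
        )
        mset.hub_flags = pd.Series(
            modules["is_hub"].to_numpy(dtype=bool), index=modules["gene"], name="is_hub"
        )
        st["module_set"] = mset
        st["tom"] = np.load(self.out / "tom.npy")

    def stage_cluster_assoc(self):
        st = self.state
        cfg = self.config
        mset: coexpression.ModuleSet = st["module_set"]
        expr_std = st["expr_std"]
        sample_ids = expr_std.sample_ids
        cols = {}
        for m in range(1, mset.n_modules + 1):
            cols[f"cluster_{m}"] = mset.eigengenes.loc[m].to_numpy()
        unclustered = [g for g in mset.labels.index if mset.labels.loc[g] == 0]
        # cap the individually tested unclustered genes (most variable first)
        if unclustered:
            sub = expr_std.data.loc[[g for g in unclustered if g in expr_std.data.index]]
            order = sub.var(axis=1).sort_values(ascending=False).index
            for g in order[: cfg.max_loco_genes]:
                cols[str(g)] = expr_std.data.loc[g].to_numpy()
        predictors = pd.DataFrame(cols, index=sample_ids)
        responses = {fr: st["tsne"][fr] for fr in FRACTIONS}
        table = cluster_rf.cluster_importance(
            predictors,
            responses,
            n_trees=cfg.n_trees,
            n_boot=cfg.n_boot,
            alpha=cfg.rf_alpha,
            seed=cfg.stage_seed("cluster_assoc"),
        )
        st["cluster_assoc"] = table
        paths = [self._write_table(table, "cluster_associations.tsv")]
        sidecar = {
            "selected": table.attrs["selected"],
            "association": table.attrs["association"],
            "n_trees": cfg.n_trees,
            "n_boot": cfg.n_boot,
            "alpha": cfg.rf_alpha,
        }
        side_path = self.out / "cluster_associations.json"
        side_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
        paths.append(side_path)
        self._record("cluster_assoc", paths)
        sel = {
            fr: sorted(
                int(p.split("_")[1]) for p in table.attrs["selected"][fr]
                if p.startswith("cluster_")
            )
            for fr in FRACTIONS
        }
        self.manifest["counts"]["clusters_selected"] = sel

    def load_cluster_assoc(self):
        sidecar = json.loads((self.out / "cluster_associations.json").read_text())
        table = pd.read_csv(self.out / "cluster_associations.tsv", sep="\t")
        table.attrs["selected"] = {k: set(v) for k, v in sidecar["selected"].items()}
        table.attrs["association"] = sidecar["association"]
        self.state["cluster_assoc"] = table

    def stage_gene_assoc(self):
        st = self.state
        cfg = self.config
        assoc_cfg = ga.GeneAssocConfig(
            fpkm_threshold=cfg.fpkm_threshold,
            n_perm=cfg.n_perm,
            s_min=cfg.s_min,
            p_max=cfg.p_max,
            max_components=cfg.max_components,
            keep_frac=cfg.keep_frac,
            n_bags=cfg.n_bags,
            candidate_frac=cfg.candidate_frac,
            seed=cfg.stage_seed("gene_assoc"),
        )
        table = ga.run_gene_association(
            st["expr_filtered"],
            {fr: st[f"metab_{fr}"] for fr in FRACTIONS},
            st["tsne"],
            assoc_cfg,
        )
        st["gene_assoc"] = table
        paths = [self._write_table(table, "gene_associations.tsv")]
        self._record("gene_assoc", paths)
        counts = self.manifest["counts"]
        for model in ("pls", "spls", "rglm"):
            sub = table[(table["model"] == model) & table["selected"]]
            counts[f"selected_{model}"] = int(sub["gene"].nunique())
        counts["putative_per_fraction"] = {
            fr: len(s) for fr, s in table.attrs["putative"].items()
        }

    def load_gene_assoc(self):
        table = pd.read_csv(self.out / "gene_associations.tsv", sep="\t")
        table.attrs["putative"] = {
            fr: set(table[(table["fraction"] == fr) & table["selected"]]["gene"])
            for fr in FRACTIONS
        }
        self.state["gene_assoc"] = table

    def stage_integrate(self):
        st = self.state
        cfg = self.config
        putative = st["gene_assoc"].attrs["putative"]
        selected = {
            fr: {
                int(p.split("_")[1])
                for p in st["cluster_assoc"].attrs["selected"][fr]
                if p.startswith("cluster_")
            }
            for fr in FRACTIONS
        }
        networks = integrate.build_network(
            putative,
            st["module_set"],
            selected,
            st["tom"],
            st["expr_std"].feature_ids,
            edge_quantile=cfg.edge_quantile,
        )
        st["networks"] = networks
        nodes, edges = integrate.network_tables(networks)
        paths = [
            self._write_table(nodes, "network_nodes.tsv"),
            self._write_table(edges, "network_edges.tsv"),
        ]
        integrate.write_graphml(networks, self.out)
        paths += [self.out / f"network_{cat}.graphml" for cat in networks]
        self._record("integrate", paths)
        self.manifest["counts"]["network_nodes"] = {
            cat: G.number_of_nodes() for cat, G in networks.items()
        }
        self.manifest["counts"]["network_edges"] = {
            cat: G.number_of_edges() for cat, G in networks.items()
        }

    def load_integrate(self):
        nodes = pd.read_csv(self.out / "network_nodes.tsv", sep="\t")
        self.state["network_nodes"] = nodes

    def stage_enrich(self):
        st = self.state
        cfg = self.config
        annotation = st.get("annotation")
        paths = []
        if annotation is None:
            logger.warning("no annotation available; enrichment skipped")
            self._record("enrich", paths)
            return
        background = set(st["expr_filtered"].feature_ids)
        if "networks" in st:
            node_sets = {
                cat: set(G.nodes) for cat, G in st["networks"].items()
            }
        else:
            nodes = st["network_nodes"]
            node_sets = {
                cat: set(nodes[nodes["category"] == cat]["gene"])
                for cat in integrate.CATEGORIES
            }
        for cat, genes in node_sets.items():
            table = integrate.fisher_enrichment(
                genes & background,
                background,
                annotation,
                alpha=cfg.enrich_alpha,
                min_term_size=cfg.min_term_size,
            )
            paths.append(self._write_table(table, f"enrichment_{cat}.tsv"))
        self._record("enrich", paths)

    # -- driver ----------------------------------------------------------------
    STAGE_FUNCS = {
        "simulate": ("stage_simulate", "load_simulate"),
        "preprocess": ("stage_preprocess", "load_preprocess"),
        "metabstats": ("stage_metabstats", "load_metabstats"),
        "coexpress": ("stage_coexpress", "load_coexpress"),
        "cluster_assoc": ("stage_cluster_assoc", "load_cluster_assoc"),
        "gene_assoc": ("stage_gene_assoc", "load_gene_assoc"),
        "integrate": ("stage_integrate", "load_integrate"),
        "enrich": ("stage_enrich", None),
    }

    def run(self, from_stage: str | None = None, to_stage: str | None = None):
        start_idx = STAGES.index(from_stage) if from_stage else 0
        end_idx = STAGES.index(to_stage) if to_stage else len(STAGES) - 1
        if from_stage:
            # resume: rebuild in-memory state from completed stage outputs
            self.load_simulate()
            for stage in STAGES[:start_idx]:
                if stage == "simulate":
                    continue
                loader = self.STAGE_FUNCS[stage][1]
                if loader:
                    getattr(self, loader)()
        for stage in STAGES[start_idx : end_idx + 1]:
            t0 = time.perf_counter()
            try:
                getattr(self, self.STAGE_FUNCS[stage][0])()
            except Exception as exc:
                raise ConfigurationError(
                    f"stage {stage!r} failed: {exc}; completed-stage outputs are intact"
                ) from exc
            logger.info("stage %s finished in %.1fs", stage, time.perf_counter() - t0)
        manifest_path = self.out / "manifest.json"
        manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return self.manifest


def run_pipeline(
    config: RunConfig,
    out_dir,
    from_stage: str | None = None,
    to_stage: str | None = None,
    force: bool = False,
) -> dict:
    """Run (or resume) the full pipeline; returns the manifest dict."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force and from_stage is None:
        raise ConfigurationError(
            f"output directory {out} is not empty (use force=True to overwrite)"
        )
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("cutinet")
    root.addHandler(handler)
    try:
        run = PipelineRun(config, out)
        return run.run(from_stage=from_stage, to_stage=to_stage)
    finally:
        root.removeHandler(handler)
        handler.close()
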