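"""Synthetic transcriptome + cuticle-metabolome generator with known truth.

The generator emulates a maize-seedling multi-omics design: 6 organs x 4
genotypes x 3 replicates (72 samples), an FPKM-scale expression matrix with
planted organ-driven co-expression modules, and two metabolite fractions
(cuticular waxes and lipidized cell-wall monomers) whose variance is
dominated by organ identity, with genotype and organ x genotype playing
smaller roles.  A configurable set of genes is causally linked to metabolites
through planted standardized slopes, giving every downstream stage a ground
truth to recover.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence` spawning; identical config + seed gives a
bit-identical dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ConfigurationError,
    DEFAULT_GENOTYPES,
    DEFAULT_ORGANS,
    OmicsMatrix,
)
from . import io as dataio

WAX_CLASSES = (
    "VLCFA",
    "fatty-alcohol",
    "fatty-aldehyde",
    "wax-ester",
    "hydrocarbon",
    "terpene",
)
LCW_CLASSES = (
    "fatty-acid",
    "omega-hydroxy-fatty-acid",
    "dicarboxylic-acid",
    "2-hydroxy-fatty-acid",
    "phenolic",
)


@dataclass
class DesignConfig:
    """All knobs of the synthetic study design.

    Effect sizes are standard deviations of Gaussian effects on the
    (standardized-core) metabolite scale; ``organ_effect_sd`` etc. apply to
    the wax fraction, the ``lcw_*`` counterparts to the LCW fraction.
    ``assoc_effect`` is the standardized slope linking an associated gene's
    expression z-score to each of its target metabolites.
    """

    organs: tuple[str, ...] = DEFAULT_ORGANS
    genotypes: tuple[str, ...] = DEFAULT_GENOTYPES
    n_reps: int = 3
    n_genes: int = 2000
    n_modules: int = 3
    module_sizes: tuple[int, ...] | None = (200, 150, 100)
    within_module_share: float = 0.72
    module_rep_sd: float = 0.4
    module_genotype_frac: float = 0.34
    module_genotype_sd: float = 0.5
    bg_organ_sd: float = 0.3
    log10_loc: float = 1.0
    log10_scale: float = 0.8
    log10_dynamic: float = 0.3
    sparse_gene_frac: float = 0.05
    sparse_dropout: float = 0.6
    n_metabolites_per_fraction: int = 48
    organ_effect_sd: float = 2.2
    genotype_effect_sd: float = 0.35
    interaction_effect_sd: float = 0.35
    noise_sd: float = 1.0
    lcw_organ_sd: float = 1.2
    lcw_genotype_sd: float = 0.75
    lcw_interaction_sd: float = 0.7
    lcw_noise_sd: float = 0.9
    n_assoc_genes: int = 40
    n_assoc_both: int = 10
    assoc_effect: float = 1.5
    metabolites_per_gene: int = 2
    assoc_in_modules: bool = True
    assoc_group_size: int = 10
    assoc_group_share: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.organs or not self.genotypes:
            raise ConfigurationError("organ and genotype lists must be non-empty")
        if len(set(self.organs)) != len(self.organs):
            raise ConfigurationError("duplicate organ label in config")
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ConfigurationError("duplicate genotype label in config")
        if self.n_reps < 2:
            raise ConfigurationError("n_reps must be >= 2")
        if self.module_sizes is None:
            self.module_sizes = ()
        self.module_sizes = tuple(int(s) for s in self.module_sizes)[: self.n_modules]
        if len(self.module_sizes) < self.n_modules:
            raise ConfigurationError("module_sizes shorter than n_modules")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError("sum(module_sizes) exceeds n_genes")
        for name in (
            "organ_effect_sd", "genotype_effect_sd", "interaction_effect_sd",
            "noise_sd", "lcw_organ_sd", "lcw_genotype_sd", "lcw_interaction_sd",
            "lcw_noise_sd", "module_rep_sd", "bg_organ_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.organ_effect_sd <= self.genotype_effect_sd:
            raise ConfigurationError(
                "organ_effect_sd must exceed genotype_effect_sd (organ-dominant design)"
            )
        if not 0 < self.within_module_share <= 1:
            raise ConfigurationError("within_module_share must be in (0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.organs) * len(self.genotypes) * self.n_reps


@dataclass
class GroundTruth:
    """Planted structure: module membership, associated gene sets and slopes."""

    module_membership: dict[str, int]
    assoc_genes_lcw: set[str]
    assoc_genes_wax: set[str]
    effect_map: dict[tuple[str, str], float] = field(default_factory=dict)

    def categories(self) -> dict[str, set[str]]:
        both = self.assoc_genes_lcw & self.assoc_genes_wax
        return {
            "lcw": self.assoc_genes_lcw - both,
            "wax": self.assoc_genes_wax - both,
            "both": both,
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "module_membership": self.module_membership,
                "assoc_genes_lcw": sorted(self.assoc_genes_lcw),
                "assoc_genes_wax": sorted(self.assoc_genes_wax),
                "effect_map": [
                    [g, m, s] for (g, m), s in sorted(self.effect_map.items())
                ],
            },
            indent=0,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(
            module_membership=dict(obj["module_membership"]),
            assoc_genes_lcw=set(obj["assoc_genes_lcw"]),
            assoc_genes_wax=set(obj["assoc_genes_wax"]),
            effect_map={(g, m): s for g, m, s in obj["effect_map"]},
        )


@dataclass
class SyntheticDataset:
    metadata: pd.DataFrame
    expression: OmicsMatrix
    metabolome_wax: OmicsMatrix
    metabolome_lcw: OmicsMatrix
    truth: GroundTruth
    annotation: dict[str, set[str]] | None = None


def _rngs(config: DesignConfig):
    children = np.random.SeedSequence(config.seed).spawn(5)
    return {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("metadata", "expression", "wax", "lcw", "annotation"), children
        )
    }


def generate_metadata(config: DesignConfig) -> pd.DataFrame:
    """Balanced organ x genotype x replicate sample table."""
    rows = []
    for organ in config.organs:
        for genotype in config.genotypes:
            for rep in range(1, config.n_reps + 1):
                rows.append(
                    {
                        "sample_id": f"{organ}_{genotype}_r{rep}",
                        "organ": organ,
                        "genotype": genotype,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def _metabolite_ids(fraction: str, config: DesignConfig) -> list[str]:
    return [f"{fraction}_met{i:03d}" for i in range(config.n_metabolites_per_fraction)]


def generate_expression(
    metadata: pd.DataFrame, config: DesignConfig
) -> tuple[OmicsMatrix, GroundTruth]:
    """FPKM-scale expression with planted co-expression modules.

    Each module m has a latent per-sample profile driven by a random organ
    signature (optionally modulated by genotype) plus replicate-level noise;
    a member gene is ``sqrt(share) * latent + sqrt(1-share) * eps`` on the
    standardized core scale, so the expected pairwise within-module Pearson
    correlation equals ``within_module_share``.  Background genes carry a
    weak organ signature plus independent noise.  Cores are mapped to an
    FPKM-like nonnegative scale by ``10 ** (mu_g + dynamic * core)`` with a
    lognormal baseline, giving a heavy right tail so the >100 FPKM stratum
    is populated.
    """
    rng = _rngs(config)["expression"]
    n = len(metadata)
    genes = [f"gene{i:04d}" for i in range(config.n_genes)]
    organ_idx = pd.Categorical(metadata["organ"], categories=config.organs).codes
    geno_idx = pd.Categorical(metadata["genotype"], categories=config.genotypes).codes

    membership = np.zeros(config.n_genes, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        membership[pos : pos + size] = m
        pos += size

    core = np.empty((config.n_genes, n))
    share = config.within_module_share
    module_latent: dict[int, np.ndarray] = {}
    # orthogonalized organ signatures: planted modules represent distinct
    # organ-expression programs, not chance-aligned ones
    n_org = len(config.organs)
    raw_profiles = rng.normal(size=(max(config.n_modules, 1), n_org))
    k_orth = min(config.n_modules, n_org)
    if k_orth >= 1:
        q, _ = np.linalg.qr(raw_profiles[:k_orth].T)
        raw_profiles[:k_orth] = q.T * np.sqrt(n_org)
    for m, size in enumerate(config.module_sizes, start=1):
        organ_profile = raw_profiles[m - 1]
        latent = organ_profile[organ_idx].astype(float)
        if rng.random() < config.module_genotype_frac:
            latent = latent + config.module_genotype_sd * rng.normal(
                size=len(config.genotypes)
            )[geno_idx]
        latent = latent + config.module_rep_sd * rng.normal(size=n)
        sd = latent.std()
        if sd > 0:
            latent = (latent - latent.mean()) / sd
        module_latent[m] = latent
        members = np.flatnonzero(membership == m)
        eps = rng.normal(size=(size, n))
        core[members] = np.sqrt(share) * latent + np.sqrt(1.0 - share) * eps

    bg = np.flatnonzero(membership == 0)
    if bg.size:
        profiles = config.bg_organ_sd * rng.normal(size=(bg.size, len(config.organs)))
        core[bg] = (profiles[:, organ_idx] + rng.normal(size=(bg.size, n))) / np.sqrt(
            1.0 + config.bg_organ_sd**2
        )

    assoc_sets = _choose_assoc_genes(membership, config, rng)
    if config.assoc_group_size > 1:
        # Associated genes form small co-regulated groups (a shared latent
        # sub-program, sized below the module floor).  Inside a module the
        # group latent replaces part of a member's private noise, so the
        # group stays a module member while carrying a low-rank signal that
        # distinguishes it from ordinary module siblings.
        gshare = config.assoc_group_share
        for idx_set in assoc_sets:
            by_module: dict[int, list[int]] = {}
            for gi in idx_set:
                by_module.setdefault(int(membership[gi]), []).append(int(gi))
            for mod in sorted(by_module):
                idxs = by_module[mod]
                for start in range(0, len(idxs), config.assoc_group_size):
                    group = np.array(idxs[start : start + config.assoc_group_size])
                    glat = rng.normal(size=n)
                    eps = rng.normal(size=(group.size, n))
                    inner = np.sqrt(gshare) * glat + np.sqrt(1 - gshare) * eps
                    if mod == 0:
                        core[group] = inner
                    else:
                        core[group] = (
                            np.sqrt(share) * module_latent[mod]
                            + np.sqrt(1.0 - share) * inner
                        )

    mu = rng.normal(config.log10_loc, config.log10_scale, size=config.n_genes)
    fpkm = 10.0 ** (mu[:, None] + config.log10_dynamic * core)

    truth = _plant_associations(genes, assoc_sets, config, rng, membership)

    protected = set()
    for g in truth.assoc_genes_lcw | truth.assoc_genes_wax:
        protected.add(genes.index(g))
    candidates = [i for i in bg if i not in protected]
    n_sparse = int(round(config.sparse_gene_frac * config.n_genes))
    if n_sparse and candidates:
        sparse = rng.choice(candidates, size=min(n_sparse, len(candidates)), replace=False)
        mask = rng.random((len(sparse), n)) < config.sparse_dropout
        fpkm[sparse] = np.where(mask, 0.0, fpkm[sparse])

    expr = OmicsMatrix(pd.DataFrame(fpkm, index=genes, columns=list(metadata["sample_id"])))
    return expr, truth


def _choose_assoc_genes(membership: np.ndarray, config: DesignConfig, rng):
    """Pick the lcw-only / wax-only / both gene index sets (sampling-order
    deterministic under the expression RNG stream)."""
    if config.assoc_in_modules and membership.max() > 0:
        pool = np.flatnonzero(membership > 0)
    else:
        pool = np.flatnonzero(membership == 0)
    n_total = 2 * config.n_assoc_genes + config.n_assoc_both
    if n_total > pool.size:
        raise ConfigurationError("not enough genes in the association pool")
    chosen = rng.choice(pool, size=n_total, replace=False)
    return (
        chosen[: config.n_assoc_genes],
        chosen[config.n_assoc_genes : 2 * config.n_assoc_genes],
        chosen[2 * config.n_assoc_genes :],
    )


def _plant_associations(genes: list[str], assoc_sets, config: DesignConfig, rng,
                        membership: np.ndarray) -> GroundTruth:
    lcw_only, wax_only, both = assoc_sets
    effect_map: dict[tuple[str, str], float] = {}
    for fraction, idx in (("lcw", np.concatenate([lcw_only, both])),
                          ("wax", np.concatenate([wax_only, both]))):
        mets = _metabolite_ids(fraction, config)
        for gi in idx:
            targets = rng.choice(
                len(mets), size=min(config.metabolites_per_gene, len(mets)), replace=False
            )
            for t in targets:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                effect_map[(genes[gi], mets[t])] = sign * config.assoc_effect

    return GroundTruth(
        module_membership={g: int(m) for g, m in zip(genes, membership)},
        assoc_genes_lcw={genes[i] for i in np.concatenate([lcw_only, both])},
        assoc_genes_wax={genes[i] for i in np.concatenate([wax_only, both])},
        effect_map=effect_map,
    )


def generate_metabolome(
    metadata: pd.DataFrame,
    expression: OmicsMatrix,
    truth_in: GroundTruth,
    config: DesignConfig,
    fraction: str = "wax",
) -> OmicsMatrix:
    """One metabolite fraction: organ + genotype + interaction + planted
    gene contributions + noise, shifted to a nonnegative concentration scale.

    Metabolite class labels are assigned round-robin over the fraction's
    canonical classes and stored in ``feature_meta``.
    """
    if fraction not in ("wax", "lcw"):
        raise ConfigurationError(f"unknown fraction {fraction!r}")
    if list(expression.sample_ids) != list(metadata["sample_id"]):
        raise ConfigurationError("expression columns do not match metadata")
    rng = _rngs(config)[fraction]
    if fraction == "wax":
        sds = (config.organ_effect_sd, config.genotype_effect_sd,
               config.interaction_effect_sd, config.noise_sd)
        classes = WAX_CLASSES
    else:
        sds = (config.lcw_organ_sd, config.lcw_genotype_sd,
               config.lcw_interaction_sd, config.lcw_noise_sd)
        classes = LCW_CLASSES
    organ_sd, geno_sd, inter_sd, noise_sd = sds

    n = len(metadata)
    mets = _metabolite_ids(fraction, config)
    organ_idx = pd.Categorical(metadata["organ"], categories=config.organs).codes
    geno_idx = pd.Categorical(metadata["genotype"], categories=config.genotypes).codes
    n_org, n_gen = len(config.organs), len(config.genotypes)

    expr_index = {g: i for i, g in enumerate(expression.feature_ids)}
    expr_values = expression.values
    conc = np.empty((len(mets), n))
    for j, met in enumerate(mets):
        y = organ_sd * rng.normal(size=n_org)[organ_idx]
        y = y + geno_sd * rng.normal(size=n_gen)[geno_idx]
        y = y + inter_sd * rng.normal(size=(n_org, n_gen))[organ_idx, geno_idx]
        y = y + noise_sd * rng.normal(size=n)
        conc[j] = y
    # planted gene contributions (deterministic order for reproducibility)
    for (gene, met), slope in sorted(truth_in.effect_map.items()):
        if not met.startswith(fraction):
            continue
        if gene not in expr_index:
            raise ConfigurationError(f"associated gene {gene!r} absent from expression")
        x = expr_values[expr_index[gene]]
        sd = x.std(ddof=1)
        if sd == 0:
            continue
        z = (x - x.mean()) / sd
        conc[mets.index(met)] += slope * z

    scale = 10.0 ** rng.normal(0.0, 0.4, size=len(mets))
    conc = (conc - conc.min(axis=1, keepdims=True)) * scale[:, None]

    meta = pd.DataFrame(
        {
            "class": [classes[j % len(classes)] for j in range(len(mets))],
            "fraction": fraction,
        },
        index=mets,
    )
    df = pd.DataFrame(conc, index=mets, columns=list(metadata["sample_id"]))
    return OmicsMatrix(df, meta)


def generate_annotation(
    truth: GroundTruth, config: DesignConfig, n_bins: int = 20
) -> dict[str, set[str]]:
    """Synthetic gene -> function-bin map with one bin enriched for the
    planted cuticle-associated genes."""
    rng = _rngs(config)["annotation"]
    genes = sorted(truth.module_membership)
    ann = {g: {f"bin{(i % n_bins):02d}"} for i, g in enumerate(genes)}
    assoc = sorted(truth.assoc_genes_lcw | truth.assoc_genes_wax)
    for g in assoc:
        ann[g].add("bin-cuticle")
    n_extra = max(1, int(0.01 * len(genes)))
    for g in rng.choice(genes, size=n_extra, replace=False):
        ann[str(g)].add("bin-cuticle")
    return ann


def generate_dataset(config: DesignConfig) -> SyntheticDataset:
    """Bundle metadata, expression, both metabolome fractions, annotation and
    ground truth into one reproducible dataset."""
    metadata = generate_metadata(config)
    expression, truth = generate_expression(metadata, config)
    wax = generate_metabolome(metadata, expression, truth, config, "wax")
    lcw = generate_metabolome(metadata, expression, truth, config, "lcw")
    annotation = generate_annotation(truth, config)
    return SyntheticDataset(metadata, expression, wax, lcw, truth, annotation)


def write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataio.write_metadata(dataset.metadata, out / "metadata.tsv")
    dataio.write_matrix(dataset.expression, out / "expression.tsv")
    dataio.write_matrix(dataset.metabolome_wax, out / "metabolome_wax.tsv")
    dataio.write_matrix(dataset.metabolome_lcw, out / "metabolome_lcw.tsv")
    for name, m in (("wax", dataset.metabolome_wax), ("lcw", dataset.metabolome_lcw)):
        m.feature_meta.to_csv(out / f"metabolite_classes_{name}.tsv", sep="\t")
    (out / "truth.json").write_text(dataset.truth.to_json())
    if dataset.annotation is not None:
        dataio.write_annotation(dataset.annotation, out / "annotation.tsv")


def load_dataset(in_dir) -> SyntheticDataset:
    src = Path(in_dir)
    metadata = dataio.load_metadata(src / "metadata.tsv")
    expression = dataio.load_matrix(src / "expression.tsv", kind="expression")
    wax = dataio.load_matrix(src / "metabolome_wax.tsv", kind="metabolite")
    lcw = dataio.load_matrix(src / "metabolome_lcw.tsv", kind="metabolite")
    for name, m in (("wax", wax), ("lcw", lcw)):
        meta_path = src / f"metabolite_classes_{name}.tsv"
        if meta_path.exists():
            m.feature_meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    truth = GroundTruth.from_json((src / "truth.json").read_text())
    ann_path = src / "annotation.tsv"
    annotation = dataio.load_annotation(ann_path) if ann_path.exists() else None
    return SyntheticDataset(metadata, expression, wax, lcw, truth, annotation)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def default_config(seed: int = 0, **overrides) -> DesignConfig:
    """Study-condition emulation: organ-dominant variance on both fractions,
    planted organ-driven modules hosting the associated genes."""
    return DesignConfig(seed=seed, **overrides)


def null_config(seed: int = 0, **overrides) -> DesignConfig:
    """Global-null dataset: expression is pure noise (no modules, no organ
    signature) and no gene-metabolite links, so X and Y are independent.
    Used to calibrate permutation and bootstrap type-I error."""
    params = dict(
        n_modules=0,
        module_sizes=(),
        bg_organ_sd=0.0,
        n_assoc_genes=0,
        n_assoc_both=0,
        assoc_effect=0.0,
        sparse_gene_frac=0.0,
    )
    params.update(overrides)
    return DesignConfig(seed=seed, **params)


def association_benchmark_config(seed: int = 0, **overrides) -> DesignConfig:
    """Gene-to-metabolite recovery benchmark: 40 planted genes per fraction
    outside any module, strong standardized slopes, modest organ structure on
    the metabolome so the planted links dominate the embeddings."""
    params = dict(
        n_modules=0,
        module_sizes=(),
        bg_organ_sd=0.1,
        n_assoc_genes=40,
        n_assoc_both=0,
        assoc_effect=2.2,
        assoc_group_share=0.7,
        metabolites_per_gene=3,
        assoc_in_modules=False,
        organ_effect_sd=0.4,
        genotype_effect_sd=0.15,
        interaction_effect_sd=0.15,
        noise_sd=0.4,
        lcw_organ_sd=0.4,
        lcw_genotype_sd=0.15,
        lcw_interaction_sd=0.15,
        lcw_noise_sd=0.4,
        sparse_gene_frac=0.0,
    )
    params.update(overrides)
    return DesignConfig(seed=seed, **params)


def network_benchmark_config(seed: int = 0, **overrides) -> DesignConfig:
    """End-to-end network recovery benchmark: associated genes live inside a
    planted module (as co-regulated sub-groups) so that the module eigengene
    carries the metabolome signal and the integration stage can be scored
    against truth.

    A single associated module is planted: the cluster stage regresses 2-D
    tSNE coordinates, which can only represent the dominant structure axes,
    so with several competing modules the smallest loses its embedding
    footprint and its selection becomes a coin flip rather than a property
    of the method.  Multi-module recovery is exercised separately by the
    module-recovery suite.
    """
    params = dict(
        n_modules=1,
        module_sizes=(300,),
        module_rep_sd=1.0,
        within_module_share=0.6,
        n_assoc_genes=20,
        n_assoc_both=20,
        assoc_effect=3.0,
        assoc_group_share=0.85,
        metabolites_per_gene=3,
        assoc_in_modules=True,
        organ_effect_sd=0.6,
        genotype_effect_sd=0.2,
        interaction_effect_sd=0.2,
        noise_sd=0.3,
        lcw_organ_sd=0.6,
        lcw_genotype_sd=0.2,
        lcw_interaction_sd=0.2,
        lcw_noise_sd=0.3,
        sparse_gene_frac=0.0,
    )
    params.update(overrides)
    return DesignConfig(seed=seed, **params)


def config_to_dict(config: DesignConfig) -> dict:
    d = asdict(config)
    d["organs"] = list(d["organs"])
    d["genotypes"] = list(d["genotypes"])
    d["module_sizes"] = list(d["module_sizes"])
    return d
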