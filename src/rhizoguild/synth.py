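"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates post-denoising rhizosphere amplicon data from a
perennial-crop sampling design — seven developmental stages (bulk soil
plus six rhizosphere stages) × five field sites × three plots — together
with a root expression matrix. Its building blocks double as ground
truth for parameter-recovery tests:

* a lognormal regional species-abundance distribution with genus labels
  wired to a trait database so guild shares roughly mirror real
  rhizosphere surveys (≈18% of bacterial ASVs plant-beneficial, ≈27% of
  fungal ASVs plant-pathogenic, Proteobacteria dominant);
* Sloan-neutral local communities (Beta-distributed local relative
  abundances around the regional mean, multinomial reads at the
  rarefaction depth);
* stage-specific deterministic selection injected by enriching or
  depleting chosen taxa, strongest at the third-year root stage;
* a negative biocontrol→pathogen abundance coupling;
* planted expression-trajectory clusters, one tracking the deterministic
  assembly share, with a planted biosynthesis pathway and a fixed number
  of co-regulated transcription factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    STAGES,
    Dataset,
    FeatureTable,
    SampleMetadata,
    TaxonomyTable,
    TraitDatabase,
)

# genus pools per trait category; shares below mirror the subgroup
# structure of genus-level plant-beneficial trait databases
_PBB_CATEGORIES = [
    # (fraction of PBB taxa, trait set, genus pool)
    (0.14, frozenset({"PGP", "Bioc", "SR"}), ["Bacillus", "Pseudomonas"]),
    (0.50, frozenset({"PGP"}), ["Rhizobium", "Mesorhizobium", "Devosia", "Arthrobacter"]),
    (0.25, frozenset({"PGP", "Bioc"}), ["Streptomyces", "Burkholderia"]),
    (0.03, frozenset({"PGP", "SR"}), ["Variovorax"]),
    (0.03, frozenset({"Bioc"}), ["Lysobacter", "Collimonas"]),
    (0.05, frozenset({"SR"}), ["Gemmatimonas", "Sphingomonas"]),
]
_NONPBB_GENERA = ["Gaiella", "Nitrospira", "Haliangium", "Bryobacter", "Candidatus"]
_BAC_PHYLA = [
    "Proteobacteria",
    "Bacteroidetes",
    "Actinobacteria",
    "Firmicutes",
    "Gemmatimonadetes",
]
_FPP_GENERA = ["Fusarium", "Volutella", "Cadophora", "Alternaria", "Ilyonectria"]
_NONFPP_GENERA = ["Trichoderma", "Mortierella", "Penicillium", "Chaetomium"]
_TF_FAMILIES = ["bHLH", "NAC", "MADS", "MYB", "bZIP", "ARF", "IFRD1", "GRF",
                "TFIIA", "TFIIH"]

ROOT_STAGES = STAGES[1:]  # no root tissue exists for unplanted bulk soil


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic study; defaults are the study conditions.

    Depths are the rarefaction depths of the emulated survey (reads per
    sample); ``nm`` is the Sloan Nm (community size × migration rate)
    used for neutral sampling; ``selected_frac`` gives the fraction of
    plant-beneficial taxa under deterministic selection per stage.
    """

    n_taxa_bac: int = 200
    n_taxa_fun: int = 80
    stages: tuple = STAGES
    n_sites: int = 5
    n_plots: int = 3
    depth_bac: int = 2339
    depth_fun: int = 3827
    nm: float = 500.0
    pbb_taxon_frac: float = 0.18
    fpp_taxon_frac: float = 0.27
    selected_frac: dict = field(
        default_factory=lambda: {"3YV": 0.1, "3YF": 0.2, "3YR": 0.3}
    )
    selection_strength: float = 10.0
    antagonism_beta: float = 25.0
    antagonism_noise_sd: float = 0.2
    lognormal_sigma: float = 1.5
    # expression block
    n_genes: int = 2000
    n_clusters: int = 5
    n_expr_reps: int = 3
    planted_tf_count: int = 13
    n_decoy_tfs: int = 20
    planted_pathway_size: int = 30
    n_pathways: int = 8
    noise_sd: float = 0.2
    rep_noise_sd: float = 0.1
    determinism: dict = field(
        default_factory=lambda: dict(
            zip(ROOT_STAGES, [0.30, 0.25, 0.20, 0.35, 0.55, 0.75])
        )
    )
    seed: int = 17

    def validate(self) -> None:
        if min(self.n_taxa_bac, self.n_taxa_fun, self.n_genes) <= 0:
            raise ValueError("counts must be positive")
        for frac in list(self.selected_frac.values()) + [
            self.pbb_taxon_frac, self.fpp_taxon_frac
        ]:
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")


@dataclass
class Metacommunity:
    p_bac: pd.Series
    p_fun: pd.Series
    taxonomy_bac: TaxonomyTable
    taxonomy_fun: TaxonomyTable
    traits: TraitDatabase
    guild_truth: dict  # guild label → frozenset of taxon ids


def _largest_remainder(fractions, total: int) -> list[int]:
    raw = np.asarray(fractions, dtype=float) * total
    counts = np.floor(raw).astype(int)
    for idx in np.argsort(raw - counts)[::-1][: total - counts.sum()]:
        counts[idx] += 1
    return counts.tolist()


def make_metacommunity(config: ScenarioConfig, rng=None) -> Metacommunity:
    """Regional relative abundances + taxonomy + trait database."""
    config.validate()
    rng = np.random.default_rng(config.seed if rng is None else rng)

    def sad(n):
        x = rng.lognormal(0.0, config.lognormal_sigma, size=n)
        return x / x.sum()

    bac_ids = [f"bASV{i + 1}" for i in range(config.n_taxa_bac)]
    fun_ids = [f"fASV{i + 1}" for i in range(config.n_taxa_fun)]
    p_bac = pd.Series(sad(config.n_taxa_bac), index=bac_ids)
    p_fun = pd.Series(sad(config.n_taxa_fun), index=fun_ids)

    # --- bacterial guild structure
    n_pbb = int(round(config.pbb_taxon_frac * config.n_taxa_bac))
    pbb_idx = rng.choice(config.n_taxa_bac, size=n_pbb, replace=False)
    cat_counts = _largest_remainder([c[0] for c in _PBB_CATEGORIES], n_pbb)
    bacterial_traits: dict[str, frozenset] = {}
    genus_of = {}
    phylum_of = {}
    cursor = 0
    guild_truth: dict[str, set] = {g: set() for g in ("PBB", "PGP", "Bioc", "SR", "FPP")}
    for (frac, traits, pool), n_cat in zip(_PBB_CATEGORIES, cat_counts):
        for k in range(n_cat):
            taxon = bac_ids[pbb_idx[cursor]]
            genus = pool[k % len(pool)]
            genus_of[taxon] = genus
            bacterial_traits[TraitDatabase.normalize(genus)] = traits
            guild_truth["PBB"].add(taxon)
            for t in traits:
                guild_truth[t].add(taxon)
            # beneficial taxa skew Proteobacteria, like real surveys
            phylum_of[taxon] = (
                "Proteobacteria"
                if rng.random() < 0.4
                else _BAC_PHYLA[1 + rng.integers(len(_BAC_PHYLA) - 1)]
            )
            cursor += 1
    for i, taxon in enumerate(bac_ids):
        if taxon not in genus_of:
            genus_of[taxon] = _NONPBB_GENERA[i % len(_NONPBB_GENERA)]
            phylum_of[taxon] = (
                "Proteobacteria"
                if rng.random() < 0.35
                else _BAC_PHYLA[1 + rng.integers(len(_BAC_PHYLA) - 1)]
            )
    taxonomy_bac = TaxonomyTable(
        pd.DataFrame(
            {
                "domain": "Bacteria",
                "phylum": [phylum_of[t] for t in bac_ids],
                "class": "",
                "order": "",
                "family": "",
                "genus": [genus_of[t] for t in bac_ids],
                "species": "",
            },
            index=bac_ids,
        )
    )

    # --- fungal guild structure
    n_fpp = int(round(config.fpp_taxon_frac * config.n_taxa_fun))
    fpp_idx = set(rng.choice(config.n_taxa_fun, size=n_fpp, replace=False).tolist())
    fungal_traits: dict[str, bool] = {}
    fun_genus, fun_phylum = {}, {}
    for i, taxon in enumerate(fun_ids):
        if i in fpp_idx:
            genus = _FPP_GENERA[i % len(_FPP_GENERA)]
            fungal_traits[TraitDatabase.normalize(genus)] = True
            guild_truth["FPP"].add(taxon)
            fun_phylum[taxon] = "Ascomycota" if rng.random() < 0.84 else "Basidiomycota"
        else:
            genus = _NONFPP_GENERA[i % len(_NONFPP_GENERA)]
            fungal_traits[TraitDatabase.normalize(genus)] = False
            fun_phylum[taxon] = "Ascomycota" if rng.random() < 0.5 else "Mortierellomycota"
        fun_genus[taxon] = genus
    taxonomy_fun = TaxonomyTable(
        pd.DataFrame(
            {
                "domain": "Fungi",
                "phylum": [fun_phylum[t] for t in fun_ids],
                "class": "",
                "order": "",
                "family": "",
                "genus": [fun_genus[t] for t in fun_ids],
                "species": "",
            },
            index=fun_ids,
        )
    )
    traits = TraitDatabase(bacterial=bacterial_traits, fungal=fungal_traits)
    return Metacommunity(
        p_bac=p_bac,
        p_fun=p_fun,
        taxonomy_bac=taxonomy_bac,
        taxonomy_fun=taxonomy_fun,
        traits=traits,
        guild_truth={g: frozenset(s) for g, s in guild_truth.items()},
    )


# ---------------------------------------------------------------------------
# Neutral sampling, selection, coupling


def sample_neutral(
    p, nm: float, depth: int, n_samples: int, rng=17, taxon_ids=None, sample_ids=None
) -> FeatureTable:
    """Sloan-neutral local communities.

    Per sample, each taxon's local relative abundance is drawn
    Beta(Nm·p_i, Nm·(1−p_i)) independently, the vector renormalised, and
    counts drawn multinomially at the target depth.
    """
    if nm <= 0:
        raise ValueError("Nm must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if isinstance(p, pd.Series):
        taxon_ids = taxon_ids or list(p.index)
        p = p.to_numpy()
    p = np.asarray(p, dtype=float)
    n_taxa = p.size
    taxon_ids = taxon_ids or [f"T{i + 1}" for i in range(n_taxa)]
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(n_samples)]
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    a = np.clip(nm * p, 1e-12, None)
    b = np.clip(nm * (1.0 - p), 1e-12, None)
    for j in range(n_samples):
        local = rng.beta(a, b)
        local = np.where(p > 0, local, 0.0)
        local = local / local.sum()
        counts[:, j] = rng.multinomial(depth, local)
    return FeatureTable(pd.DataFrame(counts, index=taxon_ids, columns=sample_ids))


def _redraw_to_depth(
    scaled: np.ndarray, depth: int, rng: np.random.Generator,
    keep_present: np.ndarray | None = None,
) -> np.ndarray:
    """Multinomial redraw of one sample to the target depth.

    ``keep_present`` marks taxa guaranteed at least one read (used so
    enrichment never removes an originally present, enriched taxon).
    """
    probs = scaled / scaled.sum()
    out = rng.multinomial(depth, probs)
    if keep_present is not None:
        lost = keep_present & (out == 0)
        for idx in np.where(lost)[0]:
            donor = int(np.argmax(out))
            if out[donor] > 1:
                out[donor] -= 1
                out[idx] = 1
    return out


def inject_selection(
    table: FeatureTable, taxa, strength: float, mode: str = "enrich", rng=17
) -> FeatureTable:
    """Apply deterministic selection to chosen taxa.

    Selected taxa's counts are multiplied (enrich) or divided (deplete)
    by ``strength`` in every sample; each sample is then redrawn to its
    original depth so totals are restored. Enriched taxa that were
    present stay present.
    """
    if strength < 1:
        raise ValueError("strength must be >= 1")
    if mode not in ("enrich", "deplete"):
        raise ValueError("mode must be 'enrich' or 'deplete'")
    if strength == 1:
        return FeatureTable(table.data.copy())
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mask = np.array([t in set(taxa) for t in table.taxon_ids])
    counts = table.counts.astype(float)
    factor = strength if mode == "enrich" else 1.0 / strength
    scaled = counts.copy()
    scaled[mask] *= factor
    out = np.zeros_like(table.counts)
    for j, sample in enumerate(table.sample_ids):
        depth = int(counts[:, j].sum())
        keep = (mask & (table.counts[:, j] > 0)) if mode == "enrich" else None
        out[:, j] = _redraw_to_depth(scaled[:, j], depth, rng, keep_present=keep)
    return FeatureTable(
        pd.DataFrame(out, index=table.taxon_ids, columns=table.sample_ids)
    )


def couple_antagonism(
    fun_table: FeatureTable,
    fpp_taxa,
    bioc_abundance: pd.Series,
    beta: float,
    noise_sd: float = 0.2,
    rng=17,
) -> FeatureTable:
    """Couple pathogen load negatively to biocontrol abundance.

    Per sample the summed reads of pathogen taxa are rescaled by
    exp(−β·(x − x̄)) × lognormal noise, where x is the sample's
    biocontrol relative abundance (centred at the overall mean so the
    average pathogen load is preserved), and the sample is redrawn to
    its depth. β = 0 leaves only the noise (no coupling).
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mask = np.array([t in set(fpp_taxa) for t in fun_table.taxon_ids])
    counts = fun_table.counts.astype(float)
    centred = bioc_abundance.loc[fun_table.sample_ids].to_numpy(dtype=float)
    centred = centred - centred.mean()
    out = np.zeros_like(fun_table.counts)
    for j in range(counts.shape[1]):
        factor = np.exp(-beta * centred[j]) * rng.lognormal(0.0, noise_sd)
        scaled = counts[:, j].copy()
        scaled[mask] *= factor
        out[:, j] = _redraw_to_depth(scaled, int(counts[:, j].sum()), rng)
    return FeatureTable(
        pd.DataFrame(out, index=fun_table.taxon_ids, columns=fun_table.sample_ids)
    )


# ---------------------------------------------------------------------------
# Expression bundle


@dataclass
class ExpressionBundle:
    counts: pd.DataFrame  # genes × samples
    gene_lengths: pd.Series
    mapped_totals: pd.Series
    sample_stages: pd.Series
    pathway_map: dict  # pathway → set of genes
    tf_table: dict  # TF gene id → family
    target_fpkm: pd.DataFrame = field(repr=False, default=None)


@dataclass
class ExpressionTruth:
    cluster_labels: pd.Series
    planted_cluster: str
    planted_pathway: str
    planted_tfs: tuple
    determinism: pd.Series


_SHAPES = {
    # trajectory library on the six root stages (before z-scoring)
    "decline": np.array([1.0, 0.6, 0.2, -0.2, -0.6, -1.0]),
    "mid_peak": np.array([-1.0, 0.2, 1.0, 1.0, 0.2, -1.0]),
    "u_shape": np.array([1.0, -0.2, -1.0, -1.0, -0.2, 1.0]),
    "early_spike": np.array([1.0, -0.4, -1.0, -0.6, -0.4, -0.2]),
}


def make_expression(
    config: ScenarioConfig, determinism: pd.Series | None = None, rng=None
) -> tuple[ExpressionBundle, ExpressionTruth]:
    """Planted-trajectory expression bundle.

    One cluster centroid equals the (z-scored) deterministic-assembly
    trajectory; a biosynthesis pathway and the planted transcription
    factors live inside that cluster so the thresholded co-expression
    network links them. Counts are generated by inverting the FPKM
    formula so FPKM(counts) matches the target up to rounding.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    if determinism is None:
        determinism = pd.Series(config.determinism)
    root_stages = list(determinism.index)
    if len(root_stages) < 3:
        raise ValueError("determinism vector needs >=3 stages")

    def z(v):
        v = np.asarray(v, dtype=float)
        return (v - v.mean()) / v.std(ddof=0)

    shapes = [z(determinism.to_numpy())]
    for name in list(_SHAPES)[: config.n_clusters - 1]:
        base = _SHAPES[name]
        if len(root_stages) != base.size:
            base = np.interp(
                np.linspace(0, 1, len(root_stages)), np.linspace(0, 1, base.size), base
            )
        shapes.append(z(base))
    centroids = np.array(shapes[: config.n_clusters])
    k = centroids.shape[0]

    gene_ids = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    labels = np.repeat(np.arange(k), int(np.ceil(config.n_genes / k)))[: config.n_genes]
    cluster0_size = int((labels == 0).sum())
    n_block = config.planted_pathway_size + config.planted_tf_count
    if n_block > cluster0_size:
        raise ValueError(
            f"planted pathway + TFs ({n_block}) exceed the planted cluster "
            f"size ({cluster0_size}); increase n_genes or shrink the plant"
        )
    stage_profiles_z = (
        centroids[labels]
        + rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(root_stages)))
    )
    # the planted regulatory block (biosynthesis pathway + its TFs, the
    # first genes of cluster 0) is co-regulated tightly by construction,
    # so its links survive the correlation threshold of the network step
    block_rows = np.where(labels == 0)[0][:n_block]
    stage_profiles_z[block_rows] = centroids[0] + rng.normal(
        0.0, config.noise_sd / 2.0, size=(n_block, len(root_stages))
    )

    samples, stages = [], []
    for st in root_stages:
        for r in range(config.n_expr_reps):
            samples.append(f"R{st}_{r + 1}")
            stages.append(st)
    base_log = rng.normal(3.0, 0.5, size=config.n_genes)
    log_fpkm = np.empty((config.n_genes, len(samples)))
    for idx, st in enumerate(stages):
        s_i = root_stages.index(st)
        log_fpkm[:, idx] = (
            base_log
            + stage_profiles_z[:, s_i]
            + rng.normal(0.0, config.rep_noise_sd, size=config.n_genes)
        )
    target = pd.DataFrame(np.exp(log_fpkm), index=gene_ids, columns=samples)

    lengths = pd.Series(rng.integers(500, 5001, size=config.n_genes), index=gene_ids)
    totals = pd.Series(
        np.round(2e7 * rng.lognormal(0.0, 0.1, size=len(samples))).astype(np.int64),
        index=samples,
    )
    counts = np.rint(
        target.to_numpy() * np.outer(lengths, totals) / 1e9
    ).astype(np.int64)
    counts = pd.DataFrame(counts, index=gene_ids, columns=samples)

    # planted structure lives in the determinism-tracking cluster (label 0)
    cluster0 = [g for g, lab in zip(gene_ids, labels) if lab == 0]
    pathway_genes = cluster0[: config.planted_pathway_size]
    planted_tfs = cluster0[
        config.planted_pathway_size : config.planted_pathway_size
        + config.planted_tf_count
    ]
    other = [g for g, lab in zip(gene_ids, labels) if lab != 0]
    decoy_tfs = list(rng.choice(other, size=config.n_decoy_tfs, replace=False))
    tf_table = {
        g: _TF_FAMILIES[i % len(_TF_FAMILIES)]
        for i, g in enumerate(planted_tfs + decoy_tfs)
    }
    pathway_map = {"biosynthesis_planted": set(pathway_genes)}
    pool = [g for g in gene_ids if g not in set(pathway_genes)]
    for i in range(config.n_pathways - 1):
        size = int(rng.integers(20, 41))
        pathway_map[f"pathway_{i + 1}"] = set(
            rng.choice(pool, size=size, replace=False).tolist()
        )

    bundle = ExpressionBundle(
        counts=counts,
        gene_lengths=lengths,
        mapped_totals=totals,
        sample_stages=pd.Series(stages, index=samples),
        pathway_map=pathway_map,
        tf_table=tf_table,
        target_fpkm=target,
    )
    truth = ExpressionTruth(
        cluster_labels=pd.Series(
            [f"K{lab + 1}" for lab in labels], index=gene_ids
        ),
        planted_cluster="K1",
        planted_pathway="biosynthesis_planted",
        planted_tfs=tuple(planted_tfs),
        determinism=determinism.astype(float),
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# Full scenario


@dataclass
class TruthBundle:
    nm: dict  # stage → Nm used for neutral sampling
    selected_taxa: dict  # stage → frozenset of enriched taxa
    guild_truth: dict
    antagonism_beta: float
    expression: ExpressionTruth


@dataclass
class Scenario:
    dataset: Dataset
    expression: ExpressionBundle
    truth: TruthBundle
    metacommunity: Metacommunity


def full_scenario(config: ScenarioConfig | None = None) -> Scenario:
    """Generate the complete study: paired amplicon tables for the full
    stage × site × plot design, trait/taxonomy tables, expression bundle
    and a truth bundle for recovery assertions. Deterministic given the
    config seed."""
    config = config or ScenarioConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta_comm = make_metacommunity(config, rng)

    sample_ids, stages_col, sites_col, plots_col = [], [], [], []
    for stage in config.stages:
        for site in range(1, config.n_sites + 1):
            for plot in range(1, config.n_plots + 1):
                sample_ids.append(f"{stage}_S{site}_P{plot}")
                stages_col.append(stage)
                sites_col.append(f"Site{site}")
                plots_col.append(str(plot))
    metadata = SampleMetadata(
        pd.DataFrame(
            {"stage": stages_col, "site": sites_col, "plot": plots_col},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    per_stage = config.n_sites * config.n_plots
    bac_parts, fun_parts = [], []
    nm_truth, selected_truth = {}, {}
    pbb_list = sorted(meta_comm.guild_truth["PBB"])
    for stage in config.stages:
        ids = [s for s, st in zip(sample_ids, stages_col) if st == stage]
        bac = sample_neutral(
            meta_comm.p_bac, config.nm, config.depth_bac, per_stage, rng,
            sample_ids=ids,
        )
        nm_truth[stage] = config.nm
        frac = config.selected_frac.get(stage, 0.0)
        if frac > 0 and config.selection_strength > 1:
            n_sel = max(1, int(round(frac * len(pbb_list))))
            chosen = rng.choice(pbb_list, size=n_sel, replace=False).tolist()
            bac = inject_selection(
                bac, chosen, config.selection_strength, mode="enrich", rng=rng
            )
            selected_truth[stage] = frozenset(chosen)
        else:
            selected_truth[stage] = frozenset()
        bac_parts.append(bac.data)
        fun = sample_neutral(
            meta_comm.p_fun, config.nm, config.depth_fun, per_stage, rng,
            sample_ids=ids,
        )
        fun_parts.append(fun.data)
    bacterial = FeatureTable(pd.concat(bac_parts, axis=1))
    fungal = FeatureTable(pd.concat(fun_parts, axis=1))

    if config.antagonism_beta > 0 or config.antagonism_noise_sd > 0:
        bioc = sorted(meta_comm.guild_truth["Bioc"])
        bioc_abund = bacterial.data.loc[bioc].sum(axis=0) / bacterial.data.sum(axis=0)
        fungal = couple_antagonism(
            fungal,
            meta_comm.guild_truth["FPP"],
            bioc_abund,
            config.antagonism_beta,
            config.antagonism_noise_sd,
            rng,
        )

    determinism = pd.Series(config.determinism)
    expr_bundle, expr_truth = make_expression(config, determinism, rng)

    ds = Dataset(
        bacterial=bacterial,
        fungal=fungal,
        bacterial_taxonomy=meta_comm.taxonomy_bac,
        fungal_taxonomy=meta_comm.taxonomy_fun,
        metadata=metadata,
        traits=meta_comm.traits,
    )
    truth = TruthBundle(
        nm=nm_truth,
        selected_taxa=selected_truth,
        guild_truth=meta_comm.guild_truth,
        antagonism_beta=config.antagonism_beta,
        expression=expr_truth,
    )
    return Scenario(
        dataset=ds, expression=expr_bundle, truth=truth, metacommunity=meta_comm
    )
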