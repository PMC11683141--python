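"""Filtering, rarefaction and functional-guild partitioning of ASV tables.

Bacterial ASVs are assigned to plant-beneficial guilds by genus-level
trait lookup (biocontrol Bioc, plant-growth-promoting PGP, stress
resistance SR); fungal ASVs are flagged as fungal plant pathogens (FPP)
from a pathogenic-capacity trait. The filtering order matches common
amplicon practice for these data: host-organelle removal, then the
low-total-read filter, then rarefaction to an even depth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FPP, FeatureTable, TaxonomyTable, TraitDatabase, ValidationError

logger = logging.getLogger("rhizoguild")

#: Guild labels accepted by :func:`subset_by_guild`. PBB is the union of
#: the three bacterial subgroups; nonPBB the bacterial complement.
SUBSETTABLE_GUILDS = ("PBB", "PGP", "Bioc", "SR", "FPP", "nonPBB")

_CONTAMINANT_NAMES = ("chloroplast", "mitochondria")


def filter_host_contaminants(
    table: FeatureTable, taxonomy: TaxonomyTable
) -> FeatureTable:
    """Drop ASVs whose lineage names plant chloroplast or mitochondria
    at any rank (case-insensitive substring match)."""
    keep = []
    for taxon in table.taxon_ids:
        contaminated = taxon in set(taxonomy.taxon_ids) and any(
            taxonomy.lineage_contains(taxon, name) for name in _CONTAMINANT_NAMES
        )
        if not contaminated:
            keep.append(taxon)
    removed = table.shape[0] - len(keep)
    logger.info("host-contaminant filter removed %d of %d taxa", removed, table.shape[0])
    return FeatureTable(table.data.loc[keep])


def filter_low_abundance(table: FeatureTable, min_total: int = 10) -> FeatureTable:
    """Drop ASVs whose total count over all samples is below ``min_total``
    (strict: a total of exactly ``min_total`` is kept)."""
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    sums = table.row_sums()
    keep = sums.index[sums >= min_total]
    logger.info(
        "low-abundance filter (<%d total reads) removed %d of %d taxa",
        min_total,
        table.shape[0] - len(keep),
        table.shape[0],
    )
    return FeatureTable(table.data.loc[keep])


def rarefy(table: FeatureTable, depth: int, seed: int = 17) -> FeatureTable:
    """Subsample every sample without replacement to an even depth.

    Uses a multivariate-hypergeometric draw per sample, so each retained
    column sums exactly to ``depth``. Samples with fewer than ``depth``
    reads are dropped with a warning. Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    sums = table.column_sums()
    shallow = sums.index[sums < depth].tolist()
    if shallow:
        warnings.warn(
            f"dropping {len(shallow)} sample(s) below depth {depth}: {shallow}",
            stacklevel=2,
        )
    keep = [s for s in table.sample_ids if s not in set(shallow)]
    out = {}
    for sample in keep:
        col = table.data[sample].to_numpy()
        out[sample] = rng.multivariate_hypergeometric(col, depth)
    rarefied = FeatureTable(pd.DataFrame(out, index=table.taxon_ids))
    logger.info(
        "rarefied to depth %d: %d taxa x %d samples", depth, *rarefied.shape
    )
    return rarefied


@dataclass
class GuildAssignment:
    """Per-taxon functional guild labels.

    ``guilds`` maps every taxon (bacterial and fungal) to a frozenset of
    labels drawn from {PGP, Bioc, SR} (bacteria) or {FPP} (fungi); an
    empty set means no functional annotation.
    """

    guilds: dict[str, frozenset]
    bacterial_taxa: frozenset
    fungal_taxa: frozenset
    #: fungal taxa matched at a coarser rank than genus (fallback used)
    fallback_matched: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for taxon, gs in self.guilds.items():
            if taxon in self.fungal_taxa and gs - {FPP}:
                raise ValidationError(f"fungal taxon {taxon!r} has bacterial guilds {gs}")
            if taxon in self.bacterial_taxa and FPP in gs:
                raise ValidationError(f"bacterial taxon {taxon!r} flagged FPP")

    def guild_taxa(self, guild: str) -> list[str]:
        """Taxa belonging to ``guild`` (PBB/nonPBB are derived sets)."""
        if guild == "PBB":
            return [t for t in self.bacterial_taxa if self.guilds.get(t)]
        if guild == "nonPBB":
            return [t for t in self.bacterial_taxa if not self.guilds.get(t)]
        if guild == FPP:
            return [t for t in self.fungal_taxa if FPP in self.guilds.get(t, ())]
        if guild in ("PGP", "Bioc", "SR"):
            return [t for t in self.bacterial_taxa if guild in self.guilds.get(t, ())]
        raise ValueError(f"unknown guild {guild!r}; expected one of {SUBSETTABLE_GUILDS}")

    def summary(self) -> dict[str, int]:
        counts = {g: len(self.guild_taxa(g)) for g in SUBSETTABLE_GUILDS}
        counts["all_three_traits"] = sum(
            1
            for t in self.bacterial_taxa
            if self.guilds.get(t, frozenset()) >= {"PGP", "Bioc", "SR"}
        )
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for taxon, gs in self.guilds.items():
            rows.append(
                {
                    "taxon_id": taxon,
                    "kingdom": "bacteria" if taxon in self.bacterial_taxa else "fungi",
                    "guilds": "|".join(sorted(gs)) if gs else "",
                }
            )
        return pd.DataFrame(rows).set_index("taxon_id").sort_index()


def assign_guilds(
    bacterial_taxonomy: TaxonomyTable,
    fungal_taxonomy: TaxonomyTable,
    traits: TraitDatabase,
) -> GuildAssignment:
    """Label taxa with functional guilds by trait-database lookup.

    Bacterial ASVs match on genus (normalised: rank prefix stripped,
    trimmed, case-insensitive); taxa with an empty genus get no guild.
    Fungal ASVs match on genus with a family fallback when the genus is
    unassigned or unknown to the database; fallback matches are flagged.
    """
    if not traits.bacterial and not traits.fungal:
        raise ValidationError("empty trait database")
    guilds: dict[str, frozenset] = {}
    fallback = set()
    for taxon in bacterial_taxonomy.taxon_ids:
        genus = bacterial_taxonomy.genus(taxon)
        guilds[taxon] = traits.bacterial_traits(genus) if genus else frozenset()
    for taxon in fungal_taxonomy.taxon_ids:
        genus = fungal_taxonomy.genus(taxon)
        if genus and traits.has_fungal(genus):
            flagged = traits.fungal_pathogenic(genus)
        else:
            family = fungal_taxonomy.rank(taxon, "family")
            if family and traits.has_fungal(family):
                flagged = traits.fungal_pathogenic(family)
                fallback.add(taxon)
            else:
                flagged = False
        guilds[taxon] = frozenset({FPP}) if flagged else frozenset()
    assignment = GuildAssignment(
        guilds=guilds,
        bacterial_taxa=frozenset(bacterial_taxonomy.taxon_ids),
        fungal_taxa=frozenset(fungal_taxonomy.taxon_ids),
        fallback_matched=frozenset(fallback),
    )
    logger.info("guild assignment: %s", assignment.summary())
    return assignment


def subset_by_guild(
    table: FeatureTable, assignment: GuildAssignment, guild: str
) -> FeatureTable:
    """Restrict a feature table to the members of one guild.

    Counts are carried over verbatim. An empty result is returned (with
    a warning) rather than raised.
    """
    members = set(assignment.guild_taxa(guild))
    keep = [t for t in table.taxon_ids if t in members]
    if not keep:
        warnings.warn(f"guild {guild!r} has no members in this table", stacklevel=2)
    return FeatureTable(table.data.loc[keep])
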