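"""Tabular I/O and validated in-memory containers.

All pipeline inputs are plain TSV: an ASV feature table (taxa rows ×
sample columns, integer counts), a QIIME-style taxonomy table with
rank-prefixed lineage strings, a sample metadata sheet keyed by the
seven-stage sampling design (bulk soil plus six rhizosphere stages), and
a trait database mapping bacterial genera to plant-beneficial functions
and fungal taxa to a plant-pathogenic flag.

Lines starting with ``#`` are treated as comments in every reader.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("rhizoguild")

#: Closed, ordered set of developmental stages: bulk (pre-planting)
#: farmland soil, then vegetative / flowering / root-inflation stages of
#: the second and third cultivation years.
STAGES = ("BL", "2YV", "2YF", "2YR", "3YV", "3YF", "3YR")

#: Taxonomic ranks, coarse to fine.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_PREFIX_TO_RANK = {
    "k": "domain",
    "d": "domain",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}

#: Recognised bacterial plant-beneficial trait labels and the fungal
#: plant-pathogen label.
BACTERIAL_TRAITS = ("Bioc", "PGP", "SR")
FPP = "FPP"


class FormatError(ValueError):
    """Malformed input file (structure, duplicates, unparseable cells)."""


class ValidationError(ValueError):
    """Well-formed input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# FeatureTable


@dataclass
class FeatureTable:
    """Taxa × samples matrix of non-negative integer counts.

    Wraps a :class:`pandas.DataFrame` whose index holds taxon ids and
    whose columns hold sample ids; both must be unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon id(s): {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample id(s): {dup}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("feature table contains non-numeric values")
        if np.any(arr < 0):
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at taxon {df.index[bad[0]]!r}, "
                f"sample {df.columns[bad[1]]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("feature table counts must be integers")
        self.data = df.astype(np.int64)
        self.data.index.name = None
        self.data.columns.name = None

    # -- accessors ---------------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def column_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def row_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        sums = self.data.sum(axis=0)
        if (sums == 0).any():
            empty = sums.index[sums == 0].tolist()
            raise ValidationError(f"zero-sum sample(s): {empty}")
        return self.data / sums

    def subset_taxa(self, taxa) -> "FeatureTable":
        keep = [t for t in self.taxon_ids if t in set(taxa)]
        return FeatureTable(self.data.loc[keep])

    def subset_samples(self, samples) -> "FeatureTable":
        keep = [s for s in self.sample_ids if s in set(samples)]
        return FeatureTable(self.data[keep])

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path, orientation: str = "taxa") -> "FeatureTable":
        """Read a TSV feature table.

        ``orientation="taxa"`` (default) expects taxa as rows; pass
        ``"samples"`` for a transposed file.
        """
        header = _first_data_line(path)
        cells = header.rstrip("\n").split("\t")
        col_ids = cells[1:]
        if len(set(col_ids)) != len(col_ids):
            dup = sorted({c for c in col_ids if col_ids.count(c) > 1})
            raise FormatError(f"duplicate column id(s) in {path}: {dup}")
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
        df.index = df.index.astype(str).str.strip()
        num = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
        for col in df.columns:
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.argmax()]
                raise FormatError(
                    f"non-numeric cell at row {row!r}, column {col!r}: "
                    f"{df.loc[row, col]!r}"
                )
            num[col] = converted
        table = cls(num)
        if orientation == "samples":
            table = cls(table.data.T)
        logger.info("read feature table %s: %d taxa x %d samples", path, *table.shape)
        return table

    def to_tsv(self, path, id_header: str = "taxon_id") -> None:
        out = self.data.copy()
        out.index.name = id_header
        out.to_csv(path, sep="\t")


def _first_data_line(path) -> str:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return line
    raise FormatError(f"{path}: no data lines")


def read_feature_table(path, orientation: str = "taxa") -> FeatureTable:
    """Alias for :meth:`FeatureTable.from_tsv`."""
    return FeatureTable.from_tsv(path, orientation=orientation)


def write_table(table: FeatureTable, path) -> None:
    table.to_tsv(path)


# ---------------------------------------------------------------------------
# TaxonomyTable


@dataclass
class TaxonomyTable:
    """Per-taxon lineage split into the seven canonical ranks.

    Stored as a DataFrame indexed by taxon id with one column per rank;
    unassigned ranks are empty strings.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon id(s) in taxonomy: {dup}")
        for rank in RANKS:
            if rank not in self.data.columns:
                self.data[rank] = ""
        self.data = self.data[list(RANKS)].fillna("").astype(str)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    def rank(self, taxon: str, rank: str) -> str:
        return str(self.data.at[taxon, rank])

    def genus(self, taxon: str) -> str:
        return self.rank(taxon, "genus")

    def lowest_assigned(self, taxon: str) -> tuple[str, str]:
        """(rank, name) of the finest non-empty rank, or ('', '')."""
        row = self.data.loc[taxon]
        for rank in reversed(RANKS):
            if row[rank]:
                return rank, row[rank]
        return "", ""

    def lineage_contains(self, taxon: str, needle: str) -> bool:
        needle = needle.casefold()
        return any(needle in str(v).casefold() for v in self.data.loc[taxon])

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t")


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a ``k__X; p__Y; ...`` lineage into rank → name.

    Rank prefixes are matched case-insensitively; unprefixed tokens are
    assigned positionally. Missing ranks are left empty.
    """
    out = {r: "" for r in RANKS}
    tokens = [t.strip() for t in str(lineage).split(";")]
    tokens = [t for t in tokens if t != ""]
    positional = 0
    for tok in tokens:
        if len(tok) >= 3 and tok[1:3] == "__" and tok[0].lower() in _PREFIX_TO_RANK:
            rank = _PREFIX_TO_RANK[tok[0].lower()]
            out[rank] = tok[3:].strip()
            positional = RANKS.index(rank) + 1
        else:
            if positional < len(RANKS):
                out[RANKS[positional]] = tok
                positional += 1
    return out


def read_taxonomy(path) -> TaxonomyTable:
    """Read a two-column TSV ``taxon_id <tab> lineage``."""
    df = pd.read_csv(path, sep="\t", comment="#", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: taxonomy needs taxon_id and lineage columns")
    ids = df.iloc[:, 0].astype(str).str.strip()
    if ids.isna().any() or (ids == "").any():
        raise FormatError(f"{path}: missing taxon id")
    rows = {}
    short = 0
    for taxon, lineage in zip(ids, df.iloc[:, 1].fillna("")):
        parsed = parse_lineage(lineage)
        if len([t for t in str(lineage).split(";") if t.strip()]) < len(RANKS):
            short += 1
        rows[taxon] = parsed
    if short:
        warnings.warn(
            f"{short} lineage(s) had fewer than {len(RANKS)} ranks; padded with empty",
            stacklevel=2,
        )
    table = TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index"))
    logger.info("read taxonomy %s: %d taxa", path, len(table.taxon_ids))
    return table


# ---------------------------------------------------------------------------
# SampleMetadata


@dataclass
class SampleMetadata:
    """sample_id → stage/site/plot, with stage from the closed set."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"stage", "site", "plot"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"metadata missing column(s): {sorted(missing)}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample id(s) in metadata: {dup}")
        bad = sorted(set(self.data["stage"]) - set(STAGES))
        if bad:
            raise ValidationError(
                f"unknown stage label(s) {bad}; allowed: {list(STAGES)}"
            )
        self.data = self.data.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def stage_of(self, sample: str) -> str:
        return self.data.at[sample, "stage"]

    def stages_present(self) -> list[str]:
        present = set(self.data["stage"])
        return [s for s in STAGES if s in present]

    def samples_for_stage(self, stage: str) -> list[str]:
        return list(self.data.index[self.data["stage"] == stage])

    def stage_series(self, samples=None) -> pd.Series:
        s = self.data["stage"]
        return s if samples is None else s.loc[list(samples)]

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: metadata requires a sample_id column")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


# ---------------------------------------------------------------------------
# TraitDatabase


@dataclass
class TraitDatabase:
    """Functional trait lookup.

    ``bacterial`` maps a normalised (casefolded) genus to a frozenset of
    trait labels from {Bioc, PGP, SR}; ``fungal`` maps a normalised
    taxon name to a plant-pathogenic flag.
    """

    bacterial: dict[str, frozenset] = field(default_factory=dict)
    fungal: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for genus, traits in self.bacterial.items():
            if not traits:
                raise ValidationError(f"genus {genus!r} has no traits")
            bad = set(traits) - set(BACTERIAL_TRAITS)
            if bad:
                raise ValidationError(f"unknown trait(s) {sorted(bad)} for {genus!r}")

    @staticmethod
    def normalize(name: str) -> str:
        name = str(name).strip()
        if len(name) >= 3 and name[1:3] == "__":
            name = name[3:]
        return name.casefold()

    def bacterial_traits(self, genus: str) -> frozenset:
        return self.bacterial.get(self.normalize(genus), frozenset())

    def fungal_pathogenic(self, taxon: str) -> bool:
        return self.fungal.get(self.normalize(taxon), False)

    def has_fungal(self, taxon: str) -> bool:
        return self.normalize(taxon) in self.fungal

    def to_tsv(self, path) -> None:
        rows = [
            {"taxon": g, "kingdom": "bacteria", "traits": "|".join(sorted(t))}
            for g, t in sorted(self.bacterial.items())
        ] + [
            {
                "taxon": t,
                "kingdom": "fungi",
                "traits": "pathogenic" if flag else "nonpathogenic",
            }
            for t, flag in sorted(self.fungal.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_trait_db(path) -> TraitDatabase:
    """Read a trait TSV with columns taxon, kingdom, traits.

    Bacterial trait cells are ``|``-separated subsets of Bioc|PGP|SR;
    fungal cells are ``pathogenic``/``nonpathogenic`` (or ``FPP``).
    Rows with an empty traits field are rejected.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"taxon", "kingdom", "traits"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: trait table missing column(s): {sorted(missing)}")
    bacterial: dict[str, frozenset] = {}
    fungal: dict[str, bool] = {}
    for _, row in df.iterrows():
        taxon = TraitDatabase.normalize(row["taxon"])
        traits = str(row["traits"]).strip() if pd.notna(row["traits"]) else ""
        if not taxon or not traits or traits.lower() == "nan":
            raise FormatError(f"{path}: empty taxon or traits field in row {row.to_dict()}")
        kingdom = str(row["kingdom"]).strip().lower()
        if kingdom.startswith("bact"):
            labels = frozenset(t.strip() for t in traits.split("|") if t.strip())
            if taxon in bacterial:
                raise FormatError(f"{path}: duplicate bacterial genus {row['taxon']!r}")
            bacterial[taxon] = labels
        elif kingdom.startswith("fung"):
            if taxon in fungal:
                raise FormatError(f"{path}: duplicate fungal taxon {row['taxon']!r}")
            fungal[taxon] = traits.strip().lower() in ("pathogenic", "fpp", "true", "1")
        else:
            raise FormatError(f"{path}: unknown kingdom {row['kingdom']!r}")
    return TraitDatabase(bacterial=bacterial, fungal=fungal)


# ---------------------------------------------------------------------------
# Dataset + validation


@dataclass
class Dataset:
    """Complete paired amplicon dataset: bacterial and fungal tables with
    their taxonomies, shared sample metadata and trait database."""

    bacterial: FeatureTable
    fungal: FeatureTable
    bacterial_taxonomy: TaxonomyTable
    fungal_taxonomy: TaxonomyTable
    metadata: SampleMetadata
    traits: TraitDatabase


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    message: str


def validate_dataset(ds: Dataset) -> list[Finding]:
    """Cross-check table/taxonomy/metadata consistency.

    Errors block the pipeline; warnings are informational. Findings are
    deterministic given the input.
    """
    findings: list[Finding] = []
    meta = set(ds.metadata.sample_ids)
    for label, table in (("bacterial", ds.bacterial), ("fungal", ds.fungal)):
        missing = sorted(set(table.sample_ids) - meta)
        if missing:
            findings.append(
                Finding("error", f"{label} sample(s) absent from metadata: {missing}")
            )
    for label, table, tax in (
        ("bacterial", ds.bacterial, ds.bacterial_taxonomy),
        ("fungal", ds.fungal, ds.fungal_taxonomy),
    ):
        missing = sorted(set(table.taxon_ids) - set(tax.taxon_ids))
        if missing:
            findings.append(
                Finding(
                    "warning",
                    f"{len(missing)} {label} taxa missing from taxonomy "
                    f"(first: {missing[:5]})",
                )
            )
    bac, fun = set(ds.bacterial.sample_ids), set(ds.fungal.sample_ids)
    unpaired = sorted(bac ^ fun)
    if unpaired:
        findings.append(
            Finding(
                "warning",
                "sample(s) present in only one table (paired analyses are "
                f"restricted to shared samples): {unpaired}",
            )
        )
    return findings
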