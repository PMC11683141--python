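"""Per-guild alpha diversity and stage-wise succession testing.

Alpha diversity is summarised per sample as observed richness, the
Chao1 estimator and Shannon entropy (natural log). Stage differences are
tested nonparametrically: a tie-corrected Kruskal–Wallis test followed
by the Nemenyi all-pairs post hoc on mean ranks (studentized-range
approximation), summarised as a compact letter display.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import STAGES, FeatureTable, SampleMetadata, TaxonomyTable
from .guilds import GuildAssignment, subset_by_guild


# ---------------------------------------------------------------------------
# Alpha diversity


def alpha_diversity(table: FeatureTable) -> pd.DataFrame:
    """Richness, Chao1 and Shannon (nats) per sample.

    Chao1 = S_obs + F1·(F1−1) / (2·(F2+1)) with F1/F2 the singleton and
    doubleton counts; Shannon H = −Σ p_i ln p_i over present taxa.
    All-zero samples get zero diversity with a warning.
    """
    counts = table.counts
    rows = []
    for j, sample in enumerate(table.sample_ids):
        col = counts[:, j]
        present = col[col > 0]
        s_obs = present.size
        if s_obs == 0:
            warnings.warn(f"sample {sample!r} has no reads; diversity 0", stacklevel=2)
            rows.append({"sample_id": sample, "richness": 0, "chao1": 0.0, "shannon": 0.0})
            continue
        f1 = int(np.sum(present == 1))
        f2 = int(np.sum(present == 2))
        chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        p = present / present.sum()
        shannon = float(-np.sum(p * np.log(p)))
        rows.append(
            {"sample_id": sample, "richness": s_obs, "chao1": chao1, "shannon": shannon}
        )
    return pd.DataFrame(rows).set_index("sample_id")


def guild_alpha_diversity(
    table: FeatureTable,
    assignment: GuildAssignment,
    guild: str,
    metadata: SampleMetadata | None = None,
) -> pd.DataFrame:
    """Alpha diversity of one guild's subcommunity, optionally annotated
    with the stage of each sample."""
    sub = subset_by_guild(table, assignment, guild)
    alpha = alpha_diversity(sub)
    alpha["guild"] = guild
    if metadata is not None:
        alpha["stage"] = metadata.stage_series(alpha.index).to_numpy()
    return alpha


# ---------------------------------------------------------------------------
# Kruskal–Wallis + Nemenyi + compact letter display


@dataclass
class StageTestResult:
    """Kruskal–Wallis omnibus + Nemenyi pairwise matrix + letters."""

    h: float
    df: int
    p: float
    pairwise_p: pd.DataFrame  # stages × stages, symmetric, unit diagonal
    letters: dict[str, str]
    group_sizes: dict[str, int]


def _nemenyi_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All-pairs Nemenyi p-values on mean ranks.

    The statistic |R̄_i − R̄_j| / sqrt(N(N+1)/12 · (1/n_i + 1/n_j)) is
    referred to the studentized range distribution (k groups, infinite
    df) after scaling by √2 — the classic Tukey-type post hoc for the
    Kruskal–Wallis setting. Ties are handled by average ranks.
    """
    labels = list(groups)
    k = len(labels)
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    offset = 0
    for g in labels:
        n = groups[g].size
        mean_ranks[g] = ranks[offset : offset + n].mean()
        sizes[g] = n
        offset += n
    out = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    big_df = 1e7  # studentized range with df → ∞
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(
            n_total * (n_total + 1) / 12.0 * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        q = abs(mean_ranks[a] - mean_ranks[b]) / se * np.sqrt(2.0)
        p = float(stats.studentized_range.sf(q, k, big_df))
        out.loc[a, b] = out.loc[b, a] = min(1.0, p)
    return out


def compact_letter_display(
    pairwise_p: pd.DataFrame, alpha: float = 0.05, order: list[str] | None = None
) -> dict[str, str]:
    """Insert–absorb compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``.
    Letters are assigned following ``order`` (default: row order).
    """
    labels = order if order is not None else list(pairwise_p.index)
    letter_sets: list[set] = [set(labels)]
    for a, b in itertools.combinations(labels, 2):
        if pairwise_p.loc[a, b] >= alpha:
            continue
        new_sets = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        letter_sets = [
            s
            for i, s in enumerate(new_sets)
            if s and not any(s < t or (s == t and i > j) for j, t in enumerate(new_sets))
        ]
    # assign letter characters in group order for stable output
    letter_sets.sort(key=lambda s: min(labels.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in labels}
    for ch, s in zip(alphabet, letter_sets):
        for g in labels:
            if g in s:
                out[g] += ch
    return out


def kruskal_wallis_by_stage(
    values: pd.Series,
    metadata: SampleMetadata,
    alpha: float = 0.05,
    min_group_size: int = 2,
) -> StageTestResult:
    """Tie-corrected Kruskal–Wallis across stages with Nemenyi post hoc.

    Stages with fewer than ``min_group_size`` samples are excluded with
    a warning. Identical values everywhere give H = 0, p = 1.
    """
    stage = metadata.stage_series(values.index)
    groups: dict[str, np.ndarray] = {}
    for st in [s for s in STAGES if s in set(stage)]:
        vals = values[stage == st].to_numpy(dtype=float)
        if vals.size < min_group_size:
            warnings.warn(
                f"stage {st!r} has {vals.size} sample(s) (<{min_group_size}); excluded",
                stacklevel=2,
            )
            continue
        groups[st] = vals
    if len(groups) < 2:
        raise ValueError("need at least two stages with enough samples")
    arrays = list(groups.values())
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    pairwise = _nemenyi_pairwise(groups)
    letters = compact_letter_display(pairwise, alpha=alpha, order=list(groups))
    return StageTestResult(
        h=float(h),
        df=len(groups) - 1,
        p=float(p),
        pairwise_p=pairwise,
        letters=letters,
        group_sizes={g: v.size for g, v in groups.items()},
    )


# ---------------------------------------------------------------------------
# Relative abundance & composition


def guild_relative_abundance(
    table: FeatureTable, assignment: GuildAssignment, guild: str
) -> pd.Series:
    """Per-sample fraction of reads belonging to one guild, in [0, 1]."""
    members = set(assignment.guild_taxa(guild))
    mask = np.array([t in members for t in table.taxon_ids])
    totals = table.counts.sum(axis=0).astype(float)
    frac = table.counts[mask].sum(axis=0) / np.where(totals == 0, np.nan, totals)
    return pd.Series(frac, index=table.sample_ids, name=guild)


def composition_summary(
    table: FeatureTable,
    taxonomy: TaxonomyTable,
    rank: str,
    metadata: SampleMetadata,
) -> pd.DataFrame:
    """Stage × taxon-group mean relative abundance at one rank.

    Per-sample relative abundances are aggregated at ``rank`` (taxa with
    no assignment pooled as "Unclassified") and averaged within stage;
    each stage row sums to 1.
    """
    if rank not in taxonomy.data.columns:
        raise ValueError(f"unknown rank {rank!r}")
    rel = table.relative_abundance()
    names = [
        taxonomy.rank(t, rank) if t in set(taxonomy.taxon_ids) else ""
        for t in table.taxon_ids
    ]
    names = [n if n else "Unclassified" for n in names]
    agg = rel.groupby(pd.Index(names, name=rank)).sum()
    stage = metadata.stage_series(agg.columns)
    by_stage = agg.T.groupby(stage.to_numpy()).mean()
    by_stage.index.name = "stage"
    order = [s for s in STAGES if s in by_stage.index]
    return by_stage.loc[order]
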