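"""Spearman-based antagonism analysis between plant-beneficial bacteria
and fungal plant pathogens.

Guild-level correlations (richness–richness and abundance–abundance) are
computed overall and within each developmental stage. A per-stage screen
correlates each widespread beneficial ASV (prevalence strictly above one
half within the stage) against the total FPP relative abundance, with
Benjamini–Hochberg correction within stage; ASVs that are significantly
negative in at least three stages are called persistent antagonists.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import STAGES, FeatureTable, SampleMetadata, TaxonomyTable


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation and its t-based p-value.

    Returns (nan, nan) for constant input; requires length >= 4.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaN-safe)."""
    q = np.full_like(p, np.nan, dtype=float)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def guild_correlations(
    metrics: pd.DataFrame,
    metadata: SampleMetadata,
    against: str = "FPP",
    per_stage: bool = True,
    min_n: int = 4,
) -> pd.DataFrame:
    """Spearman correlation of each guild series against the FPP series.

    ``metrics`` holds one column per guild (e.g. richness or relative
    abundance series aligned on samples) including the ``against``
    column. Rows are returned for the pooled "overall" correlation and,
    if requested, for every stage; stages with fewer than ``min_n``
    samples give NaN with a warning.
    """
    if against not in metrics.columns:
        raise ValueError(f"column {against!r} missing from metrics")
    stage = metadata.stage_series(metrics.index)
    scopes: list[tuple[str, pd.Index]] = [("overall", metrics.index)]
    if per_stage:
        for st in [s for s in STAGES if s in set(stage)]:
            scopes.append((st, metrics.index[(stage == st).to_numpy()]))
    rows = []
    for scope, samples in scopes:
        sub = metrics.loc[samples]
        for guild in metrics.columns:
            if guild == against:
                continue
            if len(samples) < min_n:
                warnings.warn(
                    f"stage {scope!r} has n={len(samples)} < {min_n}; NaN", stacklevel=2
                )
                rho = p = float("nan")
            else:
                rho, p = spearman(sub[guild], sub[against])
            rows.append(
                {"pair": f"{guild}~{against}", "guild": guild, "stage": scope,
                 "rho": rho, "p": p, "n": len(samples)}
            )
    return pd.DataFrame(rows)


def widespread_asv_screen(
    pbb_table: FeatureTable,
    fpp_abundance: pd.Series,
    metadata: SampleMetadata,
    min_prevalence: float = 0.5,
    alpha: float = 0.05,
    global_prevalence: bool = False,
) -> pd.DataFrame:
    """Per-stage Spearman screen of widespread beneficial ASVs vs FPP.

    Within each stage, ASVs present in strictly more than
    ``min_prevalence`` of that stage's samples are correlated (relative
    abundance) against the total FPP relative abundance; p-values are BH
    adjusted within the stage. ``global_prevalence=True`` applies the
    prevalence filter across all samples instead.
    """
    rel = pbb_table.relative_abundance()
    stage = metadata.stage_series(pbb_table.sample_ids)
    present = pbb_table.data > 0
    if global_prevalence:
        global_keep = present.mean(axis=1) > min_prevalence
    frames = []
    for st in [s for s in STAGES if s in set(stage)]:
        samples = [s for s, g in stage.items() if g == st]
        if global_prevalence:
            keep = global_keep
        else:
            keep = present[samples].mean(axis=1) > min_prevalence
        taxa = keep.index[keep].tolist()
        if not taxa:
            warnings.warn(f"no widespread ASV in stage {st!r}", stacklevel=2)
            continue
        fpp = fpp_abundance.loc[samples].to_numpy()
        rows = []
        for taxon in taxa:
            rho, p = spearman(rel.loc[taxon, samples].to_numpy(), fpp)
            rows.append({"stage": st, "taxon_id": taxon, "rho": rho, "p": p,
                         "n": len(samples)})
        frame = pd.DataFrame(rows)
        frame["q"] = _bh(frame["p"].to_numpy())
        frame["significant"] = frame["q"] < alpha
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=["stage", "taxon_id", "rho", "p", "n", "q", "significant"]
        )
    return pd.concat(frames, ignore_index=True)


def persistent_antagonists(
    screen: pd.DataFrame,
    taxonomy: TaxonomyTable | None = None,
    min_stages: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ASVs significantly (BH q < alpha) and negatively correlated with
    FPP in at least ``min_stages`` stages, with genus labels attached."""
    hits = screen[(screen["q"] < alpha) & (screen["rho"] < 0)]
    counts = hits.groupby("taxon_id").size()
    taxa = counts.index[counts >= min_stages].tolist()
    out = pd.DataFrame({"taxon_id": taxa, "n_stages": [int(counts[t]) for t in taxa]})
    if taxonomy is not None:
        out["genus"] = [
            taxonomy.genus(t) if t in set(taxonomy.taxon_ids) else "" for t in taxa
        ]
    return out.set_index("taxon_id")


# ---------------------------------------------------------------------------
# Phylogeny annotation export


@dataclass
class PhylogenyAnnotation:
    """Tables aligned to tree tip order for external tree-annotation tools."""

    tip_order: list[str]
    heatmap: pd.DataFrame  # tips × stages, ρ values (NaN where untested)
    guild_ring: pd.DataFrame  # tips × guild flags
    mismatches: list[str] = field(default_factory=list)


def export_phylogeny_annotation(
    newick: str,
    screen: pd.DataFrame,
    guild_flags: pd.DataFrame | None = None,
) -> PhylogenyAnnotation:
    """Map screen correlations onto the tips of a Newick tree.

    ``newick`` may be a path or a Newick string. Tips absent from the
    screen results get blank (NaN) rows and are listed in
    ``mismatches``; taxa in the screen but not on the tree are also
    reported there. The tree itself is not modified.
    """
    from skbio import TreeNode

    try:
        handle = _io.StringIO(newick) if str(newick).strip().startswith("(") else newick
        tree = TreeNode.read(handle)
    except Exception as exc:  # pragma: no cover - skbio error text varies
        raise ValueError(f"could not parse Newick input: {exc}") from exc
    tips = [t.name for t in tree.tips()]
    stages = [s for s in STAGES if s in set(screen["stage"])]
    rho = screen.pivot_table(index="taxon_id", columns="stage", values="rho")
    heat = pd.DataFrame(np.nan, index=tips, columns=stages)
    mismatches = []
    for tip in tips:
        if tip in rho.index:
            heat.loc[tip] = rho.loc[tip].reindex(stages)
        else:
            mismatches.append(tip)
            warnings.warn(f"tree tip {tip!r} absent from screen results", stacklevel=2)
    mismatches += sorted(set(rho.index) - set(tips))
    if guild_flags is not None:
        ring = guild_flags.reindex(tips)
    else:
        ring = pd.DataFrame(index=tips)
    return PhylogenyAnnotation(
        tip_order=tips, heatmap=heat, guild_ring=ring, mismatches=mismatches
    )
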