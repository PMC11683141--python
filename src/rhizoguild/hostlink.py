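"""Linking root transcriptome succession to assembly determinism.

The workflow: FPKM normalisation → stage-mean, per-gene z-scored
profiles → fuzzy c-means clustering of trajectories → ranking clusters
by correlation with the deterministic assembly share (1 − NTR) of the
biocontrol subcommunity → hypergeometric pathway enrichment of the
matched cluster → thresholded Spearman co-expression network within the
matched cluster → extraction of transcription-factor ↔ biosynthesis-gene
bipartite links.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .antagonism import _bh, spearman


# ---------------------------------------------------------------------------
# Expression preprocessing


def fpkm(
    counts: pd.DataFrame, gene_lengths_bp: pd.Series, mapped_totals: pd.Series
) -> pd.DataFrame:
    """FPKM_gs = count_gs · 10⁹ / (length_g · total_s)."""
    lengths = gene_lengths_bp.reindex(counts.index)
    totals = mapped_totals.reindex(counts.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        bad = lengths.index[lengths.isna() | (lengths <= 0)].tolist()[:5]
        raise ValueError(f"missing/non-positive gene length(s), e.g. {bad}")
    if totals.isna().any() or (totals <= 0).any():
        bad = totals.index[totals.isna() | (totals <= 0)].tolist()[:5]
        raise ValueError(f"missing/non-positive mapped total(s), e.g. {bad}")
    return counts * 1e9 / np.outer(lengths.to_numpy(), totals.to_numpy())


def stage_profiles(
    expr: pd.DataFrame, sample_stages: pd.Series, stage_order=None
) -> pd.DataFrame:
    """Mean expression per stage, z-scored per gene across stages.

    Zero-variance genes are dropped with a warning.
    """
    stages = sample_stages.reindex(expr.columns)
    means = expr.T.groupby(stages.to_numpy()).mean().T
    if stage_order is not None:
        means = means[[s for s in stage_order if s in means.columns]]
    sd = means.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"dropping {int(flat.sum())} zero-variance gene(s)", stacklevel=2)
    means = means.loc[~flat]
    return means.sub(means.mean(axis=1), axis=0).div(sd[~flat], axis=0)


# ---------------------------------------------------------------------------
# Fuzzy c-means


@dataclass
class FuzzyClustering:
    k: int
    fuzzifier: float
    membership: pd.DataFrame  # genes × clusters, rows sum to 1
    centroids: pd.DataFrame  # clusters × stages
    labels: pd.Series  # hard assignment by max membership
    objective: list[float] = field(repr=False, default_factory=list)
    n_iter: int = 0


def _farthest_point_init(
    x: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k-means++-style seeding: first centre uniform, then sample
    proportionally to squared distance from the nearest chosen centre."""
    n = x.shape[0]
    centres = [x[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            [np.sum((x - c) ** 2, axis=1) for c in centres], axis=0
        )
        if d2.sum() == 0:
            centres.append(x[rng.integers(n)])
            continue
        centres.append(x[rng.choice(n, p=d2 / d2.sum())])
    return np.array(centres)


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    k: int = 5,
    fuzzifier: float = 1.25,
    seed: int = 17,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FuzzyClustering:
    """Fuzzy c-means with the standard alternating updates.

    Minimises Σ_g Σ_j u_gj^φ ‖x_g − c_j‖² with
    u_gj = 1 / Σ_l (‖x_g − c_j‖ / ‖x_g − c_l‖)^{2/(φ−1)} and
    c_j = Σ_g u_gj^φ x_g / Σ_g u_gj^φ. A point coinciding with a
    centroid gets membership 1 to that cluster (limit rule). Converged
    when max |ΔU| < ``tol``.
    """
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    x = profiles.to_numpy(dtype=float)
    n = x.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of genes")
    rng = np.random.default_rng(seed)
    centroids = _farthest_point_init(x, k, rng)
    exponent = 2.0 / (fuzzifier - 1.0)
    u = np.full((n, k), 1.0 / k)
    objective = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = np.array([np.sum((x - c) ** 2, axis=1) for c in centroids]).T  # n × k
        # memberships via distance ratios to the per-point minimum: the
        # ratio is >= 1, so the negative power cannot overflow
        dmin = d2.min(axis=1, keepdims=True)
        zero = d2 <= np.maximum(1e-30, 1e-12 * dmin.max())
        any_zero = zero.any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            ratio = d2 / np.where(dmin == 0, 1.0, dmin)
            inv = ratio ** (-exponent / 2.0)
            u_new = inv / inv.sum(axis=1, keepdims=True)
        if any_zero.any():
            u_new[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
        w = u_new**fuzzifier
        centroids = (w.T @ x) / w.sum(axis=0)[:, None]
        objective.append(float(np.sum(w * d2)))
        delta = np.max(np.abs(u_new - u))
        u = u_new
        if delta < tol:
            break
    cluster_ids = [f"C{i + 1}" for i in range(k)]
    membership = pd.DataFrame(u, index=profiles.index, columns=cluster_ids)
    labels = membership.idxmax(axis=1)
    return FuzzyClustering(
        k=k,
        fuzzifier=fuzzifier,
        membership=membership,
        centroids=pd.DataFrame(centroids, index=cluster_ids, columns=profiles.columns),
        labels=labels,
        objective=objective,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# Trend matching


def trend_match(
    clustering: FuzzyClustering,
    determinism: pd.Series,
    method: str = "pearson",
) -> pd.DataFrame:
    """Rank clusters by correlation of their centroid with the
    deterministic-assembly trajectory over shared stages.

    Both vectors are z-scored before a Pearson correlation (the default;
    Spearman available). Needs at least 3 shared stages.
    """
    shared = [s for s in clustering.centroids.columns if s in determinism.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared stages for trend matching")
    d = determinism.loc[shared].to_numpy(dtype=float)
    d = (d - d.mean()) / d.std(ddof=0)
    rows = []
    for cid, centroid in clustering.centroids.iterrows():
        c = centroid.loc[shared].to_numpy(dtype=float)
        c = (c - c.mean()) / c.std(ddof=0)
        if method == "pearson":
            score = float(np.corrcoef(c, d)[0, 1])
        elif method == "spearman":
            score = float(stats.spearmanr(c, d)[0])
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"cluster": cid, "score": score})
    out = pd.DataFrame(rows).sort_values("score", ascending=False).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# Enrichment


def enrich(
    gene_set, pathway_map: dict[str, set], universe
) -> pd.DataFrame:
    """Hypergeometric over-representation test per pathway with BH.

    p = P(X ≥ k) for X ~ Hypergeom(N, K, n) with universe size N,
    pathway size K (after intersecting the universe), set size n and
    overlap k. Pathways empty after intersection are skipped.
    """
    universe = set(universe)
    gene_set = set(gene_set) & universe
    n = len(gene_set)
    big_n = len(universe)
    rows = []
    for pathway, genes in pathway_map.items():
        members = set(genes) & universe
        if not members:
            continue
        k = len(gene_set & members)
        big_k = len(members)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"pathway": pathway, "k": k, "K": big_k, "n": n, "N": big_n, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = _bh(out["p"].to_numpy())
        out = out.sort_values("p").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Co-expression network


def coexpression_network(
    expr: pd.DataFrame,
    genes=None,
    rho_min: float = 0.9,
    q_max: float = 0.001,
) -> nx.Graph:
    """Thresholded Spearman co-expression network.

    ``expr`` is genes × samples; all pairs among ``genes`` (default all)
    are tested, edges kept when ρ > rho_min AND BH-adjusted p < q_max
    (the BH family is all tested pairs). Needs ≥ 6 samples.
    """
    if expr.shape[1] < 6:
        raise ValueError("need at least 6 samples for a meaningful network")
    if genes is not None:
        expr = expr.loc[[g for g in genes if g in expr.index]]
    ids = list(expr.index)
    x = expr.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(ranks**2, axis=1))
    constant = norms == 0
    norms[constant] = 1.0
    rho = (ranks / norms[:, None]) @ (ranks / norms[:, None]).T
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    iu = np.triu_indices(len(ids), k=1)
    rho_flat = rho[iu]
    n = expr.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho_flat * np.sqrt((n - 2) / np.maximum(1.0 - rho_flat**2, 1e-300))
    p_flat = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p_flat[np.isnan(rho_flat)] = np.nan
    q_flat = _bh(p_flat)
    net = nx.Graph()
    net.add_nodes_from(ids)
    for (i, j), r, q in zip(zip(*iu), rho_flat, q_flat):
        if np.isnan(r):
            continue
        if r > rho_min and q < q_max:
            net.add_edge(ids[i], ids[j], rho=float(r), q=float(q))
    return net


def pathway_subnetwork(net: nx.Graph, pathway_genes) -> tuple[nx.Graph, list[str]]:
    """Induced subgraph on pathway genes plus their direct neighbours.

    Pathway genes absent from the network are returned as isolated.
    """
    pathway_genes = list(pathway_genes)
    isolated = [g for g in pathway_genes if g not in net]
    seeds = [g for g in pathway_genes if g in net]
    nodes = set(seeds)
    for g in seeds:
        nodes.update(net.neighbors(g))
    return net.subgraph(nodes).copy(), isolated


def tf_bipartite(
    net: nx.Graph, tf_table: dict[str, str], biosynthesis_genes
) -> pd.DataFrame:
    """Direct TF ↔ biosynthesis-gene edges of the network.

    ``tf_table`` maps gene id → TF family. TF–TF edges are excluded
    (unless one endpoint is also a biosynthesis gene and not a TF).
    Returns an edge list with the TF family attached; the distinct TF
    count is ``out["tf"].nunique()``.
    """
    tfs = set(tf_table)
    targets = set(biosynthesis_genes) - tfs
    rows = []
    for a, b, attrs in net.edges(data=True):
        if a in tfs and b in targets:
            tf, gene = a, b
        elif b in tfs and a in targets:
            tf, gene = b, a
        else:
            continue
        rows.append(
            {"tf": tf, "tf_family": tf_table[tf], "gene": gene,
             "rho": attrs.get("rho", np.nan)}
        )
    return pd.DataFrame(rows, columns=["tf", "tf_family", "gene", "rho"])
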