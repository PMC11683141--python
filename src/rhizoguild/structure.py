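"""β-diversity succession: Bray–Curtis distances, PCoA ordination,
PERMANOVA, β-dispersion, SIMPER taxon contributions and local-polynomial
abundance trajectories.

PCoA is computed by Gower double-centering of −½D² followed by an
eigendecomposition; negative eigenvalues (possible for semi-metric
Bray–Curtis) are reported, not corrected, and the imaginary-axis block
is retained so β-dispersion can subtract squared distances on those axes
(Anderson's convention). PERMANOVA partitions the squared distances into
among- and within-group sums of squares and assesses the pseudo-F by
seeded label permutation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import FeatureTable, SampleMetadata, ValidationError


# ---------------------------------------------------------------------------
# Distances


@dataclass
class DistanceMatrix:
    """Symmetric sample × sample dissimilarity matrix with zero diagonal."""

    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.sample_ids):
            raise ValidationError("distance matrix shape does not match sample ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        self.matrix = m

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)

    def subset(self, samples) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in samples]
        return DistanceMatrix(list(samples), self.matrix[np.ix_(idx, idx)])


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity BC(x, y) = Σ|x−y| / Σ(x+y) between all
    sample pairs; zero-sum samples make the pair undefined and raise."""
    sums = table.column_sums()
    empty = sums.index[sums == 0].tolist()
    if empty:
        raise ValidationError(f"zero-sum sample(s) make Bray–Curtis undefined: {empty}")
    condensed = pdist(table.counts.T.astype(float), metric="braycurtis")
    return DistanceMatrix(table.sample_ids, squareform(condensed))


def jaccard(table: FeatureTable) -> DistanceMatrix:
    """Incidence-based Jaccard dissimilarity between all sample pairs."""
    presence = (table.counts.T > 0).astype(float)
    condensed = pdist(presence, metric="jaccard")
    return DistanceMatrix(table.sample_ids, squareform(condensed))


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class OrdinationResult:
    """Principal coordinates with positive- and negative-eigenvalue blocks."""

    sample_ids: list[str]
    coordinates: pd.DataFrame  # samples × positive axes, scaled by sqrt(λ)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues
    #: coordinates on negative-eigenvalue ("imaginary") axes, scaled by sqrt(|λ|)
    imaginary_coordinates: pd.DataFrame = field(repr=False, default=None)


def pcoa(dm: DistanceMatrix, eps: float = 1e-9) -> OrdinationResult:
    """Classical scaling of a distance matrix.

    Double-centers −½D², eigendecomposes, and sorts axes by eigenvalue.
    Percent explained is reported over the positive eigenvalues only.
    """
    d2 = dm.matrix**2
    n = dm.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > eps
    neg = evals < -eps
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    imag = evecs[:, neg] * np.sqrt(-evals[neg])
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    prop = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    return OrdinationResult(
        sample_ids=dm.sample_ids,
        coordinates=pd.DataFrame(coords, index=dm.sample_ids, columns=axes),
        eigenvalues=evals,
        proportion_explained=prop,
        imaginary_coordinates=pd.DataFrame(
            imag,
            index=dm.sample_ids,
            columns=[f"NegAx{i + 1}" for i in range(imag.shape[1])],
        ),
    )


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    factor: str
    ss_among: float
    ss_within: float
    ss_total: float
    pseudo_f: float
    r2: float
    p: float
    n_permutations: int


def _ss_within(d2: np.ndarray, group_indices: list[np.ndarray]) -> float:
    ss = 0.0
    for idx in group_indices:
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def permanova(
    dm: DistanceMatrix,
    metadata: SampleMetadata,
    factor: str = "stage",
    n_perm: int = 999,
    seed: int = 17,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    SS_total = Σ_{i<j} d²_ij / n; SS_within is the analogous pooled
    within-group sum; pseudo-F = (SS_among/(k−1)) / (SS_within/(n−k)).
    The p-value is (1 + #{F_perm ≥ F_obs}) / (1 + n_perm) under seeded
    permutation of the group labels.
    """
    # canonical sample order so the seeded permutation stream (and hence
    # the p-value) does not depend on input ordering
    dm = dm.subset(sorted(dm.sample_ids))
    labels = metadata.data.loc[dm.sample_ids, factor].to_numpy()
    levels, inverse = np.unique(labels, return_inverse=True)
    k = levels.size
    if k < 2:
        raise ValueError(f"factor {factor!r} needs >=2 levels")
    sizes = np.bincount(inverse)
    if (sizes < 2).any():
        singles = levels[sizes < 2].tolist()
        raise ValueError(f"group(s) of size 1 not allowed: {singles}")
    n = dm.n
    d2 = dm.matrix**2
    ss_total = d2.sum() / (2.0 * n)
    group_idx = [np.where(inverse == g)[0] for g in range(k)]
    ss_within = _ss_within(d2, group_idx)
    ss_among = ss_total - ss_within
    f_obs = (ss_among / (k - 1)) / (ss_within / (n - k))
    rng = np.random.default_rng(seed)
    count = 0
    sizes_list = [idx.size for idx in group_idx]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        start = 0
        ss_w = 0.0
        for sz in sizes_list:
            idx = perm[start : start + sz]
            ss_w += d2[np.ix_(idx, idx)].sum() / (2.0 * sz)
            start += sz
        f_perm = ((ss_total - ss_w) / (k - 1)) / (ss_w / (n - k))
        if f_perm >= f_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return PermanovaResult(
        factor=factor,
        ss_among=float(ss_among),
        ss_within=float(ss_within),
        ss_total=float(ss_total),
        pseudo_f=float(f_obs),
        r2=float(ss_among / ss_total),
        p=float(p),
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# β-dispersion


def beta_dispersion(
    dm: DistanceMatrix, metadata: SampleMetadata, factor: str = "stage"
) -> pd.DataFrame:
    """Distance of every sample to its group centroid in PCoA space.

    Centroids are computed on both the real and imaginary axis blocks;
    squared distances on imaginary axes are subtracted (Anderson's
    convention for semi-metric dissimilarities). Singleton groups yield
    NaN with a warning.
    """
    ord_res = pcoa(dm)
    real = ord_res.coordinates.to_numpy()
    imag = ord_res.imaginary_coordinates.to_numpy()
    labels = metadata.data.loc[dm.sample_ids, factor]
    dist = np.full(dm.n, np.nan)
    for level in labels.unique():
        idx = np.where((labels == level).to_numpy())[0]
        if idx.size < 2:
            warnings.warn(
                f"group {level!r} has a single sample; dispersion undefined",
                stacklevel=2,
            )
            continue
        c_real = real[idx].mean(axis=0)
        c_imag = imag[idx].mean(axis=0) if imag.size else np.zeros(0)
        for i in idx:
            sq = np.sum((real[i] - c_real) ** 2)
            if imag.size:
                sq -= np.sum((imag[i] - c_imag) ** 2)
            dist[i] = np.sqrt(max(sq, 0.0))
    return pd.DataFrame(
        {"group": labels.to_numpy(), "distance_to_centroid": dist},
        index=dm.sample_ids,
    )


# ---------------------------------------------------------------------------
# SIMPER


@dataclass
class SimperResult:
    """Per-taxon contributions to between-group Bray–Curtis dissimilarity."""

    #: (group_a, group_b) → Series of per-taxon mean contributions
    pairwise: dict[tuple[str, str], pd.Series]
    #: taxa ranked by total contribution summed over all group pairs
    overall_ranking: pd.Series

    def mean_dissimilarity(self, pair: tuple[str, str]) -> float:
        return float(self.pairwise[pair].sum())

    def top(self, n: int = 15) -> list[str]:
        return list(self.overall_ranking.index[:n])


def simper(
    table: FeatureTable, metadata: SampleMetadata, factor: str = "stage"
) -> SimperResult:
    """SIMPER decomposition of between-group Bray–Curtis dissimilarity.

    For each between-group sample pair the per-taxon term is
    |x_i − y_i| / Σ_j (x_j + y_j); a taxon's contribution for a group
    pair is the mean of this term over all cross pairs, so contributions
    sum exactly to the mean between-group dissimilarity.
    """
    labels = metadata.data.loc[table.sample_ids, factor]
    counts = table.counts.astype(float)
    levels = list(dict.fromkeys(labels))
    pairwise: dict[tuple[str, str], pd.Series] = {}
    total = pd.Series(0.0, index=table.taxon_ids)
    for ga, gb in itertools.combinations(levels, 2):
        ia = np.where((labels == ga).to_numpy())[0]
        ib = np.where((labels == gb).to_numpy())[0]
        acc = np.zeros(counts.shape[0])
        n_pairs = 0
        for i in ia:
            x = counts[:, i]
            for j in ib:
                y = counts[:, j]
                denom = (x + y).sum()
                if denom == 0:
                    continue
                acc += np.abs(x - y) / denom
                n_pairs += 1
        contrib = pd.Series(acc / max(n_pairs, 1), index=table.taxon_ids)
        pairwise[(ga, gb)] = contrib
        total += contrib
    ranking = total.sort_values(ascending=False)
    return SimperResult(pairwise=pairwise, overall_ranking=ranking)


# ---------------------------------------------------------------------------
# Local polynomial trajectory fits


def local_polynomial_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tricube-weighted local linear regression of y on x (degree 1).

    ``span`` is the fraction of points in each local neighbourhood.
    Returns the fit evaluated on ``grid`` (default: the sorted unique x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if span * x.size < 2:
        raise ValueError("span too small for a local linear fit")
    if grid is None:
        grid = np.unique(x)
    fitted = lowess(y, x, frac=span, it=0, xvals=np.asarray(grid, dtype=float))
    return pd.DataFrame({"x": np.asarray(grid, dtype=float), "fitted": fitted})
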