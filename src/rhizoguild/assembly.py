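"""Stochastic vs deterministic community assembly.

Two complementary quantifications per guild subcommunity:

* **Sloan neutral community model (NCM).** A taxon's occurrence
  frequency across local communities is predicted from its regional mean
  relative abundance ``p`` as ``1 − BetaCDF(d; N·m·p, N·m·(1−p))`` with
  community size ``N`` (mean rarefaction depth), migration rate ``m``
  (the single free parameter, fitted by bounded least squares) and
  detection limit ``d`` (default one read, 1/N). Taxa are classified
  neutral / above / below by a 95% Wilson prediction band around the
  fitted curve; the neutral taxa ratio (NTR) is the neutral fraction,
  and 1 − NTR is read as the deterministic share of assembly. The
  neutral fit's AIC is compared against a no-dispersal binomial model
  ``1 − (1−p)^N``.

* **Normalized stochasticity ratio (NST).** Within-group pairwise
  dissimilarities are compared against a null expectation from repeated
  randomizations that preserve per-sample richness and totals, draw taxa
  with probability proportional to their observed occupancy, and assign
  counts multinomially by regional mean relative abundance. ST is 1 when
  the observed dissimilarity matches the null mean and 0 under complete
  convergence or divergence; NST is the within-group mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.proportion import proportion_confint

from .io import STAGES, FeatureTable, SampleMetadata
from .guilds import GuildAssignment, subset_by_guild


# ---------------------------------------------------------------------------
# Sloan neutral community model


def sloan_occurrence(p, m: float, n_reads: float, d: float) -> np.ndarray:
    """Sharp-threshold occurrence prediction 1 − BetaCDF(d; Nmp, Nm(1−p)).

    This is the classic closed form: a taxon is detected when its local
    relative abundance exceeds the detection limit ``d``.
    """
    p = np.asarray(p, dtype=float)
    nm = n_reads * m
    a = np.clip(nm * p, 1e-12, None)
    b = np.clip(nm * (1.0 - p), 1e-12, None)
    return stats.beta.sf(d, a, b)


def sloan_occurrence_exact(p, m: float, n_reads: float, depth: float) -> np.ndarray:
    """Exact read-detection occurrence prediction.

    Detection means at least one read among ``depth`` draws from a local
    community whose relative abundance is Beta(Nmp, Nm(1−p)); the
    presence probability is 1 − E[(1−a)^depth] = 1 − B(α, β+depth)/B(α, β),
    of which the sharp-threshold form above is the d = 1/depth
    approximation.
    """
    p = np.asarray(p, dtype=float)
    nm = n_reads * m
    a = np.clip(nm * p, 1e-12, None)
    b = np.clip(nm * (1.0 - p), 1e-12, None)
    log_absent = special.betaln(a, b + depth) - special.betaln(a, b)
    return -np.expm1(log_absent)


@dataclass
class NCMFit:
    m: float
    n_reads: float  # community size N (mean post-rarefaction depth)
    d: float  # detection limit
    r2: float
    ntr: float
    aic_neutral: float
    aic_binomial: float
    n_samples: int
    #: per-taxon table: p, f_obs, f_pred, ci_lo, ci_hi, class
    taxa: pd.DataFrame = field(repr=False, default=None)
    at_bound: bool = False

    @property
    def nm(self) -> float:
        return self.m * self.n_reads

    def class_counts(self) -> dict[str, int]:
        return self.taxa["class"].value_counts().to_dict()


def _gaussian_aic(residuals: np.ndarray, k_params: int) -> float:
    n = residuals.size
    ssr = float(np.sum(residuals**2))
    return n * np.log(max(ssr, 1e-300) / n) + 2.0 * k_params


def ncm_fit(
    table: FeatureTable, d: float | None = None, detection: str = "exact"
) -> NCMFit:
    """Fit the Sloan neutral model to one guild × stage subcommunity.

    Requires at least 5 taxa observed in at least 3 samples of rarefied
    counts. Taxa absent from every sample are excluded from the fit.

    ``detection`` selects the occurrence prediction: ``"exact"``
    (default) integrates read sampling at the observed depth, which
    keeps the migration-rate estimate unbiased for read-count data;
    ``"threshold"`` is the classic sharp-detection beta-CDF form with
    limit ``d`` (default 1/N). Taxa are classed neutral/above/below by a
    95% Wilson band around the fitted curve, with a half-count
    continuity correction so the granularity of observed frequencies
    (multiples of 1/n_samples) does not create spurious calls at the
    band edges.
    """
    counts = table.counts.astype(float)
    n_taxa, n_samples = counts.shape
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    col_sums = counts.sum(axis=0)
    if (col_sums == 0).any():
        raise ValueError("zero-sum sample in NCM input")
    rel = counts / col_sums
    p = rel.mean(axis=1)
    observed = p > 0
    if observed.sum() < 5:
        raise ValueError("need at least 5 observed taxa")
    taxa_ids = [t for t, keep in zip(table.taxon_ids, observed) if keep]
    p = p[observed]
    f_obs = (counts[observed] > 0).mean(axis=1)
    n_reads = float(col_sums.mean())
    if d is None:
        d = 1.0 / n_reads
    if detection == "exact":
        predict = lambda m: sloan_occurrence_exact(p, m, n_reads, n_reads)  # noqa: E731
    elif detection == "threshold":
        predict = lambda m: sloan_occurrence(p, m, n_reads, d)  # noqa: E731
    else:
        raise ValueError(f"unknown detection form {detection!r}")

    def sse(m: float) -> float:
        resid = f_obs - predict(m)
        return float(np.sum(resid**2))

    res = optimize.minimize_scalar(
        sse, bounds=(1e-6, 1.0), method="bounded", options={"xatol": 1e-8}
    )
    m_hat = float(res.x)
    at_bound = m_hat < 2e-6 or m_hat > 1.0 - 1e-6
    if at_bound:
        warnings.warn(f"NCM migration rate at bound: m={m_hat:.3g}", stacklevel=2)
    f_pred = predict(m_hat)
    resid = f_obs - f_pred
    sst = float(np.sum((f_obs - f_obs.mean()) ** 2))
    if sst == 0:
        warnings.warn("zero variance in occurrence frequencies; R2 undefined",
                      stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / sst
    lo, hi = proportion_confint(f_pred * n_samples, n_samples, alpha=0.05,
                                method="wilson")
    # half-count continuity correction: f_obs is granular in 1/n steps
    k_obs = f_obs * n_samples
    cls = np.where(
        k_obs > hi * n_samples + 0.5,
        "above",
        np.where(k_obs < lo * n_samples - 0.5, "below", "neutral"),
    )
    ntr = float(np.mean(cls == "neutral"))
    # no-dispersal binomial comparison model: f = 1 - (1-p)^N, no free parameter
    f_bin = 1.0 - np.exp(n_reads * np.log1p(-np.minimum(p, 1 - 1e-12)))
    aic_neutral = _gaussian_aic(resid, 1)
    aic_binomial = _gaussian_aic(f_obs - f_bin, 0)
    taxa = pd.DataFrame(
        {"p": p, "f_obs": f_obs, "f_pred": f_pred, "ci_lo": lo, "ci_hi": hi,
         "class": cls},
        index=pd.Index(taxa_ids, name="taxon_id"),
    )
    return NCMFit(
        m=m_hat, n_reads=n_reads, d=d, r2=r2, ntr=ntr,
        aic_neutral=aic_neutral, aic_binomial=aic_binomial,
        n_samples=n_samples, taxa=taxa, at_bound=at_bound,
    )


def ntr_trajectory(
    bacterial: FeatureTable,
    fungal: FeatureTable,
    assignment: GuildAssignment,
    metadata: SampleMetadata,
    guilds=("PBB", "PGP", "Bioc", "SR", "FPP", "nonPBB"),
    stages=None,
    d: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """One NCM fit per guild × stage; returns the NTR matrix and fits.

    The deterministic share is 1 − NTR. Cells whose fit fails (too few
    taxa or samples) are NaN and logged via a warning.
    """
    if stages is None:
        stages = metadata.stages_present()
    ntr = pd.DataFrame(np.nan, index=list(guilds), columns=list(stages))
    fits: dict[tuple[str, str], NCMFit] = {}
    for guild in guilds:
        base = fungal if guild == "FPP" else bacterial
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub = subset_by_guild(base, assignment, guild)
        for stage in stages:
            samples = [
                s for s in metadata.samples_for_stage(stage) if s in set(base.sample_ids)
            ]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = ncm_fit(sub.subset_samples(samples), d=d)
            except ValueError as exc:
                warnings.warn(f"NCM fit failed for {guild}/{stage}: {exc}", stacklevel=2)
                continue
            fits[(guild, stage)] = fit
            ntr.loc[guild, stage] = fit.ntr
    return ntr, fits


def determinism_from_ntr(ntr: pd.DataFrame) -> pd.DataFrame:
    """Deterministic share D = 1 − NTR (same shape as the NTR matrix)."""
    return 1.0 - ntr


# ---------------------------------------------------------------------------
# Null model + NST


def _inclusion_probs(weights: np.ndarray, size: int) -> np.ndarray:
    """Inclusion probabilities ∝ weights for a fixed-size draw, capped
    at 1 with the excess redistributed (iterative capping)."""
    pi = np.zeros_like(weights, dtype=float)
    active = weights > 0
    if active.sum() < size:
        raise ValueError("not enough positive-weight taxa for requested richness")
    capped = np.zeros_like(active)
    while True:
        remaining = size - capped.sum()
        if remaining == 0:
            return capped.astype(float)
        w = np.where(active & ~capped, weights, 0.0)
        scale = remaining / w.sum()
        over = (w * scale >= 1.0) & ~capped
        if not over.any():
            pi = np.where(capped, 1.0, w * scale)
            return pi
        capped |= over


def _systematic_sample(pi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fixed-size sample with inclusion probabilities ``pi`` (Σπ integer)
    via randomized systematic sampling."""
    order = rng.permutation(pi.size)
    cum = np.cumsum(pi[order])
    size = int(round(cum[-1]))
    targets = rng.random() + np.arange(size)
    chosen = order[np.searchsorted(cum, targets, side="left")]
    return chosen


def null_randomize(
    table: FeatureTable, rng: np.random.Generator | int = 17
) -> FeatureTable:
    """One null randomization of a (group's) feature table.

    Preserves each sample's richness and total exactly. Each sample's
    taxa are a fixed-size random draw whose *inclusion* probability is
    proportional to the taxon's occupancy frequency across the group
    (systematic probability-proportional sampling, so expected null
    occupancy matches observed occupancy); counts are then assigned by
    giving each drawn taxon one read and splitting the remaining total
    multinomially with probabilities proportional to the regional mean
    relative abundances of the drawn taxa.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    counts = table.counts
    n_taxa, n_samples = counts.shape
    occupancy = (counts > 0).mean(axis=1)
    col_sums = counts.sum(axis=0)
    rel = counts / np.where(col_sums == 0, 1, col_sums)
    regional = rel.mean(axis=1)
    out = np.zeros_like(counts)
    for j in range(n_samples):
        richness = int((counts[:, j] > 0).sum())
        total = int(col_sums[j])
        if richness == 0 or total == 0:
            continue
        pi = _inclusion_probs(occupancy, richness)
        chosen = _systematic_sample(pi, rng)
        probs = regional[chosen]
        if probs.sum() == 0:
            probs = np.ones(len(chosen))
        probs = probs / probs.sum()
        # every drawn taxon must be present: give each one read, distribute the rest
        out[chosen, j] = 1
        if total > richness:
            out[chosen, j] += rng.multinomial(total - richness, probs)
    return FeatureTable(pd.DataFrame(out, index=table.taxon_ids,
                                     columns=table.sample_ids))


@dataclass
class NSTResult:
    group: str
    nst: float
    pairwise_st: pd.DataFrame  # columns: sample_a, sample_b, observed, null_mean, st
    n_reps: int
    metric: str


def _pair_dissim(counts: np.ndarray, metric: str) -> np.ndarray:
    from scipy.spatial.distance import pdist

    if metric == "braycurtis":
        return pdist(counts.T.astype(float), metric="braycurtis")
    if metric == "jaccard":
        return pdist((counts.T > 0).astype(float), metric="jaccard")
    raise ValueError(f"unknown metric {metric!r}")


def nst(
    table: FeatureTable,
    metadata: SampleMetadata,
    factor: str = "stage",
    reps: int = 1000,
    seed: int = 17,
    metric: str = "braycurtis",
) -> list[NSTResult]:
    """Normalized stochasticity ratio per group.

    For each within-group pair with observed dissimilarity D and null
    mean Ē: ST = D/Ē when D ≤ Ē, else 1 − (D − Ē)/(D_max − Ē) with
    D_max = 1. NST is the mean ST over the group's pairs. Groups need
    at least 3 samples. Reproducible given ``seed``.
    """
    labels = metadata.data.loc[table.sample_ids, factor]
    rng = np.random.default_rng(seed)
    results = []
    for level in list(dict.fromkeys(labels)):
        samples = [s for s, g in labels.items() if g == level]
        if len(samples) < 3:
            warnings.warn(f"group {level!r} has <3 samples; skipped", stacklevel=2)
            continue
        sub = table.subset_samples(samples)
        obs = _pair_dissim(sub.counts, metric)
        null_acc = np.zeros_like(obs)
        for _ in range(reps):
            rand = null_randomize(sub, rng)
            null_acc += _pair_dissim(rand.counts, metric)
        null_mean = null_acc / reps
        st = np.empty_like(obs)
        for idx, (d_obs, e_null) in enumerate(zip(obs, null_mean)):
            if e_null == 0:
                warnings.warn("null mean dissimilarity is 0", stacklevel=2)
                st[idx] = 1.0 if d_obs == 0 else 0.0
            elif d_obs <= e_null:
                st[idx] = d_obs / e_null
            else:
                st[idx] = 1.0 - (d_obs - e_null) / (1.0 - e_null) if e_null < 1 else 1.0
        pairs = [
            (samples[i], samples[j])
            for i in range(len(samples))
            for j in range(i + 1, len(samples))
        ]
        detail = pd.DataFrame(
            {
                "sample_a": [a for a, _ in pairs],
                "sample_b": [b for _, b in pairs],
                "observed": obs,
                "null_mean": null_mean,
                "st": st,
            }
        )
        results.append(
            NSTResult(group=level, nst=float(st.mean()), pairwise_st=detail,
                      n_reps=reps, metric=metric)
        )
    return results
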