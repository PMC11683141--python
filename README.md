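# rhizoguild

Succession and assembly analysis of **functional rhizosphere
microbiomes** — the plant-beneficial bacteria (PBB: plant-growth-promoting,
biocontrol, stress-resistance genera) and fungal plant pathogens (FPP)
that live in the soil around plant roots — across the developmental
stages of a perennial crop, with a link from community assembly to host
root gene expression.

It is written for microbial ecologists working with amplicon (16S/ITS)
ASV tables plus an optional host RNA-seq count matrix. The pipeline
covers, as importable functions:

- **Guild annotation** — filter host organelles and low-abundance ASVs,
  rarefy (seeded, exact column sums), and partition taxa into guilds by
  genus-level trait lookup.
- **Diversity succession** — richness/Chao1/Shannon per guild,
  Kruskal–Wallis + Nemenyi stage tests with compact letter displays,
  stage-wise composition summaries.
- **Community structure** — Bray–Curtis, PCoA (negative eigenvalues
  reported), one-factor PERMANOVA with R², β-dispersion (centroid
  distances, semi-metric convention), SIMPER taxon contributions, local
  polynomial trajectory fits.
- **Antagonism screen** — Spearman guild correlations overall and per
  stage, a widespread-ASV screen against pathogen load with BH
  correction, persistent-antagonist calling, phylogeny annotation
  export.
- **Assembly mechanisms** — Sloan's neutral community model fit per
  guild × stage (migration rate m, R², 95%-band taxon classification,
  neutral taxa ratio NTR, AIC vs a no-dispersal binomial) and the
  null-model normalized stochasticity ratio (NST).
- **Host linkage** — FPKM, fuzzy c-means clustering of stage
  trajectories, trend matching against the deterministic assembly share
  1 − NTR, hypergeometric pathway enrichment, thresholded Spearman
  co-expression networks, TF ↔ biosynthesis-gene bipartite extraction.
- **Synthetic data** — a generator producing complete study datasets
  (7 stages × 5 sites × 3 plots) with known neutral/selective structure,
  pathogen–biocontrol coupling and planted expression clusters, used as
  ground truth throughout the test suite.

## The models at the core

**Sloan neutral community model.** A taxon with regional mean relative
abundance *p* occurs in a local community of size *N* (reads) with
frequency predicted from the Beta stationary distribution of its local
abundance, Beta(*Nmp*, *Nm*(1−*p*)), where *m* is the migration rate —
the only fitted parameter. The package evaluates the exact
read-detection probability 1 − B(α, β+N)/B(α, β) by default (the
classic sharp-threshold form 1 − BetaCDF(1/N; α, β) is available), fits
*m* by bounded least squares, and classes each taxon against a 95%
Wilson band around the curve. **NTR** — the fraction of taxa inside the
band — measures the stochastic share of assembly; 1 − NTR is the
deterministic share.

**Normalized stochasticity ratio.** Observed within-group Bray–Curtis
dissimilarities *D* are compared with their expectation *Ē* under a null
model that preserves per-sample richness and totals while drawing taxa
with inclusion probability proportional to occupancy:
ST = *D*/*Ē* if *D* ≤ *Ē*, else 1 − (*D*−*Ē*)/(1−*Ē*). NST (the mean
over pairs) is ≈ 1 for stochastic assembly and → 0 under deterministic
convergence.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices and limitations.

## Worked example

Every capability has a narrative script under `examples/`. The assembly
example generates the full synthetic study and fits the neutral model
per guild × stage:

```sh
python examples/05_assembly_mechanisms.py
```

```
neutral taxa ratio (NTR) per guild x stage:
          BL   2YV   2YF   2YR   3YV   3YF   3YR
PBB     0.97  0.97  0.97  0.94  0.97  0.88  0.85
Bioc    0.87  1.00  0.87  0.93  1.00  0.92  0.86
FPP     1.00  1.00  1.00  1.00  1.00  1.00  1.00
nonPBB  0.95  0.98  0.99  0.97  0.98  0.98  0.98

1 - NTR is the deterministic share; the generator injects selection
on beneficial taxa that peaks at 3YR, which the fits recover:
        BL   2YV   2YF   2YR   3YV   3YF   3YR
PBB   0.03  0.03  0.03  0.06  0.03  0.12  0.15
Bioc  0.13  0.00  0.13  0.07  0.00  0.08  0.14

Bioc @ 3YR neutral fit: m = 0.134, Nm = 32, R2 = 0.53, AIC neutral -44.2 vs binomial -33.8

normalized stochasticity ratio (NST), beneficial guild:
  BL   NST = 0.89
  3YR  NST = 0.81
```

Reading this: the beneficial guild (PBB) drifts neutrally through the
second year (NTR ≈ 0.95, deterministic share ≈ 0.05) and becomes
progressively more deterministically assembled toward the third-year
root stage (1 − NTR rises to 0.15 at 3YR), exactly where the generator
injected selection; the unselected non-beneficial bacteria and the
pathogens stay flat. The AIC comparison favours the dispersal-limited
neutral model over the no-dispersal binomial.

The antagonism example (`examples/04_antagonism_screen.py`) shows the
biocontrol guild as the strongest negative correlate of pathogen load
(Spearman ρ = −0.89 overall, vs −0.49/−0.35 for the PGP/SR subgroups on
the same data), and `examples/06_host_linkage.py` recovers the planted
determinism-tracking expression cluster, its enriched biosynthesis
pathway (hypergeometric q ≈ 10⁻²¹) and exactly the 13 planted
transcription factors from the thresholded co-expression network.

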