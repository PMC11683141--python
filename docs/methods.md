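# Methods

`rhizoguild` analyses the succession and assembly of functional
rhizosphere microbiomes — plant-beneficial bacteria (PBB, with
plant-growth-promoting PGP, biocontrol Bioc and stress-resistance SR
subgroups) and fungal plant pathogens (FPP) — across the developmental
stages of a perennial host, and links the assembly signal to host root
gene expression. This note records the models, the numerical choices,
and what the synthetic data generator does and does not emulate.

## Data model and preprocessing

Inputs are rarefaction-ready ASV count tables (taxa × samples, integer
TSV), rank-prefixed taxonomy lineages, sample metadata over the closed
stage set {BL, 2YV, 2YF, 2YR, 3YV, 3YF, 3YR} (bulk pre-planting soil
plus vegetative/flowering/root-inflation stages of years two and three),
and a trait database mapping bacterial genera to subsets of
{Bioc, PGP, SR} and fungal taxa to a plant-pathogenic flag.

Preprocessing order is fixed: host-organelle removal (any lineage rank
containing "Chloroplast"/"Mitochondria", case-insensitive), removal of
ASVs with total reads below 10 (strict; a total of exactly 10 is kept),
then rarefaction. Rarefaction is a per-sample multivariate
hypergeometric draw (subsampling without replacement), so every retained
column sums exactly to the target depth; it is seeded and deterministic.
Guild assignment matches bacterial genera case-insensitively after
stripping rank prefixes; fungal matching is at genus rank with a family
fallback when the genus is unassigned (fallback matches are flagged in
the result). Matching at genus rank is a choice — trait databases are
genus-resolved, and finer ranks are rarely assigned reliably in ITS
data.

## Diversity and succession

Alpha diversity per sample: observed richness, Chao1
(S_obs + F1(F1−1)/(2(F2+1))), and Shannon entropy in natural log (nats —
the convention of the common R ecology tooling). Stage differences use
the tie-corrected Kruskal–Wallis test with the Nemenyi all-pairs post
hoc: the statistic |R̄_i − R̄_j| / √(N(N+1)/12 · (1/n_i + 1/n_j)) scaled
by √2 is referred to the studentized range distribution with infinite
degrees of freedom. Note a power floor intrinsic to this statistic: with
three groups of five the maximal possible mean-rank separation of
adjacent groups yields p ≈ 0.18, so small designs cannot separate
adjacent stages regardless of effect size. Letters come from an
insert–absorb compact-letter-display pass over the p < 0.05 graph, with
letters ordered by stage.

## Community structure

Bray–Curtis dissimilarity BC(x, y) = Σ|x−y| / Σ(x+y) on rarefied counts.
PCoA Gower-centres −½D² and eigendecomposes; negative eigenvalues
(possible for this semi-metric) are reported, not corrected, and the
negative-axis coordinate block is kept. β-dispersion is the distance of
each sample to its group centroid computed on both blocks, subtracting
squared distances on the negative axes and clamping at zero — the
standard convention for semi-metric ordinations. One-factor PERMANOVA
partitions SS_total = Σ_{i<j} d²_ij / n into among/within components;
pseudo-F = (SS_among/(k−1)) / (SS_within/(n−k)); the p-value is
(1 + #{F_perm ≥ F_obs}) / (1 + n_perm) under seeded label permutation
(default 999 permutations). Samples are internally sorted by id so the
p-value does not depend on input column order. SIMPER decomposes each
between-group pair's Bray–Curtis into per-taxon terms |x_i − y_i|/Σ(x+y)
and averages over cross pairs, so contributions sum exactly to the mean
between-group dissimilarity; the overall ranking sums contributions over
all group pairs. Trajectories of top contributors are fitted by
tricube-weighted local linear regression (span = fraction of points per
neighbourhood, no robustness iterations).

## Antagonism screen

Spearman correlations (average ranks, t-approximation p) relate guild
series — richness or relative abundance — to the FPP series overall and
within stages (minimum n = 4 per scope). The widespread-ASV screen is
stage-wise: ASVs present in strictly more than half of a stage's samples
are correlated against total FPP relative abundance, with
Benjamini–Hochberg correction applied within each stage (that is the BH
family; a global-prevalence mode exists). Persistent antagonists are
ASVs with BH q < 0.05 and ρ < 0 in at least three stages. With 15
samples per stage the per-ASV screen has modest power, so few
significant calls on weakly coupled data is the expected behaviour, not
a defect. Screen results can be exported as tip-aligned annotation
tables for an externally supplied Newick tree.

## Sloan neutral model and NTR

For one guild × stage subcommunity the model predicts a taxon's
occurrence frequency from its mean relative abundance p. The community
size N is the mean post-rarefaction depth of the (sub)table; m, the
migration rate, is the single free parameter, estimated by least squares
over m ∈ (10⁻⁶, 1] with bounded scalar minimisation (tolerance 10⁻⁸).
Two prediction forms are implemented:

* `detection="exact"` (default): presence means at least one read among
  N draws from a local community whose relative abundance is
  Beta(Nmp, Nm(1−p)); the presence probability has the closed form
  1 − B(α, β+N)/B(α, β).
* `detection="threshold"`: the classic sharp-detection form
  1 − BetaCDF(d; Nmp, Nm(1−p)) with detection limit d = 1/N
  (configurable).

The threshold form is the d = 1/N approximation of the exact form. For
read-count data the approximation biases the fitted Nm upward by roughly
a quarter at the depths used here, which is why the exact form is the
default; the threshold form is kept for comparability with the
widespread convention.

Taxa are classed neutral/above/below by a 95% Wilson score band around
the fitted curve (n = number of samples), with a half-count continuity
correction: observed frequencies are multiples of 1/n, and without the
correction a taxon with f_pred just below 1 and f_obs = 1 — the expected
outcome under neutrality — would be mislabelled "above" purely by
granularity (at n = 15 this artifact alone mislabels about 30% of taxa).
NTR is the neutral fraction of taxa (richness-based, not
abundance-weighted), and 1 − NTR is reported as the deterministic share.
Model comparison uses the Gaussian-residual AIC n·ln(SSR/n) + 2k (k = 1
neutral, k = 0 for the no-dispersal binomial 1 − (1−p)^N); constants
omitted identically in both.

Fits require ≥ 5 observed taxa and ≥ 3 samples; taxa absent from every
sample are excluded; an optimizer at its bound sets a warning flag; zero
variance in observed frequencies yields R² = NaN.

## Null model and NST

The null model preserves each sample's richness and total exactly. Taxa
are drawn as a fixed-size sample whose *inclusion* probabilities are
proportional to occupancy frequency across the group (iterative capping
at 1, then randomized systematic sampling) — inclusion-proportional
sampling keeps the expected null occupancy equal to the observed
occupancy, which sequential weighted drawing does not (it flattens the
occupancy spectrum, making the null model drift away from its own data
under iteration). Counts give each drawn taxon one read, then split the
remaining total multinomially by regional mean relative abundance, so
the richness invariant is exact. The occupancy-proportionality property
holds exactly only while no inclusion probability caps at 1, i.e. in
sparse tables; in dense tables ubiquitous taxa are simply always
included.

For each within-group pair with observed dissimilarity D (Bray–Curtis
default, Jaccard optional) and null mean Ē over R reps (default 1000):
ST = D/Ē when D ≤ Ē, else 1 − (D−Ē)/(1−Ē) (D_max = 1). NST is the mean
ST over pairs: near 1 when the data are indistinguishable from the null
(stochastic), near 0 under strong convergence or divergence
(deterministic). Identical samples give NST = 0; data generated by the
null itself scores ≈ 0.9.

## Host linkage

FPKM = count · 10⁹ / (length_bp · mapped_total). Stage profiles are
per-stage means, z-scored per gene (zero-variance genes dropped).
Clustering is fuzzy c-means (default k = 5, fuzzifier φ = 1.25 —
hardening toward k-means as φ→1, with hard labels by maximal
membership), seeded farthest-point initialisation, memberships computed
from distance ratios to the per-point minimum for numerical stability,
converged when max |ΔU| < 10⁻⁶. Clusters are ranked by Pearson
correlation (Spearman optional) between their z-scored centroid and the
z-scored determinism trajectory 1 − NTR of the biocontrol guild over the
six root stages — bulk soil is excluded because no root tissue exists
before planting. Pathway enrichment is the hypergeometric upper tail
with BH across pathways. The co-expression network tests all gene pairs
within the matched cluster (Spearman on replicate-level samples,
t-approximation), keeping edges with ρ > 0.9 and BH q < 0.001 over all
tested pairs; with only six stage means such a q is reachable only at
|ρ| = 1, so replicate-level expression (≥ 6 samples) is required.
TF–biosynthesis links are network edges with exactly one endpoint in the
TF table and the other among the (non-TF) pathway genes.

## Synthetic data generator

The generator is the package's testbed and its recovery ground truth.
It emulates the post-denoising outputs of a 7-stage × 5-site × 3-plot
rhizosphere survey (105 samples) with rarefaction depths 2,339
(bacteria) and 3,827 (fungi) reads:

* **Metacommunity.** Lognormal species-abundance distribution
  (σ = 1.5, the standard SAD shape); 18% of bacterial taxa carry
  beneficial traits, partitioned across subgroup combinations so PGP
  covers most of PBB, Bioc roughly 40% and SR under a quarter, with a
  small all-three-traits core — mirroring the subgroup proportions of
  genus-level trait databases; 27% of fungal taxa are flagged
  pathogenic; Proteobacteria dominate the beneficial fraction.
* **Neutral sampling.** Local relative abundances
  Beta(Nm·p, Nm·(1−p)) per taxon (default Nm = 500), renormalised,
  then multinomial reads at depth.
* **Selection.** Chosen beneficial taxa are multiplied by a strength
  factor (default 10) and the sample is redrawn to its depth
  (multinomial; enriched taxa that were present are kept present).
  Selection fractions rise over the third year (10%/20%/30% at
  3YV/3YF/3YR), so determinism peaks at the root-inflation stage.
  Note the direction of the induced deviation: uniform multiplication
  inflates abundance while occupancy lags, so selected taxa leave the
  neutral band mostly on the occupancy-deficit ("below") side.
* **Antagonism.** Pathogen reads are rescaled per sample by
  exp(−β·(x − x̄)) × lognormal noise, with x the biocontrol relative
  abundance (centred so mean pathogen load is preserved; Spearman
  statistics are invariant to the centring). Default β = 25 with noise
  σ = 0.2 produces a strong negative coupling specific to the
  biocontrol guild; β = 0 gives the null.
* **Expression.** Five planted centroid trajectories over the six root
  stages, one equal to the determinism trajectory (default rising from
  3YV to a 3YR peak); genes get centroid + N(0, 0.2) stage noise and
  N(0, 0.1) replicate noise on the log scale across 3 replicates per
  stage. A 30-gene biosynthesis pathway and 13 transcription factors
  are planted in the determinism cluster with halved noise — a
  regulator–target block co-varies tightly by construction so its
  links survive the network threshold — plus decoy TFs in other
  clusters. Counts invert the FPKM formula, so FPKM(counts) matches
  the target up to rounding.

Default sizes (200 bacterial taxa, 80 fungal taxa, 2,000 genes) keep the
full pipeline in seconds while every guild × stage cell still satisfies
the neutral-fit preconditions; survey-scale taxon counts are a config
change. What the generator does **not** emulate: sequencing error and
chimeras, phylogenetic structure among taxa, spatial/site effects (sites
are exchangeable replicates), compositional coupling beyond the single
pathogen–biocontrol link, and library-size variation (all samples sit
exactly at the rarefaction depth). Tests passing on this generator
therefore validate the statistical machinery and its calibration — not
robustness to the messier features of real amplicon data.

## Verification protocol sizes

The acceptance script and the statistical test suite use: neutral-model
recovery at Nm = 500, 60 taxa, 30 samples, 20 seeds; NTR coverage on 20
full pure-neutral scenarios; NST self-consistency on 20 null-generated
tables at 200 reps; antagonism recovery over 50 coupled and 20 uncoupled
scenarios; PERMANOVA calibration over 200 repeats of 30 exchangeable
samples at 199 permutations (the user-facing default stays 999);
host-linkage recovery over 50 seeds at 800 genes. These sizes give
stable medians and rates while the whole protocol completes in well
under a minute of compute.

## Known limitations

* The Nemenyi post hoc cannot separate adjacent groups at very small
  group sizes (see above); the compact letters reflect that.
* NTR at 15 samples per stage is granular (multiples of 1/#taxa in
  small guilds); per-cell values for guilds near the 5-taxon minimum
  carry correspondingly coarse uncertainty.
* The NST ST statistic is asymmetric around Ē by construction; purely
  stochastic data scores slightly below 1 (≈ 0.9 at the sizes here).
* The per-ASV antagonism screen at n = 15 per stage detects only strong
  couplings; guild-level correlations are the powered analysis.
* PERMANOVA models one factor at a time (stage, or site); no
  interactions or nested designs.
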