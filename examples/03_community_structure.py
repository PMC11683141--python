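"""β-diversity succession: ordination, PERMANOVA, dispersion, SIMPER.

Quantifies how much of the beneficial subcommunity's Bray–Curtis
variation the developmental stage explains (PERMANOVA R²), summarises
within-stage heterogeneity (β-dispersion), and ranks the ASVs that
contribute most to between-stage dissimilarity (SIMPER), fitting the top
taxon's stage trajectory with local polynomial regression.
"""

import numpy as np

import rhizoguild as rg

scenario = rg.full_scenario(rg.ScenarioConfig(seed=17))
ds = scenario.dataset
assignment = rg.assign_guilds(ds.bacterial_taxonomy, ds.fungal_taxonomy, ds.traits)
pbb = rg.subset_by_guild(ds.bacterial, assignment, "PBB")

dm = rg.bray_curtis(pbb)
res = rg.permanova(dm, ds.metadata, "stage", n_perm=999, seed=17)
print(f"PERMANOVA (stage): R2 = {res.r2:.3f}, pseudo-F = {res.pseudo_f:.2f}, "
      f"p = {res.p:.3f}")
print("R2 is the fraction of community variation explained by stage.")

ordination = rg.pcoa(dm)
pc1, pc2 = ordination.proportion_explained[:2] * 100
print(f"PCoA: axis 1 {pc1:.1f}%, axis 2 {pc2:.1f}% of (positive) inertia")

disp = rg.beta_dispersion(dm, ds.metadata, "stage")
print("\nmean distance to stage centroid (β-dispersion):")
print(disp.groupby("group")["distance_to_centroid"].mean().round(3).to_string())

simper_res = rg.simper(pbb, ds.metadata, "stage")
top = simper_res.top(5)
print("\ntop 5 ASVs driving between-stage dissimilarity:", ", ".join(top))

rel = pbb.relative_abundance().loc[top[0]]
stage_idx = ds.metadata.stage_series(rel.index).map(
    {s: i for i, s in enumerate(rg.STAGES)}
)
fit = rg.local_polynomial_fit(stage_idx.to_numpy(), rel.to_numpy(), span=0.75)
print(f"\nlocal-polynomial trajectory of {top[0]} (stage index -> fitted share):")
for _, row in fit.iterrows():
    print(f"  {rg.STAGES[int(row['x'])]:4s} {row['fitted']:.4f}")
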