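"""Antagonism between biocontrol bacteria and fungal pathogens.

Correlates guild relative abundances (Spearman) overall and per stage,
screens widespread beneficial ASVs against total pathogen load with BH
correction, and lists persistent antagonists — ASVs significantly and
negatively correlated with the pathogens in at least three stages.
"""

import pandas as pd

import rhizoguild as rg

scenario = rg.full_scenario(rg.ScenarioConfig(seed=17))
ds = scenario.dataset
assignment = rg.assign_guilds(ds.bacterial_taxonomy, ds.fungal_taxonomy, ds.traits)

fpp = rg.guild_relative_abundance(ds.fungal, assignment, "FPP")
metrics = pd.DataFrame({
    g: rg.guild_relative_abundance(ds.bacterial, assignment, g)
    for g in ("PBB", "PGP", "Bioc", "SR")
})
metrics["FPP"] = fpp

corr = rg.guild_correlations(metrics, ds.metadata)
overall = corr[corr["stage"] == "overall"].set_index("guild")
print("overall Spearman rho vs pathogen abundance (negative = antagonism):")
print(overall["rho"].round(3).to_string())

pbb = rg.subset_by_guild(ds.bacterial, assignment, "PBB")
screen = rg.widespread_asv_screen(pbb, fpp, ds.metadata)
n_sig = int(screen["significant"].sum())
print(f"\nwidespread-ASV screen: {len(screen)} stage×ASV tests, "
      f"{n_sig} significant at BH q < 0.05")

persistent = rg.persistent_antagonists(screen, ds.bacterial_taxonomy)
print(f"\npersistent antagonists (negative & significant in >=3 stages): "
      f"{len(persistent)}")
if len(persistent):
    print(persistent.to_string())
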