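"""Alpha-diversity succession of the beneficial subcommunity.

Computes richness/Chao1/Shannon per sample for the plant-beneficial
guild, then tests for stage differences with Kruskal–Wallis followed by
the Nemenyi post hoc. Stages sharing a compact-display letter are not
significantly different (α = 0.05).
"""

import rhizoguild as rg

scenario = rg.full_scenario(rg.ScenarioConfig(seed=17))
ds = scenario.dataset
assignment = rg.assign_guilds(ds.bacterial_taxonomy, ds.fungal_taxonomy, ds.traits)

alpha = rg.guild_alpha_diversity(ds.bacterial, assignment, "PBB", ds.metadata)
print("per-stage mean PBB richness:")
print(alpha.groupby("stage")["richness"].mean().round(1).to_string())

res = rg.kruskal_wallis_by_stage(alpha["richness"], ds.metadata)
print(f"\nKruskal-Wallis: H = {res.h:.2f}, df = {res.df}, p = {res.p:.2e}")
print("compact letter display (shared letter = not separable):")
for stage in rg.STAGES:
    print(f"  {stage:4s} {res.letters[stage]}")
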