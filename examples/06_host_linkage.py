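"""Link root gene expression to biocontrol assembly determinism.

Normalises counts to FPKM, clusters stage-mean trajectories with fuzzy
c-means, ranks clusters by correlation with the deterministic assembly
share of the biocontrol guild, tests the matched cluster for pathway
enrichment, builds a thresholded Spearman co-expression network inside
it, and extracts the transcription-factor ↔ biosynthesis-gene links.
"""

import warnings

import rhizoguild as rg

scenario = rg.full_scenario(rg.ScenarioConfig(seed=17))
bundle = scenario.expression
truth = scenario.truth.expression

fpkm = rg.fpkm(bundle.counts, bundle.gene_lengths, bundle.mapped_totals)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    profiles = rg.stage_profiles(fpkm, bundle.sample_stages,
                                 stage_order=rg.ROOT_STAGES)
    clustering = rg.fuzzy_cmeans(profiles, k=5, seed=17)

ranking = rg.trend_match(clustering, truth.determinism)
print("clusters ranked by match to the determinism trajectory (1 - NTR):")
print(ranking.round(3).to_string(index=False))
top = ranking.iloc[0]["cluster"]
genes_top = clustering.labels.index[clustering.labels == top]
print(f"\nbest-matching cluster {top}: {len(genes_top)} genes")

enrichment = rg.enrich(set(genes_top), bundle.pathway_map, profiles.index)
print("\npathway enrichment of the matched cluster (hypergeometric, BH):")
print(enrichment.head(3).round(4).to_string(index=False))

net = rg.coexpression_network(fpkm, genes=genes_top)
print(f"\nco-expression network (rho > 0.9, q < 0.001): "
      f"{net.number_of_nodes()} nodes, {net.number_of_edges()} edges")

biosynthesis = bundle.pathway_map[truth.planted_pathway]
links = rg.tf_bipartite(net, bundle.tf_table, biosynthesis)
print(f"TF-biosynthesis links: {len(links)} edges, "
      f"{links['tf'].nunique()} distinct TFs "
      f"(planted: {len(truth.planted_tfs)})")
print(links.groupby("tf_family")["tf"].nunique().to_string())
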