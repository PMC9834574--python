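"""Over-representation analysis of regulated proteins against gene sets.

Generates gene sets over a synthetic cohort — five of them deliberately
over-sampling the planted AS-specific class — queries them with the up- and
down-regulated protein lists, applies the significance and intersection
filters, removes redundant terms and summarizes category proportions.
"""

import valveproteome as vp

cfg = vp.SynthConfig(n_proteins=1500, effect_size_lfc=2.0, noise_sd=0.5, seed=2)
matrix, meta, truth = vp.generate_cohort(cfg)
fit = vp.fit_linear_model(matrix, vp.build_design(meta))
prior = vp.estimate_variance_prior(fit, trend=True)
res = vp.moderated_statistics(fit, prior, "AS_vs_CON")

collection = vp.generate_gene_sets(truth, n_sets=40, n_enriched=5, seed=2)
queries = vp.queries_from_result(res, alpha=0.05)
print(f"query sizes: up = {len(queries['up'])}, down = {len(queries['down'])}, "
      f"background = {matrix.n_proteins}")

table = vp.run_enrichment(queries, set(matrix.proteins), collection)
table = vp.reduce_redundant_terms(table)
sig = table[table["significant"]]
print(f"significant sets after filters: {len(sig)} of {len(table)} tested")
print(sig[["set", "direction", "overlap", "set_size_bg", "adj_p"]]
      .to_string(index=False))

category_map = {name: "planted pathway" for name in list(collection.sets)[:5]}
props = vp.summarize_categories(table, category_map)
print("\ncategory proportions over significant sets (unmapped -> other terms):")
print(props.to_string())
print("\nSets SET0001..SET0005 over-sample truly AS-regulated proteins, so"
      "\nthey should dominate the significant list; random sets stay quiet.")
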