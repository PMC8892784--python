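"""Score shift-work expression changes against disease gene modules.

Three views: (1) per-module enrichment of upregulated genes versus the null
module M0 (one-sided Fisher's exact test); (2) per-module distributions of
log2 WRF/C median ratios versus M0 (Kruskal-Wallis); (3) a disease gene
set's ratio distribution versus all genes, both normalized to 500 quantiles,
compared with a Kolmogorov-Smirnov test.
"""

import numpy as np

from circaheart import (StudyConfig, differential_expression_screen,
                        filter_modules, generate_disease_gene_sets,
                        generate_module_catalog, generate_study, ks_shift_test,
                        module_enrichment, module_expression_shift)

config = StudyConfig(seed=4, n_genes=2000, n_de_genes=200, de_up_fraction=0.9,
                     de_fold=2.0, responder_fraction=1.0)
matrix, truth = generate_study(config)
rng = np.random.default_rng(40)

# module catalog: M1 seeded with 40% planted-up genes, M2/M3 background
modules = generate_module_catalog(
    n_modules=3, sizes=60, planted_enrichment={"M1": 0.4},
    up_gene_set=truth.de_genes("up"), universe=matrix.gene_ids, rng=rng)
modules = filter_modules(modules, matrix.gene_ids, min_size=50)

de = differential_expression_screen(matrix)
up_called = set(de.loc[de["category"] == "WRF_up_vs_C_and_W", "gene_id"])
print(f"{len(up_called)} genes called up in WRF\n")

enrich = module_enrichment(up_called, modules, matrix.gene_ids)
print("module enrichment vs M0 (one-sided Fisher):")
for _, r in enrich.iterrows():
    flag = " *" if r["flagged"] else ""
    print(f"  {r['module_id']:3s} n={r['size_in_universe']:4d} "
          f"percent_up={r['percent_up']:5.1f}% p={r['fisher_p']:.3g}{flag}")

ratios, shift = module_expression_shift(matrix, modules, "WRF", "C")
print("\nlog2 WRF/C median-ratio shift vs M0 (Kruskal-Wallis):")
for _, r in shift.iterrows():
    flag = " *" if r["flagged"] else ""
    print(f"  {r['module_id']:3s} median={r['median_log2_ratio']:+.3f} "
          f"p={r['kw_p_vs_M0']:.3g}{flag}" if np.isfinite(r["kw_p_vs_M0"])
          else f"  {r['module_id']:3s} median={r['median_log2_ratio']:+.3f} (reference)")

pair = generate_disease_gene_sets(150, 15, 0.5, truth, rng, label="synthetic_icm")
for name, members in (("up", pair.up_genes), ("down", pair.down_genes)):
    sel = ratios["gene_id"].isin(members)
    if sel.sum() >= 2:
        ks = ks_shift_test(ratios["log2_ratio"], ratios.loc[sel, "log2_ratio"],
                           label=f"{pair.label}_{name}")
        r = ks.iloc[0]
        print(f"\nKS {r['label']}: D={r['D']:.3f} p={r['ks_p']:.3g} "
              f"median shift {r['median_shift']:+.3f} log2 "
              f"({'significant' if r['ks_p'] < 0.05 else 'not significant'})")
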