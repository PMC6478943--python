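"""Detect co-expression modules in each dataset and select the conserved ones.

Modules are detected per dataset from the topological overlap of the
residualized expression (TIN and batch regressed out).  A biopsy module is
kept when some non-biopsy module's PC1 correlates with its PC1 above 0.85 in
every dataset; retained modules are then restricted to genes shared with a
correlated partner.
"""

from pmlsubtypes import (SimulationConfig, build_compendium, conservation_select,
                        filter_module_genes, generate_multidataset, residualize,
                        run_wgcna)

cfg = SimulationConfig(seed=1)
datasets, truth = generate_multidataset(cfg)
processed = {n: residualize(d, ["tin", "batch"]) for n, d in datasets.items()}

modules = {}
for name, ds in processed.items():
    mods, tom = run_wgcna(ds)
    modules[name] = mods
    print(f"{name:8s} {len(mods):2d} modules at soft power {tom.power}")

comp = build_compendium(modules, processed)
decision = filter_module_genes(conservation_select(comp, 0.85, "biopsy"), comp)

print(f"\nretained biopsy modules: {len(decision.retained_biopsy_modules)} "
      f"(9 shared modules were planted; private ones should be rejected)")
for m in decision.retained_biopsy_modules:
    planted = max(truth.module_genes["biopsy"],
                  key=lambda p: len(set(comp.gene_sets[m])
                                    & set(truth.module_genes["biopsy"][p])))
    print(f"  {m:14s} -> planted {planted:4s}  "
          f"{len(decision.filtered_genes[m])} genes, "
          f"{len(decision.partners[m])} conserved partners")
total = sum(len(v) for v in decision.filtered_genes.values())
print(f"total genes carried into subtype discovery: {total}")
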