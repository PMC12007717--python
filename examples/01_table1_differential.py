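"""Rebuild the published 12-site wildtype vs mps1-1 comparison and classify it.

Aggregates the deterministic PSM fixture into per-site phospho/total counts
and runs the differential classifier.  Sites whose phospho-peptide fraction
drops in the kinase mutant are candidate Mps1-dependent events.
"""

from kinsites import aggregate_sites, differential_table, table1_fixture

proteins, tables, _sites = table1_fixture()
records = [r for s in sorted(tables) for r in tables[s]]
sites, _skipped = aggregate_sites(records, proteins)

results = differential_table(sites, "wt", "mut")
print(f"{'site':<14}{'WT':>8}{'mps1-1':>10}  status")
for r in results:
    wt = f"{r.wt_phospho}/{r.wt_total}"
    mut = f"{r.mut_phospho}/{r.mut_total}" if r.mut_total else "no PSMs"
    print(f"{r.site.label:<14}{wt:>8}{mut:>10}  {r.status}")

lost = sum(r.status == "lost_or_reduced" for r in results)
print(f"\n{lost} of {len(results)} sites lost or reduced phosphorylation in the mutant")
print("(each line shows phospho-PSMs / covering PSMs per purification;")
print(" a falling fraction, even with a persistent count, flags kinase dependence)")
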