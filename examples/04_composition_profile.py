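"""Bait-relative composition of two purifications and enrichment ranking.

Raw per-protein PSM counts are divided by the bait's count ("relative
PSMs"), making runs of different depth comparable; proteins most enriched in
condition B are ranked by the difference of relative PSMs.
"""

from kinsites import enrichment_rank, relative_psms

# spectral counts from two purifications of the same bait (deeper run in B)
run_a = {"Dsn1": 120, "Mtw1": 95, "Nsl1": 80, "Ndc80": 60, "Spc24": 33}
run_b = {"Dsn1": 240, "Mtw1": 180, "Nsl1": 150, "Ndc80": 130, "Spc24": 60,
         "Act1": 210, "Abp1": 96}

comp_a = relative_psms(run_a, bait="Dsn1")
comp_b = relative_psms(run_b, bait="Dsn1")
print(f"{'protein':<8}{'rel A':>8}{'rel B':>8}")
for row in comp_b.rows:
    print(f"{row.protein_id:<8}{comp_a.relative(row.protein_id):>8.2f}{row.relative_psms:>8.2f}")

print("\ntop enriched in condition B (delta of relative PSMs):")
for protein, rel_a, rel_b, delta in enrichment_rank(comp_a, comp_b, top_n=3):
    print(f"  {protein:<8} {rel_a:.2f} -> {rel_b:.2f}  (+{delta:.2f})")
print("\n(the bait is 1.0 by definition; core complex members keep their")
print(" relative levels across runs, so condition-specific interactors rank top)")
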