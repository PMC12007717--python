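"""Classify phospho-site sequence contexts against kinase consensus motifs.

The worked example uses the published Ndc80 immunogen peptide, which places
Thr-248 and Thr-252 in their native context: T252 has a glutamate at −2 and
so fits the Mps1 motif [D/E/N/C-X-S/T-Y]; T248 has a glutamine at −2 and
does not.
"""

from kinsites import assign_category, extract_context, map_peptide, tally_categories

immunogen = "INQNTQEITILSQP"
protein = "A" * 243 + immunogen + "A" * 20  # places the peptide at position 244

(offset,) = map_peptide(immunogen, protein)
print(f"immunogen maps at protein position {offset}; its T's are T248 and T252\n")

for pos in (248, 252):
    context = extract_context(protein, pos)
    a = assign_category(context)
    print(f"T{pos}  context {context}  -> category {a.category} "
          f"(matches: {list(a.matched_motifs) or 'none'})")

examples = {
    "Ipl1-style (K at -2)": "AAAKGSLAAAA",
    "Cdk1-style (P at +1)": "AAAAGSPAAAA",
    "primed (T at -2)": "AAATGSLAAAA",
    "no motif": "AAAAGSLAAAA",
}
print()
assignments = []
for label, context in examples.items():
    a = assign_category(context)
    assignments.append(a)
    flag = " +primed" if a.mps1_primed else ""
    print(f"{label:<22} {context} -> {a.category}{flag}")

print("\ncategory tally:", tally_categories(assignments))
print("(the single category label is the highest-precedence matching motif;")
print(" -2 [S/T] phospho-priming is reported as a flag, not a category)")
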