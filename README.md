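# kinsites

Phospho-site discovery and kinase consensus-motif analysis for
immunoprecipitation mass spectrometry (IP-MS) of protein complexes —
built around the post-processing workflow used to map phosphorylation on
purified budding-yeast kinetochores.

Proteomics cores hand back peptide-spectrum-match (PSM) tables; the
questions a chromosome-segregation lab actually asks are: *which residues
are phosphorylated with credible evidence, which kinase most plausibly put
each phosphate there, which sites disappear when a kinase is crippled, and
did the purification itself change?*  `kinsites` answers those four
questions as a tested, scriptable pipeline:

1. **Site extraction** — peptides are mapped exactly to protein
   coordinates; each site's evidence per sample is
   (phospho-PSMs, covering PSMs, best localization confidence), and sites
   are retained when detected with **≥ 2 PSMs at ≥ 75 % localization
   confidence** in some sample.
2. **Kinase motif classification** — each site's ±5-residue context is
   matched against mitotic kinase consensus motifs:
   Cdk1 `[S/T-P]`, Aurora B/Ipl1 `[K/R-X-S/T-Ψ]` (Ψ ≠ Pro),
   Mps1 `[D/E/N/C-X-S/T-Ψ]` (Ψ ∉ {Glu, Pro}), a configurable Polo/Cdc5
   default, and the Mps1 −2 `[S/T]` phospho-priming variant (reported as a
   flag).  The three headline motifs are provably disjoint; one category
   label per site is chosen by precedence (Mps1 > Ipl1 > Cdk1 > Cdc5,
   otherwise `Other`).
3. **Differential phospho-fraction analysis** — for paired wildtype /
   kinase-mutant purifications, the per-site phospho-peptide fraction
   *k/n* (phospho-PSMs over covering PSMs) is compared exactly as
   rationals; a strictly lower mutant fraction flags the site
   `lost_or_reduced`, with explicit `gained`, `unchanged`,
   `no_coverage_*` and `not_phospho_wt` statuses for every other case.
4. **Composition profiling** — per-protein raw PSM counts divided by the
   bait's count ("relative PSMs") and cross-condition enrichment ranking.

A first-class synthetic-data generator (`kinsites.simulate`) plants
motif-exact sites with known occupancy, coverage, confidence and
kinase-dependence into random proteomes, so every stage is testable with
complete ground truth and no external download.  Novelty annotation
compares detected sites against any user-supplied known-sites list.

## Worked example

```bash
python examples/01_table1_differential.py
```

```
site                WT    mps1-1  status
Cnn1-S105          2/7   no PSMs  no_coverage_mutant
Duo1-T30           2/6       0/4  lost_or_reduced
...
Ndc80-T38         2/17      2/38  lost_or_reduced
Ndc80-T252        2/11      0/18  lost_or_reduced
Spc105-T111        0/6       2/4  gained
...

7 of 12 sites lost or reduced phosphorylation in the mutant
```

Each row is one phospho-site with its phospho-PSMs / covering-PSMs
fraction in the wildtype and *mps1-1* kinetochore purifications.
Ndc80-T38 shows why the rule compares *fractions*, not counts: two
phospho-PSMs persist in the mutant, but over 38 covering spectra instead
of 17, so its occupancy fell and the site is flagged.  Sites with no
mutant coverage are reported as such rather than called lost — the
absence of spectra is not evidence of dephosphorylation.

Other entry points: `examples/02_motif_classification.py` (the
Ndc80 T248/T252 motif calls from the published immunogen-peptide
context), `examples/03_synthetic_recovery.py` (ground-truth recovery on
simulated data), `examples/04_composition_profile.py` (bait-relative
composition and enrichment ranking).  The same capabilities are exposed
as a thin CLI: `kinsites simulate | extract | assign | diff | compose |
run-all | dump-motifs`.

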