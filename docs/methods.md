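# Methods

## Scope and data model

`kinsites` post-processes identified peptide-spectrum matches (PSMs); it
does not touch spectra.  Spectral database search, phospho-localization
scoring and FDR control are upstream of this package, which consumes the
search engine's export as delimited text.  Because vendor export schemas
vary and none is canonical, the PSM dialect here is deliberately minimal
and vendor-neutral: a header row, a column map (sample / protein /
peptide / modifications, remappable via `DialectConfig`), and a fixed
modification grammar `RESIDUE<pos>(<confidence>)` joined by `;`, with the
per-mod percent-scale localization confidence embedded in the entry.
Rows failing validation are returned as structured `RowError`s, never
dropped silently: every filtering decision in this pipeline is meant to
be auditable, and the run manifest records all counts (rows read, rows
failed, sites before/after filter, category and status tallies).

Coordinates are 1-based in both peptide and protein space, matching how
sites are named in the literature (e.g. Thr-248).

## Site extraction

A peptide is placed by exact substring search against its assigned
protein.  Peptides matching at zero or at two or more locations
contribute no evidence and are written to a side report; no protein
inference is attempted, because exclusion is conservative and auditable
where a heuristic assignment would not be.  For every
(protein, position, residue) observed phosphorylated in any sample, the
per-sample evidence is

* `phospho_psms` — PSMs carrying a localized phospho mod at the position
  (a PSM with two mods contributes to two sites),
* `total_psms` — PSMs, phosphorylated or not, whose mapped span covers
  the position; this is the denominator of the phospho-peptide fraction
  and makes cells like 0/18 (covered but never modified) well defined,
* `max_confidence` — the best localization confidence among contributing
  mods.  Confidence is aggregated by maximum because the discovery filter
  operates on sites, not individual spectra; the threshold is applied to
  that maximum.

The inclusion filter retains a site when some single sample shows at
least `min_psms` phospho-PSMs (default 2) together with confidence at
least `min_confidence` (default 75 %).  Requiring both conditions in the
*same* sample is the stricter of the possible readings and corresponds
to per-dataset filtering followed by compilation.  Retention is
monotone in both thresholds (property-tested).

Context windows are `2·halfwidth + 1` residues (halfwidth default 5)
centered on the site, padded with `-` beyond the termini.

## Motif engine

Motifs are positional constraint sets: offset → (allowed | forbidden,
residue set), with offset 0 governed by the acceptor set (S/T for all
defaults; phospho-Tyr is always `Other`).  Padding semantics at termini:
a `-` at a constrained offset fails an *allowed* constraint — the
required residue cannot exist beyond the terminus — and passes a
*forbidden* one.  So a serine at position 1 can never be an Ipl1/Mps1
call, but can be a Cdk1 call.

Defaults (all configurable via YAML/JSON, `kinsites dump-motifs`):

| name | acceptor | −2 | +1 | role |
|---|---|---|---|---|
| Mps1 | S/T | allowed {D,E,N,C} | forbidden {E,P} | category |
| Ipl1 | S/T | allowed {K,R} | forbidden {P} | category |
| Cdk1 | S/T | — | allowed {P} | category |
| Cdc5 | S/T | allowed {D,E} | forbidden {E,P} | category |
| Mps1_primed | S/T | allowed {S,T} | forbidden {E,P} | flag |

Cdk1, Ipl1 and Mps1 are pairwise disjoint (Cdk1 requires +1 = P, which
both others forbid; the −2 sets of Ipl1 and Mps1 are disjoint), verified
by exhaustive enumeration of all 400 (−2, +1) pairs against an
independent brute-force oracle; the derived match counts are 20, 38 and
72 pairs respectively, and 36 for the Cdc5 default.  No published regex
exists for Cdc5's motif in this workflow's source material, so the
shipped default — an acidic −2 with the same +1 exclusions as Mps1 — is
explicitly non-authoritative.  It is a strict subset of the Mps1
pattern, which together with the precedence order
Mps1 > Ipl1 > Cdk1 > Cdc5 yields the conventional three-way + Other
presentation: Cdc5 co-matches are reported in `matched_motifs` but the
category label goes to Mps1.  The −2 [S/T] phospho-priming variant of
the Mps1 motif is reported as an independent boolean flag rather than a
category, since whether the priming phosphate is actually present cannot
be decided from the sequence alone.

## Differential classification

For a site with wildtype evidence k_w/n_w and mutant evidence k_m/n_m,
statuses are assigned in order: n_m = 0 → `no_coverage_mutant`;
n_w = 0 → `no_coverage_wt`; k_w = 0 → `gained` if k_m > 0 else
`not_phospho_wt`; otherwise the fractions are compared exactly as
rationals (`fractions.Fraction`, no float ties):
k_m/n_m < k_w/n_w → `lost_or_reduced`, > → `gained`, = → `unchanged`.

This rule is the one consistent with every call in the published 12-site
wildtype/*mps1-1* comparison this package reproduces, including the two
subtle classes: a site whose phospho-count persists but whose fraction
falls (2/17 → 2/38) is *lost_or_reduced*, and sites with no mutant
coverage are *not* called lost.  The classification is antisymmetric
under sample swap and invariant under scaling one sample's counts —
both property-tested.  No statistical test drives the status: single
spectral-counting runs do not support a calibrated test, and absence of
phosphorylation in one purification is suggestive, not conclusive.  An
optional two-sided Fisher exact p-value (scipy) can be attached per site
for prioritization only.

The differential table is restricted by default to sites with wildtype
coverage of at least `min_wt_total` PSMs (default 2), i.e. sites
actually detected in the wildtype purification.  Detection here means
peptide coverage, not phospho-evidence: sites phosphorylated only in the
mutant (0/6 wildtype) are genuinely informative `gained` calls and are
retained.

## Composition profiling

Raw per-protein PSM counts are divided by the bait's raw count, giving
"relative PSMs" with the bait at exactly 1.  A missing or zero-count
bait is a hard error (the normalization is undefined), and profiles are
scale-invariant by construction.  Cross-condition enrichment is ranked
by the difference of relative PSMs, with proteins absent from a run
contributing zero (no imputation, matching spectral-counting
convention); a ratio metric is available behind a flag since "most
enriched" admits either reading.

## Synthetic-data generator

The generator emulates exactly the statistical structure the pipeline
consumes, with defaults set to the study conditions this package
re-analyzes: 26 proteins of 200–800 residues, a 65/31/33/60
Mps1/Ipl1/Cdk1/Other site mix, mean coverage λ = 20 PSMs per site per
sample, wildtype occupancy 0.3, mutant occupancy 0 at dependent sites
(the Mps1 category by default) and 0.3 elsewhere, plus 10 + 10 decoys.

* Sites are planted at positions ≥ max(2·halfwidth+1, flank+1) apart,
  which keeps context windows disjoint and guarantees no site's covering
  peptide spans a neighbour — so recorded ground-truth counts equal
  aggregated counts identically.
* The −2 and +1 residues of each planted window are rewritten from
  pools chosen so the context matches exactly the intended category and
  no other (e.g. Mps1 sites use −2 ∈ {N,C} to avoid a Cdc5 co-match);
  the result is verified against the motif engine at generation time.
  Cdc5 is therefore not a plantable class — no context can match it
  exclusively under the default patterns — and requesting it is an
  error.
* Coverage is Poisson(λ) conditioned ≥ 1 per site per sample;
  phospho-PSMs are Binomial(coverage, occupancy); confidences are
  normal draws clipped to [75, 100] for true sites and [20, 74] for
  low-confidence decoys, so filter outcomes are exactly predictable.
  Each site's realized pass/fail label (`should_pass_filter`) is
  recorded in the ground truth, making filter tests exact even at
  occupancies where a true site can stochastically miss the PSM floor.
* Tryptic digestion, retention time and intensities are not simulated:
  the analysis consumes PSM tables, so one fixed covering peptide per
  site (global uniqueness checked) is sufficient, and coverage is
  modeled per site rather than per digest fragment.

What passing synthetic tests does *not* show: real exports have
correlated coverage between sites sharing peptides, protein-inference
ambiguity, decoy structure far messier than two clean failure modes, and
localization confidences that are not independent of peptide identity.
The generator validates the pipeline's logic, not search-engine
behaviour.

Alongside the stochastic generator, `table1_fixture()` deterministically
rebuilds — as PSM tables over synthetic stand-in sequences (labelled as
such) — the 12-site wildtype/*mps1-1* count table, including the real
immunogen-peptide context around Ndc80 T248/T252, a shared covering
peptide for Spc105 T107/T111 (their printed per-sample totals are
identical, consistent with one peptide), −2 [S/T] primed contexts for
the Spc105 sites and strict Mps1 contexts elsewhere, and "no PSMs" cells
encoded as zero coverage.

## Numerical and design choices

* Fraction comparisons use exact rational arithmetic; sorting is always
  by (protein, position) with explicit tiebreaks, and all writers emit
  byte-identical output for identical input.
* ">1 PSM" and "≥2 PSMs" are the same integer constraint; the default is
  stored as `min_psms = 2`.
* Ambiguous/unmapped peptides, malformed rows and all thresholds are
  surfaced in outputs and the JSON manifest rather than logged and lost.
* Seeds: a single integer fixes every draw (NumPy `default_rng`); the
  pipeline is deterministic end-to-end under fixed config.

## Known limitations

* No protein inference or isoform handling; shared peptides are excluded
  rather than apportioned.
* The site-inclusion rule uses the per-site maximum confidence; a
  per-PSM filtering convention would be slightly stricter.
* The Cdc5 default motif is a placeholder for an unpublished pattern and
  unreachable as a category under default precedence; users studying
  Polo-kinase substrates should supply their own pattern.
* The differential call is unpowered at low coverage by design — it
  reports what the spectra show and attaches no significance claim.
* Problem sizes in the test suite and acceptance script (tens of
  proteins, ≤ 200 planted sites, 10 replicate seeds) were chosen as the
  smallest sizes at which the stochastic checks are stable; all scale
  linearly if enlarged.
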