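"""Paired wildtype / kinase-mutant differential phospho-fraction analysis.

For each site the phospho-peptide fraction — phosphorylated PSMs over all
PSMs covering the site — is compared between a wildtype and a kinase-mutant
purification and the site is classified:

* ``no_coverage_mutant`` / ``no_coverage_wt`` — no covering PSMs in that
  sample, so no call can be made;
* ``not_phospho_wt`` — the site carried no phosphate in wildtype and none
  appeared in the mutant;
* ``gained`` — the mutant fraction exceeds the wildtype fraction (including
  phosphorylation appearing where wildtype had none);
* ``lost_or_reduced`` — the mutant fraction is strictly below the wildtype
  fraction, the signature of kinase dependence;
* ``unchanged`` — equal fractions.

No statistical test drives the call: absence of phosphorylation in a single
purification is suggestive, not conclusive, and the classification mirrors
that reasoning.  An optional two-proportion exact-test p-value can be
attached for prioritization but never changes the status.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .extract import PhosphoSite, SampleEvidence
from .io import ConfigurationError

LOST_OR_REDUCED = "lost_or_reduced"
GAINED = "gained"
UNCHANGED = "unchanged"
NO_COVERAGE_MUTANT = "no_coverage_mutant"
NO_COVERAGE_WT = "no_coverage_wt"
NOT_PHOSPHO_WT = "not_phospho_wt"

STATUSES = (
    LOST_OR_REDUCED,
    GAINED,
    UNCHANGED,
    NO_COVERAGE_MUTANT,
    NO_COVERAGE_WT,
    NOT_PHOSPHO_WT,
)


@dataclass(frozen=True)
class DifferentialResult:
    site: PhosphoSite | None
    wt_phospho: int
    wt_total: int
    mut_phospho: int
    mut_total: int
    status: str
    p_value: float | None = None

    @property
    def wt_fraction(self) -> float | None:
        return self.wt_phospho / self.wt_total if self.wt_total else None

    @property
    def mut_fraction(self) -> float | None:
        return self.mut_phospho / self.mut_total if self.mut_total else None


def _counts(evidence) -> tuple[int, int]:
    if evidence is None:
        return 0, 0
    if isinstance(evidence, SampleEvidence):
        return evidence.phospho_psms, evidence.total_psms
    phospho, total = evidence
    return int(phospho), int(total)


def compare_site(wt_evidence, mut_evidence, site: PhosphoSite | None = None) -> DifferentialResult:
    """Classify one site from its wildtype and mutant evidence.

    Each evidence argument is a ``(phospho, total)`` pair, a
    :class:`~kinsites.extract.SampleEvidence`, or ``None`` (treated as 0/0).
    Fractions are compared exactly (as rationals), so e.g. 2/4 vs 1/2 is
    ``unchanged``.
    """
    wt_phospho, wt_total = _counts(wt_evidence)
    mut_phospho, mut_total = _counts(mut_evidence)
    for phospho, total, label in ((wt_phospho, wt_total, "wt"), (mut_phospho, mut_total, "mutant")):
        if phospho < 0 or total < 0 or phospho > total:
            raise ValueError(f"{label} counts invalid: {phospho}/{total}")

    if mut_total == 0:
        status = NO_COVERAGE_MUTANT
    elif wt_total == 0:
        status = NO_COVERAGE_WT
    elif wt_phospho == 0:
        status = GAINED if mut_phospho > 0 else NOT_PHOSPHO_WT
    else:
        wt_frac = Fraction(wt_phospho, wt_total)
        mut_frac = Fraction(mut_phospho, mut_total)
        if mut_frac < wt_frac:
            status = LOST_OR_REDUCED
        elif mut_frac > wt_frac:
            status = GAINED
        else:
            status = UNCHANGED
    return DifferentialResult(
        site=site,
        wt_phospho=wt_phospho,
        wt_total=wt_total,
        mut_phospho=mut_phospho,
        mut_total=mut_total,
        status=status,
    )


def attach_p_value(result: DifferentialResult) -> DifferentialResult:
    """Attach a two-sided Fisher exact-test p-value (informational only)."""
    from scipy.stats import fisher_exact

    table = [
        [result.wt_phospho, result.wt_total - result.wt_phospho],
        [result.mut_phospho, result.mut_total - result.mut_phospho],
    ]
    if result.wt_total == 0 or result.mut_total == 0:
        p = None
    else:
        p = float(fisher_exact(table, alternative="two-sided")[1])
    return DifferentialResult(
        site=result.site,
        wt_phospho=result.wt_phospho,
        wt_total=result.wt_total,
        mut_phospho=result.mut_phospho,
        mut_total=result.mut_total,
        status=result.status,
        p_value=p,
    )


def differential_table(
    sites: Sequence[PhosphoSite],
    wt_sample: str,
    mut_sample: str,
    min_wt_total: int = 2,
    with_p_values: bool = False,
) -> list[DifferentialResult]:
    """Classify every site between ``wt_sample`` and ``mut_sample``.

    By default results are restricted to sites actually detected in the
    wildtype purification (``min_wt_total`` covering PSMs in WT), mirroring
    a comparison table built from sites "detected in a purification of
    wildtype" material.  A sample id never seen in any site's evidence is a
    configuration error; per-site absent evidence is treated as 0/0.
    """
    if sites:
        seen = {s for site in sites for s in site.evidence}
        for sample in (wt_sample, mut_sample):
            if sample not in seen:
                raise ConfigurationError(
                    f"sample {sample!r} never seen in site evidence (samples: {sorted(seen)})"
                )
    results = []
    for site in sorted(sites, key=lambda s: (s.protein_id, s.protein_pos)):
        wt = site.evidence.get(wt_sample)
        if min_wt_total and (wt is None or wt.total_psms < min_wt_total):
            continue
        res = compare_site(wt, site.evidence.get(mut_sample), site=site)
        if with_p_values:
            res = attach_p_value(res)
        results.append(res)
    return results


def tally_statuses(results: Sequence[DifferentialResult]) -> dict[str, int]:
    tally = {s: 0 for s in STATUSES}
    for r in results:
        tally[r.status] += 1
    return tally


def write_differential_table(results: Sequence[DifferentialResult], path) -> None:
    """Write a TSV mirroring a WT-vs-mutant fraction comparison table."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = [
            "protein_id", "position", "residue",
            "wt_phospho", "wt_total", "mut_phospho", "mut_total",
            "wt_fraction", "mut_fraction", "status",
        ]
        any_p = any(r.p_value is not None for r in results)
        if any_p:
            header.append("p_value")
        writer.writerow(header)
        for r in results:
            row = [
                r.site.protein_id if r.site else "",
                r.site.protein_pos if r.site else "",
                r.site.residue if r.site else "",
                r.wt_phospho, r.wt_total, r.mut_phospho, r.mut_total,
                "" if r.wt_fraction is None else f"{r.wt_fraction:.6g}",
                "" if r.mut_fraction is None else f"{r.mut_fraction:.6g}",
                r.status,
            ]
            if any_p:
                row.append("" if r.p_value is None else f"{r.p_value:.6g}")
            writer.writerow(row)
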