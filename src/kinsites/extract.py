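"""Turn PSM-level records into protein-coordinate phospho-sites.

A phospho-site is a (protein, position, residue) triple observed carrying a
phosphate in at least one sample.  Per sample, its evidence is:

* ``phospho_psms`` — PSMs carrying a localized phospho mod at that position;
* ``total_psms``  — PSMs (phospho or not) whose mapped peptide span covers
  the position, i.e. the "total peptides detected for a given site";
* ``max_confidence`` — the best localization confidence among contributing
  mods.

Peptides mapping to zero or to multiple protein locations contribute no
evidence; they are reported separately so the exclusion is auditable.
Site-level inclusion follows the discovery filter of the study this package
reimplements: at least ``min_psms`` phospho-PSMs (default 2) and localization
confidence at least ``min_confidence`` percent (default 75) in some sample.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import PAD, PHOSPHO_RESIDUES, KnownSiteList, ProteinDb, PsmRecord

DEFAULT_CONTEXT_HALFWIDTH = 5


@dataclass(frozen=True)
class SampleEvidence:
    phospho_psms: int
    total_psms: int
    max_confidence: float

    def __post_init__(self) -> None:
        if not 0 <= self.phospho_psms <= self.total_psms:
            raise ValueError(
                f"phospho_psms={self.phospho_psms} must lie in [0, total_psms={self.total_psms}]"
            )


@dataclass(frozen=True)
class PhosphoSite:
    """A protein-coordinate phospho-site with per-sample evidence."""

    protein_id: str
    protein_pos: int  # 1-based
    residue: str
    context: str
    evidence: Mapping[str, SampleEvidence] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return f"{self.protein_id}-{self.residue}{self.protein_pos}"

    def best_phospho_psms(self) -> int:
        return max((ev.phospho_psms for ev in self.evidence.values()), default=0)

    def max_confidence(self) -> float:
        return max((ev.max_confidence for ev in self.evidence.values()), default=0.0)


@dataclass(frozen=True)
class FilterThresholds:
    """Site-inclusion thresholds: ``min_psms`` phospho-PSMs at ``min_confidence``%."""

    min_psms: int = 2
    min_confidence: float = 75.0

    def __post_init__(self) -> None:
        if self.min_psms < 1:
            raise ValueError("min_psms must be >= 1")
        if not 0.0 <= self.min_confidence <= 100.0:
            raise ValueError("min_confidence must lie in [0, 100]")


@dataclass(frozen=True)
class SkippedPsm:
    """A PSM excluded from site evidence, with the reason (unmapped/ambiguous)."""

    record: PsmRecord
    reason: str  # "unmapped" | "ambiguous"
    n_matches: int


def map_peptide(peptide: str, protein_seq: str) -> list[int]:
    """All 1-based start offsets of ``peptide`` in ``protein_seq`` (overlapping)."""
    offsets = []
    start = protein_seq.find(peptide)
    while start != -1:
        offsets.append(start + 1)
        start = protein_seq.find(peptide, start + 1)
    return offsets


def extract_context(protein_seq: str, protein_pos: int, halfwidth: int = DEFAULT_CONTEXT_HALFWIDTH) -> str:
    """Residue window of ``2*halfwidth + 1`` centered at ``protein_pos`` (1-based),
    padded with ``-`` beyond the protein termini."""
    i = protein_pos - 1
    chars = []
    for off in range(-halfwidth, halfwidth + 1):
        j = i + off
        chars.append(protein_seq[j] if 0 <= j < len(protein_seq) else PAD)
    return "".join(chars)


def aggregate_sites(
    records: Sequence[PsmRecord],
    proteins: ProteinDb,
    context_halfwidth: int = DEFAULT_CONTEXT_HALFWIDTH,
) -> tuple[list[PhosphoSite], list[SkippedPsm]]:
    """Aggregate PSMs into per-site, per-sample evidence.

    Returns ``(sites, skipped)`` where ``sites`` holds one
    :class:`PhosphoSite` per (protein, position, residue) ever observed
    phosphorylated, ordered by (protein, position), and ``skipped`` lists
    PSMs whose peptide mapped to zero or to multiple locations in their
    protein.  An unknown protein accession is a hard error listing every
    offender.
    """
    offenders = sorted({r.protein_id for r in records if r.protein_id not in proteins})
    if offenders:
        raise KeyError(f"protein accessions absent from the proteome: {offenders}")

    skipped: list[SkippedPsm] = []
    # (sample, protein) -> list of covering spans (start, end) 1-based inclusive
    coverage: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    # (protein, pos, residue) -> sample -> [phospho_psm_count, max_confidence]
    phospho: dict[tuple[str, int, str], dict[str, list]] = defaultdict(dict)

    for rec in records:
        seq = proteins[rec.protein_id]
        offsets = map_peptide(rec.peptide, seq)
        if len(offsets) != 1:
            reason = "unmapped" if not offsets else "ambiguous"
            skipped.append(SkippedPsm(record=rec, reason=reason, n_matches=len(offsets)))
            continue
        start = offsets[0]
        coverage[(rec.sample_id, rec.protein_id)].append((start, start + len(rec.peptide) - 1))
        for mod in rec.phospho_mods:
            pos = start + mod.peptide_pos - 1
            key = (rec.protein_id, pos, mod.residue)
            per_sample = phospho[key].setdefault(rec.sample_id, [0, 0.0])
            per_sample[0] += 1
            per_sample[1] = max(per_sample[1], mod.confidence)

    samples = sorted({s for s, _ in coverage})
    sites: list[PhosphoSite] = []
    for (protein_id, pos, residue) in sorted(phospho):
        seq = proteins[protein_id]
        assert seq[pos - 1] == residue  # guaranteed by PsmRecord + exact mapping
        evidence: dict[str, SampleEvidence] = {}
        for sample in samples:
            total = sum(
                1 for (a, b) in coverage.get((sample, protein_id), ()) if a <= pos <= b
            )
            n_phospho, conf = phospho[(protein_id, pos, residue)].get(sample, (0, 0.0))
            if total == 0 and n_phospho == 0:
                continue
            evidence[sample] = SampleEvidence(
                phospho_psms=n_phospho, total_psms=total, max_confidence=conf
            )
        sites.append(
            PhosphoSite(
                protein_id=protein_id,
                protein_pos=pos,
                residue=residue,
                context=extract_context(seq, pos, context_halfwidth),
                evidence=evidence,
            )
        )
    return sites, skipped


def filter_sites(
    sites: Iterable[PhosphoSite], thresholds: FilterThresholds | None = None
) -> list[PhosphoSite]:
    """Retain sites whose best single-sample evidence meets both thresholds.

    A site passes if some sample shows ``phospho_psms >= min_psms`` with
    ``max_confidence >= min_confidence`` in that same sample.  Output order
    is (protein, position).
    """
    thresholds = thresholds or FilterThresholds()
    kept = [
        site
        for site in sites
        if any(
            ev.phospho_psms >= thresholds.min_psms
            and ev.max_confidence >= thresholds.min_confidence
            for ev in site.evidence.values()
        )
    ]
    return sorted(kept, key=lambda s: (s.protein_id, s.protein_pos))


def annotate_known(sites: Sequence[PhosphoSite], known: KnownSiteList) -> list[bool]:
    """Per-site flag: True iff (protein, position, residue) is previously reported."""
    return [(s.protein_id, s.protein_pos, s.residue) in known for s in sites]
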