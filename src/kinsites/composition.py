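"""Bait-relative PSM composition of IP-MS purifications.

In immunoprecipitation mass spectrometry the raw spectral count of each
co-purifying protein is divided by the raw count of the bait (the tagged,
immunoprecipitated protein) to give "relative PSMs", a scale-free
composition profile that can be compared across runs.  Cross-condition
enrichment is ranked by the difference of relative PSMs by default (a
ratio-based alternative is available); proteins absent from a run
contribute zero, matching spectral-counting convention.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io import ConfigurationError, PsmRecord


@dataclass(frozen=True)
class CompositionRow:
    protein_id: str
    raw_psms: int
    relative_psms: float


@dataclass(frozen=True)
class Composition:
    bait: str
    rows: tuple[CompositionRow, ...]

    def relative(self, protein_id: str) -> float:
        for row in self.rows:
            if row.protein_id == protein_id:
                return row.relative_psms
        return 0.0


def psm_counts(records: Sequence[PsmRecord], sample_id: str) -> dict[str, int]:
    """Raw PSM count per protein for one sample (every PSM counts once)."""
    return dict(Counter(r.protein_id for r in records if r.sample_id == sample_id))


def relative_psms(counts: Mapping[str, int], bait: str) -> Composition:
    """Normalize raw per-protein PSM counts by the bait's count.

    Rows are sorted by descending relative PSMs with protein id as the
    tiebreak; the bait row is exactly 1.  A missing or zero-count bait makes
    the normalization undefined and is a hard error.
    """
    bait_count = counts.get(bait, 0)
    if bait_count <= 0:
        raise ConfigurationError(
            f"bait {bait!r} absent or has zero PSMs; relative normalization undefined"
        )
    rows = [
        CompositionRow(protein_id=p, raw_psms=int(n), relative_psms=n / bait_count)
        for p, n in counts.items()
    ]
    rows.sort(key=lambda r: (-r.relative_psms, r.protein_id))
    return Composition(bait=bait, rows=tuple(rows))


def enrichment_rank(
    cond_a: Composition,
    cond_b: Composition,
    top_n: int | None = None,
    metric: str = "difference",
) -> list[tuple[str, float, float, float]]:
    """Rank proteins most enriched in condition B relative to condition A.

    Returns ``(protein, rel_a, rel_b, delta)`` tuples sorted by descending
    delta (protein id tiebreak), truncated to ``top_n``.  ``metric`` is
    ``"difference"`` (rel_b − rel_a, the default) or ``"ratio"``
    (rel_b / rel_a, with absence treated as a pseudo-relative of 0 giving
    ``inf`` for condition-B-only proteins).  Both compositions must be
    normalized to the same bait.
    """
    if cond_a.bait != cond_b.bait:
        raise ConfigurationError(
            f"compositions use different baits: {cond_a.bait!r} vs {cond_b.bait!r}"
        )
    if metric not in ("difference", "ratio"):
        raise ValueError(f"metric must be difference/ratio, got {metric!r}")
    rel_a = {r.protein_id: r.relative_psms for r in cond_a.rows}
    rel_b = {r.protein_id: r.relative_psms for r in cond_b.rows}
    out = []
    for protein in sorted(set(rel_a) | set(rel_b)):
        a = rel_a.get(protein, 0.0)
        b = rel_b.get(protein, 0.0)
        if metric == "difference":
            delta = b - a
        else:
            delta = b / a if a > 0 else (float("inf") if b > 0 else 0.0)
        out.append((protein, a, b, delta))
    out.sort(key=lambda t: (-t[3], t[0]))
    return out[:top_n] if top_n is not None else out


def write_composition(composition: Composition, path) -> None:
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "raw_psms", "relative_psms"])
        for row in composition.rows:
            writer.writerow([row.protein_id, row.raw_psms, f"{row.relative_psms:.6g}"])
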