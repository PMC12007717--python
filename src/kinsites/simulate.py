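"""Synthetic proteomes and PSM tables with fully known ground truth.

The generator emulates the evidence structure of a paired wildtype /
kinase-mutant IP-MS phosphoproteomics experiment:

* random protein sequences into which motif-consistent context windows are
  planted (the −2 and +1 residues are rewritten so each planted site
  satisfies exactly its intended kinase category and no other, verified
  against the motif engine at generation time);
* per site and sample, covering PSMs drawn Poisson(``coverage_lambda``)
  conditioned ≥ 1 and phospho PSMs Binomial(total, occupancy), where the
  occupancy is ``occupancy_wt`` in wildtype and, in the mutant,
  ``occupancy_mut_dependent`` for kinase-dependent sites (those in
  ``dependent_categories``, Mps1 by default) or
  ``occupancy_mut_independent`` otherwise;
* localization confidences drawn from a high distribution for true sites
  and a sub-threshold distribution for low-confidence decoys;
* decoy sites planted with sub-threshold PSM counts or confidence, so the
  discovery filter's behaviour is exactly predictable.

Tryptic digestion is not simulated: the downstream analysis consumes PSM
tables, so coverage is modeled per site with one fixed covering peptide per
site (peptide uniqueness across the proteome is checked at generation).

Default parameters mirror the study conditions this package re-analyzes:
26 proteins, a 65/31/33/60 Mps1/Ipl1/Cdk1/Other site mix, ~20 covering
PSMs per site, 30% wildtype phospho-occupancy, and complete loss of
dependent-site occupancy in the mutant.

:func:`table1_fixture` is separate and deterministic: it rebuilds, as PSM
tables over synthetic sequences, the per-site wildtype and *mps1-1* count
pairs of the published 12-site comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .extract import aggregate_sites, extract_context, filter_sites, FilterThresholds
from .io import (
    AMINO_ACIDS,
    KnownSiteList,
    PhosphoMod,
    ProteinDb,
    PsmRecord,
    write_fasta,
    write_known_sites,
    write_psm_table,
)
from .motifs import assign_category, default_motifs

WT_SAMPLE = "wt"
MUT_SAMPLE = "mut"

_AA = sorted(AMINO_ACIDS)
# residue pools used when rewriting a planted window so that the context
# matches exactly the intended category pattern and none of the others
_NEUTRAL_MINUS2 = sorted(AMINO_ACIDS - set("KRDENCST"))
_PLANT_RULES: dict[str, tuple[list[str], list[str]]] = {
    # category -> (choices for -2, choices for +1)
    "Mps1": (["N", "C"], sorted(AMINO_ACIDS - set("EP"))),
    "Ipl1": (["K", "R"], sorted(AMINO_ACIDS - set("P"))),
    "Cdk1": (_NEUTRAL_MINUS2, ["P"]),
    "Other": (_NEUTRAL_MINUS2, sorted(AMINO_ACIDS - set("P"))),
}


class GenerationError(RuntimeError):
    """Raised when a simulation request cannot be satisfied (e.g. more sites
    than available positions)."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment (all draws fixed by ``seed``)."""

    seed: int = 0
    n_proteins: int = 26
    protein_length: tuple[int, int] = (200, 800)
    n_sites: Mapping[str, int] = field(
        default_factory=lambda: {"Mps1": 65, "Ipl1": 31, "Cdk1": 33, "Other": 60}
    )
    coverage_lambda: float = 20.0
    occupancy_wt: float = 0.3
    occupancy_mut_dependent: float = 0.0
    occupancy_mut_independent: float = 0.3
    conf_true_mean: float = 93.0
    conf_true_sd: float = 3.0
    conf_decoy_mean: float = 55.0
    conf_decoy_sd: float = 8.0
    n_decoy_lowpsm: int = 10
    n_decoy_lowconf: int = 10
    fraction_known: float = 0.3
    context_halfwidth: int = 5
    peptide_flank: int = 7
    dependent_categories: tuple[str, ...] = ("Mps1",)

    def __post_init__(self) -> None:
        for name in (
            "occupancy_wt",
            "occupancy_mut_dependent",
            "occupancy_mut_independent",
            "fraction_known",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if any(n < 0 for n in self.n_sites.values()):
            raise ValueError("site counts must be non-negative")
        if self.n_decoy_lowpsm < 0 or self.n_decoy_lowconf < 0:
            raise ValueError("decoy counts must be non-negative")
        unknown = set(self.n_sites) - set(_PLANT_RULES)
        if unknown:
            raise ValueError(
                f"unsupported planting categories {sorted(unknown)}; "
                f"supported: {sorted(_PLANT_RULES)}"
            )


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted site, consistent with the emitted tables."""

    protein_id: str
    position: int
    residue: str
    category: str
    mps1_dependent: bool
    is_decoy: bool
    decoy_kind: str | None
    should_pass_filter: bool
    known: bool
    wt_phospho: int
    wt_total: int
    mut_phospho: int
    mut_total: int


@dataclass(frozen=True)
class SimulatedDataset:
    config: SimConfig
    proteins: ProteinDb
    psm_tables: Mapping[str, tuple[PsmRecord, ...]]
    known_sites: KnownSiteList
    ground_truth: tuple[PlantedSite, ...]

    def all_records(self) -> list[PsmRecord]:
        out: list[PsmRecord] = []
        for sample in sorted(self.psm_tables):
            out.extend(self.psm_tables[sample])
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, outdir / "proteins.fasta")
        for sample, records in sorted(self.psm_tables.items()):
            write_psm_table(records, outdir / f"psms_{sample}.tsv")
        write_known_sites(self.known_sites, outdir / "known_sites.tsv")
        self._write_ground_truth(outdir / "ground_truth.tsv")

    def _write_ground_truth(self, path: Path) -> None:
        import csv

        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(
                [
                    "protein_id", "position", "residue", "category",
                    "mps1_dependent", "is_decoy", "decoy_kind",
                    "should_pass_filter", "known",
                    "wt_phospho", "wt_total", "mut_phospho", "mut_total",
                ]
            )
            for s in self.ground_truth:
                writer.writerow(
                    [
                        s.protein_id, s.position, s.residue, s.category,
                        int(s.mps1_dependent), int(s.is_decoy), s.decoy_kind or "",
                        int(s.should_pass_filter), int(s.known),
                        s.wt_phospho, s.wt_total, s.mut_phospho, s.mut_total,
                    ]
                )


def _poisson_at_least_one(rng: np.random.Generator, lam: float) -> int:
    while True:
        n = int(rng.poisson(lam))
        if n >= 1:
            return n


def _draw_confidence(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    return round(float(np.clip(rng.normal(mean, sd), lo, hi)), 2)


def _choose_positions(
    rng: np.random.Generator,
    sequences: dict[str, list[str]],
    n_needed: int,
    halfwidth: int,
    min_gap: int,
) -> list[tuple[str, int]]:
    margin = halfwidth + 1
    candidates = [
        (acc, pos)
        for acc, seq in sequences.items()
        for pos in range(margin, len(seq) - halfwidth + 1)
    ]
    rng.shuffle(candidates)
    chosen: list[tuple[str, int]] = []
    taken: dict[str, list[int]] = {acc: [] for acc in sequences}
    for acc, pos in candidates:
        if len(chosen) == n_needed:
            break
        if all(abs(pos - p) >= min_gap for p in taken[acc]):
            taken[acc].append(pos)
            chosen.append((acc, pos))
    if len(chosen) < n_needed:
        raise GenerationError(
            f"requested {n_needed} sites but only {len(chosen)} positions available"
        )
    return chosen


def _unique_peptide(
    sequences: Mapping[str, str], acc: str, pos: int, flank: int
) -> tuple[str, int]:
    """Covering peptide for a site; returns (peptide, 1-based start).  The
    peptide must occur exactly once in the whole proteome."""
    seq = sequences[acc]
    start = max(1, pos - flank)
    end = min(len(seq), pos + flank)
    peptide = seq[start - 1 : end]
    hits = sum(_count_occurrences(s, peptide) for s in sequences.values())
    if hits != 1:
        raise GenerationError(
            f"covering peptide for {acc}:{pos} is not unique in the proteome "
            f"({hits} occurrences); re-run with a different seed"
        )
    return peptide, start


def _count_occurrences(seq: str, sub: str) -> int:
    count = 0
    start = seq.find(sub)
    while start != -1:
        count += 1
        start = seq.find(sub, start + 1)
    return count


def simulate(config: SimConfig) -> SimulatedDataset:
    """Generate a full synthetic experiment from ``config``.

    Returns the proteome, one PSM table per sample (``wt`` and ``mut``), the
    known-sites list, and per-site ground truth.  Identical configs produce
    byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.protein_length
    sequences_mut: dict[str, list[str]] = {}
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        sequences_mut[f"SYN{i + 1:03d}"] = list(rng.choice(_AA, size=length))

    plan: list[tuple[str, bool, str | None]] = []  # (category, is_decoy, decoy_kind)
    for category in sorted(config.n_sites):
        plan += [(category, False, None)] * config.n_sites[category]
    plan += [("Other", True, "low_psm")] * config.n_decoy_lowpsm
    plan += [("Other", True, "low_conf")] * config.n_decoy_lowconf

    # spacing keeps context windows disjoint and guarantees that a site's
    # covering peptide never spans a neighbouring planted site
    min_gap = max(2 * config.context_halfwidth + 1, config.peptide_flank + 1)
    positions = _choose_positions(
        rng, sequences_mut, len(plan), config.context_halfwidth, min_gap
    )

    # rewrite each planted window to match exactly the intended category
    planted: list[dict] = []
    for (category, is_decoy, decoy_kind), (acc, pos) in zip(plan, positions):
        seq = sequences_mut[acc]
        residue = str(rng.choice(["S", "T"]))
        minus2_pool, plus1_pool = _PLANT_RULES[category]
        seq[pos - 1] = residue
        seq[pos - 3] = str(rng.choice(minus2_pool))
        seq[pos] = str(rng.choice(plus1_pool))
        planted.append(
            dict(
                acc=acc, pos=pos, residue=residue, category=category,
                is_decoy=is_decoy, decoy_kind=decoy_kind,
            )
        )

    sequences = {acc: "".join(chars) for acc, chars in sequences_mut.items()}
    proteins = ProteinDb(sequences=sequences, source=f"simulated(seed={config.seed})")

    # verify planted categories against the motif engine
    motifs = default_motifs()
    for p in planted:
        context = extract_context(sequences[p["acc"]], p["pos"], config.context_halfwidth)
        assignment = assign_category(context, motifs)
        if assignment.category != p["category"]:
            raise GenerationError(
                f"planted {p['category']} context {context!r} assigned "
                f"{assignment.category} by the motif engine"
            )

    planted.sort(key=lambda p: (p["acc"], p["pos"]))

    thresholds = FilterThresholds()
    records: dict[str, list[PsmRecord]] = {WT_SAMPLE: [], MUT_SAMPLE: []}
    truth: list[PlantedSite] = []
    for p in planted:
        peptide, pep_start = _unique_peptide(sequences, p["acc"], p["pos"], config.peptide_flank)
        pep_pos = p["pos"] - pep_start + 1
        dependent = (not p["is_decoy"]) and p["category"] in config.dependent_categories
        counts: dict[str, tuple[int, int]] = {}
        passes: dict[str, bool] = {}
        for sample in (WT_SAMPLE, MUT_SAMPLE):
            total = _poisson_at_least_one(rng, config.coverage_lambda)
            if p["decoy_kind"] == "low_psm":
                n_phospho = min(1, total)
            else:
                occ = config.occupancy_wt if sample == WT_SAMPLE else (
                    config.occupancy_mut_dependent
                    if dependent
                    else config.occupancy_mut_independent
                )
                n_phospho = int(rng.binomial(total, occ))
            confs = []
            for _ in range(n_phospho):
                if p["decoy_kind"] == "low_conf":
                    conf = _draw_confidence(
                        rng, config.conf_decoy_mean, config.conf_decoy_sd,
                        20.0, thresholds.min_confidence - 1.0,
                    )
                else:
                    conf = _draw_confidence(
                        rng, config.conf_true_mean, config.conf_true_sd,
                        max(thresholds.min_confidence, 75.0), 100.0,
                    )
                confs.append(conf)
            for conf in confs:
                records[sample].append(
                    PsmRecord(
                        sample_id=sample,
                        protein_id=p["acc"],
                        peptide=peptide,
                        phospho_mods=(
                            PhosphoMod(peptide_pos=pep_pos, residue=p["residue"], confidence=conf),
                        ),
                    )
                )
            for _ in range(total - n_phospho):
                records[sample].append(
                    PsmRecord(sample_id=sample, protein_id=p["acc"], peptide=peptide)
                )
            counts[sample] = (n_phospho, total)
            passes[sample] = (
                n_phospho >= thresholds.min_psms
                and bool(confs)
                and max(confs) >= thresholds.min_confidence
            )
        known = (not p["is_decoy"]) and bool(rng.random() < config.fraction_known)
        truth.append(
            PlantedSite(
                protein_id=p["acc"],
                position=p["pos"],
                residue=p["residue"],
                category=p["category"],
                mps1_dependent=dependent,
                is_decoy=p["is_decoy"],
                decoy_kind=p["decoy_kind"],
                should_pass_filter=any(passes.values()),
                known=known,
                wt_phospho=counts[WT_SAMPLE][0],
                wt_total=counts[WT_SAMPLE][1],
                mut_phospho=counts[MUT_SAMPLE][0],
                mut_total=counts[MUT_SAMPLE][1],
            )
        )

    known_sites = KnownSiteList(
        sites=frozenset(
            (s.protein_id, s.position, s.residue) for s in truth if s.known
        )
    )
    return SimulatedDataset(
        config=config,
        proteins=proteins,
        psm_tables={s: tuple(r) for s, r in records.items()},
        known_sites=known_sites,
        ground_truth=tuple(truth),
    )


# --- published 12-site comparison-table fixture ------------------------------

#: (protein, residue, position, (wt_phospho, wt_total), (mut_phospho, mut_total) or
#: None for "no PSMs", expected_lost_or_reduced, primed_context)
TABLE1_ROWS: tuple = (
    ("Ndc80", "T", 38, (2, 17), (2, 38), True, False),
    ("Ndc80", "S", 97, (2, 4), (0, 3), True, False),
    ("Ndc80", "T", 252, (2, 11), (0, 18), True, False),
    ("Duo1", "T", 30, (2, 6), (0, 4), True, False),
    ("Spc105", "T", 107, (2, 6), (0, 4), True, True),
    ("Spc105", "T", 111, (0, 6), (2, 4), False, True),
    ("Spc105", "S", 250, (2, 4), (0, 4), True, True),
    ("Spc105", "T", 355, (0, 7), (7, 16), False, True),
    ("Cnn1", "S", 105, (2, 7), None, False, False),
    ("Mif2", "S", 162, (8, 21), (0, 2), True, False),
    ("Mif2", "S", 325, (4, 13), None, False, False),
    ("Ubr2", "S", 717, (2, 4), None, False, False),
)

#: the seven sites reported with lost or reduced phosphorylation in the mutant
TABLE1_LOST_OR_REDUCED: frozenset[tuple[str, int]] = frozenset(
    (protein, pos) for protein, _res, pos, _wt, _mut, lost, _pr in TABLE1_ROWS if lost
)

_IMMUNOGEN = "INQNTQEITILSQP"  # places T248 at its center-left; T252 at offset +8

_FIXTURE_LENGTHS = {
    "Ndc80": 280, "Duo1": 60, "Spc105": 380, "Cnn1": 130, "Mif2": 350, "Ubr2": 740,
}
# deterministic context rewrites: strict Mps1 sites get an acidic/amide −2,
# primed sites (per the priming-site list) get S/T at −2; +1 never E/P
_FIXTURE_CONTEXTS = {
    ("Ndc80", 38): ("E", "L"),
    ("Ndc80", 97): ("D", "A"),
    # Ndc80 248/252 come verbatim from the immunogen peptide
    ("Duo1", 30): ("N", "V"),
    ("Spc105", 107): ("S", "A"),
    ("Spc105", 111): ("S", "A"),
    ("Spc105", 250): ("T", "A"),
    ("Spc105", 355): ("S", "T"),
    ("Cnn1", 105): ("E", "A"),
    ("Mif2", 162): ("D", "L"),
    ("Mif2", 325): ("E", "V"),
    ("Ubr2", 717): ("N", "A"),
}
_FIXTURE_CONFIDENCE = 99.0


def table1_proteins() -> ProteinDb:
    """Deterministic synthetic stand-in sequences for the six proteins of the
    published comparison table, with each site's context planted to fit the
    Mps1 motif (strict or −2 [S/T] phospho-primed) at the printed position."""
    rng = np.random.default_rng(20250404)
    seqs: dict[str, list[str]] = {
        name: list(rng.choice(_AA, size=length))
        for name, length in _FIXTURE_LENGTHS.items()
    }
    for (protein, _res, pos, _wt, _mut, _lost, _pr) in TABLE1_ROWS:
        seq = seqs[protein]
        seq[pos - 1] = _res_for(protein, pos)
        minus2, plus1 = _FIXTURE_CONTEXTS.get((protein, pos), (None, None))
        if minus2 is not None:
            seq[pos - 3] = minus2
            seq[pos] = plus1
    # plant the real immunogen peptide so Thr-248 and Thr-252 carry their
    # published sequence context
    ndc80 = seqs["Ndc80"]
    ndc80[243:243 + len(_IMMUNOGEN)] = list(_IMMUNOGEN)
    return ProteinDb(
        sequences={name: "".join(chars) for name, chars in seqs.items()},
        source="table1_fixture",
    )


def _res_for(protein: str, pos: int) -> str:
    for (p, res, q, _wt, _mut, _lost, _pr) in TABLE1_ROWS:
        if p == protein and q == pos:
            return res
    raise KeyError((protein, pos))


def table1_fixture() -> tuple[ProteinDb, dict[str, tuple[PsmRecord, ...]], list[tuple[str, str, int]]]:
    """Deterministic PSM tables whose aggregation reproduces every wildtype and
    mutant phospho/total count pair of the published 12-site table.

    Returns ``(proteins, psm_tables, site_list)`` where ``psm_tables`` maps
    the ``wt`` and ``mut`` sample ids to PSM records and ``site_list`` holds
    ``(protein, residue, position)`` in table order.  Spc105 T107 and T111
    lie on one shared covering peptide, consistent with their identical
    per-sample totals in the printed table.
    """
    proteins = table1_proteins()
    records: dict[str, list[PsmRecord]] = {WT_SAMPLE: [], MUT_SAMPLE: []}

    def emit(sample: str, protein: str, pep_start: int, pep_end: int,
             phospho_at: Sequence[tuple[int, str]], n_total: int, n_each: Sequence[int]) -> None:
        """Emit ``n_total`` PSMs on one peptide; ``n_each[i]`` of them carry a
        phospho mod at ``phospho_at[i]`` (positions are protein coordinates)."""
        seq = proteins[protein]
        peptide = seq[pep_start - 1 : pep_end]
        assert sum(_count_occurrences(s, peptide) for s in proteins.sequences.values()) == 1
        emitted = 0
        for (pos, residue), k in zip(phospho_at, n_each):
            for _ in range(k):
                records[sample].append(
                    PsmRecord(
                        sample_id=sample,
                        protein_id=protein,
                        peptide=peptide,
                        phospho_mods=(
                            PhosphoMod(
                                peptide_pos=pos - pep_start + 1,
                                residue=residue,
                                confidence=_FIXTURE_CONFIDENCE,
                            ),
                        ),
                    )
                )
                emitted += 1
        for _ in range(n_total - emitted):
            records[sample].append(
                PsmRecord(sample_id=sample, protein_id=protein, peptide=peptide)
            )

    grouped = {("Spc105", 107), ("Spc105", 111)}
    for (protein, residue, pos, wt, mut, _lost, _pr) in TABLE1_ROWS:
        if (protein, pos) in grouped:
            continue  # handled jointly below
        start, end = max(1, pos - 7), min(len(proteins[protein]), pos + 7)
        for sample, cell in ((WT_SAMPLE, wt), (MUT_SAMPLE, mut)):
            if cell is None:
                continue  # "no PSMs"
            k, n = cell
            emit(sample, protein, start, end, [(pos, residue)], n, [k])

    # Spc105 T107/T111 share one covering peptide (identical totals per sample)
    emit(WT_SAMPLE, "Spc105", 103, 115, [(107, "T"), (111, "T")], 6, [2, 0])
    emit(MUT_SAMPLE, "Spc105", 103, 115, [(107, "T"), (111, "T")], 4, [0, 2])

    site_list = [(protein, res, pos) for (protein, res, pos, *_rest) in TABLE1_ROWS]
    return proteins, {s: tuple(r) for s, r in records.items()}, site_list
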