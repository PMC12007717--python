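"""Readers and writers for every external artifact the pipeline touches.

Covers PSM (peptide-spectrum match) export tables in delimited text, FASTA
proteomes, known-site lists, motif/threshold configuration files, and the
compiled per-site result table.

The PSM dialect is vendor-neutral: a header row, a configurable column map
(sample / protein / peptide / modifications), and a fixed modification-string
grammar ``RESIDUE<pos>(<confidence>)`` with entries joined by ``;`` — e.g.
``T5(99.1);T9(88.0)``.  Confidence is the percent-scale site-localization
score carried per phospho modification.  Rows that fail validation are
collected as :class:`RowError` values, never silently dropped.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: extended alphabet accepted in proteome sequences (X = unknown residue)
SEQUENCE_ALPHABET = AMINO_ACIDS | {"X"}
PHOSPHO_RESIDUES = frozenset("STY")
#: padding character used beyond protein termini in context windows
PAD = "-"

_MOD_ENTRY_RE = re.compile(r"^([A-Z])(\d+)\((\d+(?:\.\d+)?)\)$")


class ConfigurationError(ValueError):
    """A configuration problem (missing column, unknown sample id, bad bait...)."""


@dataclass(frozen=True)
class PhosphoMod:
    """One localized phospho modification within a peptide (1-based position)."""

    peptide_pos: int
    residue: str
    confidence: float


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match.

    ``phospho_mods`` holds the localized phospho positions (peptide
    coordinates, 1-based) with their percent-scale localization confidence.
    A record with no phospho mods is a plain (covering) PSM.
    """

    sample_id: str
    protein_id: str
    peptide: str
    phospho_mods: tuple[PhosphoMod, ...] = ()

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("empty peptide")
        bad = set(self.peptide) - AMINO_ACIDS
        if bad:
            raise ValueError(f"peptide contains non-standard residues: {sorted(bad)}")
        for mod in self.phospho_mods:
            if not 1 <= mod.peptide_pos <= len(self.peptide):
                raise ValueError(
                    f"mod position {mod.peptide_pos} outside peptide of length {len(self.peptide)}"
                )
            if mod.residue not in PHOSPHO_RESIDUES:
                raise ValueError(f"phospho residue must be S/T/Y, got {mod.residue!r}")
            if self.peptide[mod.peptide_pos - 1] != mod.residue:
                raise ValueError(
                    f"peptide position {mod.peptide_pos} is "
                    f"{self.peptide[mod.peptide_pos - 1]!r}, not {mod.residue!r}"
                )
            if not 0.0 <= mod.confidence <= 100.0:
                raise ValueError(f"confidence {mod.confidence} outside [0, 100]")

    @property
    def is_phospho(self) -> bool:
        return bool(self.phospho_mods)


@dataclass(frozen=True)
class RowError:
    """A PSM-table row that failed parsing/validation (1-based data row number)."""

    row_number: int
    message: str


@dataclass(frozen=True)
class DialectConfig:
    """Column mapping and delimiter for the delimited-text PSM dialect.

    ``delimiter=None`` auto-detects between comma and tab from the header.
    """

    sample_column: str = "sample"
    protein_column: str = "protein"
    peptide_column: str = "peptide"
    modifications_column: str = "modifications"
    delimiter: str | None = None


@dataclass(frozen=True)
class ProteinDb:
    """Accession -> sequence map with a source label."""

    sequences: Mapping[str, str]
    source: str = ""

    def __post_init__(self) -> None:
        for acc, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for {acc}")
            bad = set(seq) - SEQUENCE_ALPHABET
            if bad:
                raise ValueError(f"{acc}: non-standard residues {sorted(bad)}")

    def __contains__(self, accession: str) -> bool:
        return accession in self.sequences

    def __getitem__(self, accession: str) -> str:
        return self.sequences[accession]

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class KnownSiteList:
    """Previously reported phospho-sites: (protein_id, 1-based position, residue)."""

    sites: frozenset[tuple[str, int, str]] = frozenset()

    def __contains__(self, site: tuple[str, int, str]) -> bool:
        return site in self.sites

    def __len__(self) -> int:
        return len(self.sites)


def parse_modifications(text: str) -> tuple[PhosphoMod, ...]:
    """Parse a modification string like ``"T5(99.1);T9(88.0)"``.

    An empty or whitespace-only string means no phospho modifications.
    Raises :class:`ValueError` on any malformed entry.
    """
    text = text.strip()
    if not text:
        return ()
    mods = []
    for entry in text.split(";"):
        entry = entry.strip()
        m = _MOD_ENTRY_RE.match(entry)
        if m is None:
            raise ValueError(f"malformed modification entry {entry!r}")
        residue, pos, conf = m.group(1), int(m.group(2)), float(m.group(3))
        mods.append(PhosphoMod(peptide_pos=pos, residue=residue, confidence=conf))
    return tuple(mods)


def format_modifications(mods: Iterable[PhosphoMod]) -> str:
    return ";".join(f"{m.residue}{m.peptide_pos}({m.confidence:g})" for m in mods)


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def read_psm_table(
    path: str | Path, dialect: DialectConfig | None = None
) -> tuple[list[PsmRecord], list[RowError]]:
    """Read a delimited PSM table; returns ``(records, row_errors)``.

    Parsing is total and order-preserving: every data row becomes either a
    record or a :class:`RowError`, and ``len(records) + len(errors)`` equals
    the number of data rows.  A missing required column raises
    :class:`ConfigurationError` naming the column.
    """
    dialect = dialect or DialectConfig()
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first:
            raise ConfigurationError(f"{path}: empty file, no header row")
        delim = dialect.delimiter or _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        required = {
            "sample": dialect.sample_column,
            "protein": dialect.protein_column,
            "peptide": dialect.peptide_column,
            "modifications": dialect.modifications_column,
        }
        for role, col in required.items():
            if col not in header:
                raise ConfigurationError(
                    f"{path}: missing required {role} column {col!r} (header: {header})"
                )
        records: list[PsmRecord] = []
        errors: list[RowError] = []
        for row_number, row in enumerate(reader, start=1):
            try:
                mods = parse_modifications(row[dialect.modifications_column] or "")
                rec = PsmRecord(
                    sample_id=(row[dialect.sample_column] or "").strip(),
                    protein_id=(row[dialect.protein_column] or "").strip(),
                    peptide=(row[dialect.peptide_column] or "").strip(),
                    phospho_mods=mods,
                )
                if not rec.sample_id or not rec.protein_id:
                    raise ValueError("empty sample or protein field")
            except ValueError as exc:
                errors.append(RowError(row_number=row_number, message=str(exc)))
            else:
                records.append(rec)
    return records, errors


def write_psm_table(
    records: Sequence[PsmRecord], path: str | Path, dialect: DialectConfig | None = None
) -> None:
    dialect = dialect or DialectConfig(delimiter="\t")
    delim = dialect.delimiter or "\t"
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(
            [
                dialect.sample_column,
                dialect.protein_column,
                dialect.peptide_column,
                dialect.modifications_column,
            ]
        )
        for rec in records:
            writer.writerow(
                [rec.sample_id, rec.protein_id, rec.peptide, format_modifications(rec.phospho_mods)]
            )


def read_fasta(path: str | Path) -> ProteinDb:
    """Read a FASTA proteome; accession is the first whitespace token of each header.

    Duplicate accessions and empty sequences are hard errors.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        acc = record.id
        seq = str(record.seq).upper()
        if acc in sequences:
            raise ValueError(f"{path}: duplicate accession {acc!r}")
        if not seq:
            raise ValueError(f"{path}: empty sequence for {acc!r}")
        sequences[acc] = seq
    return ProteinDb(sequences=sequences, source=str(path))


def write_fasta(db: ProteinDb, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="") for acc, seq in db.sequences.items()
    ]
    with Path(path).open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_known_sites(path: str | Path) -> KnownSiteList:
    """Read a TSV of previously reported sites (columns protein_id, position, residue)."""
    sites = set()
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for col in ("protein_id", "position", "residue"):
            if col not in (reader.fieldnames or []):
                raise ConfigurationError(f"{path}: known-sites file missing column {col!r}")
        for row in reader:
            sites.add((row["protein_id"], int(row["position"]), row["residue"]))
    return KnownSiteList(sites=frozenset(sites))


def write_known_sites(known: KnownSiteList, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "position", "residue"])
        for protein_id, pos, residue in sorted(known.sites):
            writer.writerow([protein_id, pos, residue])


# --- compiled site table -----------------------------------------------------

_FIXED_COLUMNS = ["protein_id", "position", "residue", "context"]
_TRAILING_COLUMNS = ["matched_motifs", "category", "mps1_primed", "previously_reported"]


def write_site_table(sites, assignments, path, known=None) -> None:
    """Write the compiled per-site result table as TSV.

    ``sites`` and ``assignments`` must be aligned one-to-one; ``known`` is an
    optional aligned sequence of previously-reported flags.  Output columns:
    protein/position/residue/context, then per-sample
    ``<sample>:phospho`` / ``<sample>:total`` / ``<sample>:confidence``
    triplets (samples in sorted order), then matched motifs, category,
    priming flag and known/novel flag.  Row order is (protein, position);
    re-running on identical input produces a byte-identical file.
    """
    if len(sites) != len(assignments):
        raise ValueError("sites and assignments must align one-to-one")
    if known is None:
        known = [False] * len(sites)
    if len(known) != len(sites):
        raise ValueError("known flags must align with sites")

    samples = sorted({s for site in sites for s in site.evidence})
    header = list(_FIXED_COLUMNS)
    for s in samples:
        header += [f"{s}:phospho", f"{s}:total", f"{s}:confidence"]
    header += _TRAILING_COLUMNS

    order = sorted(
        range(len(sites)), key=lambda i: (sites[i].protein_id, sites[i].protein_pos)
    )
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for i in order:
            site, assignment = sites[i], assignments[i]
            row = [site.protein_id, site.protein_pos, site.residue, site.context]
            for s in samples:
                ev = site.evidence.get(s)
                if ev is None:
                    row += [0, 0, 0.0]
                else:
                    row += [ev.phospho_psms, ev.total_psms, ev.max_confidence]
            row += [
                ";".join(assignment.matched_motifs),
                assignment.category,
                int(assignment.mps1_primed),
                int(known[i]),
            ]
            writer.writerow(row)


def read_site_table(path):
    """Re-read a table written by :func:`write_site_table`.

    Returns ``(sites, assignments, known_flags)``; the numeric evidence fields
    round-trip exactly.
    """
    from .extract import PhosphoSite, SampleEvidence
    from .motifs import SiteAssignment

    sites, assignments, known = [], [], []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        samples = sorted(
            {c.split(":", 1)[0] for c in header if c.endswith(":phospho")}
        )
        for row in reader:
            evidence = {}
            for s in samples:
                ev = SampleEvidence(
                    phospho_psms=int(row[f"{s}:phospho"]),
                    total_psms=int(row[f"{s}:total"]),
                    max_confidence=float(row[f"{s}:confidence"]),
                )
                if ev.total_psms or ev.phospho_psms or ev.max_confidence:
                    evidence[s] = ev
            sites.append(
                PhosphoSite(
                    protein_id=row["protein_id"],
                    protein_pos=int(row["position"]),
                    residue=row["residue"],
                    context=row["context"],
                    evidence=evidence,
                )
            )
            matched = tuple(m for m in row["matched_motifs"].split(";") if m)
            assignments.append(
                SiteAssignment(
                    matched_motifs=matched,
                    category=row["category"],
                    mps1_primed=bool(int(row["mps1_primed"])),
                )
            )
            known.append(bool(int(row["previously_reported"])))
    return sites, assignments, known


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}
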