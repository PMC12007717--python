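"""End-to-end pipeline orchestration with manifest-based auditability.

``run_pipeline`` wires the stages together — read, aggregate, filter,
motif-assign, novelty-annotate, differential, composition — writes every
result table, and records a run manifest (config snapshot, input digests,
per-stage record counts) so that every filtering decision is auditable and
identical inputs + config yield identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .composition import psm_counts, relative_psms, write_composition
from .differential import differential_table, tally_statuses, write_differential_table
from .extract import (
    DEFAULT_CONTEXT_HALFWIDTH,
    FilterThresholds,
    aggregate_sites,
    annotate_known,
    filter_sites,
)
from .io import (
    ConfigurationError,
    DialectConfig,
    KnownSiteList,
    read_fasta,
    read_known_sites,
    read_psm_table,
    write_site_table,
)
from .motifs import (
    DEFAULT_PRECEDENCE,
    assign_category,
    default_motifs,
    motifs_from_config,
    tally_categories,
)

logger = logging.getLogger("kinsites")


class PipelineError(RuntimeError):
    """A stage failure; the message is prefixed with the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _dialect_from_config(config: Mapping) -> DialectConfig:
    io_cfg = config.get("io", {}) or {}
    columns = io_cfg.get("columns", {}) or {}
    return DialectConfig(
        sample_column=columns.get("sample", "sample"),
        protein_column=columns.get("protein", "protein"),
        peptide_column=columns.get("peptide", "peptide"),
        modifications_column=columns.get("modifications", "modifications"),
        delimiter=io_cfg.get("delimiter"),
    )


def summary_report(assignments, differentials, sites=None, known=None) -> dict:
    """Per-category, per-protein, novelty and differential-status summaries.

    ``sites`` and ``known`` (aligned with ``assignments``) enable the
    per-protein and novel-per-category breakdowns; without them those
    sections are empty.  All counts are plain tallies of the input tables,
    so section totals always equal the corresponding table lengths.
    """
    summary: dict = {
        "category_counts": tally_categories(assignments),
        "per_protein_sites": {},
        "novel_per_category": {},
        "differential_status_counts": tally_statuses(differentials or []),
    }
    if sites is not None:
        per_protein: dict[str, int] = {}
        for site in sites:
            per_protein[site.protein_id] = per_protein.get(site.protein_id, 0) + 1
        summary["per_protein_sites"] = dict(sorted(per_protein.items()))
    if known is not None:
        novel: dict[str, int] = {}
        for a, k in zip(assignments, known):
            if not k:
                novel[a.category] = novel.get(a.category, 0) + 1
        summary["novel_per_category"] = dict(sorted(novel.items()))
    return summary


def write_summary(summary: Mapping, path) -> None:
    import csv

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["section", "key", "count"])
        for section in sorted(summary):
            for key, count in sorted(summary[section].items()):
                writer.writerow([section, key, count])


def run_pipeline(config: Mapping, outdir: str | Path | None = None) -> dict:
    """Run every configured stage and write all outputs under ``outdir``.

    ``config`` sections: ``inputs`` (psm_tables, fasta, known_sites),
    ``io`` (column map, delimiter), ``thresholds``, ``motifs``/``precedence``,
    ``samples`` (wt, mut, bait), ``context_halfwidth``, ``output_dir``.
    Returns the run manifest.  Any stage error aborts with a stage-tagged
    :class:`PipelineError` and removes partial outputs.
    """
    outdir = Path(outdir if outdir is not None else config.get("output_dir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def out(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    try:
        return _run(config, outdir, out)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run(config: Mapping, outdir: Path, out) -> dict:
    inputs = config.get("inputs", {}) or {}
    manifest: dict = {
        "tool": "kinsites",
        "version": __version__,
        "config": json.loads(json.dumps(config, sort_keys=True, default=str)),
        "inputs": {},
        "counts": {},
    }

    # --- read ---------------------------------------------------------------
    stage = "read"
    try:
        fasta_path = inputs["fasta"]
    except KeyError:
        raise PipelineError(stage, "config inputs.fasta is required")
    psm_paths = inputs.get("psm_tables") or []
    if not psm_paths:
        raise PipelineError(stage, "config inputs.psm_tables is required")
    try:
        proteins = read_fasta(fasta_path)
        manifest["inputs"][str(fasta_path)] = _sha256(Path(fasta_path))
        dialect = _dialect_from_config(config)
        records, row_errors = [], []
        for path in psm_paths:
            recs, errs = read_psm_table(path, dialect)
            records.extend(recs)
            row_errors.extend((str(path), e) for e in errs)
            manifest["inputs"][str(path)] = _sha256(Path(path))
        known = KnownSiteList()
        if inputs.get("known_sites"):
            known = read_known_sites(inputs["known_sites"])
            manifest["inputs"][str(inputs["known_sites"])] = _sha256(Path(inputs["known_sites"]))
    except (OSError, ValueError) as exc:
        raise PipelineError(stage, str(exc))
    logger.info("[%s] %d PSM rows read, %d row errors", stage, len(records), len(row_errors))
    manifest["counts"]["psm_rows_read"] = len(records) + len(row_errors)
    manifest["counts"]["psm_rows_parsed"] = len(records)
    manifest["counts"]["psm_row_errors"] = len(row_errors)
    if row_errors:
        import csv

        with out("row_errors.tsv").open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["file", "row_number", "message"])
            for path, err in row_errors:
                writer.writerow([path, err.row_number, err.message])

    # --- aggregate ----------------------------------------------------------
    stage = "aggregate"
    halfwidth = int(config.get("context_halfwidth", DEFAULT_CONTEXT_HALFWIDTH))
    try:
        sites, skipped = aggregate_sites(records, proteins, halfwidth)
    except KeyError as exc:
        raise PipelineError(stage, str(exc))
    manifest["counts"]["psms_unmapped_or_ambiguous"] = len(skipped)
    manifest["counts"]["sites_before_filter"] = len(sites)
    if skipped:
        import csv

        with out("skipped_psms.tsv").open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["sample", "protein", "peptide", "reason", "n_matches"])
            for s in skipped:
                writer.writerow(
                    [s.record.sample_id, s.record.protein_id, s.record.peptide, s.reason, s.n_matches]
                )
    logger.info("[%s] %d sites, %d PSMs skipped", stage, len(sites), len(skipped))

    # --- filter -------------------------------------------------------------
    stage = "filter"
    t_cfg = config.get("thresholds", {}) or {}
    try:
        thresholds = FilterThresholds(
            min_psms=int(t_cfg.get("min_psms", 2)),
            min_confidence=float(t_cfg.get("min_confidence", 75.0)),
        )
    except ValueError as exc:
        raise PipelineError(stage, str(exc))
    kept = filter_sites(sites, thresholds)
    manifest["counts"]["sites_after_filter"] = len(kept)
    manifest["counts"]["sites_removed_by_filter"] = len(sites) - len(kept)
    manifest["thresholds"] = {
        "min_psms": thresholds.min_psms,
        "min_confidence": thresholds.min_confidence,
    }
    logger.info("[%s] %d/%d sites retained", stage, len(kept), len(sites))

    # --- assign -------------------------------------------------------------
    stage = "assign"
    try:
        motifs = (
            motifs_from_config(config["motifs"]) if config.get("motifs") else default_motifs()
        )
        precedence = tuple(config.get("precedence", DEFAULT_PRECEDENCE))
        assignments = [assign_category(s.context, motifs, precedence) for s in kept]
    except (KeyError, ValueError) as exc:
        raise PipelineError(stage, str(exc))
    known_flags = annotate_known(kept, known)
    write_site_table(kept, assignments, out("site_table.tsv"), known=known_flags)
    tally = tally_categories(assignments)
    manifest["counts"]["category_tally"] = tally
    manifest["counts"]["novel_sites"] = sum(1 for k in known_flags if not k)
    logger.info("[%s] category tally: %s", stage, tally)

    # --- differential -------------------------------------------------------
    stage = "differential"
    samples_cfg = config.get("samples", {}) or {}
    differentials = []
    if samples_cfg.get("wt") and samples_cfg.get("mut"):
        try:
            differentials = differential_table(
                kept,
                samples_cfg["wt"],
                samples_cfg["mut"],
                min_wt_total=int(samples_cfg.get("min_wt_total", thresholds.min_psms)),
                with_p_values=bool(config.get("with_p_values", False)),
            )
        except (ConfigurationError, ValueError) as exc:
            raise PipelineError(stage, str(exc))
        write_differential_table(differentials, out("differential.tsv"))
        manifest["counts"]["differential_status_tally"] = tally_statuses(differentials)
        logger.info("[%s] %d sites compared", stage, len(differentials))

    # --- composition --------------------------------------------------------
    stage = "composition"
    if samples_cfg.get("bait"):
        bait = samples_cfg["bait"]
        sample_ids = sorted({r.sample_id for r in records})
        comp_counts = {}
        for sample in sample_ids:
            counts = psm_counts(records, sample)
            try:
                comp = relative_psms(counts, bait)
            except ConfigurationError as exc:
                raise PipelineError(stage, str(exc))
            write_composition(comp, out(f"composition_{sample}.tsv"))
            comp_counts[sample] = len(comp.rows)
        manifest["counts"]["composition_proteins"] = comp_counts

    # --- summary ------------------------------------------------------------
    summary = summary_report(assignments, differentials, sites=kept, known=known_flags)
    write_summary(summary, out("summary.tsv"))
    manifest_path = out("manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
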