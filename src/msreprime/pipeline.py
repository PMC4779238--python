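"""End-to-end orchestration of the primer-design workflow.

Steps per target: extend by flanks -> extract the design sequence ->
enumerate candidate primers and pairs -> predict restriction cut sites
(MSRE mode) -> annotate with SNPs/CpG islands/repeats/genes -> assign
quality levels and apply the MSRE validation filter -> emit the summary
table, per-target GTF tracks, and browser links.

Targets are processed independently; with ``workers > 1`` the per-target
design work runs in a process pool, and results are assembled in input
target order, so output bytes are identical for any worker count.
"""

from __future__ import annotations

import logging
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import annotator, design_core, genome_io, msre_enzymes, report, selector
from . import target_prep

__all__ = ["RunConfig", "TargetResult", "RunResult", "run_pipeline"]

logger = logging.getLogger("msreprime")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``mode`` is "msre" (cut-site prediction + MSRE filter available) or
    "genomic" (cut-site columns all zero, uniform output schema).
    """

    genome_fasta: str | Path
    target_bed: str | Path
    snp_bed: str | Path
    cpg_bed: str | Path
    repeat_bed: str | Path
    gene_bed: str | Path
    out_dir: str | Path
    mode: str = "msre"
    parameter_file: Optional[str | Path] = None
    enzyme_file: Optional[str | Path] = None
    quality_matrix: Optional[str | Path] = None
    flank_up: int = 0
    flank_down: int = 0
    n_return: int = 5
    proximity_bp: int = 50
    apply_msre_filter: bool = False
    workers: int = 1
    assembly: str = "hg19"
    fail_fast: bool = False

    def validate(self) -> None:
        if self.mode not in ("msre", "genomic"):
            raise ConfigError(f"mode must be 'msre' or 'genomic', got {self.mode!r}")
        if self.mode == "msre" and self.enzyme_file is None:
            raise ConfigError("MSRE mode requires an enzyme list file")
        required = {
            "genome FASTA": self.genome_fasta,
            "target BED": self.target_bed,
            "SNP BED": self.snp_bed,
            "CpG island BED": self.cpg_bed,
            "repeat BED": self.repeat_bed,
            "gene BED": self.gene_bed,
        }
        if self.enzyme_file is not None:
            required["enzyme list"] = self.enzyme_file
        if self.parameter_file is not None:
            required["parameter file"] = self.parameter_file
        if self.quality_matrix is not None:
            required["quality matrix"] = self.quality_matrix
        for what, path in required.items():
            if not Path(path).exists():
                raise ConfigError(f"{what} not found: {path}")
        if self.workers < 1:
            raise ConfigError("workers must be >= 1")


@dataclass
class TargetResult:
    """Per-target outcome: selected pairs with audit data, or an error."""

    target_id: str
    annotated: list[annotator.AnnotatedPair] = field(default_factory=list)
    selection: Optional[selector.SelectionResult] = None
    msre_filter: list[tuple[bool, list[str]]] = field(default_factory=list)
    rows: list[dict] = field(default_factory=list)
    error: Optional[str] = None
    elapsed_s: float = 0.0


@dataclass
class RunResult:
    targets: list[TargetResult]
    summary_tsv: Optional[Path] = None
    summary_html: Optional[Path] = None
    gtf_paths: dict[str, Path] = field(default_factory=dict)
    n_failed: int = 0


def _design_one_target(payload) -> TargetResult:
    """Design, scan, annotate, and select for one target (worker function)."""
    (target_seq, subsets, params, enzymes, rules, n_return,
     proximity_bp, apply_filter, assembly) = payload
    t0 = time.perf_counter()
    target_id = target_seq.design_range.target.target_id
    result = TargetResult(target_id=target_id)
    try:
        candidates = design_core.candidate_primers(target_seq.sequence, params)
        pairs = design_core.enumerate_pairs(
            candidates, params, n_return,
            target_sequence=target_seq.sequence,
            pair_id_prefix=target_id,
        )
        for pair in pairs:
            cut = msre_enzymes.count_cut_sites(pair, target_seq.sequence, enzymes)
            apair = annotator.annotate_pair(
                pair, target_seq.design_range, subsets, cut
            )
            result.annotated.append(apair)

        result.selection = selector.assign_quality_levels(
            result.annotated, rules, assembly=assembly
        )
        chosen = result.selection.selected
        level_of = {
            id(rec.pair): rec.quality_level for rec in result.selection.records
        }
        kept = []
        for rec in chosen:
            passed, reasons = selector.msre_validation_filter(
                rec.pair, proximity_bp
            )
            result.msre_filter.append((passed, reasons))
            if passed or not apply_filter:
                kept.append(rec.pair)
        result.rows = [
            report.summary_row(ap, assembly=assembly,
                               quality_level=level_of.get(id(ap)))
            for ap in kept
        ]
    except Exception as exc:  # per-target isolation: record, don't raise
        result.error = f"{type(exc).__name__}: {exc}"
    result.elapsed_s = time.perf_counter() - t0
    return result


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full workflow; returns per-target results and output paths.

    A hard error in one target aborts that target with a logged reason and
    the run continues (unless ``fail_fast``); the caller can inspect
    ``RunResult.n_failed``.
    """
    config.validate()
    genome = genome_io.read_fasta(config.genome_fasta)
    targets = genome_io.read_target_bed(config.target_bed, genome)
    tracks = {
        "snp": genome_io.read_annotation_bed(config.snp_bed, "snp"),
        "cpg_island": genome_io.read_annotation_bed(config.cpg_bed, "cpg_island"),
        "repeat": genome_io.read_annotation_bed(config.repeat_bed, "repeat"),
        "gene": genome_io.read_annotation_bed(config.gene_bed, "gene"),
    }
    params = (
        design_core.parse_parameter_file(config.parameter_file)
        if config.parameter_file else design_core.DesignParameters()
    )
    enzymes: list[msre_enzymes.Enzyme] = []
    if config.mode == "msre" and config.enzyme_file:
        enzymes = msre_enzymes.parse_enzyme_list(config.enzyme_file)
    rules: list[selector.QualityRule] = []
    if config.quality_matrix:
        rules = selector.parse_quality_matrix(config.quality_matrix)

    lengths = genome.lengths
    design_ranges = [
        target_prep.extend_region(t, config.flank_up, config.flank_down,
                                  lengths[t.chrom])
        for t in targets
    ]
    payloads = []
    for dr in design_ranges:
        target_seq = target_prep.extract_sequence(genome, dr)
        subsets = {
            kind: target_prep.subset_annotations(aset, [dr])
            for kind, aset in tracks.items()
        }
        payloads.append((
            target_seq, subsets, params, enzymes, rules, config.n_return,
            config.proximity_bp, config.apply_msre_filter, config.assembly,
        ))

    if config.workers > 1 and len(payloads) > 1:
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            results = list(pool.map(_design_one_target, payloads, chunksize=8))
    else:
        results = [_design_one_target(p) for p in payloads]

    out = RunResult(targets=results)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_rows: list[dict] = []
    gtf_dir = out_dir / "tracks"
    for res in results:
        if res.error is not None:
            out.n_failed += 1
            logger.error("target %s failed: %s", res.target_id, res.error)
            if config.fail_fast:
                raise RuntimeError(f"target {res.target_id} failed: {res.error}")
            continue
        logger.info(
            "target %s: %d pairs annotated, %d rows emitted (%.2fs)",
            res.target_id, len(res.annotated), len(res.rows), res.elapsed_s,
        )
        all_rows.extend(res.rows)
        if res.rows:
            gtf_dir.mkdir(exist_ok=True)
            emitted_ids = {row["pair_id"] for row in res.rows}
            pairs_for_track = [
                ap for ap in res.annotated if ap.pair.pair_id in emitted_ids
            ]
            out.gtf_paths[res.target_id] = report.write_gtf_track(
                pairs_for_track, gtf_dir / f"{res.target_id}.gtf"
            )
    out.summary_tsv, out.summary_html = report.write_summary(all_rows, out_dir)
    return out
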