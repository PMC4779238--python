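"""Design-range preparation: flank extension, sequence extraction, and
annotation subsetting to the design ranges.

Subsetting replaces the external interval tool of the original workflow
with an in-house interval-tree overlap query; intervals are half-open, so
two intervals overlap iff max(starts) < min(ends) — a boundary touch is not
an overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .genome_io import AnnotationSet, GenomeIOError, ReferenceGenome, TargetRegion

__all__ = [
    "DesignRange",
    "TargetSequence",
    "extend_region",
    "extract_sequence",
    "subset_annotations",
]

logger = logging.getLogger("msreprime")


@dataclass(frozen=True)
class DesignRange:
    """A target extended by optional flanks, clamped to the chromosome."""

    target: TargetRegion
    flank_up: int
    flank_down: int
    range_start: int
    range_end: int

    @property
    def chrom(self) -> str:
        return self.target.chrom

    @property
    def length(self) -> int:
        return self.range_end - self.range_start


@dataclass(frozen=True)
class TargetSequence:
    """The extracted design sequence with the original target's offset in it."""

    design_range: DesignRange
    sequence: str

    @property
    def target_offset(self) -> int:
        return self.design_range.target.start - self.design_range.range_start

    def __len__(self) -> int:
        return len(self.sequence)


def extend_region(
    target: TargetRegion,
    flank_up: int,
    flank_down: int,
    chrom_length: int,
) -> DesignRange:
    """Extend a target by flanks, silently clamping to [0, chrom_length)."""
    if flank_up < 0 or flank_down < 0:
        raise ValueError("flanks must be non-negative")
    start = max(0, target.start - flank_up)
    end = min(chrom_length, target.end + flank_down)
    if start != target.start - flank_up or end != target.end + flank_down:
        logger.debug(
            "target %s: design range clamped to [%d, %d)",
            target.target_id, start, end,
        )
    return DesignRange(target, flank_up, flank_down, start, end)


def extract_sequence(genome: ReferenceGenome, design_range: DesignRange) -> TargetSequence:
    """Extract the design-range substring from the reference genome."""
    chrom = design_range.chrom
    if chrom not in genome:
        raise GenomeIOError(f"chromosome {chrom!r} not in reference genome")
    seq = genome.sequences[chrom][design_range.range_start:design_range.range_end]
    return TargetSequence(design_range, seq)


def subset_annotations(
    annotation_set: AnnotationSet,
    design_ranges: Sequence[DesignRange],
) -> AnnotationSet:
    """Keep exactly the records overlapping >=1 bp with >=1 design range."""
    trees: dict[str, IntervalTree] = {}
    for dr in design_ranges:
        trees.setdefault(dr.chrom, IntervalTree()).addi(
            dr.range_start, dr.range_end
        )
    kept = [
        rec
        for rec in annotation_set.records
        if rec.chrom in trees and trees[rec.chrom].overlaps(rec.start, rec.end)
    ]
    return AnnotationSet(annotation_set.kind, kept)
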