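"""Lift primer pairs to genomic coordinates and annotate them with SNPs,
CpG islands, repeats, and the nearest flanking genes.

Upstream/downstream are genomic left/right of the amplicon regardless of
gene strand (strand is reported alongside); a gene overlapping the amplicon
is reported on both sides with distance 0. Distances are measured from the
amplicon's outer boundaries — the 5' ends of the two primers, which are the
amplicon itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .design_core import PrimerPair
from .genome_io import AnnotationRecord, AnnotationSet
from .msre_enzymes import CutSiteSummary
from .target_prep import DesignRange

__all__ = ["GenomicIntervals", "AnnotatedPair", "to_genomic", "annotate_pair",
           "nearest_genes"]


@dataclass(frozen=True)
class GenomicIntervals:
    """Genomic (chrom, 0-based half-open) intervals of one primer pair."""

    chrom: str
    amplicon: tuple[int, int]
    forward: tuple[int, int]
    reverse: tuple[int, int]
    oligo: Optional[tuple[int, int]] = None


@dataclass
class AnnotatedPair:
    """A primer pair with genomic coordinates and full annotation."""

    pair: PrimerPair
    design_range: DesignRange
    genomic: GenomicIntervals
    n_snps_fwd: int = 0
    n_snps_rev: int = 0
    n_snps_amplicon: int = 0
    n_snps_oligo: int = 0
    n_cpg_islands: int = 0
    n_repeats: int = 0
    repeat_in_primer: bool = False
    upstream_gene: Optional[str] = None
    upstream_strand: Optional[str] = None
    dist_upstream: Optional[int] = None
    downstream_gene: Optional[str] = None
    downstream_strand: Optional[str] = None
    dist_downstream: Optional[int] = None
    cut_summary: CutSiteSummary = None
    target_distance: int = 0  # bp from target midpoint to amplicon; 0 if inside

    def __post_init__(self) -> None:
        if self.cut_summary is None:
            self.cut_summary = CutSiteSummary()

    @property
    def target_id(self) -> str:
        return self.design_range.target.target_id


def to_genomic(pair: PrimerPair, design_range: DesignRange) -> GenomicIntervals:
    """Translate a pair's sequence-space coordinates into genomic intervals."""
    off = design_range.range_start
    f_lo, f_hi = pair.forward.footprint
    r_lo, r_hi = pair.reverse.footprint
    oligo = None
    if pair.oligo is not None:
        o_lo, o_hi = pair.oligo.footprint
        oligo = (off + o_lo, off + o_hi)
    return GenomicIntervals(
        chrom=design_range.chrom,
        amplicon=(off + pair.amplicon_start, off + pair.amplicon_end),
        forward=(off + f_lo, off + f_hi),
        reverse=(off + r_lo, off + r_hi),
        oligo=oligo,
    )


def _count_overlaps(records, chrom: str, start: int, end: int) -> int:
    return sum(
        1 for r in records
        if r.chrom == chrom and max(r.start, start) < min(r.end, end)
    )


def nearest_genes(
    chrom: str,
    amplicon: tuple[int, int],
    gene_set: AnnotationSet,
) -> tuple[Optional[AnnotationRecord], Optional[int],
           Optional[AnnotationRecord], Optional[int]]:
    """Nearest genes left (upstream) and right (downstream) of the amplicon.

    Upstream is the gene with the greatest end <= amplicon start (distance =
    amplicon_start − gene_end); downstream the least start >= amplicon end.
    An overlapping gene is returned on both sides with distance 0. Missing
    genes yield (None, None) on that side.
    """
    a_start, a_end = amplicon
    genes = [g for g in gene_set.records if g.chrom == chrom]
    up: Optional[AnnotationRecord] = None
    down: Optional[AnnotationRecord] = None
    up_dist: Optional[int] = None
    down_dist: Optional[int] = None
    for g in genes:
        if max(g.start, a_start) < min(g.end, a_end):  # overlap
            return g, 0, g, 0
    for g in genes:
        if g.end <= a_start:
            d = a_start - g.end
            if up_dist is None or d < up_dist or (d == up_dist and g.end > up.end):
                up, up_dist = g, d
        if g.start >= a_end:
            d = g.start - a_end
            if down_dist is None or d < down_dist:
                down, down_dist = g, d
    return up, up_dist, down, down_dist


def annotate_pair(
    pair: PrimerPair,
    design_range: DesignRange,
    annotation_sets: Mapping[str, AnnotationSet],
    cut_summary: Optional[CutSiteSummary] = None,
) -> AnnotatedPair:
    """Annotate one primer pair against (already subset) annotation tracks."""
    genomic = to_genomic(pair, design_range)
    chrom = genomic.chrom
    snps = annotation_sets["snp"].records
    cpgs = annotation_sets["cpg_island"].records
    repeats = annotation_sets["repeat"].records

    out = AnnotatedPair(
        pair=pair, design_range=design_range, genomic=genomic,
        cut_summary=cut_summary,
    )
    out.n_snps_fwd = _count_overlaps(snps, chrom, *genomic.forward)
    out.n_snps_rev = _count_overlaps(snps, chrom, *genomic.reverse)
    out.n_snps_amplicon = _count_overlaps(snps, chrom, *genomic.amplicon)
    if genomic.oligo is not None:
        out.n_snps_oligo = _count_overlaps(snps, chrom, *genomic.oligo)
    out.n_cpg_islands = _count_overlaps(cpgs, chrom, *genomic.amplicon)
    out.n_repeats = _count_overlaps(repeats, chrom, *genomic.amplicon)
    out.repeat_in_primer = bool(
        _count_overlaps(repeats, chrom, *genomic.forward)
        or _count_overlaps(repeats, chrom, *genomic.reverse)
    )

    up, d_up, down, d_down = nearest_genes(chrom, genomic.amplicon,
                                           annotation_sets["gene"])
    if up is not None:
        out.upstream_gene, out.upstream_strand = up.name, up.strand
        out.dist_upstream = d_up
    if down is not None:
        out.downstream_gene, out.downstream_strand = down.name, down.strand
        out.dist_downstream = d_down

    # signed-distance-style proximity of the original target midpoint
    mid = design_range.target.midpoint
    a_start, a_end = genomic.amplicon
    if a_start <= mid < a_end:
        out.target_distance = 0
    elif mid < a_start:
        out.target_distance = a_start - mid
    else:
        out.target_distance = mid - (a_end - 1)
    return out
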