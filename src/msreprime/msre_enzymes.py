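"""Type-II methylation-sensitive restriction enzymes: parsing, site scanning,
cut-site counting per assay region, and genome-wide CpG coverage statistics.

Recognition motifs use IUPAC degenerate codes and caret notation for the
cleavage position (e.g. ``C^CGG`` cleaves after the first C). Degenerate
codes are handled as base *sets*, so the reverse complement of a degenerate
motif is computed symbolically (complement of M={A,C} is K={G,T}).

A scan reports every physical recognition site: all matches of the motif on
the + strand plus all matches of its reverse complement, the latter reported
as − strand. Palindromic motifs (equal to their own reverse complement after
IUPAC expansion) yield each physical site exactly once, as + strand.
Overlapping and self-overlapping matches are all counted — each one is a
physical site the enzyme can cleave.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Enzyme",
    "CutSite",
    "CutSiteSummary",
    "IUPAC_SETS",
    "BUILTIN_CATALOG",
    "parse_recognition",
    "reverse_complement_iupac",
    "parse_enzyme_list",
    "load_catalog_tsv",
    "scan_sites",
    "concrete_site",
    "count_cut_sites",
    "cpg_coverage_stats",
]

IUPAC_SETS: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "M": frozenset("AC"),
    "K": frozenset("GT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_BASE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# symbolic complement for every IUPAC code: complement of the base set
_SET_TO_CODE = {v: k for k, v in IUPAC_SETS.items()}
IUPAC_COMPLEMENT = {
    code: _SET_TO_CODE[frozenset(_BASE_COMPLEMENT[b] for b in bases)]
    for code, bases in IUPAC_SETS.items()
}


class EnzymeError(ValueError):
    """Unknown enzyme or malformed recognition motif."""


@dataclass(frozen=True)
class Enzyme:
    """A type-II restriction enzyme with a single cleavage position.

    ``recognition`` is the IUPAC motif without the caret; ``cut_offset`` is
    the 0-based position of the caret counted from the motif start.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise EnzymeError(f"{self.name}: empty recognition sequence")
        bad = set(self.recognition) - set(IUPAC_SETS)
        if bad:
            raise EnzymeError(
                f"{self.name}: invalid IUPAC codes {sorted(bad)} in "
                f"{self.recognition!r}"
            )
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise EnzymeError(
                f"{self.name}: cut offset {self.cut_offset} outside motif"
            )

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == reverse_complement_iupac(self.recognition)


@dataclass(frozen=True)
class CutSite:
    """One recognition-site match on a scanned sequence.

    ``position`` is the 0-based start of the match; ``cut_position`` is the
    gap index on the + sequence where the + strand is cleaved (for − strand
    matches, where the enzyme bound on the bottom strand cleaves the top).
    """

    position: int
    strand: str
    cut_position: int
    enzyme: str


@dataclass
class CutSiteSummary:
    """Cut-site counts for one primer pair's regions, with per-enzyme detail."""

    n_fwd: int = 0
    n_rev: int = 0
    n_oligo: int = 0
    n_amplicon: int = 0
    per_enzyme: dict[str, dict[str, int]] = None  # enzyme -> region -> count
    amplicon_sites: list[CutSite] = None  # positions relative to amplicon start

    def __post_init__(self) -> None:
        if self.per_enzyme is None:
            self.per_enzyme = {}
        if self.amplicon_sites is None:
            self.amplicon_sites = []


def reverse_complement_iupac(motif: str) -> str:
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(motif))


def parse_recognition(caret_motif: str) -> tuple[str, int]:
    """Split caret notation into (motif, cut_offset): ``"C^CGG" -> ("CCGG", 1)``."""
    if caret_motif.count("^") != 1:
        raise EnzymeError(
            f"recognition {caret_motif!r} must contain exactly one '^'"
        )
    offset = caret_motif.index("^")
    return caret_motif.replace("^", ""), offset


def _make_catalog(entries: Sequence[tuple[str, str]]) -> dict[str, Enzyme]:
    catalog = {}
    for name, caret_motif in entries:
        motif, offset = parse_recognition(caret_motif)
        catalog[name.lower()] = Enzyme(name, motif, offset)
    return catalog


# Built-in MSRE catalog: CpG-containing type-II enzymes commonly used for
# methylation-sensitive digestion, caret marking the cleavage position.
BUILTIN_CATALOG: dict[str, Enzyme] = _make_catalog([
    ("HpaII", "C^CGG"),
    ("Hin6I", "G^CGC"),
    ("AciI", "C^CGC"),
    ("HpyCH4IV", "A^CGT"),
    ("Bsu15I", "AT^CGAT"),
    ("NarI", "GG^CGCC"),
    ("Bsp119I", "TT^CGAA"),
    ("Psp1406I", "AA^CGTT"),
    ("XmiI", "GT^MKAC"),
    ("Hin1I", "GR^CGYC"),
])


def load_catalog_tsv(path: str | Path) -> dict[str, Enzyme]:
    """Read a user catalog TSV (``NAME<TAB>RECOGNITION_WITH_CARET`` per line)."""
    catalog: dict[str, Enzyme] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise EnzymeError(f"{path}:{lineno}: expected NAME<TAB>MOTIF^")
            name, caret_motif = parts
            motif, offset = parse_recognition(caret_motif)
            catalog[name.lower()] = Enzyme(name, motif, offset)
    return catalog


def parse_enzyme_list(
    path: str | Path,
    catalog: Optional[Mapping[str, Enzyme]] = None,
) -> list[Enzyme]:
    """Read an enzyme list file (one name per line, case-insensitive).

    Names are resolved against ``catalog`` (defaults to the built-in table);
    unknown names raise listing the known ones.
    """
    catalog = dict(BUILTIN_CATALOG) if catalog is None else dict(catalog)
    enzymes: list[Enzyme] = []
    with open(path) as fh:
        for line in fh:
            name = line.strip()
            if not name or name.startswith("#"):
                continue
            key = name.lower()
            if key not in catalog:
                known = ", ".join(sorted(e.name for e in catalog.values()))
                raise EnzymeError(f"unknown enzyme {name!r}; known: {known}")
            enzymes.append(catalog[key])
    return enzymes


def _matches_at(sequence: str, motif: str, pos: int) -> bool:
    for j, code in enumerate(motif):
        if sequence[pos + j] not in IUPAC_SETS[code]:
            return False
    return True


def scan_sites(sequence: str, enzyme: Enzyme) -> list[CutSite]:
    """Find all recognition sites of ``enzyme`` on both strands of ``sequence``.

    Returns sites sorted by position (+ before − at the same position). For
    palindromic enzymes each physical site is reported once, as + strand.
    """
    sequence = sequence.upper()
    motif = enzyme.recognition
    k = len(motif)
    n = len(sequence)
    sites: list[CutSite] = []
    rc_motif = reverse_complement_iupac(motif)
    palindromic = enzyme.is_palindromic
    for pos in range(n - k + 1):
        if _matches_at(sequence, motif, pos):
            sites.append(
                CutSite(pos, "+", pos + enzyme.cut_offset, enzyme.name)
            )
        if not palindromic and _matches_at(sequence, rc_motif, pos):
            # enzyme bound to the bottom strand; top-strand cleavage sits
            # cut_offset from the motif *end* in + coordinates
            sites.append(
                CutSite(pos, "-", pos + k - enzyme.cut_offset, enzyme.name)
            )
    return sites


def concrete_site(enzyme: Enzyme, rng: np.random.Generator) -> str:
    """A concrete DNA realisation of the enzyme's degenerate recognition motif."""
    out = []
    for code in enzyme.recognition:
        choices = sorted(IUPAC_SETS[code])
        out.append(choices[int(rng.integers(0, len(choices)))])
    return "".join(out)


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return max(a_start, b_start) < min(a_end, b_end)


def count_cut_sites(pair, target_sequence: str, enzymes: Sequence[Enzyme]) -> CutSiteSummary:
    """Count recognition sites overlapping each region of a primer pair.

    A site is attributed to a region (forward primer, reverse primer,
    internal oligo, amplicon) when its recognition match overlaps that
    region's interval on the target sequence by >=1 bp — a primer touching
    any part of a recognition site is disrupted by digestion. A site
    straddling a primer/amplicon-interior boundary therefore counts for
    both. Identical (enzyme, position, strand) matches are counted once even
    if the enzyme list repeats.

    With an empty enzyme list (genomic-PCR mode) all counts are zero.
    """
    summary = CutSiteSummary()
    if not enzymes:
        return summary
    regions = {
        "fwd": (pair.forward.start, pair.forward.start + pair.forward.length),
        "rev": (pair.reverse.start - pair.reverse.length + 1, pair.reverse.start + 1),
        "amplicon": (pair.amplicon_start, pair.amplicon_end),
    }
    if pair.oligo is not None:
        regions["oligo"] = (pair.oligo.start, pair.oligo.start + pair.oligo.length)
    seen: set[tuple[str, int, str]] = set()
    for enzyme in enzymes:
        k = len(enzyme.recognition)
        per_region = {r: 0 for r in ("fwd", "rev", "oligo", "amplicon")}
        for site in scan_sites(target_sequence, enzyme):
            key = (enzyme.name, site.position, site.strand)
            if key in seen:
                continue
            seen.add(key)
            s, e = site.position, site.position + k
            for region, (rs, re_) in regions.items():
                if _overlaps(s, e, rs, re_):
                    per_region[region] += 1
                    if region == "amplicon":
                        summary.amplicon_sites.append(
                            CutSite(site.position - pair.amplicon_start,
                                    site.strand,
                                    site.cut_position - pair.amplicon_start,
                                    enzyme.name)
                        )
        summary.per_enzyme[enzyme.name] = per_region
        summary.n_fwd += per_region["fwd"]
        summary.n_rev += per_region["rev"]
        summary.n_oligo += per_region["oligo"]
        summary.n_amplicon += per_region["amplicon"]
    return summary


def cpg_coverage_stats(genome, enzymes: Sequence[Enzyme], cpg_islands) -> pd.DataFrame:
    """Per-enzyme CpG coverage and recognition-site density statistics.

    For each enzyme:

    - ``cpg_coverage_percent``: percentage of CpG dinucleotides in the genome
      whose C lies inside at least one recognition-site match of the enzyme.
    - ``sites_per_kb_islands``: recognition sites per kb inside CpG-island
      intervals (a site counts when its match overlaps the island).
    - ``sites_per_kb_outside``: recognition sites per kb outside islands.

    A genome with zero CpG dinucleotides yields 0% coverage with a warning.
    """
    import warnings

    islands_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for rec in cpg_islands:
        islands_by_chrom.setdefault(rec.chrom, []).append((rec.start, rec.end))

    total_island_bp = sum(
        e - s for ivs in islands_by_chrom.values() for s, e in ivs
    )
    total_bp = sum(genome.lengths.values())
    outside_bp = total_bp - total_island_bp

    # all CpG positions (index of the C) per chromosome
    cpg_positions: dict[str, list[int]] = {}
    n_cpgs = 0
    for chrom, seq in genome.sequences.items():
        pos = [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]
        cpg_positions[chrom] = pos
        n_cpgs += len(pos)
    if n_cpgs == 0:
        warnings.warn("genome contains no CpG dinucleotides; coverage reported as 0")

    rows = []
    for enzyme in enzymes:
        k = len(enzyme.recognition)
        covered = 0
        n_in_islands = 0
        n_outside = 0
        for chrom, seq in genome.sequences.items():
            sites = scan_sites(seq, enzyme)
            islands = islands_by_chrom.get(chrom, [])
            covered_pos: set[int] = set()
            for site in sites:
                s, e = site.position, site.position + k
                for p in cpg_positions[chrom]:
                    # C at p, G at p+1: CpG covered if C inside the match
                    if s <= p < e:
                        covered_pos.add(p)
                if any(_overlaps(s, e, is_, ie) for is_, ie in islands):
                    n_in_islands += 1
                else:
                    n_outside += 1
            covered += len(covered_pos)
        rows.append({
            "enzyme": enzyme.name,
            "recognition": enzyme.recognition,
            "cpg_coverage_percent": 100.0 * covered / n_cpgs if n_cpgs else 0.0,
            "sites_per_kb_islands": (
                1000.0 * n_in_islands / total_island_bp if total_island_bp else 0.0
            ),
            "sites_per_kb_outside": (
                1000.0 * n_outside / outside_bp if outside_bp else 0.0
            ),
        })
    return pd.DataFrame(rows)
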