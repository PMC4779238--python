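"""Reference genome, target BED, and annotation-track I/O plus synthetic fixtures.

All coordinates are 0-based half-open (BED convention) throughout the
package; conversion to 1-based inclusive happens only when writing GTF or
UCSC position strings.

The fixture generator replaces the genome-browser download step of the
original workflow: it produces a small reference genome with planted CpG
islands, restriction-enzyme recognition sites, SNPs, repeats, and genes,
together with a truth table of everything planted, so the whole pipeline is
testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ReferenceGenome",
    "TargetRegion",
    "AnnotationRecord",
    "AnnotationSet",
    "FixtureSpec",
    "read_fasta",
    "write_fasta",
    "read_target_bed",
    "write_target_bed",
    "read_annotation_bed",
    "write_annotation_bed",
    "generate_fixture",
    "fixture_targets",
    "write_fixture",
]

ANNOTATION_KINDS = ("snp", "cpg_island", "repeat", "gene")

VALID_BASES = frozenset("ACGTN")


class GenomeIOError(ValueError):
    """Malformed or inconsistent genomic input."""


@dataclass
class ReferenceGenome:
    """Uppercase DNA sequences keyed by chromosome name, order preserved."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise GenomeIOError(
                    f"chromosome {name!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass(frozen=True)
class TargetRegion:
    """One design target: BED interval (0-based half-open) with a unique ID."""

    chrom: str
    start: int
    end: int
    target_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"target {self.target_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class AnnotationRecord:
    chrom: str
    start: int
    end: int
    name: str
    strand: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationSet:
    """Sorted genomic intervals of one kind: snp, cpg_island, repeat, or gene."""

    kind: str
    records: list[AnnotationRecord]

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise GenomeIOError(
                f"unknown annotation kind {self.kind!r}; expected one of "
                f"{ANNOTATION_KINDS}"
            )
        self.records = sorted(self.records, key=lambda r: (r.chrom, r.start, r.end))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic fixture genome.

    ``planted_enzyme_sites`` lists (enzyme_name, count_per_island): that many
    concrete recognition-site occurrences of the enzyme are written into every
    CpG island, at positions recorded in the truth table.

    ``ensure_clean_background`` removes chance occurrences of the planted
    enzymes' recognition sites outside the planted positions, so the truth
    table enumerates every site of those enzymes exactly.
    """

    n_chroms: int = 1
    chrom_length: int = 20_000
    n_cpg_islands: int = 4
    n_snps: int = 20
    n_repeats: int = 4
    n_genes: int = 4
    planted_enzyme_sites: tuple[tuple[str, int], ...] = (("HpaII", 2),)
    seed: int = 0
    island_length: int = 400
    repeat_length: int = 150
    gene_length: int = 600
    ensure_clean_background: bool = True

    def __post_init__(self) -> None:
        counts = (
            self.n_chroms,
            self.chrom_length,
            self.n_cpg_islands,
            self.n_snps,
            self.n_repeats,
            self.n_genes,
        )
        if any(c < 0 for c in counts):
            raise GenomeIOError("fixture counts must be non-negative")
        if any(n < 0 for _, n in self.planted_enzyme_sites):
            raise GenomeIOError("planted site counts must be non-negative")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> ReferenceGenome:
    """Read a (multi-record) FASTA file into a :class:`ReferenceGenome`.

    Sequences are uppercased; record order is preserved. Duplicate record
    names and empty files are hard errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise GenomeIOError(f"duplicate chromosome name {record.id!r} in {path}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise GenomeIOError(f"no FASTA records found in {path}")
    return ReferenceGenome(sequences)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def _bed_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line.split("\t")


def read_target_bed(path: str | Path, genome: ReferenceGenome) -> list[TargetRegion]:
    """Read a 4-column target BED, validating against genome bounds.

    Each line is chrom, start, end, unique ID (tab-delimited, 0-based
    half-open). Duplicate IDs, inverted intervals, out-of-bounds coordinates
    and unknown chromosomes are hard errors with the offending line number.
    """
    targets: list[TargetRegion] = []
    seen: set[str] = set()
    lengths = genome.lengths
    for lineno, fields in _bed_lines(path):
        if len(fields) < 4:
            raise GenomeIOError(
                f"{path}:{lineno}: expected 4 tab-delimited columns, got {len(fields)}"
            )
        chrom, start_s, end_s, target_id = fields[:4]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise GenomeIOError(f"{path}:{lineno}: non-integer coordinate") from exc
        if chrom not in lengths:
            raise GenomeIOError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if start >= end:
            raise GenomeIOError(
                f"{path}:{lineno}: start {start} >= end {end} for target {target_id!r}"
            )
        if start < 0 or end > lengths[chrom]:
            raise GenomeIOError(
                f"{path}:{lineno}: target {target_id!r} [{start}, {end}) outside "
                f"{chrom} length {lengths[chrom]}"
            )
        if target_id in seen:
            raise GenomeIOError(f"{path}:{lineno}: duplicate target ID {target_id!r}")
        seen.add(target_id)
        targets.append(TargetRegion(chrom, start, end, target_id))
    return targets


def write_target_bed(targets: Iterable[TargetRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in targets:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.target_id}\n")


def read_annotation_bed(path: str | Path, kind: str) -> AnnotationSet:
    """Read a BED3+/BED6 annotation track of the given kind.

    Gene tracks must carry a strand column (+/-); other kinds may omit both
    name and strand. Records come back sorted by (chrom, start).
    """
    records: list[AnnotationRecord] = []
    for lineno, fields in _bed_lines(path):
        if len(fields) < 3:
            raise GenomeIOError(f"{path}:{lineno}: expected >=3 columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else f"{kind}_{lineno}"
        strand = None
        if kind == "gene":
            if len(fields) < 6 or fields[5] not in ("+", "-"):
                raise GenomeIOError(
                    f"{path}:{lineno}: gene record needs a +/- strand in column 6"
                )
            strand = fields[5]
        elif len(fields) >= 6 and fields[5] in ("+", "-"):
            strand = fields[5]
        records.append(AnnotationRecord(chrom, start, end, name, strand))
    return AnnotationSet(kind, records)


def write_annotation_bed(aset: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in aset.records:
            if r.strand is not None:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")


# ---------------------------------------------------------------------------
# Synthetic fixture generation
# ---------------------------------------------------------------------------

def _random_background(rng: np.random.Generator, n: int) -> np.ndarray:
    """AT-rich background with depleted CpG dinucleotide frequency."""
    bases = np.array(list("ACGT"))
    probs = np.array([0.30, 0.20, 0.20, 0.30])
    return bases[rng.choice(4, size=n, p=probs)]


def _island_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    """GC-rich island body with elevated CG-dinucleotide frequency."""
    seq = np.empty(n, dtype="<U1")
    bases = "ACGT"
    probs = np.array([0.15, 0.35, 0.35, 0.15])
    i = 0
    while i < n:
        # ~15% of positions start an explicit CpG dinucleotide
        if i + 1 < n and rng.random() < 0.15:
            seq[i], seq[i + 1] = "C", "G"
            i += 2
        else:
            seq[i] = bases[rng.choice(4, p=probs)]
            i += 1
    return seq


def _place_intervals(
    rng: np.random.Generator,
    n: int,
    length: int,
    chrom_length: int,
    occupied: list[tuple[int, int]],
    *,
    min_gap: int = 20,
    what: str = "feature",
) -> list[tuple[int, int]]:
    """Place n non-overlapping intervals avoiding `occupied` (with a gap)."""
    placed: list[tuple[int, int]] = []
    taken = list(occupied)
    for k in range(n):
        ok = None
        for _ in range(400):
            start = int(rng.integers(0, max(1, chrom_length - length)))
            end = start + length
            if all(
                start - min_gap >= e or end + min_gap <= s for s, e in taken
            ):
                ok = (start, end)
                break
        if ok is None:
            raise GenomeIOError(
                f"could not place {what} {k + 1}/{n} of length {length} in "
                f"chromosome of length {chrom_length}"
            )
        taken.append(ok)
        placed.append(ok)
    return sorted(placed)


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[ReferenceGenome, dict[str, AnnotationSet], pd.DataFrame]:
    """Generate a deterministic synthetic genome with planted features.

    Returns the genome, the four annotation sets keyed by kind, and a truth
    table (DataFrame with columns feature, chrom, start, end, name, detail)
    listing every planted feature, including every planted enzyme
    recognition site with its concrete sequence.

    Deterministic: the same spec (including seed) yields identical output.
    """
    from .msre_enzymes import BUILTIN_CATALOG, concrete_site, scan_sites

    rng = np.random.default_rng(spec.seed)
    sequences: dict[str, str] = {}
    truth_rows: list[dict] = []
    ann: dict[str, list[AnnotationRecord]] = {k: [] for k in ANNOTATION_KINDS}

    enzymes = []
    for enz_name, count in spec.planted_enzyme_sites:
        key = enz_name.lower()
        if key not in BUILTIN_CATALOG:
            raise GenomeIOError(f"unknown enzyme {enz_name!r} in fixture spec")
        enzymes.append((BUILTIN_CATALOG[key], count))

    for ci in range(spec.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = _random_background(rng, spec.chrom_length)

        islands = _place_intervals(
            rng, spec.n_cpg_islands, spec.island_length, spec.chrom_length, [],
            what="CpG island",
        )
        for ii, (istart, iend) in enumerate(islands):
            seq[istart:iend] = _island_sequence(rng, iend - istart)
            name = f"CpG_{chrom}_{ii + 1}"
            ann["cpg_island"].append(AnnotationRecord(chrom, istart, iend, name))
            truth_rows.append(
                dict(feature="cpg_island", chrom=chrom, start=istart, end=iend,
                     name=name, detail="")
            )
            # plant recognition sites at evenly spread offsets within the island
            site_intervals: list[tuple[int, int]] = []
            for enzyme, count in enzymes:
                site_len = len(enzyme.recognition)
                for si in range(count):
                    placed_at = None
                    for _ in range(200):
                        off = int(rng.integers(0, spec.island_length - site_len))
                        if all(
                            off + site_len <= s or off >= e
                            for s, e in site_intervals
                        ):
                            placed_at = off
                            break
                    if placed_at is None:
                        raise GenomeIOError(
                            f"could not plant {enzyme.name} site {si + 1} in "
                            f"island {name}"
                        )
                    site_intervals.append((placed_at, placed_at + site_len))
                    site_seq = concrete_site(enzyme, rng)
                    gstart = istart + placed_at
                    seq[gstart:gstart + site_len] = list(site_seq)
                    truth_rows.append(
                        dict(feature="enzyme_site", chrom=chrom, start=gstart,
                             end=gstart + site_len, name=enzyme.name,
                             detail=site_seq)
                    )

        occupied = list(islands)
        repeats = _place_intervals(
            rng, spec.n_repeats, spec.repeat_length, spec.chrom_length, occupied,
            what="repeat",
        )
        for ri, (rstart, rend) in enumerate(repeats):
            unit = "".join(rng.choice(list("ACGT"), size=4))
            rep = (unit * ((rend - rstart) // len(unit) + 1))[: rend - rstart]
            seq[rstart:rend] = list(rep)
            name = f"rep_{chrom}_{ri + 1}"
            ann["repeat"].append(AnnotationRecord(chrom, rstart, rend, name))
            truth_rows.append(
                dict(feature="repeat", chrom=chrom, start=rstart, end=rend,
                     name=name, detail=unit)
            )
        occupied += repeats

        # genes may overlap islands (promoters do); avoid repeats only
        genes = _place_intervals(
            rng, spec.n_genes, spec.gene_length, spec.chrom_length, repeats,
            what="gene",
        )
        for gi, (gstart, gend) in enumerate(genes):
            name = f"gene_{chrom}_{gi + 1}"
            strand = "+" if rng.random() < 0.5 else "-"
            ann["gene"].append(AnnotationRecord(chrom, gstart, gend, name, strand))
            truth_rows.append(
                dict(feature="gene", chrom=chrom, start=gstart, end=gend,
                     name=name, detail=strand)
            )

        # SNPs: single-bp positions anywhere (including islands)
        snp_pos = rng.choice(spec.chrom_length, size=spec.n_snps, replace=False)
        for si, pos in enumerate(sorted(int(p) for p in snp_pos)):
            name = f"rs{spec.seed}{ci}{si:04d}"
            ann["snp"].append(AnnotationRecord(chrom, pos, pos + 1, name))
            truth_rows.append(
                dict(feature="snp", chrom=chrom, start=pos, end=pos + 1,
                     name=name, detail=seq[pos])
            )

        chrom_seq = "".join(seq)

        if spec.ensure_clean_background and enzymes:
            planted = {
                (row["start"], row["end"])
                for row in truth_rows
                if row["feature"] == "enzyme_site" and row["chrom"] == chrom
            }
            chrom_seq = _scrub_chance_sites(
                chrom_seq, [e for e, _ in enzymes], planted, rng, scan_sites
            )
        sequences[chrom] = chrom_seq

    genome = ReferenceGenome(sequences)
    annotation_sets = {k: AnnotationSet(k, v) for k, v in ann.items()}
    truth = pd.DataFrame(
        truth_rows, columns=["feature", "chrom", "start", "end", "name", "detail"]
    )
    return genome, annotation_sets, truth


def _scrub_chance_sites(sequence, enzymes, planted, rng, scan_sites, max_rounds=50):
    """Mutate chance recognition-site matches so only planted sites remain.

    A chance match is destroyed by flipping one base inside it to a base that
    cannot satisfy the recognition pattern at that offset; planted intervals
    are never touched.
    """
    seq = list(sequence)
    for _ in range(max_rounds):
        dirty = False
        s = "".join(seq)
        for enzyme in enzymes:
            for site in scan_sites(s, enzyme):
                span = (site.position, site.position + len(enzyme.recognition))
                if span in planted:
                    continue
                # overlap with a planted site: mutate only outside it
                candidates = [
                    i for i in range(*span)
                    if not any(ps <= i < pe for ps, pe in planted)
                ]
                if not candidates:
                    continue
                i = candidates[int(rng.integers(0, len(candidates)))]
                current = seq[i]
                choices = [b for b in "ACGT" if b != current]
                seq[i] = choices[int(rng.integers(0, 3))]
                dirty = True
        if not dirty:
            return "".join(seq)
    raise GenomeIOError("could not scrub chance enzyme sites from background")


def fixture_targets(
    truth: pd.DataFrame,
    genome: ReferenceGenome,
    *,
    target_length: int = 120,
    n_off_island: int = 0,
    seed: int = 0,
) -> list[TargetRegion]:
    """Derive target regions from a fixture truth table.

    One target is centred on each planted CpG island; optionally
    ``n_off_island`` additional targets are placed per chromosome in regions
    free of planted features.
    """
    rng = np.random.default_rng(seed)
    targets: list[TargetRegion] = []
    lengths = genome.lengths
    islands = truth[truth.feature == "cpg_island"]
    for i, row in enumerate(islands.itertuples()):
        mid = (row.start + row.end) // 2
        start = max(0, mid - target_length // 2)
        end = min(lengths[row.chrom], start + target_length)
        targets.append(TargetRegion(row.chrom, start, end, f"T_island_{i + 1}"))
    for chrom, clen in lengths.items():
        feats = truth[truth.chrom == chrom]
        placed = 0
        attempts = 0
        while placed < n_off_island and attempts < 500:
            attempts += 1
            start = int(rng.integers(0, clen - target_length))
            end = start + target_length
            if ((feats.start < end) & (feats.end > start)).any():
                continue
            placed += 1
            targets.append(
                TargetRegion(chrom, start, end, f"T_bg_{chrom}_{placed}")
            )
        if placed < n_off_island:
            raise GenomeIOError(
                f"could not place {n_off_island} off-island targets on {chrom}"
            )
    return targets


def write_fixture(
    spec: FixtureSpec,
    out_dir: str | Path,
    *,
    target_length: int = 120,
    n_off_island_targets: int = 1,
) -> dict[str, Path]:
    """Generate a fixture and write genome.fa, the four tracks, targets.bed,
    and truth.tsv into ``out_dir``. Returns the path of each artifact."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, tracks, truth = generate_fixture(spec)
    paths = {
        "genome": out / "genome.fa",
        "snp": out / "snp.bed",
        "cpg_island": out / "cpg.bed",
        "repeat": out / "repeats.bed",
        "gene": out / "genes.bed",
        "targets": out / "targets.bed",
        "truth": out / "truth.tsv",
    }
    write_fasta(genome, paths["genome"])
    write_annotation_bed(tracks["snp"], paths["snp"])
    write_annotation_bed(tracks["cpg_island"], paths["cpg_island"])
    write_annotation_bed(tracks["repeat"], paths["repeat"])
    write_annotation_bed(tracks["gene"], paths["gene"])
    targets = fixture_targets(
        truth, genome, target_length=target_length,
        n_off_island=n_off_island_targets, seed=spec.seed,
    )
    write_target_bed(targets, paths["targets"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
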