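# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open (BED convention): an
interval `[start, end)` has length `end − start`, and two intervals overlap
iff `max(starts) < min(ends)` — a boundary touch is not an overlap.
Conversion to 1-based inclusive coordinates happens only at emission time,
in the GTF writer (`start+1`, `end`) and in UCSC position strings
(`chrom:start+1-end`). Target BED input is read as standard 0-based
half-open BED; nothing in the pipeline assumes 1-based input.

## Design ranges and sequence extraction

Each target may be extended by independent upstream/downstream flanks
(default 0/0) and is clamped silently (but logged) to the chromosome.
Annotation tracks are subset to the union of design ranges with an
interval-tree overlap query before per-target work starts; the all-pairs
intersection is retained in the test suite as the oracle for this engine.
Reference bases `N` are legal in the genome; any candidate primer window
containing `N` is rejected.

## Primer design engine

The engine enumerates every (strand, start, length) window within the
configured size bounds — exhaustive, not heuristic — and keeps a window iff
it passes all hard constraints:

| constraint | default | unit |
|---|---|---|
| primer size min/opt/max | 18 / 20 / 27 | bp |
| Tm min/opt/max | 57 / 60 / 63 | °C |
| GC min/opt/max | 20 / 50 / 80 | % |
| max self-any / self-end | 8 / 3 | score |
| max homopolymer run | 5 | bp |
| product size ranges | 100–300 | bp |

Defaults mirror Primer3 v2.3.6 for the implemented parameter subset; the
Boulder-IO reader accepts the corresponding `PRIMER_*` keys, warns on and
ignores unsupported keys, and hard-errors on unparseable numerics.
Compatibility is at the parameter interface, not bit-level score parity:
mispriming libraries, full secondary-structure ΔG, and masking are out of
scope.

**Penalty.** Each candidate's penalty is
`w_size·|len − opt| + w_tm·|Tm − opt| + w_gc·|GC − opt|`
with default weights 1 / 1 / 0 (the Primer3 defaults for these terms). A
pair's penalty is the sum of its primers' penalties plus optional
pair-level terms (Tm difference, product-size deviation; default weight 0).
Pairs require forward 5′ strictly left of reverse 5′, non-overlapping
footprints, and a product size inside a configured range; they are sorted
by (penalty, amplicon start, product size, forward start) — a total,
deterministic order — and truncated to `n_return` (default 5 per target,
the package's choice where no published default exists).

**Melting temperature.** Nearest-neighbour summation over the unified
duplex parameter set of Allawi & SantaLucia (1997), with terminal
initiation terms and the symmetry correction for self-complementary
oligos. Salt enters through the SantaLucia (1998) entropic correction
`ΔS += 0.368·(N−1)·ln[Mon+]`, with divalent cations folded into the
monovalent equivalent by the von Ahsen (2001) term
`Mon+ += 120·√(divalent − dNTP)` (mM). The duplex concentration factor is
`Ct/4` for non-self-complementary oligos and `Ct` for self-complementary
ones. Defaults: 50 mM monovalent, 1.5 mM divalent, 0.6 mM dNTP, 50 nM
oligo. The constants are frozen in `design_core.NN_TABLE`; the test suite
checks the implementation against an independently written NN-sum oracle
and against Bio.SeqUtils.MeltingTemp configured for the same model.

**Self-complementarity.** The sequence is aligned ungapped against its own
reverse complement at every offset, +1 per match and −1 per mismatch;
`self_any` is the best contiguous-window sum over all offsets (floored at
0) and `self_end` restricts windows to those ending at the 3′-terminal
base (primer-dimer extension risk). These integer-scaled scores are
simpler than Primer3's thermodynamic alignment but play the same
role and use the same default caps (8 / 3).

**Internal oligos** (optional) reuse the window enumerator with
oligo-specific size/Tm bounds on the forward strand; a pair is kept only if
some oligo fits strictly between the primers' footprints, and the
lowest-penalty one is attached.

## Restriction-site model

Enzyme motifs are IUPAC-degenerate with caret cleavage notation (HpaII
`C^CGG` → motif `CCGG`, cut offset 1). Degenerate codes are base *sets*,
and reverse complements are computed symbolically (complement of M={A,C}
is K={G,T}), which is what makes XmiI `GT^MKAC` and Hin1I `GR^CGYC`
correct. A scan reports every + strand motif match plus every match of the
reverse-complement motif as − strand; palindromic motifs (after IUPAC
expansion) report each physical site once. Overlapping and
self-overlapping matches all count — each is a physical site.

A cut site is attributed to a region (forward primer, reverse primer,
oligo, amplicon) when its *recognition match* overlaps the region by ≥1 bp,
not when the cleavage point falls inside it: a primer overlapping any part
of a recognition site is disrupted by digestion, so this is the
conservative reading, and a site straddling a primer/amplicon-interior
boundary counts for both. Enzymes with two cleavage positions or cleavage
outside the recognition string are out of scope.

The built-in catalog holds ten CpG-targeting type-II MSREs (HpaII, Hin6I,
AciI, HpyCH4IV, Bsu15I, NarI, Bsp119I, Psp1406I, XmiI, Hin1I) and is
user-extendable via a `NAME<TAB>MOTIF^` TSV. Genome-wide statistics report,
per enzyme, the percentage of CpG dinucleotides covered by ≥1 recognition
match and recognition sites per kb inside vs outside CpG islands; a genome
with zero CpGs reports 0% with a warning.

## Annotation

SNP counts are computed separately for each primer footprint, the oligo
(when present), and the amplicon; CpG-island and repeat counts over the
amplicon, with a separate flag for repeats under a primer.
Upstream/downstream genes are genomic left/right of the amplicon
regardless of gene strand (strand is reported alongside); distances are
measured from the amplicon's outer boundaries, which are the primers' 5′
ends; an overlapping gene is reported on both sides at distance 0.

## Selection

Quality-matrix rules are `column operator value rank` over any summary
column, operators `> < >= <= -` with `-` an inclusive range, ranks 1–10.
Semantics are cumulative: a pair's quality level is the smallest rank r
such that it satisfies **all** rules of rank ≤ r, giving a strictness
ladder in which level 1 is best; an independent-per-rank mode is available
behind a flag. Per target, the pairs achieving the best attained level are
selected in penalty order; with no matrix at all, selection is pure
penalty order. Every pair keeps a full per-rule audit record.

The MSRE validation filter encodes the four wet-lab design criteria:
≥1 cut site in the amplicon, no SNP under either primer, no repeat in the
assay, and the original target inside or within ±50 bp of the amplified
sequence. The proximity test uses the target midpoint by default because
the criterion is ambiguous for targets longer than the amplicon; a
whole-target-containment mode is flag-selectable.

## Pipeline and determinism

Targets are processed independently; the per-target design work (candidate
enumeration through annotation and selection) can run in a process pool.
Results are assembled in input target order, so the summary TSV is
byte-identical for any worker count — verified at 250 targets in the test
suite. A per-target hard error aborts that target with a logged reason and
the run continues (a fail-fast flag inverts this). Memory per target is
bounded by its design range; targets are streamed.

## Synthetic fixtures

The fixture generator emulates the annotation stack the pipeline consumes:
an AT-leaning background (CpG-depleted), GC-rich islands with ~15% of
positions starting an explicit CpG dinucleotide, literal enzyme
recognition sites planted at recorded positions inside islands, and
planted SNPs (1 bp), tandem-unit repeats, and stranded genes, all
non-overlapping by construction and all recorded in a truth table. By
default, chance occurrences of the planted enzymes' motifs outside the
planted positions are mutated away, so the truth table enumerates those
enzymes' sites exactly — this is what lets the planted-truth test demand
exact agreement between the MSRE filter and the truth table. Generation is
a pure function of the spec (including seed); placement failure is a hard
error, never silent truncation.

What the fixtures do **not** emulate: realistic human base composition and
repeat families, SNP allele frequencies, methylation state, chromosome-
scale sequence length, or homology between targets. Passing the planted-
truth tests therefore demonstrates the correctness of the interval
arithmetic, scanning, and filtering logic — not wet-lab primer success
rates on real genomes.

## qPCR calibration evaluation

A calibration curve is an OLS fit (scipy.stats.linregress) of Cq against
log10(input ng); the log base is isolated in one place. Derived values:
efficiency `E = (10^(−1/slope) − 1)·100` (slope −1/log10 2 ≈ −3.32 ↔ 100%,
i.e. perfect doubling), R², and the theoretical 1 ng detection = the
intercept (log10 1 = 0). Fits need ≥2 points with distinct amounts;
non-negative slopes are a hard error for efficiency conversion. The
dilution-series simulator inverts the same model
(`Cq = ct_1ng − log10(amount)/log10(1 + E/100)` plus Gaussian noise), so
noiseless recovery is exact to numerical precision — a generator/fit
consistency invariant in the test suite.

Default qualification thresholds — efficiency 90–110%, R² ≥ 0.99, optional
Cq-at-1 ng cap — reflect common MIQE-style practice. They are explicit,
overridable configuration, not published constants.

## Numerical and degenerate-input choices

- Pair ordering ties are broken by (amplicon start, product size, forward
  start); candidate enumeration order is strand, then start, then length.
- Noiseless calibration fits are checked to R² = 1 within 1e−12.
- An empty target list or a target yielding no pairs produces a
  header-only summary TSV — absence is explicit, never silent.
- Unknown Boulder-IO keys warn; malformed values error with the key name.
- Duplicate enzymes in a run are de-duplicated per (enzyme, position,
  strand) during counting.

## Known limitations

- No mispriming/secondary-structure thermodynamic alignment and no
  cross-target multiplex dimer checking; self-scores are integer-scaled
  match counts, not ΔG.
- Genomic-PCR mode shares the full output schema with MSRE mode (cut-site
  columns all zero) by design.
- The qPCR module evaluates calibration tables; it does not process raw
  fluorescence curves or model pre-amplification chemistry in multiplex
  assays — multiplex batches are just labelled tables run through the same
  fit/qualify path.
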