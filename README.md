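# msreprime

High-throughput design of **MSRE-PCR** and genomic PCR primer pairs from
BED-defined target regions, with restriction cut-site prediction, genomic
annotation, rank-based quality selection, and qPCR calibration evaluation.

## The problem

Methylation-sensitive restriction enzymes (MSREs) such as HpaII (C^CGG) or
AciI (C^CGC) cleave their recognition site only when the CpG inside it is
unmethylated; methylation blocks digestion, so PCR amplification across a
site after digestion reads out DNA methylation (MSRE-qPCR). Designing such
assays at scale means, for every target region: extracting the design
sequence, enumerating primer pairs under thermodynamic constraints,
predicting every enzyme cut site in primers and amplicon, rejecting pairs
with SNPs under a primer or repeats inside the assay, and keeping the
target close to the amplified sequence. `msreprime` automates all of this
for hundreds of targets per run, entirely offline against local FASTA/BED
files.

Users are epigenetics and regulatory-genomics groups validating candidate
regions from methylome-wide discovery screens, and anyone needing batch
genomic-PCR design with genomic annotation of the results.

## What it computes

- **Primer design** — exhaustive enumeration of (position, length, strand)
  windows passing hard constraints (size, Tm, GC%, self-complementarity
  caps, homopolymer cap), ranked by a penalty
  `Σ w·|value − opt|` over size/Tm/GC, with Primer3-compatible Boulder-IO
  parameters. Melting temperatures use unified nearest-neighbour
  thermodynamics (Allawi & SantaLucia 1997) with the SantaLucia 1998
  entropic salt correction:
  `Tm = ΔH / (ΔS + R·ln(Ct/x)) − 273.15`.
- **Cut-site prediction** — IUPAC-degenerate scanning of both strands, with
  symbolic reverse complements of degenerate motifs (complement of M={A,C}
  is K={G,T}); palindromic sites counted once per physical site.
- **Annotation** — SNP counts per primer and amplicon, CpG-island and
  repeat overlap, nearest upstream/downstream genes with distances.
- **Selection** — a ranked quality matrix (rules `column op value rank`,
  ranks 1–10, cumulative semantics) plus the MSRE validation filter:
  ≥1 cut site in the amplicon, SNP-free primers, repeat-free assay, target
  within ±50 bp of the amplified sequence.
- **qPCR evaluation** — calibration-curve fits of Cq against log10(input ng);
  efficiency `E = (10^(−1/slope) − 1)·100` (slope −3.32 ↔ 100%, perfect
  doubling), R², and the theoretical 1 ng detection (the intercept).

## Worked example

Generate a synthetic genome with planted CpG islands, HpaII sites, SNPs and
repeats, then design MSRE primers for it:

```bash
msreprime fixtures --out fx --seed 5
cat > params.txt <<EOF
PRIMER_MIN_TM=50
PRIMER_OPT_TM=58
PRIMER_MAX_TM=70
PRIMER_PRODUCT_SIZE_RANGE=80-160
EOF
echo HpaII > enzymes.txt
msreprime run --genome fx/genome.fa --targets fx/targets.bed \
  --snp fx/snp.bed --cpg fx/cpg.bed --repeats fx/repeats.bed \
  --genes fx/genes.bed --params params.txt --enzymes enzymes.txt \
  --mode msre --flank-up 60 --flank-down 60 --out out
```

This prints `summary: out/summary.tsv`. The TSV has one row per selected
pair; for the first island target of the seed-5 fixture the top row reads
(columns abridged):

```
target_id   forward_primer      reverse_primer      product_size  n_cutsites_amplicon  n_snps_fwd  n_repeats
T_island_1  GCCATCTGAGGCGTCCAC  CTCGTGTCTCCGCGGCTC  83            1                    0           0
```

i.e. an 83-bp amplicon holding one HpaII recognition site, no SNP under
either primer, and no repeat in the assay — a pair that passes the MSRE
validation filter. `out/tracks/<target_id>.gtf` holds a UCSC custom track
(amplicon + both primers) per target, and the `browser_url` /
`insilico_url` columns link the pair to the genome browser and to in-silico
PCR.

Calibration evaluation from a Cq table (`assay_id,input_ng,cq`):

```bash
msreprime qpcr-eval --in cq.csv --out fits.csv
```

writes one row per assay with slope, R², efficiency, theoretical 1 ng Cq,
and a pass/fail against the qualification criteria (defaults: efficiency
90–110%, R² ≥ 0.99; both overridable).

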