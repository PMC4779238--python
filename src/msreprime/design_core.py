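"""In-house primer design engine with a Primer3-compatible parameter surface.

Candidate generation is exhaustive over (strand, position, length) windows;
every emitted candidate satisfies all hard constraints (size, melting
temperature, GC fraction, self-complementarity caps, homopolymer cap, no
ambiguous bases), and soft deviations from the optima are folded into a
non-negative penalty used for ranking — the smaller, the better.

Melting temperatures come from nearest-neighbour thermodynamics using the
unified duplex parameter set of Allawi & SantaLucia (1997) with the
SantaLucia (1998) entropic salt correction; divalent cations are converted
to a monovalent equivalent with the von Ahsen (2001) square-root term. The
frozen ΔH/ΔS table lives in this module.

Compatibility with the Primer3 ecosystem is at the *parameter interface*
(Boulder-IO keys, defaults of Primer3 v2.3.6 for the implemented subset),
not bit-level score parity: unimplemented keys are warned about and ignored.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

__all__ = [
    "DesignParameters",
    "PrimerCandidate",
    "PrimerPair",
    "parse_parameter_file",
    "melting_temperature",
    "gc_percent",
    "complementarity_scores",
    "candidate_primers",
    "enumerate_pairs",
    "reverse_complement",
]

GAS_CONSTANT = 1.987  # cal/(K*mol)

# Unified nearest-neighbour duplex parameters, Allawi & SantaLucia (1997):
# (delta-H kcal/mol, delta-S cal/(K*mol)) per stacked pair 5'-XY-3'/3'-X'Y'-5'
NN_TABLE = {
    "AA/TT": (-7.9, -22.2),
    "AT/TA": (-7.2, -20.4),
    "TA/AT": (-7.2, -21.3),
    "CA/GT": (-8.5, -22.7),
    "GT/CA": (-8.4, -22.4),
    "CT/GA": (-7.8, -21.0),
    "GA/CT": (-8.2, -22.2),
    "CG/GC": (-10.6, -27.2),
    "GC/CG": (-9.8, -24.4),
    "GG/CC": (-8.0, -19.9),
}
NN_INIT_AT = (2.3, 4.1)   # duplex initiation at a terminal A·T
NN_INIT_GC = (0.1, -2.8)  # duplex initiation at a terminal G·C
NN_SYMMETRY = (0.0, -1.4)  # self-complementary duplex symmetry term

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _nn_key(dinuc: str) -> str:
    comp = dinuc.translate(_COMPLEMENT)
    key = f"{dinuc}/{comp}"
    if key in NN_TABLE:
        return key
    rc = comp[::-1]
    return f"{rc}/{rc.translate(_COMPLEMENT)}"


@dataclass
class DesignParameters:
    """The implemented subset of Primer3-style design parameters.

    Units: sizes bp, temperatures °C, GC in percent, salt in mM, oligo
    (annealing DNA) concentration in nM. Defaults follow Primer3 v2.3.6.
    """

    size_min: int = 18
    size_opt: int = 20
    size_max: int = 27
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    gc_min: float = 20.0
    gc_opt: float = 50.0
    gc_max: float = 80.0
    product_size_ranges: tuple[tuple[int, int], ...] = ((100, 300),)
    max_self_any: float = 8.0
    max_self_end: float = 3.0
    max_poly_x: int = 5
    salt_monovalent_mM: float = 50.0
    salt_divalent_mM: float = 1.5
    dntp_mM: float = 0.6
    oligo_conc_nM: float = 50.0
    num_return: int = 5
    design_internal_oligo: bool = False
    oligo_size_min: int = 18
    oligo_size_opt: int = 20
    oligo_size_max: int = 27
    oligo_tm_min: float = 57.0
    oligo_tm_opt: float = 60.0
    oligo_tm_max: float = 63.0
    wt_size: float = 1.0
    wt_tm: float = 1.0
    wt_gc: float = 0.0
    wt_pair_diff_tm: float = 0.0
    wt_product_size: float = 0.0

    def __post_init__(self) -> None:
        for lo, opt, hi, what in (
            (self.size_min, self.size_opt, self.size_max, "size"),
            (self.tm_min, self.tm_opt, self.tm_max, "Tm"),
            (self.gc_min, self.gc_opt, self.gc_max, "GC"),
        ):
            if not (lo <= opt <= hi):
                raise ValueError(f"{what}: need min <= opt <= max, got {lo}/{opt}/{hi}")
        if not self.product_size_ranges:
            raise ValueError("at least one product size range required")
        for lo, hi in self.product_size_ranges:
            if lo > hi:
                raise ValueError(f"product size range {lo}-{hi} inverted")
            if lo < 2 * self.size_min:
                raise ValueError(
                    f"product size minimum {lo} below twice the minimum primer "
                    f"size ({2 * self.size_min})"
                )


@dataclass(frozen=True)
class PrimerCandidate:
    """One primer (or internal oligo) candidate.

    ``start`` is the 0-based position of the 5' end on its strand, expressed
    in + coordinates of the target sequence: for a forward candidate the
    footprint is [start, start+length); for a reverse candidate it is
    (start-length, start], i.e. [start-length+1, start+1) half-open.
    ``sequence`` is always written 5'->3' on the candidate's own strand.
    """

    strand: str  # "forward" | "reverse"
    start: int
    length: int
    sequence: str
    tm: float
    gc: float
    self_any: float
    self_end: float
    penalty: float

    @property
    def footprint(self) -> tuple[int, int]:
        if self.strand == "forward":
            return (self.start, self.start + self.length)
        return (self.start - self.length + 1, self.start + 1)


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair with its amplicon on the target sequence."""

    pair_id: str
    forward: PrimerCandidate
    reverse: PrimerCandidate
    amplicon_start: int
    amplicon_end: int
    pair_penalty: float
    oligo: Optional[PrimerCandidate] = None

    @property
    def product_size(self) -> int:
        return self.amplicon_end - self.amplicon_start


# ---------------------------------------------------------------------------
# Boulder-IO parameter file
# ---------------------------------------------------------------------------

_INT_KEYS = {
    "PRIMER_MIN_SIZE": "size_min",
    "PRIMER_OPT_SIZE": "size_opt",
    "PRIMER_MAX_SIZE": "size_max",
    "PRIMER_MAX_POLY_X": "max_poly_x",
    "PRIMER_NUM_RETURN": "num_return",
    "PRIMER_INTERNAL_MIN_SIZE": "oligo_size_min",
    "PRIMER_INTERNAL_OPT_SIZE": "oligo_size_opt",
    "PRIMER_INTERNAL_MAX_SIZE": "oligo_size_max",
}
_FLOAT_KEYS = {
    "PRIMER_MIN_TM": "tm_min",
    "PRIMER_OPT_TM": "tm_opt",
    "PRIMER_MAX_TM": "tm_max",
    "PRIMER_MIN_GC": "gc_min",
    "PRIMER_OPT_GC_PERCENT": "gc_opt",
    "PRIMER_MAX_GC": "gc_max",
    "PRIMER_MAX_SELF_ANY": "max_self_any",
    "PRIMER_MAX_SELF_END": "max_self_end",
    "PRIMER_SALT_MONOVALENT": "salt_monovalent_mM",
    "PRIMER_SALT_DIVALENT": "salt_divalent_mM",
    "PRIMER_DNTP_CONC": "dntp_mM",
    "PRIMER_DNA_CONC": "oligo_conc_nM",
    "PRIMER_INTERNAL_MIN_TM": "oligo_tm_min",
    "PRIMER_INTERNAL_OPT_TM": "oligo_tm_opt",
    "PRIMER_INTERNAL_MAX_TM": "oligo_tm_max",
    "PRIMER_WT_SIZE_LT": "wt_size",
    "PRIMER_WT_SIZE_GT": "wt_size",
    "PRIMER_WT_TM_LT": "wt_tm",
    "PRIMER_WT_TM_GT": "wt_tm",
    "PRIMER_WT_GC_PERCENT_LT": "wt_gc",
    "PRIMER_WT_GC_PERCENT_GT": "wt_gc",
    "PRIMER_PAIR_WT_DIFF_TM": "wt_pair_diff_tm",
    "PRIMER_PAIR_WT_PRODUCT_SIZE_LT": "wt_product_size",
    "PRIMER_PAIR_WT_PRODUCT_SIZE_GT": "wt_product_size",
}
_BOOL_KEYS = {
    "PRIMER_PICK_INTERNAL_OLIGO": "design_internal_oligo",
}


def parse_parameter_file(path: str | Path) -> DesignParameters:
    """Parse a Boulder-IO (``KEY=VALUE`` per line) parameter file.

    A bare ``=`` line terminates the record; unknown keys warn and are
    ignored; missing keys fall back to the defaults; an unparseable numeric
    value is a hard error naming the key.
    """
    values: dict[str, object] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "=":
                break
            if "=" not in line:
                raise ValueError(f"malformed Boulder-IO line {line!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            try:
                if key in _INT_KEYS:
                    values[_INT_KEYS[key]] = int(value)
                elif key in _FLOAT_KEYS:
                    values[_FLOAT_KEYS[key]] = float(value)
                elif key in _BOOL_KEYS:
                    values[_BOOL_KEYS[key]] = bool(int(value))
                elif key == "PRIMER_PRODUCT_SIZE_RANGE":
                    ranges = []
                    for part in value.split():
                        lo, _, hi = part.partition("-")
                        ranges.append((int(lo), int(hi)))
                    values["product_size_ranges"] = tuple(ranges)
                else:
                    warnings.warn(f"ignoring unsupported parameter {key!r}")
            except ValueError as exc:
                raise ValueError(f"unparseable value {value!r} for {key}") from exc
    return DesignParameters(**values)


# ---------------------------------------------------------------------------
# Thermodynamics and sequence statistics
# ---------------------------------------------------------------------------

def melting_temperature(sequence: str, params: DesignParameters) -> float:
    """Nearest-neighbour melting temperature in °C.

    Sums the unified NN stack table with terminal-initiation terms (plus the
    symmetry term for self-complementary oligos), applies the entropic salt
    correction ΔS += 0.368·(N−1)·ln[Mon+] with divalents folded in as
    Mon+ += 120·√(divalent − dNTP), and evaluates
    Tm = ΔH / (ΔS + R·ln(Ct/x)) with x = 4 (x = 1 when self-complementary).
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("melting temperature needs a sequence of length >= 2")
    if set(seq) - set("ACGT"):
        raise ValueError(f"melting temperature undefined for ambiguous bases in {seq!r}")

    d_h, d_s = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        dh, ds = NN_INIT_AT if end in "AT" else NN_INIT_GC
        d_h += dh
        d_s += ds
    self_comp = seq == reverse_complement(seq)
    if self_comp:
        d_h += NN_SYMMETRY[0]
        d_s += NN_SYMMETRY[1]
    for i in range(len(seq) - 1):
        dh, ds = NN_TABLE[_nn_key(seq[i:i + 2])]
        d_h += dh
        d_s += ds

    mon_mM = params.salt_monovalent_mM
    dv = params.salt_divalent_mM - params.dntp_mM
    if dv > 0:
        mon_mM += 120.0 * math.sqrt(dv)
    d_s += 0.368 * (len(seq) - 1) * math.log(mon_mM / 1000.0)

    ct = params.oligo_conc_nM * 1e-9
    k = ct if self_comp else ct / 4.0
    return (1000.0 * d_h) / (d_s + GAS_CONSTANT * math.log(k)) - 273.15


def gc_percent(sequence: str) -> float:
    seq = sequence.upper()
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def max_homopolymer_run(sequence: str) -> int:
    best = run = 1
    for a, b in zip(sequence, sequence[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def complementarity_scores(sequence: str) -> tuple[float, float]:
    """Self-complementarity (self_any, self_end) scores.

    The sequence is aligned against its own reverse complement at every
    ungapped offset; positions scoring +1 for a match and −1 for a mismatch.
    ``self_any`` is the best contiguous-window sum over all offsets (floored
    at 0); ``self_end`` restricts the window to ones ending at the
    sequence's 3'-terminal base, capturing primer-dimer extension risk.
    """
    seq = sequence.upper()
    rc = reverse_complement(seq)
    n = len(seq)
    best_any = 0.0
    best_end = 0.0
    for offset in range(-(n - 1), n):
        # seq[i] aligns with rc[i + offset]
        lo = max(0, -offset)
        hi = min(n, n - offset)
        run = 0.0
        best_here = 0.0
        suffix = 0.0
        for i in range(lo, hi):
            s = 1.0 if seq[i] == rc[i + offset] else -1.0
            run = max(0.0, run + s)
            best_here = max(best_here, run)
        best_any = max(best_any, best_here)
        # windows that end exactly at the 3' base (i = n-1)
        if lo <= n - 1 < hi:
            run = 0.0
            best_suffix = 0.0
            acc = 0.0
            for i in range(n - 1, lo - 1, -1):
                s = 1.0 if seq[i] == rc[i + offset] else -1.0
                acc += s
                best_suffix = max(best_suffix, acc)
            best_end = max(best_end, best_suffix)
    return best_any, best_end


# ---------------------------------------------------------------------------
# Candidate and pair enumeration
# ---------------------------------------------------------------------------

def _score_window(
    sequence: str,
    strand: str,
    start: int,
    length: int,
    params: DesignParameters,
    *,
    size_opt: int,
    tm_bounds: tuple[float, float, float],
    gc_bounds: tuple[float, float, float],
) -> Optional[PrimerCandidate]:
    """Build a candidate for one window, or None if any hard constraint fails."""
    if strand == "forward":
        primer = sequence[start:start + length]
        pos5 = start
    else:
        primer = reverse_complement(sequence[start:start + length])
        pos5 = start + length - 1
    if "N" in primer:
        return None
    if max_homopolymer_run(primer) > params.max_poly_x:
        return None
    gc = gc_percent(primer)
    gc_min, gc_opt, gc_max = gc_bounds
    if not (gc_min <= gc <= gc_max):
        return None
    tm_min, tm_opt, tm_max = tm_bounds
    tm = melting_temperature(primer, params)
    if not (tm_min <= tm <= tm_max):
        return None
    self_any, self_end = complementarity_scores(primer)
    if self_any > params.max_self_any or self_end > params.max_self_end:
        return None
    penalty = (
        params.wt_size * abs(length - size_opt)
        + params.wt_tm * abs(tm - tm_opt)
        + params.wt_gc * abs(gc - gc_opt)
    )
    return PrimerCandidate(
        strand=strand, start=pos5, length=length, sequence=primer,
        tm=tm, gc=gc, self_any=self_any, self_end=self_end, penalty=penalty,
    )


def candidate_primers(
    target_sequence: str,
    params: DesignParameters,
    *,
    role: str = "primer",
) -> list[PrimerCandidate]:
    """Exhaustively enumerate all primer candidates passing hard constraints.

    ``role="oligo"`` enumerates internal-oligo candidates (forward strand
    only, oligo size/Tm bounds). Order is deterministic: strand
    (forward first), then window start, then length.
    """
    seq = target_sequence.upper()
    n = len(seq)
    if role == "oligo":
        sizes = range(params.oligo_size_min, params.oligo_size_max + 1)
        tm_bounds = (params.oligo_tm_min, params.oligo_tm_opt, params.oligo_tm_max)
        size_opt = params.oligo_size_opt
        strands = ("forward",)
    else:
        sizes = range(params.size_min, params.size_max + 1)
        tm_bounds = (params.tm_min, params.tm_opt, params.tm_max)
        size_opt = params.size_opt
        strands = ("forward", "reverse")
    gc_bounds = (params.gc_min, params.gc_opt, params.gc_max)
    out: list[PrimerCandidate] = []
    for strand in strands:
        for start in range(n):
            for length in sizes:
                if start + length > n:
                    break
                cand = _score_window(
                    seq, strand, start, length, params,
                    size_opt=size_opt, tm_bounds=tm_bounds, gc_bounds=gc_bounds,
                )
                if cand is not None:
                    out.append(cand)
    return out


def _pair_penalty(f: PrimerCandidate, r: PrimerCandidate, product: int,
                  params: DesignParameters) -> float:
    return (
        f.penalty + r.penalty
        + params.wt_pair_diff_tm * abs(f.tm - r.tm)
        + params.wt_product_size * abs(product - params.product_size_ranges[0][0])
    )


def enumerate_pairs(
    candidates: Sequence[PrimerCandidate],
    params: DesignParameters,
    n_return: Optional[int] = None,
    *,
    target_sequence: Optional[str] = None,
    pair_id_prefix: str = "pair",
) -> list[PrimerPair]:
    """Pair forward and reverse candidates within the product-size ranges.

    A valid pair has the forward 5' end strictly left of the reverse 5' end,
    non-overlapping primer footprints, and a product size inside at least
    one configured range. Pairs come back sorted by (pair_penalty,
    amplicon_start, product_size, forward.start) and truncated to
    ``n_return``. When ``params.design_internal_oligo`` is set,
    ``target_sequence`` must be given and pairs without a feasible internal
    oligo strictly between the primers are dropped.
    """
    if n_return is None:
        n_return = params.num_return
    from bisect import bisect_left, bisect_right

    forwards = sorted(
        (c for c in candidates if c.strand == "forward"), key=lambda c: c.start
    )
    reverses = sorted(
        (c for c in candidates if c.strand == "reverse"), key=lambda c: c.start
    )
    rev_starts = [r.start for r in reverses]
    lo_product = min(lo for lo, _ in params.product_size_ranges)
    hi_product = max(hi for _, hi in params.product_size_ranges)
    scored: list[tuple[tuple, PrimerPair]] = []
    for f in forwards:
        f_end = f.start + f.length
        # reverse 5' ends compatible with some product-size range
        i_lo = bisect_left(rev_starts, f.start + lo_product - 1)
        i_hi = bisect_right(rev_starts, f.start + hi_product - 1)
        for r in reverses[i_lo:i_hi]:
            if r.start <= f.start:
                continue
            product = r.start + 1 - f.start
            if not any(lo <= product <= hi for lo, hi in params.product_size_ranges):
                continue
            if r.start - r.length + 1 < f_end:  # overlapping primers
                continue
            penalty = _pair_penalty(f, r, product, params)
            pair = PrimerPair(
                pair_id="",
                forward=f, reverse=r,
                amplicon_start=f.start, amplicon_end=r.start + 1,
                pair_penalty=penalty,
            )
            scored.append(((penalty, pair.amplicon_start, product, f.start), pair))
    scored.sort(key=lambda t: t[0])

    out: list[PrimerPair] = []
    oligo_pool: Optional[list[PrimerCandidate]] = None
    for _, pair in scored:
        if len(out) >= n_return:
            break
        if params.design_internal_oligo:
            if target_sequence is None:
                raise ValueError("internal-oligo design needs the target sequence")
            if oligo_pool is None:
                oligo_pool = candidate_primers(target_sequence, params, role="oligo")
            oligo = _best_internal_oligo(pair, oligo_pool)
            if oligo is None:
                continue
            pair = replace(pair, oligo=oligo)
        pair = replace(pair, pair_id=f"{pair_id_prefix}_{len(out) + 1}")
        out.append(pair)
    return out


def _best_internal_oligo(
    pair: PrimerPair, pool: Sequence[PrimerCandidate]
) -> Optional[PrimerCandidate]:
    """Lowest-penalty oligo lying strictly between the primers' footprints."""
    inner_lo = pair.forward.start + pair.forward.length
    inner_hi = pair.reverse.start - pair.reverse.length + 1
    best = None
    for cand in pool:
        lo, hi = cand.footprint
        if lo >= inner_lo and hi <= inner_hi:
            if best is None or (cand.penalty, cand.start) < (best.penalty, best.start):
                best = cand
    return best
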