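"""Primer design engine: parameter parsing, thermodynamics, candidate and
pair enumeration — each checked against an independent oracle."""

import itertools
import math

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt
from hypothesis import given, settings
from hypothesis import strategies as st

from msreprime.design_core import (
    DesignParameters,
    candidate_primers,
    complementarity_scores,
    enumerate_pairs,
    gc_percent,
    max_homopolymer_run,
    melting_temperature,
    parse_parameter_file,
    reverse_complement,
)

dna = st.text(alphabet="ACGT", min_size=2, max_size=36)


# ---------------------------------------------------------------------------
# Boulder-IO parameter file
# ---------------------------------------------------------------------------

class TestParameterFile:
    def test_single_key(self, tmp_path):
        p = tmp_path / "p3.txt"
        p.write_text("PRIMER_OPT_SIZE=20\n")
        assert parse_parameter_file(p).size_opt == 20

    def test_empty_file_gives_defaults(self, tmp_path):
        p = tmp_path / "p3.txt"
        p.write_text("")
        assert parse_parameter_file(p) == DesignParameters()

    def test_product_size_range_list(self, tmp_path):
        p = tmp_path / "p3.txt"
        p.write_text("PRIMER_PRODUCT_SIZE_RANGE=80-150 150-250\n")
        params = parse_parameter_file(p)
        assert params.product_size_ranges == ((80, 150), (150, 250))

    def test_unknown_key_warns(self, tmp_path):
        p = tmp_path / "p3.txt"
        p.write_text("PRIMER_MISPRIMING_LIBRARY=human\n")
        with pytest.warns(UserWarning, match="PRIMER_MISPRIMING_LIBRARY"):
            parse_parameter_file(p)

    def test_bad_numeric_is_hard_error(self, tmp_path):
        p = tmp_path / "p3.txt"
        p.write_text("PRIMER_OPT_TM=sixty\n")
        with pytest.raises(ValueError, match="PRIMER_OPT_TM"):
            parse_parameter_file(p)

    def test_record_terminator_stops_parse(self, tmp_path):
        p = tmp_path / "p3.txt"
        p.write_text("PRIMER_OPT_SIZE=19\n=\nPRIMER_OPT_SIZE=25\n")
        assert parse_parameter_file(p).size_opt == 19


# ---------------------------------------------------------------------------
# Melting temperature
# ---------------------------------------------------------------------------

def _nn_sum_oracle(seq, mono_mM, conc_nM):
    """Independent NN summation: unified duplex table keyed by all 16
    dinucleotides, written separately from the implementation."""
    dh_ds = {
        "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
        "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
        "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
        "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
        "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
        "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
        "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
        "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
    }
    dh = ds = 0.0
    for i in range(len(seq) - 1):
        h, s = dh_ds[seq[i:i + 2]]
        dh += h
        ds += s
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dh, ds = dh + 2.3, ds + 4.1
        else:
            dh, ds = dh + 0.1, ds - 2.8
    selfcomp = seq == reverse_complement(seq)
    if selfcomp:
        ds -= 1.4
    ds += 0.368 * (len(seq) - 1) * math.log(mono_mM / 1000.0)
    ct = conc_nM * 1e-9
    k = ct if selfcomp else ct / 4.0
    return 1000.0 * dh / (ds + 1.987 * math.log(k)) - 273.15


class TestMeltingTemperature:
    def test_frozen_oracle_value(self):
        # 20-mer at 50 mM monovalent, 250 nM oligo; value frozen from the
        # independent NN-sum oracle (self-complementary sequence)
        params = DesignParameters(salt_monovalent_mM=50, salt_divalent_mM=0,
                                  dntp_mM=0, oligo_conc_nM=250)
        tm = melting_temperature("ACGTACGTACGTACGTACGT", params)
        assert tm == pytest.approx(56.13054993779946, abs=1e-9)
        assert tm == pytest.approx(
            _nn_sum_oracle("ACGTACGTACGTACGTACGT", 50, 250), abs=1e-9
        )

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(seq=dna)
    def test_matches_independent_nn_sum(self, seq):
        params = DesignParameters(salt_monovalent_mM=50, salt_divalent_mM=0,
                                  dntp_mM=0, oligo_conc_nM=250)
        assert melting_temperature(seq, params) == pytest.approx(
            _nn_sum_oracle(seq, 50, 250), abs=1e-9
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seq=dna)
    def test_duplex_symmetry(self, seq):
        params = DesignParameters()
        assert melting_temperature(seq, params) == pytest.approx(
            melting_temperature(reverse_complement(seq), params), abs=1e-9
        )

    def test_matches_biopython_reference(self, rng):
        """Cross-check against an established implementation configured for
        the same table, salt correction, and strand concentration."""
        params = DesignParameters()
        for n in (18, 20, 25, 30):
            for _ in range(20):
                seq = "".join(rng.choice(list("ACGT"), size=n))
                selfcomp = seq == reverse_complement(seq)
                expected = mt.Tm_NN(
                    seq, nn_table=mt.DNA_NN3, Na=50, Mg=1.5, dNTPs=0.6,
                    dnac1=50 if selfcomp else 25, dnac2=0 if selfcomp else 25,
                    selfcomp=selfcomp, saltcorr=5,
                )
                assert melting_temperature(seq, params) == pytest.approx(
                    expected, abs=1e-9
                )

    def test_appending_gc_raises_tm(self, rng):
        params = DesignParameters()
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=16))
            assert melting_temperature(seq + "GC", params) > melting_temperature(
                seq, params
            )

    def test_ambiguous_base_is_error(self):
        with pytest.raises(ValueError, match="ambiguous"):
            melting_temperature("ACGTN", DesignParameters())


# ---------------------------------------------------------------------------
# Self-complementarity
# ---------------------------------------------------------------------------

def _complementarity_oracle(seq):
    """Exhaustive enumeration of every ungapped window at every offset."""
    rc = reverse_complement(seq)
    n = len(seq)
    best_any = 0.0
    best_end = 0.0
    for offset in range(-(n - 1), n):
        lo, hi = max(0, -offset), min(n, n - offset)
        for i in range(lo, hi):
            for j in range(i, hi):
                score = sum(
                    1.0 if seq[k] == rc[k + offset] else -1.0
                    for k in range(i, j + 1)
                )
                best_any = max(best_any, score)
                if j == n - 1:
                    best_end = max(best_end, score)
    return best_any, best_end


class TestComplementarity:
    def test_palindrome_scores_full_span(self):
        any_, end_ = complementarity_scores("ACGTACGT")
        assert any_ == 8.0

    def test_homopolymer_scores_zero(self):
        any_, end_ = complementarity_scores("AAAAAA")
        assert (any_, end_) == (0.0, 0.0)

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(seq=st.text(alphabet="ACGT", min_size=2, max_size=12))
    def test_matches_exhaustive_oracle(self, seq):
        assert complementarity_scores(seq) == _complementarity_oracle(seq)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seq=dna)
    def test_self_end_bounded_by_self_any(self, seq):
        any_, end_ = complementarity_scores(seq)
        assert end_ <= any_


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

def _check_hard_constraints(cand, params):
    assert params.size_min <= cand.length <= params.size_max
    assert params.tm_min <= cand.tm <= params.tm_max
    assert params.gc_min <= cand.gc <= params.gc_max
    assert cand.self_any <= params.max_self_any
    assert cand.self_end <= params.max_self_end
    assert max_homopolymer_run(cand.sequence) <= params.max_poly_x
    assert "N" not in cand.sequence


class TestCandidatePrimers:
    def test_short_target_gives_empty_list(self, relaxed_params):
        assert candidate_primers("ACGT", relaxed_params) == []

    def test_count_matches_closed_form_when_relaxed(self, rng, relaxed_params):
        target = "".join(rng.choice(list("ACGT"), size=30))
        out = candidate_primers(target, relaxed_params)
        n, smin, smax = 30, relaxed_params.size_min, relaxed_params.size_max
        expected = 2 * sum(n - L + 1 for L in range(smin, smax + 1))
        assert len(out) == expected

    def test_sequences_match_target_substrings(self, rng, relaxed_params):
        target = "".join(rng.choice(list("ACGT"), size=40))
        for cand in candidate_primers(target, relaxed_params):
            lo, hi = cand.footprint
            window = target[lo:hi]
            if cand.strand == "forward":
                assert cand.sequence == window
            else:
                assert cand.sequence == reverse_complement(window)

    def test_candidates_with_n_never_returned(self, relaxed_params):
        target = "ACGTACGTACGTACGTACGTNACGTACGTACGTACGTACGT"
        for cand in candidate_primers(target, relaxed_params):
            assert "N" not in cand.sequence

    def test_hard_constraint_soundness_fuzz(self, rng):
        params = DesignParameters(
            size_min=18, size_opt=20, size_max=23,
            tm_min=45.0, tm_opt=55.0, tm_max=65.0,
            product_size_ranges=((40, 200),),
        )
        for _ in range(10):
            target = "".join(rng.choice(list("ACGT"), size=80))
            for cand in candidate_primers(target, params):
                _check_hard_constraints(cand, params)

    def test_penalty_formula(self, rng, relaxed_params):
        target = "".join(rng.choice(list("ACGT"), size=30))
        p = relaxed_params
        for cand in candidate_primers(target, p):
            expected = (
                p.wt_size * abs(cand.length - p.size_opt)
                + p.wt_tm * abs(cand.tm - p.tm_opt)
                + p.wt_gc * abs(cand.gc - p.gc_opt)
            )
            assert cand.penalty == pytest.approx(expected)
            assert cand.penalty >= 0

    def test_deterministic(self, rng, relaxed_params):
        target = "".join(rng.choice(list("ACGT"), size=50))
        assert candidate_primers(target, relaxed_params) == candidate_primers(
            target, relaxed_params
        )


# ---------------------------------------------------------------------------
# Pair enumeration
# ---------------------------------------------------------------------------

def _brute_force_pairs(candidates, params):
    """All-pairs oracle with the same penalty and ordering rules."""
    pairs = []
    for f in candidates:
        if f.strand != "forward":
            continue
        for r in candidates:
            if r.strand != "reverse" or r.start <= f.start:
                continue
            product = r.start + 1 - f.start
            if not any(lo <= product <= hi
                       for lo, hi in params.product_size_ranges):
                continue
            if r.start - r.length + 1 < f.start + f.length:
                continue
            penalty = (
                f.penalty + r.penalty
                + params.wt_pair_diff_tm * abs(f.tm - r.tm)
                + params.wt_product_size
                * abs(product - params.product_size_ranges[0][0])
            )
            pairs.append((penalty, f.start, product, f, r))
    pairs.sort(key=lambda t: (t[0], t[3].start, t[2], t[3].start))
    return pairs


class TestEnumeratePairs:
    def test_no_valid_product_size_gives_empty(self, rng, relaxed_params):
        from dataclasses import replace
        params = replace(relaxed_params, product_size_ranges=((390, 400),))
        target = "".join(rng.choice(list("ACGT"), size=60))
        cands = candidate_primers(target, params)
        assert enumerate_pairs(cands, params, 5) == []

    def test_penalties_sorted_non_decreasing(self, rng, relaxed_params):
        target = "".join(rng.choice(list("ACGT"), size=60))
        cands = candidate_primers(target, relaxed_params)
        pairs = enumerate_pairs(cands, relaxed_params, 10)
        penalties = [p.pair_penalty for p in pairs]
        assert penalties == sorted(penalties)

    def test_product_size_equals_amplicon_span(self, rng, relaxed_params):
        target = "".join(rng.choice(list("ACGT"), size=60))
        cands = candidate_primers(target, relaxed_params)
        for pair in enumerate_pairs(cands, relaxed_params, 10):
            assert pair.product_size == pair.amplicon_end - pair.amplicon_start
            assert pair.amplicon_start == pair.forward.start
            assert pair.amplicon_end == pair.reverse.start + 1

    def test_top_pairs_match_brute_force(self, rng, relaxed_params):
        for _ in range(5):
            target = "".join(rng.choice(list("ACGT"), size=55))
            cands = candidate_primers(target, relaxed_params)
            got = enumerate_pairs(cands, relaxed_params, 8)
            expected = _brute_force_pairs(cands, relaxed_params)[:8]
            assert len(got) == len(expected)
            for pair, (penalty, _, product, f, r) in zip(got, expected):
                assert pair.pair_penalty == pytest.approx(penalty)
                assert (pair.forward, pair.reverse) == (f, r)

    def test_internal_oligo_strictly_between_primers(self, rng):
        params = DesignParameters(
            size_min=18, size_opt=20, size_max=22,
            tm_min=0.0, tm_opt=60.0, tm_max=200.0,
            gc_min=0.0, gc_opt=50.0, gc_max=100.0,
            product_size_ranges=((80, 120),),
            max_self_any=100.0, max_self_end=100.0, max_poly_x=50,
            design_internal_oligo=True,
            oligo_size_min=18, oligo_size_opt=20, oligo_size_max=22,
            oligo_tm_min=0.0, oligo_tm_opt=60.0, oligo_tm_max=200.0,
        )
        target = "".join(rng.choice(list("ACGT"), size=130))
        cands = candidate_primers(target, params)
        pairs = enumerate_pairs(cands, params, 5, target_sequence=target)
        assert pairs, "internal-oligo design found no pair"
        for pair in pairs:
            assert pair.oligo is not None
            o_lo, o_hi = pair.oligo.footprint
            assert o_lo >= pair.forward.start + pair.forward.length
            assert o_hi <= pair.reverse.start - pair.reverse.length + 1
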