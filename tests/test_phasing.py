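import itertools
import math
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from phasekit.io import RunConfig
from phasekit.preprocess import Alignment, CollapsedRead
from phasekit.phasing import (
    PhaseWindow,
    call_phas_loci,
    merge_windows,
    phas_pvalue,
    phas_pmf,
    phasing_score,
    register_position,
    scan_windows,
    window_filter,
)

_counter = itertools.count()


def mk_aln(pos, strand="+", length=21, count=1, ref="chr1", seq=None):
    """A distinct synthetic alignment (unique sequence per call unless given)."""
    if seq is None:
        i = next(_counter)
        seq = ("ACGT"[i % 4] + format(i, "016d"))[:length].ljust(length, "A")
    read = CollapsedRead(seq=seq, count=count, rpm=100.0)
    start = pos if strand == "+" else pos - 2  # leftmost coordinate convention
    return Alignment(read=read, ref_id=ref, strand=strand, start=start, hits=1)


def oracle_pvalue(n, k, m, register_len=21):
    """Exact-rational brute-force tail of the phasing hypergeometric."""
    total, white = register_len * m, m
    denom = math.comb(total, n)
    acc = Fraction(0)
    for x in range(k, min(n, m) + 1):
        acc += Fraction(math.comb(total - white, n - x) * math.comb(white, x), denom)
    return acc


class TestRegisterPosition:
    def test_plus_strand_uses_five_prime_end(self):
        assert register_position(mk_aln(0)) == 0

    def test_minus_strand_gets_duplex_overhang_offset(self):
        # leftmost coordinate 19 -> phase coordinate 21 -> register 0
        a = Alignment(CollapsedRead("A" * 21, 1), "chr1", "-", 19, 1)
        assert register_position(a) == 21
        assert register_position(a) % 21 == 0

    def test_register_arithmetic(self):
        assert (44 - 2) % 21 == 0  # plus read at 44 in a window starting at 2


class TestPvalue:
    def test_tail_from_zero_is_one(self):
        assert phas_pvalue(12, 0, 9) == 1.0

    def test_spot_value_exact(self):
        assert phas_pvalue(3, 3, 9) == pytest.approx(84 / 1_107_414, rel=1e-12)

    def test_matches_bruteforce_oracle(self):
        assert phas_pvalue(12, 5, 9) == pytest.approx(float(oracle_pvalue(12, 5, 9)), rel=1e-9)
        assert phas_pvalue(20, 7, 9, 24) == pytest.approx(
            float(oracle_pvalue(20, 7, 9, 24)), rel=1e-9
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            phas_pvalue(3, 4, 9)
        with pytest.raises(ValueError):
            phas_pvalue(5, 6, 5)
        with pytest.raises(ValueError):
            phas_pvalue(200, 3, 9)

    def test_monotone_in_k_and_normalized(self):
        for n in (5, 12, 25):
            ps = [phas_pvalue(n, k, 9) for k in range(min(n, 9) + 1)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))
            total = sum(phas_pmf(x, n, 9) for x in range(max(0, n - 180), min(n, 9) + 1))
            assert total == pytest.approx(1.0, abs=1e-12)


class TestPhasingScore:
    def test_closed_form(self):
        assert phasing_score(50, 4, 5) == pytest.approx(3 * math.log(101))

    def test_degenerate_cases(self):
        assert phasing_score(123.0, 0, 2) == 0.0  # too few occupied registers
        assert phasing_score(0.0, 7, 8) == 0.0  # no in-phase abundance


def window(n_all, n_reg, k, pvalue=1.0, score=0.0, start=0, offset=0, reg=21):
    return PhaseWindow(
        ref_id="chr1", start=start, register_len=reg, cycles=9, phase_offset=offset,
        n_unique_all=n_all, n_unique_reg=n_reg, n_positions=k, k_inphase=k,
        occupied_registers=k, inphase_abundance=10.0, outphase_unique=0,
        pvalue=pvalue, score=score,
    )


class TestWindowFilter:
    def test_thresholds(self):
        cfg = RunConfig()
        assert window_filter(window(9, 9, 9), cfg) == (False, "unique<10")
        ok, why = window_filter(window(10, 5, 5), cfg)
        assert not ok and "half" in why  # exactly half is not "more than half"
        assert window_filter(window(10, 6, 2), cfg)[0] is False
        assert window_filter(window(10, 6, 3), cfg)[0] is True


class TestCalling:
    def test_pvalue_cutoff_is_strict(self):
        cfg = RunConfig()
        assert call_phas_loci([window(20, 15, 9, pvalue=0.001)], cfg) == []
        assert len(call_phas_loci([window(20, 15, 9, pvalue=0.0009999)], cfg)) == 1

    def test_24nt_score_cutoff_is_inclusive(self):
        cfg = RunConfig(register_len=24)
        assert len(call_phas_loci([window(20, 15, 9, score=15.0, reg=24)], cfg)) == 1
        assert call_phas_loci([window(20, 15, 9, score=14.99, reg=24)], cfg) == []

    def test_no_positive_windows(self):
        assert call_phas_loci([], RunConfig()) == []


class TestMerging:
    def test_same_register_adjacent_windows_merge(self):
        w1 = window(20, 15, 9, pvalue=1e-5, start=0, offset=0)
        w2 = window(20, 15, 9, pvalue=1e-7, start=63, offset=0)
        w2.phase_offset = (0 - 63) % 21  # same absolute residue 0
        (locus,) = merge_windows([w1, w2])
        assert (locus.start, locus.end) == (0, 252)
        assert locus.best_pvalue == 1e-7 and locus.window_count == 2

    def test_different_residue_does_not_merge(self):
        w1 = window(20, 15, 9, start=0, offset=0)
        w2 = window(20, 15, 9, start=63, offset=1)
        assert len(merge_windows([w1, w2])) == 2

    def test_single_window_locus_span(self):
        (locus,) = merge_windows([window(20, 15, 9, start=42)])
        assert locus.end - locus.start == 189


def phased_alignments(first_pos, n_cycles=9, reg=21, offset_within=0):
    """Sense/antisense duplexes at perfect reg-spacing from first_pos."""
    alns = []
    for i in range(n_cycles):
        p = first_pos + i * reg + offset_within
        alns.append(mk_aln(p, "+", length=reg))
        alns.append(mk_aln(p, "-", length=reg))
    return alns


class TestScanWindows:
    def test_window_grid_enumeration(self):
        cfg = RunConfig()
        # oracle: every start with start + 189 <= 400 under step 63
        expected = [s for s in range(0, 400, 63) if s + 189 <= 400]
        assert expected == [0, 63, 126, 189]
        alns = phased_alignments(0, n_cycles=19)  # cover the whole reference
        wins = scan_windows(alns, {"chr1": 400}, cfg)
        assert {w.start for w in wins} == set(expected)

    def test_no_alignments_no_windows(self):
        assert scan_windows([], {"chr1": 10_000}, RunConfig()) == []

    def test_dominant_register_and_k(self):
        cfg = RunConfig()
        alns = [mk_aln(5 + i * 21) for i in range(9)] + [mk_aln(7), mk_aln(11)]
        (w,) = scan_windows(alns, {"chr1": 189}, cfg)
        assert w.phase_offset == 5 and w.k_inphase == 9
        assert w.n_unique_all == 11

    def test_translation_by_one_step_is_exact(self):
        cfg = RunConfig()
        alns = phased_alignments(100) + [mk_aln(130), mk_aln(150, "-")]
        base = call_phas_loci(scan_windows(alns, {"chr1": 800}, cfg), cfg)
        shifted_alns = [
            Alignment(a.read, a.ref_id, a.strand, a.start + 63, a.hits) for a in alns
        ]
        shifted = call_phas_loci(scan_windows(shifted_alns, {"chr1": 863}, cfg), cfg)
        assert [(l.start - 63, l.end - 63, l.phase_offset) for l in shifted] == [
            (l.start, l.end, (l.phase_offset + 63) % 21) for l in base
        ]

    def test_translation_by_one_register_preserves_detection(self):
        # a 21-nt shift moves reads off the 63-nt window grid, so locus
        # boundaries may shift by a step, but the locus is still found with
        # the shifted phase residue and covers the shifted reads
        cfg = RunConfig()
        alns = phased_alignments(100)
        (base,) = call_phas_loci(scan_windows(alns, {"chr1": 800}, cfg), cfg)
        shifted_alns = [
            Alignment(a.read, a.ref_id, a.strand, a.start + 21, a.hits) for a in alns
        ]
        (shifted,) = call_phas_loci(scan_windows(shifted_alns, {"chr1": 821}, cfg), cfg)
        assert shifted.phase_offset == (base.phase_offset + 21) % 21
        assert shifted.start <= 121 and shifted.end >= 121 + 9 * 21
        assert abs((shifted.start - 21) - base.start) <= cfg.step

    def test_duplex_strand_symmetry_in_tallies(self):
        cfg = RunConfig()
        both = scan_windows(phased_alignments(0), {"chr1": 189}, cfg)
        sense_only = [a for a in phased_alignments(0) if a.strand == "+"]
        # sense-only halves the read count but occupies the same registers
        w = both[0]
        assert w.k_inphase == 9 and w.outphase_unique == 0
        assert w.phase_offset == 0
        assert all(register_position(a) % 21 == 0 for a in sense_only)
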