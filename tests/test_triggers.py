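import shutil

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phasekit.io import SequenceRecord, revcomp
from phasekit.preprocess import Alignment, CollapsedRead
from phasekit.phasing import PhasLocus
from phasekit.triggers import (
    EncodedTarget,
    TriggerCandidate,
    align_srna_target,
    annotate_mirna,
    classify_target,
    classify_trigger_model,
    degradome_support,
    evaluate_hairpin,
    filter_triggers,
    phase_consistency,
    scan_target,
    _IDX,
    _PEN,
)

SRNA = "TAGCTAGCTAGCTAGCTAGCT"  # 21 nt


def site_for(srna, mutate=None):
    """Forward-orientation target site perfectly complementary to srna,
    optionally with the base paired to sRNA position ``mutate[0]`` (1-based)
    replaced by ``mutate[1]``."""
    site = list(revcomp(srna))
    if mutate:
        pos, base = mutate
        site[len(srna) - pos] = base
    return "".join(site)


class TestAlignScore:
    def test_perfect_complement_scores_zero(self):
        a = align_srna_target(SRNA, "GG" + site_for(SRNA) + "AA")
        assert a.score == 0.0 and a.variant == "ungapped"
        assert (a.target_start, a.target_end) == (2, 23)

    def test_gu_wobble_outside_core(self):
        # sRNA position 15 is G; target U(T) opposite it is a 0.5 wobble
        srna = SRNA[:14] + "G" + SRNA[15:]
        a = align_srna_target(srna, site_for(srna, mutate=(15, "T")))
        assert a.score == 0.5

    def test_mismatch_in_core_is_doubled(self):
        # position 5 (T); a T opposite it is a plain mismatch, doubled in 2-13
        a = align_srna_target(SRNA, site_for(SRNA, mutate=(5, "T")))
        assert a.score == 2.0

    def test_window_shorter_than_srna(self):
        assert align_srna_target(SRNA, "ACGT") is None

    def test_cleavage_opposite_position_ten(self):
        window = "GGGG" + site_for(SRNA) + "CCCC"
        a = align_srna_target(SRNA, window)
        # site is [4, 25); sRNA position 10 pairs window base 25 - 10
        assert a.cleavage_pos == 15


def brute_best(srna, window):
    """Exhaustive enumeration of ungapped and single-bulge duplexes."""
    t = revcomp(window)
    L, Lt = len(srna), len(t)
    w = [2.0 if 1 <= i <= 12 else 1.0 for i in range(L)]
    pen = lambda s, tb: _PEN[_IDX[s], _IDX[tb]]
    best = float("inf")
    for j in range(Lt - L + 1):
        best = min(best, sum(pen(srna[i], t[j + i]) * w[i] for i in range(L)))
    for j in range(Lt - L):
        for p in range(1, L):
            sc = (
                sum(pen(srna[i], t[j + i]) * w[i] for i in range(p))
                + sum(pen(srna[i], t[j + i + 1]) * w[i] for i in range(p, L))
                + 2 * w[p]
            )
            best = min(best, sc)
    for j in range(Lt - (L - 1) + 1):
        for p in range(1, L - 1):
            sc = (
                sum(pen(srna[i], t[j + i]) * w[i] for i in range(p))
                + sum(pen(srna[i], t[j + i - 1]) * w[i] for i in range(p + 1, L))
                + 2 * w[p]
            )
            best = min(best, sc)
    return best


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.data())
def test_aligner_matches_exhaustive_enumeration(data):
    bases = "ACGT"
    L = data.draw(st.integers(19, 23))
    Lw = data.draw(st.integers(L, 60))
    srna = "".join(data.draw(st.sampled_from(bases)) for _ in range(L))
    window = "".join(data.draw(st.sampled_from(bases)) for _ in range(Lw))
    got = align_srna_target(srna, window).score
    assert got == pytest.approx(brute_best(srna, window), abs=1e-9)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.data())
def test_orientation_scan_is_mirror_consistent(data):
    # scanning the reverse complement of a window in '-' orientation must
    # report the same duplexes, at mirrored coordinates, as the forward scan
    bases = "ACGT"
    srna = "".join(data.draw(st.sampled_from(bases)) for _ in range(21))
    window = "".join(data.draw(st.sampled_from(bases)) for _ in range(40))
    fwd = scan_target(srna, EncodedTarget("w", window), max_score=1e9, orientation="+")
    rev = scan_target(
        srna, EncodedTarget("w", revcomp(window)), max_score=1e9, orientation="-"
    )
    Lw = len(window)
    fwd_set = {(h.score, h.target_start, h.target_end, h.cleavage_pos) for h in fwd}
    rev_set = {
        (h.score, Lw - h.target_end, Lw - h.target_start, Lw - 1 - h.cleavage_pos)
        for h in rev
    }
    assert fwd_set == rev_set


def _locus(start=1000, end=1210, reg=21):
    return PhasLocus(
        ref_id="chr1", start=start, end=end, register_len=reg,
        phase_offset=start % reg, best_pvalue=1e-6, best_phasing_score=20.0,
        window_count=1, locus_id="L",
    )


class TestPhaseConsistency:
    def test_cleavage_on_register(self):
        loc = _locus(1000)
        assert phase_consistency(1000, loc) == "in_phase"
        assert phase_consistency(1000 - 42, loc) == "in_phase"  # 2 registers upstream
        assert phase_consistency(1010, loc) == "out_of_phase"


def _cand(phase, length=21, status="putative", match=None, cleavage=0, deg="no_data"):
    return TriggerCandidate(
        alignment=None, locus=_locus(), end="5prime", trigger_len=length,
        genomic_site=(cleavage - 11, cleavage + 10), genomic_cleavage=cleavage,
        phase_relation=phase, mirna_status=status, matched_mirna=match, degradome=deg,
    )


class TestFilterAndModel:
    def test_out_of_phase_unknown_dropped(self):
        kept, dropped = filter_triggers([_cand("out_of_phase")], whitelist=set())
        assert kept == [] and dropped["out_of_phase_unknown"] == 1

    def test_out_of_phase_whitelisted_known_kept(self):
        c = _cand("out_of_phase", status="known", match="ath-miR482a")
        kept, _ = filter_triggers([c], whitelist={"mir482"})
        assert kept == [c]
        validated = _cand("out_of_phase", status="known", match="novel-x", deg="validated")
        kept, _ = filter_triggers([validated], whitelist=set())
        assert kept == [validated]

    def test_in_phase_putative_kept(self):
        c = _cand("in_phase")
        assert filter_triggers([c], whitelist=set())[0] == [c]

    def test_model_classification(self):
        two = [_cand("in_phase", cleavage=0), _cand("in_phase", cleavage=210)]
        assert classify_trigger_model(two) == "two_hit"
        assert classify_trigger_model([_cand("in_phase", length=22)]) == "one_hit_22"
        assert classify_trigger_model([_cand("in_phase", length=21)]) == "unclassified"

    def test_alignment_variants_of_one_site_are_one_hit(self):
        variants = [_cand("in_phase", cleavage=c) for c in (100, 101, 100)]
        assert classify_trigger_model(variants) == "unclassified"


class TestAnnotateMirna:
    known = [SequenceRecord("osa-miR2118a", "TTGCCGATTCCACCCATTCCTA")]

    def test_exact_match(self):
        assert annotate_mirna("TTGCCGATTCCACCCATTCCTA", self.known) == (
            "known", "osa-miR2118a"
        )

    def test_two_mismatches_known_three_putative(self):
        two = "AAGCCGATTCCACCCATTCCTA"
        three = "AAACCGATTCCACCCATTCCTA"
        assert annotate_mirna(two, self.known)[0] == "known"
        assert annotate_mirna(three, self.known)[0] == "putative"

    def test_empty_known_set(self):
        assert annotate_mirna(SRNA, []) == ("putative", None)


class TestDegradome:
    deg = {"chr1": {1000: 10, 1500: 1}}

    def test_validated_at_cleavage(self):
        assert degradome_support("chr1", 1000, self.deg) == "validated"
        assert degradome_support("chr1", 1001, self.deg) == "validated"  # +/-1 nt

    def test_unsupported_and_no_data(self):
        assert degradome_support("chr1", 1005, self.deg) == "unsupported"
        assert degradome_support("chr1", 1500, self.deg) == "unsupported"  # below 2 reads
        assert degradome_support("chr1", 1000, None) == "no_data"


class TestHairpin:
    def test_inverted_repeat_or_no_engine(self):
        rng = np.random.default_rng(5)
        arm = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        srna = arm[30:51]
        hairpin = arm + "TTTTT" + revcomp(arm)
        genome = {"chr1": "A" * 50 + hairpin + "C" * 50}
        pl = [Alignment(CollapsedRead(srna, 1), "chr1", "+", 50 + 30, 1)]
        (verdict,) = evaluate_hairpin(srna, genome, pl)
        if shutil.which("RNAfold") is None:
            assert verdict == "no_engine"
        else:
            assert verdict == "plausible_mirna"

    def test_homopolymer_context_is_not_hairpin(self):
        if shutil.which("RNAfold") is None:
            pytest.skip("folding engine not installed")
        srna = "A" * 21
        genome = {"chr1": "A" * 400}
        pl = [Alignment(CollapsedRead(srna, 1), "chr1", "+", 200, 1)]
        assert evaluate_hairpin(srna, genome, pl) == ["not_hairpin"]


class TestClassifyTarget:
    fams = {"gA": "NBS", "gB": "NBS", "gC": "PPR"}

    def test_relations(self):
        assert classify_target("gA", "gA", self.fams) == "cis"
        assert classify_target("gB", "gA", self.fams) == "same_family"
        assert classify_target("gC", "gA", self.fams) == "trans"

    def test_missing_gene_is_singleton_family(self):
        assert classify_target("gX", "gA", self.fams) == "trans"
        assert classify_target("gX", "gX", self.fams) == "cis"
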