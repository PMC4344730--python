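import numpy as np
import pytest

from conftest import random_dna
from oracles import hairpin_mfe_enumeration

from helhunt.seqio import GenomicSequence, Region, reverse_complement
from helhunt.structure_annotate import (
    LOOP_A,
    LOOP_B,
    MISMATCH_PENALTY,
    NN_STACK,
    AnnotationConfig,
    Hairpin,
    annotate_element,
    classify_element,
    find_inverted_repeats,
    find_microsatellites,
    find_termini,
    fold_hairpin,
)

GS = GenomicSequence

OPEN_CFG = AnnotationConfig(dg_ceiling=1e9)  # no reporting ceiling (oracle tests)


class TestTermini:
    def test_both_termini_with_canonical_flanks(self):
        elem = GS("e", "TCCAG" + "A" * 40 + "GGCTAG")
        calls = find_termini(elem, context=("GGGA", "TGGG"))
        kinds = {c.kind: c for c in calls}
        t5, t3 = kinds["five_prime"], kinds["three_prime"]
        assert t5.position == 1 and t5.motif == "TCC"
        assert t3.motif == "CTAG" and t3.position == len(elem) - 3
        assert t5.flanking_dinucleotide == "GA" and t3.flanking_dinucleotide == "TG"
        assert t5.matches_canonical and t3.matches_canonical

    def test_non_at_flank_fails_canonical_rule(self):
        elem = GS("e", "TC" + "A" * 40 + "CTAG")
        calls = find_termini(elem, context=("GGGC", "CGGG"))
        assert not any(c.matches_canonical for c in calls)

    def test_no_termini_in_homopolymer(self):
        assert find_termini(GS("e", "G" * 60)) == []

    def test_ctgg_is_valid_purine_terminus(self):
        elem = GS("e", "TC" + "A" * 40 + "CTGG")
        t3 = [c for c in find_termini(elem) if c.kind == "three_prime"][0]
        assert t3.motif == "CTGG"

    def test_rightmost_ctrr_wins(self):
        elem = GS("e", "TC" + "A" * 34 + "CTAA" + "AA" + "CTAG")
        t3 = [c for c in find_termini(elem) if c.kind == "three_prime"][0]
        assert t3.position == len(elem) - 3 and t3.motif == "CTAG"

    def test_end_window_larger_than_element_rejected(self):
        with pytest.raises(ValueError):
            find_termini(GS("e", "ACGT"), end_window=10)


class TestFoldHairpin:
    def test_textbook_stem_loop(self):
        hp = fold_hairpin(GS("w", "GGGGAAAACCCC"), OPEN_CFG)
        assert hp is not None
        assert (hp.left_arm.start, hp.left_arm.end) == (1, 4)
        assert (hp.right_arm.start, hp.right_arm.end) == (9, 12)
        assert hp.loop_len == 4 and hp.mismatches_in_stem == 0
        # hand-summed: three GG stacks + tetraloop penalty
        assert hp.dG == pytest.approx(3 * NN_STACK["GG"] + LOOP_A + LOOP_B, abs=0.005)

    def test_homopolymer_has_no_hairpin(self):
        assert fold_hairpin(GS("w", "A" * 20), OPEN_CFG) is None

    def test_mismatch_destabilises_stem(self):
        perfect = "GCGCGC" + "TTTT" + "GCGCGC"
        # break the middle pair of the stem
        broken = "GCG" + "A" + "GC" + "TTTT" + "GCGCGC"
        dg_perfect = fold_hairpin(GS("w", perfect), OPEN_CFG).dG
        dg_broken = fold_hairpin(GS("w", broken), OPEN_CFG).dG
        assert dg_broken > dg_perfect

    @pytest.mark.parametrize("batch", range(10))
    def test_mfe_matches_exhaustive_enumeration(self, batch):
        """50 random windows per batch (500 total) <= 30 nt: the kernel's
        minimum free energy equals the structure-enumeration oracle."""
        rng = np.random.default_rng(7000 + batch)
        cfg = OPEN_CFG
        for _ in range(50):
            n = int(rng.integers(11, 31))
            s = random_dna(rng, n)
            got = fold_hairpin(GS("w", s), cfg)
            want = hairpin_mfe_enumeration(
                s, NN_STACK, LOOP_A, LOOP_B, MISMATCH_PENALTY,
                cfg.min_stem, cfg.max_stem_mismatch, cfg.min_loop,
            )
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert got.dG == pytest.approx(want[0], abs=0.005)

    def test_reverse_complement_window_has_same_mfe(self, rng):
        for _ in range(20):
            s = random_dna(rng, 28)
            a = fold_hairpin(GS("w", s), OPEN_CFG)
            b = fold_hairpin(GS("w", reverse_complement(s)), OPEN_CFG)
            if a is None:
                assert b is None
            else:
                assert b is not None and b.dG == pytest.approx(a.dG, abs=0.005)

    def test_window_length_cap(self):
        with pytest.raises(ValueError):
            fold_hairpin(GS("w", "A" * 201))


class TestInvertedRepeats:
    def test_planted_five_prime_ir(self, rng):
        arm = "ACGGTACGTT"
        filler = random_dna(rng, 250)
        s = filler[:4] + arm + filler[14:29] + reverse_complement(arm) + filler[39:]
        pairs = find_inverted_repeats(GS("e", s), min_arm=10, max_mismatch=0)
        ir5 = [p for p in pairs if p.kind == "five_prime_IR"]
        assert any(
            p.arm_a.start == 5 and p.arm_b.start == 30 and p.arm_len >= 10 for p in ir5
        )

    def test_planted_sir_detected(self, rng):
        arm = "ACGGTACGTTAC"
        filler = random_dna(rng, 300)
        n = len(filler)
        s = (filler[:19] + arm + filler[31 : n - 60]
             + reverse_complement(arm) + filler[n - 48 :])
        pairs = find_inverted_repeats(GS("e", s), min_arm=12, max_mismatch=0)
        assert any(p.kind == "SIR" and p.arm_a.start == 20 for p in pairs)

    def test_random_sequence_almost_surely_empty_at_arm_12(self):
        # closed-form expected count ~ 0.25^12 * pair count << 1
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(8000 + seed)
            pairs = find_inverted_repeats(GS("e", random_dna(rng, 250)),
                                          min_arm=12, max_mismatch=0)
            hits += len(pairs)
        assert hits == 0

    def test_min_arm_validation(self):
        with pytest.raises(ValueError):
            find_inverted_repeats(GS("e", "ACGT" * 20), min_arm=3)


class TestMicrosatellites:
    def test_ctgt_array(self):
        out = find_microsatellites(GS("e", "CTGTCTGTCTGTCTGT"))
        assert len(out) == 1
        assert out[0].unit == "CTGT" and out[0].copies == 4.0
        assert out[0].span.span == (1, 16)

    def test_gttt_array(self):
        out = find_microsatellites(GS("e", "GTTTGTTTGTTT"))
        assert out[0].unit == "GTTT" and out[0].copies == 3.0

    def test_below_min_copies_empty(self):
        assert find_microsatellites(GS("e", "CTGTCTGA")) == []

    def test_fractional_final_unit(self):
        out = find_microsatellites(GS("e", "ACTGTCTGTCTGTCTA"))
        assert out and out[0].copies == pytest.approx(3.5)
        m = out[0]
        assert len(m.span) == int(m.copies * 4)

    def test_arrays_never_overlap_and_span_bound(self, rng):
        for _ in range(30):
            s = random_dna(rng, 60) + "CTGT" * int(rng.integers(3, 7)) + random_dna(rng, 60)
            arrays = find_microsatellites(GS("e", s))
            spans = sorted(a.span.span for a in arrays)
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                assert b1 < a2
            for a in arrays:
                assert a.copies * len(a.unit) <= len(a.span) + len(a.unit) - 1

    def test_empty_units_rejected(self):
        with pytest.raises(ValueError):
            find_microsatellites(GS("e", "ACGT"), units=[])


class TestClassifyAndAnnotate:
    def _t5(self):
        from helhunt.structure_annotate import TerminusCall
        return TerminusCall("five_prime", 1, "TC", "CA", True)

    def _t3(self):
        from helhunt.structure_annotate import TerminusCall
        return TerminusCall("three_prime", 290, "CTAG", "TG", True)

    def _hp(self):
        return Hairpin(Region("e", 250, 257), Region("e", 262, 269), 4, 0, -9.0)

    def test_full_tier(self):
        a = classify_element(Region("e", 1, 300), [self._t5(), self._t3()], self._hp())
        assert a.tier == "full"

    def test_single_terminus_with_hairpin_is_partial(self):
        a = classify_element(Region("e", 1, 300), [self._t3()], self._hp())
        assert a.tier == "partial"

    def test_both_termini_without_hairpin_is_partial(self):
        a = classify_element(Region("e", 1, 300), [self._t5(), self._t3()], None)
        assert a.tier == "partial"

    def test_structural_only_from_hairpin(self):
        a = classify_element(Region("e", 1, 300), [], self._hp())
        assert a.tier == "structural_only"

    def test_no_features_rejected(self):
        a = classify_element(Region("e", 1, 300), [], None)
        assert a.tier == "rejected"

    @pytest.mark.parametrize("seed", range(12))
    def test_rendered_template_annotates_full_with_exact_termini(self, seed):
        """Zero-divergence synthetic elements: exact terminus positions and
        tier = full, every time."""
        from helhunt.synthetic_data import render_template

        rend = render_template(seed=seed)
        anno = annotate_element(rend.sequence, ("CCGA", "TGCC"))
        assert anno.tier == "full"
        t5 = next(t for t in anno.termini if t.kind == "five_prime")
        t3 = next(t for t in anno.termini if t.kind == "three_prime")
        assert t5.position == rend.features["terminus_5p"].start
        assert t3.position == rend.features["terminus_3p"].start
        assert any(p.kind == "SIR" for p in anno.irs)
        assert any(m.unit == "CTGT" for m in anno.microsatellites)
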