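import numpy as np
import pytest

from conftest import random_dna
from oracles import enumerate_local_best

from helhunt.homology_scan import (
    HomologyHit,
    ScoringScheme,
    default_score_floor,
    evalue,
    filter_hits,
    local_align,
)
from helhunt.seqio import GenomicSequence, Region, reverse_complement

GS = GenomicSequence


def _hit(identity=80.0, ev=1e-8, cls="full_length", qlen=100, qlo=1, qhi=100):
    return HomologyHit(
        query_span=Region("q", qlo, qhi),
        subject_span=Region("s", 1000, 1000 + (qhi - qlo)),
        strand="+",
        score=100.0,
        identity_pct=identity,
        evalue=ev,
        coverage_class=cls,
    )


class TestLocalAlign:
    def test_exact_embedded_query(self):
        q = GS("q", "ACGGACGT")
        s = GS("s", "TTTTT" + q.residues + "CCCCC")
        hits = local_align(q, s, score_floor=10)
        top = hits[0]
        assert top.identity_pct == 100.0
        assert top.score == 8 * 2.0
        assert top.subject_span.span == (6, 13)
        assert top.coverage_class == "full_length"

    def test_reverse_complement_found_on_minus_strand(self, rng):
        q = GS("q", random_dna(rng, 40))
        host = random_dna(rng, 200)
        s = GS("s", host[:100] + reverse_complement(q.residues) + host[100:])
        hits = local_align(q, s, score_floor=30)
        top = hits[0]
        assert top.strand == "-"
        assert top.identity_pct == 100.0
        assert top.subject_span.span == (101, 140)

    def test_strand_invariance(self, rng):
        q = GS("q", random_dna(rng, 30))
        s = GS("s", random_dna(rng, 55) + q.residues + random_dna(rng, 60))
        fwd = local_align(q, s, score_floor=25)
        rev = local_align(q, GS("s", reverse_complement(s.residues)), score_floor=25)
        n = len(s)
        fset = {(h.subject_span.span, h.strand, h.score) for h in fwd}
        rset = {
            ((n - h.subject_span.span[1] + 1, n - h.subject_span.span[0] + 1),
             "+" if h.strand == "-" else "-", h.score)
            for h in rev
        }
        assert fset == rset

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align(GS("q", "ACGT"), GenomicSequence("s", ""))

    @pytest.mark.parametrize("case", range(100))
    def test_score_matches_exhaustive_oracle(self, case):
        """DP optimum equals brute-force max over all substring-pair global
        alignments on short random pairs."""
        rng = np.random.default_rng(3000 + case)
        a = random_dna(rng, int(rng.integers(2, 7)), "ACG")
        b = random_dna(rng, int(rng.integers(2, 7)), "ACG")
        scoring = ScoringScheme(match=2, mismatch=-3, gap_open=5, gap_extend=2)
        hits = local_align(GS("a", a), GS("b", b), scoring,
                           score_floor=1e-6, max_hits=1, both_strands=False)
        got = hits[0].score if hits else 0.0
        want = enumerate_local_best(a, b, 2, -3, 5, 2)
        assert got == pytest.approx(want, abs=1e-9)

    def test_suboptimal_hits_do_not_overlap_on_subject(self, rng):
        q = GS("q", random_dna(rng, 40))
        s = GS(
            "s",
            random_dna(rng, 50) + q.residues + random_dna(rng, 50)
            + q.residues + random_dna(rng, 50),
        )
        hits = [h for h in local_align(q, s, score_floor=40) if h.strand == "+"]
        assert len(hits) >= 2
        spans = sorted(h.subject_span.span for h in hits)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            assert b1 < a2


class TestEvalue:
    def test_score_zero_is_kmn(self):
        sc = ScoringScheme()
        assert evalue(0, 100, 1000, sc) == pytest.approx(sc.karlin_K * 100 * 1000)

    def test_linear_in_subject_length(self):
        sc = ScoringScheme()
        assert evalue(10, 100, 2000, sc) == pytest.approx(2 * evalue(10, 100, 1000, sc))

    def test_closed_form_value(self):
        sc = ScoringScheme(karlin_lambda=1.37, karlin_K=0.711)
        got = evalue(40, 250, 10**6, sc)
        want = 0.711 * 250 * 1e6 * np.exp(-1.37 * 40)
        assert got == pytest.approx(want, rel=1e-12)

    def test_strictly_decreasing_in_score(self):
        sc = ScoringScheme()
        es = [evalue(s, 300, 5000, sc) for s in range(0, 100, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))


class TestFilterHits:
    def test_identity_just_below_threshold_rejected(self):
        assert filter_hits([_hit(identity=64.9, ev=1e-8)]) == []

    def test_evalue_above_threshold_rejected(self):
        assert filter_hits([_hit(identity=80.0, ev=1e-3)]) == []

    def test_terminal_partial_retained(self):
        h = _hit(identity=70.0, ev=1e-6, cls="five_prime_partial", qlen=300, qlo=1, qhi=52)
        assert filter_hits([h]) == [h]

    def test_short_terminal_partial_rejected(self):
        h = _hit(identity=70.0, ev=1e-6, cls="five_prime_partial", qlen=300, qlo=1, qhi=40)
        assert filter_hits([h]) == []

    def test_internal_hit_rejected_regardless_of_length(self):
        h = _hit(identity=90.0, ev=1e-20, cls="internal", qlo=100, qhi=220)
        assert filter_hits([h]) == []

    def test_empty_in_empty_out(self):
        assert filter_hits([]) == []

    def test_monotone_in_thresholds(self, rng):
        hits = [
            _hit(identity=float(rng.uniform(50, 100)), ev=float(10.0 ** rng.uniform(-20, 0)))
            for _ in range(50)
        ]
        base = set(map(id, filter_hits(hits)))
        looser = set(map(id, filter_hits(hits, min_identity=50, max_evalue=1e-2)))
        assert base <= looser


def test_planted_copy_recall_at_default_filters():
    """Every planted element copy at <= 20% divergence overlaps a retained
    hit under the default identity/E-value/terminal filters."""
    from helhunt.phylo import PhyloModel
    from helhunt.synthetic_data import evolve, plant_elements, random_genome, render_template

    model = PhyloModel()
    total = missed = 0
    for rep in range(8):
        rend = render_template(seed=rep)
        rng = np.random.default_rng(500 + rep)
        copies = [evolve(rend.sequence, 0.2, model, rng) for _ in range(3)]
        g, truth = plant_elements(random_genome(3000, 0.4, rng), copies, seed=rng)
        hits = filter_hits(local_align(rend.sequence, g, ScoringScheme()))
        for tr in truth:
            lo, hi = tr.element.span
            total += 1
            missed += not any(h.overlaps_subject(lo, hi) for h in hits)
    assert total == 24 and missed == 0


def test_default_score_floor_matches_definition():
    sc = ScoringScheme()
    assert default_score_floor(sc) == pytest.approx(50 * (0.65 * 2 - 0.35 * 3))
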