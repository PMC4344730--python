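"""Local-alignment homology scanning with identity / E-value / terminal filters.

Candidate element copies are found by affine-gap Smith-Waterman alignment of
a query element against both strands of a subject sequence.  Non-overlapping
suboptimal hits are extracted by greedily masking the subject span of each
accepted alignment and re-running, down to a score floor corresponding to a
50 bp alignment at 65% identity.  Hit significance uses the Karlin-Altschul
expectation E = K * m * n * exp(-lambda * S) with documented default
parameters; lambda and K are configuration constants, not estimated.

Retention filters mirror standard practice for divergent-element searches:
identity >= 65%, E <= 1e-5, and either full query coverage (with a small
end slack for eroded termini) or a >= 50 bp alignment anchored at the query
5' or 3' end, so truncated copies and insertion-interrupted copies are kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from . import _dp
from .seqio import GenomicSequence, Region, reverse_complement

__all__ = ["ScoringScheme", "HomologyHit", "local_align", "evalue", "filter_hits"]

CoverageClass = Literal["full_length", "five_prime_partial", "three_prime_partial", "internal"]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores plus the Karlin-Altschul statistical parameters.

    Defaults are blastn-like (+2/-3, gap open 5 / extend 2).  lambda and K
    default to the ungapped-theory values for +2/-3 at uniform base
    composition (lambda solves sum_ij pi_i pi_j exp(lambda * s_ij) = 1).
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 5.0
    gap_extend: float = 2.0
    karlin_lambda: float = 0.625
    karlin_K: float = 0.41

    def __post_init__(self) -> None:
        if not (self.match > 0 and self.mismatch < 0):
            raise ValueError("require match > 0 and mismatch < 0")
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("require gap_open >= gap_extend > 0")
        if not (self.karlin_lambda > 0 and self.karlin_K > 0):
            raise ValueError("Karlin-Altschul parameters must be positive")


@dataclass(frozen=True)
class HomologyHit:
    """One filtered-or-unfiltered local alignment between query and subject."""

    query_span: Region
    subject_span: Region
    strand: str
    score: float
    identity_pct: float
    evalue: float
    coverage_class: CoverageClass
    n_columns: int = 0

    def overlaps_subject(self, lo: int, hi: int) -> bool:
        slo, shi = self.subject_span.span
        return not (shi < lo or slo > hi)


def evalue(score: float, m: int, n: int, scoring: ScoringScheme) -> float:
    """Karlin-Altschul expected number of chance hits at or above ``score``."""
    if score < 0:
        raise ValueError("score must be >= 0")
    return scoring.karlin_K * m * n * math.exp(-scoring.karlin_lambda * score)


def default_score_floor(scoring: ScoringScheme, min_terminal_len: int = 50,
                        min_identity: float = 65.0) -> float:
    """Score achieved by a gap-free ``min_terminal_len`` bp alignment at
    ``min_identity`` percent identity — the floor for suboptimal extraction."""
    p = min_identity / 100.0
    return min_terminal_len * (p * scoring.match + (1 - p) * scoring.mismatch)


def _classify_coverage(qlo: int, qhi: int, qlen: int, end_slack: int) -> CoverageClass:
    """Coverage class from the 1-based inclusive aligned query span."""
    at5 = qlo <= 1 + end_slack
    at3 = qhi >= qlen - end_slack
    if at5 and at3:
        return "full_length"
    if at5:
        return "five_prime_partial"
    if at3:
        return "three_prime_partial"
    return "internal"


def _identity_from_ops(q: str, s: str, ops, qi0: int, si0: int) -> tuple[float, int]:
    """Percent identity over aligned columns; gap columns count as non-matches."""
    qi, si = qi0, si0
    matches = 0
    for op in ops:
        if op == 0:
            if q[qi] == s[si]:
                matches += 1
            qi += 1
            si += 1
        elif op == 1:
            qi += 1
        else:
            si += 1
    ncol = len(ops)
    return (100.0 * matches / ncol if ncol else 0.0), ncol


def _scan_strand(
    query: GenomicSequence,
    subject_res: str,
    subject_id: str,
    strand: str,
    scoring: ScoringScheme,
    score_floor: float,
    max_hits: int,
    end_slack: int,
) -> list[HomologyHit]:
    eq = _dp.encode(query.residues)
    es = _dp.encode(subject_res)
    sub = _dp.substitution_matrix(scoring.match, scoring.mismatch)
    mask = np.zeros(len(subject_res), dtype=np.bool_)
    n_sub = len(subject_res)
    hits: list[HomologyHit] = []
    for _ in range(max_hits):
        score, qs, qe, ss, se, ops = _dp.local_dp(
            eq, es, sub, scoring.gap_open, scoring.gap_extend, mask
        )
        if score < score_floor or qe == qs:
            break
        ident, ncol = _identity_from_ops(query.residues, subject_res, ops, qs, ss)
        # 1-based inclusive coordinates
        q_span = Region(query.id, qs + 1, qe, "+")
        if strand == "+":
            s_span = Region(subject_id, ss + 1, se, "+")
        else:
            # coordinates on the forward strand of the original subject
            s_span = Region(subject_id, n_sub - ss, n_sub - se + 1, "-")
        hits.append(
            HomologyHit(
                query_span=q_span,
                subject_span=s_span,
                strand=strand,
                score=float(score),
                identity_pct=round(ident, 2),
                evalue=evalue(float(score), len(query), n_sub, scoring),
                coverage_class=_classify_coverage(qs + 1, qe, len(query), end_slack),
                n_columns=ncol,
            )
        )
        mask[ss:se] = True
    return hits


def local_align(
    query: GenomicSequence,
    subject: GenomicSequence,
    scoring: ScoringScheme | None = None,
    score_floor: float | None = None,
    max_hits: int = 25,
    end_slack: int = 20,
    both_strands: bool = True,
) -> list[HomologyHit]:
    """Smith-Waterman scan of ``query`` against ``subject``.

    Both strands are searched; hits are returned sorted by descending score
    (ties by subject position).  ``max_hits`` bounds the greedy suboptimal
    extraction per strand.
    """
    if not len(query) or not len(subject):
        raise ValueError("local_align requires non-empty sequences")
    scoring = scoring or ScoringScheme()
    if score_floor is None:
        score_floor = default_score_floor(scoring)
    hits = _scan_strand(
        query, subject.residues, subject.id, "+", scoring, score_floor, max_hits, end_slack
    )
    if both_strands:
        hits += _scan_strand(
            query,
            reverse_complement(subject.residues),
            subject.id,
            "-",
            scoring,
            score_floor,
            max_hits,
            end_slack,
        )
    hits.sort(key=lambda h: (-h.score, h.subject_span.span[0], h.strand))
    return hits


def filter_hits(
    hits: list[HomologyHit],
    min_identity: float = 65.0,
    max_evalue: float = 1e-5,
    min_terminal_len: int = 50,
) -> list[HomologyHit]:
    """Apply the identity / E-value / terminal-coverage retention filters.

    A hit is retained when identity >= ``min_identity``, E <= ``max_evalue``,
    and it is either full-length or a >= ``min_terminal_len`` bp alignment
    anchored at the query 5' or 3' end.
    """
    kept = []
    for h in hits:
        if h.identity_pct < min_identity or h.evalue > max_evalue:
            continue
        if h.coverage_class == "full_length":
            kept.append(h)
        elif h.coverage_class in ("five_prime_partial", "three_prime_partial"):
            if len(h.query_span) >= min_terminal_len:
                kept.append(h)
    return kept
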