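"""Diagnostic structural annotation of candidate Helitron elements.

Non-autonomous Hel-2-class Helitrons are recognised by a composite of
primary-sequence and secondary-structure features rather than by coding
capacity: a 5'-TC (sometimes TCC) terminus, a 3'-CTRR terminus (R = purine,
typically CTAG), integration between AT/TT dinucleotides (so the bases
immediately flanking the element are A/T), a stem-loop (hairpin) just
upstream of the 3' terminus, a 5'-terminal inverted repeat (5'-IR), a
subterminal inverted-repeat pairing between the 5' and 3' regions (SIR),
and an internal tetranucleotide microsatellite such as (CTGT)n or (GTTT)n.

Hairpin stability is scored with a nearest-neighbor stacking model
(unified DNA parameters, 37 C, 1 M NaCl) plus a simple linear hairpin-loop
penalty; stems may contain a bounded number of mismatches (which interrupt
stacking and add a fixed destabilisation) but no bulges.  This is a
deliberately small, exhaustively checkable energy model: presence/absence
and relative stability of a terminal hairpin is what the classification
needs, not full secondary-structure prediction.

Candidates are ranked into confidence tiers:

* ``full``            — both canonical termini and a stable 3' hairpin
* ``partial``         — one terminus + hairpin, or both termini without hairpin
* ``structural_only`` — hairpin or SIR present but no canonical terminus
* ``rejected``        — none of the above
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
from numba import njit

from ._dp import encode
from .seqio import GenomicSequence, Region

__all__ = [
    "AnnotationConfig",
    "TerminusCall",
    "Hairpin",
    "InvertedRepeatPair",
    "MicrosatelliteArray",
    "HelitronAnnotation",
    "find_termini",
    "fold_hairpin",
    "find_inverted_repeats",
    "find_microsatellites",
    "classify_element",
    "annotate_element",
]

Tier = Literal["full", "partial", "structural_only", "rejected"]
_TIER_ORDER = {"full": 3, "partial": 2, "structural_only": 1, "rejected": 0}

# ---------------------------------------------------------------------------
# Nearest-neighbor thermodynamics (unified DNA set, 37 C, 1 M NaCl)
# ---------------------------------------------------------------------------

#: Delta-G (kcal/mol) for the 5'->3' top-strand dinucleotide step XY paired
#: with its Watson-Crick complement.  The 16 entries collapse to the 10
#: unique published duplex values by reverse-complement symmetry.
NN_STACK: dict[str, float] = {
    "AA": -1.00, "AT": -0.88, "AG": -1.28, "AC": -1.44,
    "TA": -0.58, "TT": -1.00, "TG": -1.45, "TC": -1.30,
    "GA": -1.30, "GT": -1.44, "GG": -1.84, "GC": -2.24,
    "CA": -1.45, "CT": -1.28, "CG": -2.17, "CC": -1.84,
}

#: Linear hairpin-loop initiation penalty: a + b * (loop_len - 3), kcal/mol.
LOOP_A = 3.0
LOOP_B = 0.3

#: Each stem mismatch interrupts stacking and adds this penalty (kcal/mol).
MISMATCH_PENALTY = 1.0


def _stack_array() -> np.ndarray:
    arr = np.zeros((4, 4))
    order = "ACGT"
    for i, x in enumerate(order):
        for j, y in enumerate(order):
            arr[i, j] = NN_STACK[x + y]
    return arr


_STACKS = _stack_array()
# Watson-Crick complement by code: A<->T (0,3), C<->G (1,2); code 4 (N) pairs nothing
_WC = np.array([3, 2, 1, 0, -1], dtype=np.int64)


@dataclass(frozen=True)
class AnnotationConfig:
    """Window sizes and thresholds for structural annotation (all tunable)."""

    end_window: int = 15            # terminus search window at each element end
    hairpin_window: int = 100       # 3' window scanned for the stem-loop
    min_stem: int = 4               # minimum stem pairs
    max_stem_mismatch: int = 2
    min_loop: int = 3
    dg_ceiling: float = -3.0        # hairpins above this dG are not reported
    five_prime_ir_window: int = 60
    sir_window: int = 120
    ir_min_arm: int = 10
    ir_max_mismatch: int = 1
    microsat_min_copies: float = 3.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TerminusCall:
    kind: Literal["five_prime", "three_prime"]
    position: int                      # 1-based motif start within the element
    motif: str
    flanking_dinucleotide: Optional[str]
    matches_canonical: bool


@dataclass(frozen=True)
class Hairpin:
    left_arm: Region
    right_arm: Region
    loop_len: int
    mismatches_in_stem: int
    dG: float                          # kcal/mol; negative = stable


@dataclass(frozen=True)
class InvertedRepeatPair:
    kind: Literal["five_prime_IR", "SIR"]
    arm_a: Region
    arm_b: Region
    arm_len: int
    mismatches: int


@dataclass(frozen=True)
class MicrosatelliteArray:
    unit: str
    copies: float                      # fractional final unit allowed
    span: Region


@dataclass(frozen=True)
class HelitronAnnotation:
    element: Region
    termini: tuple[TerminusCall, ...]
    hairpin: Optional[Hairpin]
    irs: tuple[InvertedRepeatPair, ...]
    microsatellites: tuple[MicrosatelliteArray, ...]
    tier: Tier

    @property
    def name(self) -> str:
        return self.tier

    @property
    def feature_type(self) -> str:
        return "helitron"


# ---------------------------------------------------------------------------
# Termini
# ---------------------------------------------------------------------------

_RE_5P = re.compile("TC")
_RE_3P = re.compile("CT[AG][AG]")


def find_termini(
    seq: GenomicSequence,
    context: tuple[str, str] | None = None,
    end_window: int = 15,
) -> list[TerminusCall]:
    """Call the 5'-TC and 3'-CTRR termini within the end windows.

    The 5' call is the leftmost TC (reported as TCC when a C follows) in the
    first ``end_window`` bases; the 3' call is the rightmost CTRR whose last
    base lies in the final ``end_window`` bases.  Flanking dinucleotides are
    read from ``context`` (left flank, right flank) immediately outside the
    element; a missing context leaves the flank unset without failing the
    A/T-site rule.
    """
    s = seq.residues
    if end_window > len(s):
        raise ValueError("end_window exceeds element length")
    left_ctx, right_ctx = (context or (None, None))
    calls: list[TerminusCall] = []

    m5 = _RE_5P.search(s[:end_window])
    if m5:
        pos = m5.start() + 1
        motif = "TCC" if s[pos - 1 : pos + 2] == "TCC" else "TC"
        flank = left_ctx[-2:] if left_ctx else None
        adjacent_ok = left_ctx is None or (len(left_ctx) > 0 and left_ctx[-1] in "AT")
        calls.append(TerminusCall("five_prime", pos, motif, flank, bool(adjacent_ok)))

    tail_start = max(0, len(s) - end_window)
    best3 = None
    for m in _RE_3P.finditer(s, max(0, tail_start - 3)):
        if m.end() > tail_start:  # final base inside the window
            best3 = m
    if best3:
        pos = best3.start() + 1
        flank = right_ctx[:2] if right_ctx else None
        adjacent_ok = right_ctx is None or (len(right_ctx) > 0 and right_ctx[0] in "AT")
        calls.append(TerminusCall("three_prime", pos, best3.group(), flank, bool(adjacent_ok)))
    return calls


# ---------------------------------------------------------------------------
# Hairpin folding
# ---------------------------------------------------------------------------

@njit(cache=True)
def _hairpin_mfe(enc, wc, stacks, min_stem, max_mismatch, min_loop,
                 loop_a, loop_b, mm_penalty):  # pragma: no cover
    """Exhaustive minimum-free-energy stem-loop over an encoded window.

    Structures are parameterised by the outermost pair (i, j) and stem depth;
    outermost and innermost pairs must be Watson-Crick; interior mismatches
    (bounded) break stacking and add ``mm_penalty`` each; no bulges.
    Returns (dG, i, j, stem_len, mismatches) with dG = +inf when nothing
    qualifies.
    """
    n = enc.shape[0]
    best = (1e30, -1, -1, 0, 0)
    for i in range(n):
        ci = enc[i]
        if ci > 3:
            continue
        for j in range(i + 2 * min_stem + min_loop - 1, n):
            if wc[ci] != enc[j]:
                continue
            # extend inward from the outer pair (i, j)
            energy = 0.0
            mism = 0
            prev_paired = True
            t = 1
            while i + t < j - t and (j - t) - (i + t) - 1 >= 0:
                a = enc[i + t]
                b = enc[j - t]
                loop_len = (j - t) - (i + t) - 1
                paired = a <= 3 and b <= 3 and wc[a] == b
                if paired:
                    if prev_paired:
                        energy += stacks[enc[i + t - 1], a]
                else:
                    mism += 1
                    if mism > max_mismatch:
                        break
                    energy += mm_penalty
                stem_len = t + 1
                if paired and stem_len >= min_stem and loop_len >= min_loop:
                    dg = energy + loop_a + loop_b * (loop_len - 3)
                    if dg < best[0]:
                        best = (dg, i, j, stem_len, mism)
                prev_paired = paired
                t += 1
    return best


def fold_hairpin(
    window: GenomicSequence, config: AnnotationConfig | None = None
) -> Optional[Hairpin]:
    """Minimum-free-energy stem-loop in a 3'-terminal window.

    Returns None when no structure with stem >= ``min_stem`` pairs, loop >=
    ``min_loop``, and dG <= ``dg_ceiling`` exists.  Coordinates in the
    returned :class:`Hairpin` are 1-based within the window.
    """
    config = config or AnnotationConfig()
    if len(window) > 200:
        raise ValueError("hairpin window must be <= 200 bases")
    enc = encode(window.residues).astype(np.int64)
    dg, i, j, stem, mism = _hairpin_mfe(
        enc, _WC, _STACKS, config.min_stem, config.max_stem_mismatch,
        config.min_loop, LOOP_A, LOOP_B, MISMATCH_PENALTY,
    )
    if i < 0 or dg > config.dg_ceiling:
        return None
    left = Region(window.id, i + 1, i + stem)
    right = Region(window.id, j - stem + 2, j + 1)
    loop_len = (j - (stem - 1)) - (i + (stem - 1)) - 1
    return Hairpin(left, right, loop_len, int(mism), round(float(dg), 2))


# ---------------------------------------------------------------------------
# Inverted repeats
# ---------------------------------------------------------------------------

def _maximal_ir_pairs(s: str, min_arm: int, max_mismatch: int,
                      lo_a: int, hi_a: int, lo_b: int, hi_b: int) -> list[tuple[int, int, int, int]]:
    """All maximal (a_start, b_start, arm_len, mismatches) with arm_a in
    [lo_a, hi_a) and arm_b in [lo_b, hi_b), arm_b = revcomp(arm_a) up to
    mismatches.  0-based coordinates; arms must not overlap."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    out = []
    n = len(s)
    for a in range(lo_a, hi_a):
        # e is the outer (rightmost) base of arm_b: pairs with s[a]
        for e in range(max(lo_b + min_arm - 1, a + 2 * min_arm - 1), hi_b):
            if comp.get(s[a]) != s[e]:
                continue
            # skip non-maximal starts: extendable outward within the windows
            if a - 1 >= lo_a and e + 1 < hi_b and comp.get(s[a - 1]) == s[e + 1]:
                continue
            mism = 0
            best_k = 0
            k = 1
            while a + k <= e - k and e - k >= lo_b:
                if comp.get(s[a + k]) == s[e - k]:
                    if k + 1 >= min_arm:
                        best_k = k + 1
                else:
                    mism += 1
                    if mism > max_mismatch:
                        break
                k += 1
            if best_k >= min_arm:
                # recount mismatches within the reported arm
                mm = sum(1 for t in range(best_k) if comp.get(s[a + t]) != s[e - t])
                if e - best_k + 1 >= lo_b and a + best_k <= e - best_k:  # non-overlapping
                    out.append((a, e - best_k + 1, best_k, mm))
    return out


def find_inverted_repeats(
    seq: GenomicSequence,
    min_arm: int = 10,
    max_mismatch: int = 1,
    config: AnnotationConfig | None = None,
) -> list[InvertedRepeatPair]:
    """Find the 5'-IR (both arms in the 5' window) and the SIR (one arm in
    each subterminal window) as maximal mismatch-bounded arm pairs."""
    if min_arm < 4:
        raise ValueError("min_arm must be >= 4")
    config = config or AnnotationConfig()
    s = seq.residues
    n = len(s)
    pairs: list[InvertedRepeatPair] = []
    w5 = min(config.five_prime_ir_window, n)
    for a, b, k, mm in _maximal_ir_pairs(s, min_arm, max_mismatch, 0, w5, 0, w5):
        pairs.append(
            InvertedRepeatPair(
                "five_prime_IR",
                Region(seq.id, a + 1, a + k),
                Region(seq.id, b + 1, b + k),
                k, mm,
            )
        )
    ws = min(config.sir_window, n)
    for a, b, k, mm in _maximal_ir_pairs(s, min_arm, max_mismatch, 0, ws, max(0, n - ws), n):
        if b + 1 <= ws and a + k <= ws:
            continue  # already reported as a 5'-IR candidate region
        pairs.append(
            InvertedRepeatPair(
                "SIR",
                Region(seq.id, a + 1, a + k),
                Region(seq.id, b + 1, b + k),
                k, mm,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Microsatellites
# ---------------------------------------------------------------------------

def _rotations(unit: str) -> list[str]:
    return [unit[i:] + unit[:i] for i in range(len(unit))]


def find_microsatellites(
    seq: GenomicSequence,
    units: Iterable[str] = ("CTGT", "GTTT"),
    min_copies: float = 3.0,
) -> list[MicrosatelliteArray]:
    """Maximal tandem arrays of the given units (rotation-equivalent).

    Copies may end in a fractional partial unit; overlapping arrays are
    merged keeping the longest.  Arrays below ``min_copies`` are dropped.
    """
    units = list(units)
    if not units:
        raise ValueError("units must be non-empty")
    s = seq.residues
    found: list[MicrosatelliteArray] = []
    for unit in units:
        k = len(unit)
        for rot in _rotations(unit):
            p = 0
            while p + k <= len(s):
                if s[p : p + k] != rot:
                    p += 1
                    continue
                # maximality: not a continuation of an array starting earlier
                if p >= 1 and s[p - 1] == rot[-1] and s[p - 1 : p - 1 + k] == rot:
                    p += 1
                    continue
                full = 1
                while s[p + full * k : p + (full + 1) * k] == rot:
                    full += 1
                extra = 0
                tail = s[p + full * k :]
                while extra < k - 1 and extra < len(tail) and tail[extra] == rot[extra]:
                    extra += 1
                copies = full + extra / k
                if copies >= min_copies:
                    span_len = int(copies * k)
                    found.append(
                        MicrosatelliteArray(unit, copies, Region(seq.id, p + 1, p + span_len))
                    )
                p += full * k + extra + 1
    # merge overlaps, longest first
    found.sort(key=lambda m: (-(len(m.span)), m.span.span[0]))
    kept: list[MicrosatelliteArray] = []
    for m in found:
        lo, hi = m.span.span
        if all(hi < k.span.span[0] or lo > k.span.span[1] for k in kept):
            kept.append(m)
    kept.sort(key=lambda m: m.span.span[0])
    return kept


# ---------------------------------------------------------------------------
# Tier classification and the one-stop annotator
# ---------------------------------------------------------------------------

def classify_element(
    element: Region,
    termini: Iterable[TerminusCall],
    hairpin: Optional[Hairpin],
    irs: Iterable[InvertedRepeatPair] = (),
    microsatellites: Iterable[MicrosatelliteArray] = (),
) -> HelitronAnnotation:
    """Deterministic confidence-tier assignment from annotation parts."""
    termini = tuple(termini)
    irs = tuple(irs)
    microsatellites = tuple(microsatellites)
    kinds = {t.kind for t in termini}
    has5, has3 = "five_prime" in kinds, "three_prime" in kinds
    has_sir = any(p.kind == "SIR" for p in irs)
    if has5 and has3 and hairpin is not None:
        tier: Tier = "full"
    elif (int(has5) + int(has3) == 1 and hairpin is not None) or (has5 and has3):
        tier = "partial"
    elif hairpin is not None or has_sir:
        tier = "structural_only"
    else:
        tier = "rejected"
    return HelitronAnnotation(element, termini, hairpin, irs, microsatellites, tier)


def annotate_element(
    seq: GenomicSequence,
    context: tuple[str, str] | None = None,
    element: Region | None = None,
    config: AnnotationConfig | None = None,
) -> HelitronAnnotation:
    """Run the full structural annotation on one candidate element.

    The hairpin is sought in the ``hairpin_window`` bases upstream of the 3'
    terminus (or of the element end when no terminus was called); reported
    hairpin/IR coordinates are 1-based within the element.
    """
    config = config or AnnotationConfig()
    element = element or Region(seq.id, 1, len(seq))
    termini = find_termini(seq, context, config.end_window)
    t3 = next((t for t in termini if t.kind == "three_prime"), None)
    win_end = (t3.position - 1) if t3 else len(seq)
    win_start = max(0, win_end - config.hairpin_window)
    hp = None
    if win_end - win_start >= 2 * config.min_stem + config.min_loop:
        sub = GenomicSequence(seq.id, seq.residues[win_start:win_end])
        hp = fold_hairpin(sub, config)
        if hp is not None:  # shift back to element coordinates
            hp = Hairpin(
                Region(seq.id, hp.left_arm.start + win_start, hp.left_arm.end + win_start),
                Region(seq.id, hp.right_arm.start + win_start, hp.right_arm.end + win_start),
                hp.loop_len, hp.mismatches_in_stem, hp.dG,
            )
    irs = find_inverted_repeats(seq, config.ir_min_arm, config.ir_max_mismatch, config)
    micros = find_microsatellites(seq, min_copies=config.microsat_min_copies)
    return classify_element(element, termini, hp, irs, micros)
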