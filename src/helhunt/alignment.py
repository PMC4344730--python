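"""Pairwise and progressive multiple alignment, identity statistics, and
gapped-site filtering.

Alignment scoring follows the ClustalW-style parameterisation used
throughout the pipeline: nucleotide match +1, mismatch 0, affine gap
penalties with open 10 / extend 0.2 for pairwise alignment and open 10.0
for progressive MSA.  Tie-breaking in the traceback is deterministic
(diagonal > up > left).

"Identity" and "similarity" are computed by :func:`percent_identity` in two
documented modes: ``all_columns`` counts gap columns in the denominator
(a gapped column is a non-match), ``ungapped_columns`` restricts the
denominator to columns where both rows carry a residue.  Both are exposed
because published identity figures do not always state which convention
was used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import _dp
from .seqio import GenomicSequence

__all__ = [
    "Alignment",
    "IdentityMatrix",
    "pairwise_global",
    "progressive_msa",
    "percent_identity",
    "complete_deletion",
    "identity_matrix",
]

GAP = "-"

IdentityMode = Literal["all_columns", "ungapped_columns"]


@dataclass
class Alignment:
    """A multiple (or pairwise) alignment: list of (id, gapped string) rows."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        lengths = {len(g) for _, g in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def row(self, key: int | str) -> str:
        if isinstance(key, str):
            for i, g in self.rows:
                if i == key:
                    return g
            raise KeyError(key)
        return self.rows[key][1]

    def degapped(self, key: int | str) -> str:
        return self.row(key).replace(GAP, "")


@dataclass
class IdentityMatrix:
    """Symmetric pairwise percent-identity matrix."""

    labels: list[str]
    values: np.ndarray  # (n, n) float, diagonal 100.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("identity matrix must be symmetric")

    def value(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", float_format="%.2f"
        )

    @classmethod
    def from_tsv(cls, path) -> "IdentityMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=[str(c) for c in df.index], values=df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

# profile columns over {A,C,G,T,N, gap}; gap is index 5
_NSYM = 6


def _profile(rows: Sequence[str]) -> np.ndarray:
    L = len(rows[0])
    prof = np.zeros((L, _NSYM))
    for g in rows:
        for j, c in enumerate(g):
            prof[j, 5 if c == GAP else _dp._ENCODE.get(c, 4)] += 1.0
    prof /= len(rows)
    return prof


def _column_scores(pa: np.ndarray, pb: np.ndarray, match: float, mismatch: float) -> np.ndarray:
    sub = np.zeros((_NSYM, _NSYM))
    sub[:5, :5] = _dp.substitution_matrix(match, mismatch)
    # N and gap columns score 0 against everything in profile scoring
    sub[4, :] = 0.0
    sub[:, 4] = 0.0
    sub[5, :] = 0.0
    sub[:, 5] = 0.0
    return pa @ sub @ pb.T


def _merge(rows_a: list[tuple[str, str]], rows_b: list[tuple[str, str]],
           gap_open: float, gap_extend: float,
           match: float = 1.0, mismatch: float = 0.0) -> list[tuple[str, str]]:
    """Profile-profile merge: align the two sub-alignments and re-gap rows."""
    pa = _profile([g for _, g in rows_a])
    pb = _profile([g for _, g in rows_b])
    S = _column_scores(pa, pb, match, mismatch)
    _, ops = _dp.global_dp(S, gap_open, gap_extend)
    out_a = {i: [] for i, _ in rows_a}
    out_b = {i: [] for i, _ in rows_b}
    ia = ib = 0
    for op in ops:
        if op == 0:
            for i, g in rows_a:
                out_a[i].append(g[ia])
            for i, g in rows_b:
                out_b[i].append(g[ib])
            ia += 1
            ib += 1
        elif op == 1:  # consume profile A only
            for i, g in rows_a:
                out_a[i].append(g[ia])
            for i, _ in rows_b:
                out_b[i].append(GAP)
            ia += 1
        else:
            for i, _ in rows_a:
                out_a[i].append(GAP)
            for i, g in rows_b:
                out_b[i].append(g[ib])
            ib += 1
    merged = [(i, "".join(out_a[i])) for i, _ in rows_a]
    merged += [(i, "".join(out_b[i])) for i, _ in rows_b]
    return merged


# ---------------------------------------------------------------------------
# Pairwise global alignment
# ---------------------------------------------------------------------------

def pairwise_global(
    a: GenomicSequence,
    b: GenomicSequence,
    gap_open: float = 10.0,
    gap_extend: float = 0.2,
    match: float = 1.0,
    mismatch: float = 0.0,
) -> Alignment:
    """Optimal affine-gap global alignment of two sequences.

    The score of an alignment is the sum of match/mismatch scores minus, for
    every gap run of length L, ``gap_open + L * gap_extend`` (end gaps
    included).  Deterministic traceback.
    """
    if not len(a) or not len(b):
        raise ValueError("pairwise_global requires non-empty sequences")
    ea, eb = _dp.encode(a.residues), _dp.encode(b.residues)
    sub = _dp.substitution_matrix(match, mismatch)
    S = sub[ea][:, eb]
    _, ops = _dp.global_dp(S, gap_open, gap_extend)
    ga, gb = [], []
    ia = ib = 0
    for op in ops:
        if op == 0:
            ga.append(a.residues[ia]); gb.append(b.residues[ib])
            ia += 1; ib += 1
        elif op == 1:
            ga.append(a.residues[ia]); gb.append(GAP)
            ia += 1
        else:
            ga.append(GAP); gb.append(b.residues[ib])
            ib += 1
    return Alignment([(a.id, "".join(ga)), (b.id, "".join(gb))])


def global_score(
    a: str,
    b: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.2,
    match: float = 1.0,
    mismatch: float = 0.0,
) -> float:
    """Optimal global alignment score only (used by tests and scanners)."""
    ea, eb = _dp.encode(a), _dp.encode(b)
    sub = _dp.substitution_matrix(match, mismatch)
    S = sub[ea][:, eb]
    score, _ = _dp.global_dp(S, gap_open, gap_extend)
    return float(score)


# ---------------------------------------------------------------------------
# Progressive MSA
# ---------------------------------------------------------------------------

def _kmer_distance(a: str, b: str, k: int = 4) -> float:
    """Fractional common k-mer distance used only for the guide tree."""
    if len(a) < k or len(b) < k:
        return 1.0
    ka = {}
    for i in range(len(a) - k + 1):
        w = a[i : i + k]
        ka[w] = ka.get(w, 0) + 1
    shared = 0
    kb = {}
    for i in range(len(b) - k + 1):
        w = b[i : i + k]
        kb[w] = kb.get(w, 0) + 1
    for w, c in kb.items():
        shared += min(c, ka.get(w, 0))
    return 1.0 - shared / (min(len(a), len(b)) - k + 1)


def _nj_merge_order(d: np.ndarray) -> list[tuple[int, int]]:
    """Neighbor-joining agglomeration order on a small distance matrix.

    Returns the sequence of (cluster_i, cluster_j) merges over live cluster
    indices (original leaves are 0..n-1, merged clusters take the lower
    index).  Ties break on smallest (i, j).
    """
    n = d.shape[0]
    d = d.astype(float).copy()
    active = list(range(n))
    order: list[tuple[int, int]] = []
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        bi, bj = np.unravel_index(np.argmin(q), q.shape)
        if bi > bj:
            bi, bj = bj, bi
        i, j = active[bi], active[bj]
        # distances from the new cluster: standard NJ update
        dn = 0.5 * (d[i, active] + d[j, active] - d[i, j])
        d[i, active] = dn
        d[active, i] = dn
        d[i, i] = 0.0
        active.remove(j)
        order.append((i, j))
    if len(active) == 2:
        order.append((active[0], active[1]))
    return order


def progressive_msa(
    seqs: Sequence[GenomicSequence],
    gap_penalty: float = 10.0,
    gap_extend: float = 0.2,
) -> Alignment:
    """Progressive multiple alignment.

    A guide tree is built by neighbor joining on pairwise k-mer distances;
    profiles are merged in guide-tree order with affine-gap profile-profile
    alignment.  Row order in the result follows the input order.
    """
    if len(seqs) == 0:
        raise ValueError("progressive_msa requires at least one sequence")
    if len(seqs) == 1:
        return Alignment([(seqs[0].id, seqs[0].residues)])
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _kmer_distance(seqs[i].residues, seqs[j].residues)
    clusters: dict[int, list[tuple[str, str]]] = {
        i: [(s.id, s.residues)] for i, s in enumerate(seqs)
    }
    for i, j in _nj_merge_order(d):
        clusters[i] = _merge(clusters[i], clusters[j], gap_penalty, gap_extend)
        del clusters[j]
    (final,) = clusters.values()
    by_id = dict(final)
    return Alignment([(s.id, by_id[s.id]) for s in seqs])


# ---------------------------------------------------------------------------
# Identity statistics and gapped-site filtering
# ---------------------------------------------------------------------------

def percent_identity(
    aln: Alignment, i: int | str, j: int | str, mode: IdentityMode = "all_columns"
) -> float:
    """Percent identity between two alignment rows, to 2 decimals.

    ``all_columns``: denominator = columns where at least one row has a
    residue (a gap against a residue is a non-match).  ``ungapped_columns``:
    denominator = columns where both rows have residues.  Columns gapped in
    both rows are never counted.  A zero denominator yields NaN.
    """
    ra, rb = aln.row(i), aln.row(j)
    matches = denom = 0
    for ca, cb in zip(ra, rb):
        if ca == GAP and cb == GAP:
            continue
        if mode == "ungapped_columns" and (ca == GAP or cb == GAP):
            continue
        denom += 1
        if ca == cb and ca != GAP:
            matches += 1
    if denom == 0:
        return math.nan
    return round(100.0 * matches / denom, 2)


def complete_deletion(aln: Alignment) -> Alignment:
    """Remove every column containing at least one gap ("complete deletion").

    Idempotent; preserves row count.  An all-gapped alignment degenerates to
    zero columns (a warning-worthy but legal state).
    """
    import warnings

    keep = [
        k for k in range(aln.length) if all(g[k] != GAP for _, g in aln.rows)
    ]
    if aln.length and not keep:
        warnings.warn("complete deletion removed every column", stacklevel=2)
    return Alignment([(i, "".join(g[k] for k in keep)) for i, g in aln.rows])


def identity_matrix(aln: Alignment, mode: IdentityMode = "all_columns") -> IdentityMatrix:
    """Pairwise percent-identity matrix over all alignment rows."""
    if len(aln.rows) < 2:
        raise ValueError("identity_matrix requires at least two rows")
    n = len(aln.rows)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            v = percent_identity(aln, i, j, mode)
            vals[i, j] = vals[j, i] = v
    return IdentityMatrix(labels=aln.ids, values=vals)
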