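"""Distance and likelihood phylogenetics for transposable-element copies.

The substitution model is Tamura's three-parameter (T3P / T92) model, which
distinguishes transitions from transversions and allows biased G+C content;
JC and K2P are recovered as special cases (kappa = 1 and/or theta = 0.5).
Among-site rate heterogeneity uses a discrete gamma approximation with
category rates at the means of equal-probability slices.

Trees are :class:`dendropy.Tree` objects throughout (newick IO, consensus
and bipartition machinery come with them).  Tree construction is neighbor
joining, optionally polished by nearest-neighbor-interchange hill climbing
scored with a Felsenstein-pruning log-likelihood; node support comes from
nonparametric bootstrap with majority-rule consensus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from .alignment import Alignment, complete_deletion

__all__ = [
    "PhyloModel",
    "DistanceMatrixT",
    "gamma_category_rates",
    "t3p_distance",
    "distance_matrix",
    "nj_tree",
    "rate_matrix",
    "transition_probability",
    "pruning_loglik",
    "nni_search",
    "bootstrap_consensus",
    "robinson_foulds",
    "tree_from_newick",
    "tree_to_newick",
]

_BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(_BASES)}
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class PhyloModel:
    """Substitution model configuration.

    gamma_shape is the shape parameter of the gamma rate distribution
    (dimensionless; the bundled default 2.249 suits moderately heterogeneous
    element families); kappa is the transition/transversion rate ratio of
    the T92 rate matrix; gc_content is the model's theta.
    """

    model: Literal["JC", "K2P", "T3P"] = "T3P"
    gamma_shape: float = 2.249
    n_rate_categories: int = 4
    gc_content: float = 0.5
    kappa: float = 2.0

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.n_rate_categories < 1:
            raise ValueError("n_rate_categories must be >= 1")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")

    @property
    def theta(self) -> float:
        return 0.5 if self.model in ("JC", "K2P") else self.gc_content

    @property
    def effective_kappa(self) -> float:
        return 1.0 if self.model == "JC" else self.kappa

    @property
    def base_frequencies(self) -> np.ndarray:
        th = self.theta
        return np.array([(1 - th) / 2, th / 2, th / 2, (1 - th) / 2])


@dataclass
class DistanceMatrixT:
    """Symmetric matrix of substitutions/site; saturated pairs are NaN."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if math.isnan(self.values[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out


def gamma_category_rates(shape: float, k: int) -> np.ndarray:
    """Discrete-gamma category rates: the mean of each equal-probability
    slice of a gamma distribution with mean 1 (shape = rate = ``shape``)."""
    if k == 1:
        return np.ones(1)
    bounds = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=shape, scale=1.0 / shape)
    upper = gamma_dist.cdf(bounds, a=shape + 1, scale=1.0 / shape)
    rates = k * np.diff(upper)
    return rates / rates.mean() * 1.0  # guard tiny numerical drift


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _pq(a: str, b: str) -> tuple[float, float, int]:
    """Transition and transversion proportions over comparable sites."""
    p = q = n = 0
    for ca, cb in zip(a, b):
        if ca not in _IDX or cb not in _IDX:
            continue
        n += 1
        if ca != cb:
            if (ca, cb) in _TRANSITIONS:
                p += 1
            else:
                q += 1
    return (p / n if n else 0.0, q / n if n else 0.0, n)


def t3p_distance(a: str, b: str, model: PhyloModel | None = None) -> float:
    """Tamura-3-parameter distance between two gap-filtered aligned rows.

    d = -h ln(1 - P/h - Q) - (1/2)(1 - h) ln(1 - 2Q), h = 2 theta (1 - theta);
    with gamma rate variation each -ln(x) becomes a (x^(-1/a) - 1).
    Saturated pairs (non-positive log arguments) return NaN.
    """
    model = model or PhyloModel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("t3p_distance requires non-empty rows")
    if len(a) != len(b):
        raise ValueError("rows must have equal length")
    P, Q, n = _pq(a, b)
    if n == 0:
        return math.nan
    th = model.theta
    h = 2.0 * th * (1.0 - th)
    w1 = 1.0 - P / h - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    if model.n_rate_categories > 1:
        shp = model.gamma_shape
        d = h * shp * (w1 ** (-1.0 / shp) - 1.0) + 0.5 * (1 - h) * shp * (
            w2 ** (-1.0 / shp) - 1.0
        )
    else:
        d = -h * math.log(w1) - 0.5 * (1 - h) * math.log(w2)
    return max(d, 0.0)


def distance_matrix(
    aln: Alignment, model: PhyloModel | None = None, gap_filter: bool = True
) -> DistanceMatrixT:
    """Pairwise T3P distances over alignment rows (complete deletion first).

    theta defaults to the alignment's empirical G+C when the model carries
    the T3P default of 0.5 — the T3P theta is defined from the data.
    """
    model = model or PhyloModel()
    if gap_filter:
        aln = complete_deletion(aln)
    if model.model == "T3P":
        concat = "".join(g for _, g in aln.rows)
        acgt = sum(concat.count(b) for b in _BASES)
        if acgt:
            gc = (concat.count("G") + concat.count("C")) / acgt
            gc = min(max(gc, 1e-6), 1 - 1e-6)
            model = PhyloModel(model.model, model.gamma_shape, model.n_rate_categories,
                               gc, model.kappa)
    n = len(aln.rows)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = t3p_distance(aln.rows[i][1], aln.rows[j][1], model)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrixT(labels=aln.ids, values=vals)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrixT) -> dendropy.Tree:
    """Standard neighbor joining.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling edge.  Ties in the Q criterion break deterministically on
    the lexicographically smallest (representative label) pair.
    """
    if dm.undefined_pairs:
        raise ValueError(f"undefined distances for pairs: {dm.undefined_pairs}")
    n = len(dm.labels)
    if n < 3:
        raise ValueError("nj_tree requires at least 3 taxa")
    d = {
        (a, b): float(dm.values[i, j])
        for i, a in enumerate(dm.labels)
        for j, b in enumerate(dm.labels)
    }
    # newick fragment and representative (smallest) label per live cluster
    frag = {lab: lab for lab in dm.labels}
    live = sorted(dm.labels)

    def D(a: str, b: str) -> float:
        return d[(a, b)] if a != b else 0.0

    while len(live) > 3:
        m = len(live)
        r = {a: sum(D(a, k) for k in live) for a in live}
        best = None
        for i, a in enumerate(live):
            for b in live[i + 1 :]:
                q = (m - 2) * D(a, b) - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        la = 0.5 * D(a, b) + (r[a] - r[b]) / (2 * (m - 2))
        lb = D(a, b) - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        new = f"({frag[a]}:{la:.10g},{frag[b]}:{lb:.10g})"
        for k in live:
            if k in (a, b):
                continue
            dk = 0.5 * (D(a, k) + D(b, k) - D(a, b))
            d[(a, k)] = d[(k, a)] = dk
        live.remove(b)
        frag[a] = new
        # cluster keeps representative label a
    a, b, c = live
    # three-point formulas for the final star
    la = 0.5 * (D(a, b) + D(a, c) - D(b, c))
    lb = 0.5 * (D(a, b) + D(b, c) - D(a, c))
    lc = 0.5 * (D(a, c) + D(b, c) - D(a, b))
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    newick = f"({frag[a]}:{la:.10g},{frag[b]}:{lb:.10g},{frag[c]}:{lc:.10g});"
    return tree_from_newick(newick)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def rate_matrix(model: PhyloModel) -> np.ndarray:
    """Normalised T92 instantaneous rate matrix (mean rate 1)."""
    pi = model.base_frequencies
    k = model.effective_kappa
    Q = np.zeros((4, 4))
    for i, x in enumerate(_BASES):
        for j, y in enumerate(_BASES):
            if i == j:
                continue
            Q[i, j] = pi[j] * (k if (x, y) in _TRANSITIONS else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


def transition_probability(model: PhyloModel, t: float, rate: float = 1.0) -> np.ndarray:
    """P(t) = expm(Q * rate * t)."""
    return expm(rate_matrix(model) * rate * max(t, 0.0))


def _encode_columns(aln: Alignment, leaf_order: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns (rows = leaves) and their counts; non-ACGT = -1."""
    rows = [aln.row(name) for name in leaf_order]
    L = len(rows[0])
    cols = np.full((len(rows), L), -1, dtype=np.int64)
    for i, g in enumerate(rows):
        for j, c in enumerate(g):
            cols[i, j] = _IDX.get(c, -1)
    patterns, counts = np.unique(cols, axis=1, return_counts=True)
    return patterns, counts


def pruning_loglik(tree: dendropy.Tree, aln: Alignment, model: PhyloModel | None = None) -> float:
    """Log-likelihood (nats) of the alignment on the tree by Felsenstein
    pruning, under the T92 matrix with discrete-gamma rate mixing.

    The alignment must be gap-filtered (non-ACGT states are treated as
    fully ambiguous); leaf labels must match alignment row ids.
    """
    model = model or PhyloModel()
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if set(leaves) != set(aln.ids):
        raise ValueError(
            f"leaf labels {sorted(leaves)} do not match alignment ids {sorted(aln.ids)}"
        )
    patterns, counts = _encode_columns(aln, leaves)
    leaf_index = {name: i for i, name in enumerate(leaves)}
    rates = gamma_category_rates(model.gamma_shape, model.n_rate_categories)
    pi = model.base_frequencies
    npat = patterns.shape[1]
    site_lik = np.zeros(npat)
    for rate in rates:
        pmats = {}
        for node in tree.postorder_node_iter():
            if node.parent_node is not None:
                bl = node.edge.length or 0.0
                pmats[id(node)] = transition_probability(model, bl, rate)

        def partial(node) -> np.ndarray:
            if node.is_leaf():
                states = patterns[leaf_index[node.taxon.label]]
                out = np.zeros((npat, 4))
                amb = states < 0
                out[amb, :] = 1.0
                out[np.arange(npat)[~amb], states[~amb]] = 1.0
                return out
            res = np.ones((npat, 4))
            for ch in node.child_nodes():
                res *= partial(ch) @ pmats[id(ch)].T
            return res

        root_partial = partial(tree.seed_node)
        site_lik += (root_partial @ pi) / len(rates)
    if np.any(site_lik <= 0):
        return -math.inf
    return float(np.sum(np.log(site_lik) * counts))


# ---------------------------------------------------------------------------
# NNI search
# ---------------------------------------------------------------------------

def _internal_edges(tree: dendropy.Tree):
    for edge in tree.preorder_edge_iter():
        head, tail = edge.head_node, edge.tail_node
        if tail is None or head.is_leaf():
            continue
        yield edge


def _swap_subtrees(a, b) -> None:
    pa, pb = a.parent_node, b.parent_node
    pa.remove_child(a)
    pb.remove_child(b)
    pa.add_child(b)
    pb.add_child(a)


def nni_search(
    start: dendropy.Tree, aln: Alignment, model: PhyloModel | None = None,
    max_rounds: int = 20,
) -> dendropy.Tree:
    """Nearest-neighbor-interchange hill climbing scored by pruning
    log-likelihood; moves are accepted only on strict improvement, so the
    accepted-move log-likelihood sequence is non-decreasing and the search
    terminates at a local optimum.  Deterministic given the start tree."""
    model = model or PhyloModel()
    tree = start.clone(depth=1)
    best = pruning_loglik(tree, aln, model)
    for _ in range(max_rounds):
        improved = False
        for edge in list(_internal_edges(tree)):
            head, tail = edge.head_node, edge.tail_node
            children = list(head.child_nodes())
            siblings = [c for c in tail.child_nodes() if c is not head]
            if not siblings or len(children) < 2:
                continue
            s = siblings[0]
            for c in children[:2]:
                _swap_subtrees(c, s)
                cand = pruning_loglik(tree, aln, model)
                if cand > best + 1e-9:
                    best = cand
                    improved = True
                    break
                _swap_subtrees(s, c)  # revert
            if improved:
                break
        if not improved:
            break
    return tree


# ---------------------------------------------------------------------------
# Bootstrap and consensus
# ---------------------------------------------------------------------------

def bootstrap_consensus(
    aln: Alignment,
    model: PhyloModel | None = None,
    n_reps: int = 1000,
    support_floor: float = 50.0,
    seed: int | None = None,
    use_nni: bool = False,
) -> dendropy.Tree:
    """Majority-rule consensus of trees built on column-resampled replicates.

    Columns are resampled with replacement per replicate; each replicate
    tree is NJ (optionally NNI-polished).  Internal edges below
    ``support_floor`` percent are collapsed; retained supports are stored as
    percentages in ``node.label``.  Saturated replicate distances fall back
    to 1.5x the largest finite distance in that replicate.
    """
    if n_reps < 10:
        raise ValueError("n_reps must be >= 10")
    model = model or PhyloModel()
    rng = np.random.default_rng(seed)
    aln = complete_deletion(aln)
    L = aln.length
    taxa = dendropy.TaxonNamespace()
    trees = dendropy.TreeList(taxon_namespace=taxa)
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        rep = Alignment([(i, "".join(g[k] for k in idx)) for i, g in aln.rows])
        dmat = distance_matrix(rep, model, gap_filter=False)
        finite = dmat.values[np.isfinite(dmat.values)]
        fallback = (finite.max() if finite.size else 1.0) * 1.5
        dmat.values = np.where(np.isfinite(dmat.values), dmat.values, fallback)
        t = nj_tree(dmat)
        if use_nni:
            t = nni_search(t, rep, model)
        trees.append(
            dendropy.Tree.get(data=tree_to_newick(t), schema="newick",
                              taxon_namespace=taxa, preserve_underscores=True)
        )
    cons = trees.consensus(min_freq=support_floor / 100.0)
    cons.encode_bipartitions()
    for node in cons.internal_nodes():
        freq = getattr(node, "support", None)
        if freq is None and node.label is not None:
            try:
                freq = float(node.label)
            except ValueError:
                freq = None
        if freq is not None:
            node.label = f"{100.0 * freq:.0f}" if freq <= 1.0 else f"{freq:.0f}"
    return cons


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unweighted Robinson-Foulds distance (symmetric difference of
    non-trivial bipartitions); trees must share a leaf set."""
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    taxa = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=tree_to_newick(t1), schema="newick",
                          taxon_namespace=taxa, preserve_underscores=True)
    b = dendropy.Tree.get(data=tree_to_newick(t2), schema="newick",
                          taxon_namespace=taxa, preserve_underscores=True)
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()
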