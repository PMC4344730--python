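"""Independent oracles used by the test suite.

Each function recomputes a quantity by brute force (exhaustive enumeration
of alignments, structures, or ancestral states; closed forms) in a code
path deliberately separate from the package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

NEG = float("-inf")


# ---------------------------------------------------------------------------
# Alignment scores by exhaustive enumeration of alignments
# ---------------------------------------------------------------------------

def enumerate_global_best(a: str, b: str, match: float, mismatch: float,
                          gap_open: float, gap_extend: float) -> float:
    """Optimal global alignment score by enumerating every alignment.

    A gap run of length L costs gap_open + L * gap_extend; end gaps count.
    """
    best = [NEG]

    def walk(i: int, j: int, last: int, score: float) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            walk(i + 1, j + 1, 0, score + s)
        if i < len(a):
            cost = gap_extend if last == 1 else gap_open + gap_extend
            walk(i + 1, j, 1, score - cost)
        if j < len(b):
            cost = gap_extend if last == 2 else gap_open + gap_extend
            walk(i, j + 1, 2, score - cost)

    walk(0, 0, 0, 0.0)
    return best[0]


def enumerate_local_best(a: str, b: str, match: float, mismatch: float,
                         gap_open: float, gap_extend: float) -> float:
    """Smith-Waterman optimum: max over all substring pairs of the global
    enumeration (0 when nothing scores positively)."""
    best = 0.0
    for i in range(len(a)):
        for k in range(i + 1, len(a) + 1):
            for j in range(len(b)):
                for l in range(j + 1, len(b) + 1):
                    s = enumerate_global_best(a[i:k], b[j:l], match, mismatch,
                                              gap_open, gap_extend)
                    if s > best:
                        best = s
    return best


# ---------------------------------------------------------------------------
# Hairpin stem-loops by exhaustive structure enumeration
# ---------------------------------------------------------------------------

def hairpin_mfe_enumeration(seq: str, stacks: dict, loop_a: float, loop_b: float,
                            mm_penalty: float, min_stem: int, max_mismatch: int,
                            min_loop: int):
    """Exhaustive minimum over all stem-loop structures of a window.

    A structure is (left_start i, right_end j, stem_len k): pairs
    (i + t, j - t) for t in 0..k-1; outermost and innermost pairs must be
    Watson-Crick; interior mismatches bounded by max_mismatch; energy =
    sum of nearest-neighbor stacks over consecutive paired steps
    + mm_penalty per mismatch + loop_a + loop_b * (loop_len - 3).
    Returns (dG, i, j, k, mismatches) or None.
    """
    n = len(seq)
    best = None
    for i in range(n):
        for j in range(i + 1, n):
            max_k = (j - i + 1 - min_loop) // 2
            for k in range(min_stem, max_k + 1):
                loop = (j - k + 1) - (i + k - 1) - 1
                if loop < min_loop:
                    continue
                pairs = [(i + t, j - t) for t in range(k)]
                wc = [COMP.get(seq[x]) == seq[y] for x, y in pairs]
                if not (wc[0] and wc[-1]):
                    continue
                mism = wc.count(False)
                if mism > max_mismatch:
                    continue
                energy = mism * mm_penalty + loop_a + loop_b * (loop - 3)
                for t in range(k - 1):
                    if wc[t] and wc[t + 1]:
                        energy += stacks[seq[i + t] + seq[i + t + 1]]
                if best is None or energy < best[0] - 1e-12:
                    best = (energy, i, j, k, mism)
    return best


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def newick_bipartitions(newick: str) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each encoded as the
    frozenset of labels on the side NOT containing the alphabetically first
    label (a canonical orientation)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    anchor = min(all_leaves)
    bips = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        bips.add(side if anchor not in side else other)
    return bips


def rf_distance(newick1: str, newick2: str) -> int:
    return len(newick_bipartitions(newick1) ^ newick_bipartitions(newick2))


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """A random binary tree with positive branch lengths and its exact
    patristic distance matrix.  Returns (newick, labels, matrix)."""
    import dendropy

    labels = [f"t{i+1}" for i in range(n_taxa)]
    frags = {lab: lab for lab in labels}
    live = list(labels)
    while len(live) > 3:
        i, j = sorted(rng.choice(len(live), size=2, replace=False))
        a, b = live[i], live[j]
        la, lb = rng.uniform(0.05, 0.5, size=2)
        frags[a] = f"({frags[a]}:{la:.6f},{frags[b]}:{lb:.6f})"
        live.remove(b)
    parts = []
    for lab in live:
        parts.append(f"{frags[lab]}:{rng.uniform(0.05, 0.5):.6f}")
    newick = "(" + ",".join(parts) + ");"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in tree.taxon_namespace}
    mat = np.zeros((n_taxa, n_taxa))
    for x in range(n_taxa):
        for y in range(x + 1, n_taxa):
            d = pdm.patristic_distance(tx[labels[x]], tx[labels[y]])
            mat[x, y] = mat[y, x] = d
    return newick, labels, mat


def patristic_matrix(newick: str, labels: list[str]) -> np.ndarray:
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    mat = np.zeros((n, n))
    for x in range(n):
        for y in range(x + 1, n):
            d = pdm.patristic_distance(tx[labels[x]], tx[labels[y]])
            mat[x, y] = mat[y, x] = d
    return mat


def brute_force_loglik(tree, aln, model) -> float:
    """Likelihood by explicit summation over all ancestral state
    assignments (and rate categories), log-summed over sites."""
    from helhunt.phylo import _IDX, gamma_category_rates, transition_probability

    pi = model.base_frequencies
    internal = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    rates = (
        gamma_category_rates(model.gamma_shape, model.n_rate_categories)
        if model.n_rate_categories > 1
        else np.ones(1)
    )
    pmat = {
        id(n): [transition_probability(model, n.edge.length or 0.0, float(r)) for r in rates]
        for n in tree.postorder_node_iter()
        if n.parent_node is not None
    }
    total = 0.0
    for site in range(aln.length):
        states = {lab: _IDX.get(aln.row(lab)[site], -1) for lab in aln.ids}
        site_l = 0.0
        for c in range(len(rates)):
            for assign in itertools.product(range(4), repeat=len(internal)):
                amap = {id(n): s for n, s in zip(internal, assign)}
                p = pi[amap[id(tree.seed_node)]]
                for n in tree.postorder_node_iter():
                    if n.parent_node is None:
                        continue
                    P = pmat[id(n)][c]
                    row = amap[id(n.parent_node)]
                    s = states[n.taxon.label] if n.is_leaf() else amap[id(n)]
                    p *= P[row, :].sum() if s < 0 else P[row, s]
                site_l += p / len(rates)
        total += np.log(site_l)
    return float(total)
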