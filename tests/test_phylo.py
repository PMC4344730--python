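import math

import dendropy
import numpy as np
import pytest

from conftest import random_dna
from oracles import brute_force_loglik, patristic_matrix, random_additive_tree, rf_distance

from helhunt.alignment import Alignment
from helhunt.phylo import (
    DistanceMatrixT,
    PhyloModel,
    bootstrap_consensus,
    distance_matrix,
    gamma_category_rates,
    nj_tree,
    nni_search,
    pruning_loglik,
    rate_matrix,
    robinson_foulds,
    t3p_distance,
    transition_probability,
    tree_from_newick,
    tree_to_newick,
)

NO_GAMMA = PhyloModel(n_rate_categories=1)


class TestGammaRates:
    def test_mean_one_and_ordered(self):
        r = gamma_category_rates(2.249, 4)
        assert r.mean() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(r) > 0)

    def test_single_category_is_unit(self):
        assert gamma_category_rates(2.249, 1).tolist() == [1.0]


class TestT3PDistance:
    def test_identical_rows_zero(self):
        assert t3p_distance("ACGTACGT", "ACGTACGT", NO_GAMMA) == 0.0

    def test_reduces_to_k2p_at_half_gc(self, rng):
        a = random_dna(rng, 400)
        b = "".join(
            c if rng.random() > 0.15 else "ACGT"[rng.integers(0, 4)] for c in a
        )
        mt = PhyloModel(model="T3P", gc_content=0.5, n_rate_categories=1)
        mk = PhyloModel(model="K2P", n_rate_categories=1)
        assert t3p_distance(a, b, mt) == pytest.approx(t3p_distance(a, b, mk), abs=1e-9)

    def test_closed_form_value(self):
        """P=0.1, Q=0.05, theta=0.4: direct numeric evaluation of the
        estimator d = -h ln(1-P/h-Q) - (1-h)/2 ln(1-2Q)."""
        # rows engineered to give exactly P=0.1 (transitions), Q=0.05
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        m = PhyloModel(model="T3P", gc_content=0.4, n_rate_categories=1)
        h = 2 * 0.4 * 0.6
        want = -h * math.log(1 - 0.1 / h - 0.05) - 0.5 * (1 - h) * math.log(1 - 0.1)
        assert t3p_distance(a, b, m) == pytest.approx(want, abs=1e-12)

    def test_gamma_corrected_form(self):
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        m = PhyloModel(model="T3P", gc_content=0.4, gamma_shape=2.249, n_rate_categories=4)
        h = 2 * 0.4 * 0.6
        s = 2.249
        want = h * s * ((1 - 0.1 / h - 0.05) ** (-1 / s) - 1) + 0.5 * (1 - h) * s * (
            (1 - 0.1) ** (-1 / s) - 1
        )
        assert t3p_distance(a, b, m) == pytest.approx(want, abs=1e-12)

    def test_saturated_pair_flagged_nan(self):
        assert math.isnan(t3p_distance("A" * 10, "G" * 10, NO_GAMMA))

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            t3p_distance("", "", NO_GAMMA)


class TestNJ:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrixT(["A", "B", "C"], np.array(
            [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]
        ))
        t = nj_tree(dm)
        mat = patristic_matrix(tree_to_newick(t), ["A", "B", "C"])
        assert np.allclose(mat, dm.values, atol=1e-9)

    def test_additive_matrix_recovered_exactly(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            n = int(rng.integers(5, 9))
            newick, labels, mat = random_additive_tree(rng, n)
            t = nj_tree(DistanceMatrixT(labels, mat))
            assert rf_distance(tree_to_newick(t), newick) == 0
            assert np.allclose(patristic_matrix(tree_to_newick(t), labels), mat, atol=1e-6)

    def test_equal_distances_deterministic(self):
        dm = DistanceMatrixT(list("ABCDE"), np.full((5, 5), 0.4) - 0.4 * np.eye(5))
        t1, t2 = nj_tree(dm), nj_tree(dm)
        assert tree_to_newick(t1) == tree_to_newick(t2)

    def test_undefined_distances_listed(self):
        vals = np.array([[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]])
        with pytest.raises(ValueError, match="A.*C"):
            nj_tree(DistanceMatrixT(["A", "B", "C"], vals))


class TestPruningLoglik:
    def test_degenerate_two_taxa_zero_branches(self):
        aln = Alignment([("A", "C"), ("B", "C")])
        tree = tree_from_newick("(A:0.0,B:0.0);")
        m = PhyloModel(model="T3P", gc_content=0.5, n_rate_categories=1)
        assert pruning_loglik(tree, aln, m) == pytest.approx(math.log(0.25), abs=1e-9)

    @pytest.mark.parametrize("case", range(10))
    def test_matches_ancestral_state_enumeration(self, case):
        rng = np.random.default_rng(600 + case)
        n_taxa = int(rng.integers(3, 6))
        labels = [f"s{i}" for i in range(n_taxa)]
        newick, labels2, _ = random_additive_tree(rng, n_taxa)
        tree = tree_from_newick(newick)
        L = int(rng.integers(2, 7))
        aln = Alignment([(lab, random_dna(rng, L)) for lab in labels2])
        model = PhyloModel(gc_content=0.4, n_rate_categories=2, gamma_shape=1.5)
        got = pruning_loglik(tree, aln, model)
        want = brute_force_loglik(tree, aln, model)
        assert got == pytest.approx(want, abs=1e-8)

    def test_invariant_to_rerooting(self, rng):
        newick, labels, _ = random_additive_tree(rng, 6)
        aln = Alignment([(lab, random_dna(rng, 30)) for lab in labels])
        model = PhyloModel(n_rate_categories=1)
        t1 = tree_from_newick(newick)
        ll1 = pruning_loglik(t1, aln, model)
        t2 = tree_from_newick(newick)
        node = [n for n in t2.preorder_node_iter() if not n.is_leaf()][-1]
        t2.reroot_at_node(node)
        ll2 = pruning_loglik(t2, aln, model)
        assert ll1 == pytest.approx(ll2, abs=1e-6)

    def test_label_mismatch_rejected(self):
        aln = Alignment([("A", "AC"), ("X", "AC")])
        with pytest.raises(ValueError):
            pruning_loglik(tree_from_newick("(A:0.1,B:0.1);"), aln, NO_GAMMA)


class TestNNI:
    def _sim_alignment(self, newick, seed, length=400):
        from helhunt.synthetic_data import _simulate_along_tree, random_genome

        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        root = random_genome(length, 0.5, seed, "r")
        tips = _simulate_along_tree(
            tree, root, 1.0, PhyloModel(n_rate_categories=1), np.random.default_rng(seed)
        )
        return Alignment([(k, tips[k].residues) for k in sorted(tips)])

    def test_four_taxa_search_equals_exhaustive(self):
        truth = "((A:0.08,B:0.08):0.08,(C:0.08,D:0.08):0.08);"
        aln = self._sim_alignment(truth, 11)
        model = PhyloModel(n_rate_categories=1)
        tops = [
            "((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);",
            "((A:0.1,C:0.1):0.1,(B:0.1,D:0.1):0.1);",
            "((A:0.1,D:0.1):0.1,(B:0.1,C:0.1):0.1);",
        ]
        lls = [pruning_loglik(tree_from_newick(t), aln, model) for t in tops]
        best_top = tops[int(np.argmax(lls))]
        found = nni_search(tree_from_newick(tops[1]), aln, model)
        assert rf_distance(tree_to_newick(found), best_top) == 0

    def test_true_tree_is_local_optimum(self):
        truth = "((A:0.08,B:0.08):0.08,(C:0.08,D:0.08):0.08);"
        ok = 0
        for seed in range(8):
            aln = self._sim_alignment(truth, 100 + seed)
            model = PhyloModel(n_rate_categories=1)
            out = nni_search(tree_from_newick(truth), aln, model)
            ok += rf_distance(tree_to_newick(out), truth) == 0
        assert ok >= 7


class TestBootstrapConsensus:
    def test_clean_clade_gets_full_support(self):
        # two 30-site blocks each perfectly supporting the split AB|CD
        rows = [
            ("A", "A" * 30 + "C" * 30),
            ("B", "A" * 30 + "C" * 30),
            ("C", "G" * 30 + "T" * 30),
            ("D", "G" * 30 + "C" * 30),
        ]
        cons = bootstrap_consensus(Alignment(rows), NO_GAMMA, n_reps=50, seed=5)
        newick = tree_to_newick(cons)
        from oracles import newick_bipartitions

        bips = newick_bipartitions(newick)
        assert frozenset({"C", "D"}) in bips or frozenset({"A", "B"}) in bips
        supports = [
            float(n.label) for n in cons.internal_nodes()
            if n.label is not None and n.parent_node is not None
        ]
        assert supports and max(supports) == 100.0
        assert all(s >= 50.0 for s in supports)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        rows = [(f"s{i}", random_dna(rng, 80)) for i in range(5)]
        a = bootstrap_consensus(Alignment(rows), NO_GAMMA, n_reps=10, seed=9)
        b = bootstrap_consensus(Alignment(rows), NO_GAMMA, n_reps=10, seed=9)
        assert tree_to_newick(a) == tree_to_newick(b)

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_consensus(Alignment([("a", "AC"), ("b", "AC")]), n_reps=5)


class TestRobinsonFoulds:
    def test_identical_trees_zero(self):
        t = "((A:1,B:1):1,(C:1,D:1):1);"
        assert robinson_foulds(tree_from_newick(t), tree_from_newick(t)) == 0

    def test_conflicting_four_taxon_trees(self):
        t1 = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = tree_from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert robinson_foulds(t1, t2) == 2

    def test_matches_bipartition_enumeration_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            n = int(rng.integers(5, 10))
            n1, labels, _ = random_additive_tree(rng, n)
            n2, _, _ = random_additive_tree(rng, n)
            got = robinson_foulds(tree_from_newick(n1), tree_from_newick(n2))
            assert got == rf_distance(n1, n2)

    def test_leaf_set_mismatch_rejected(self):
        t1 = tree_from_newick("((A:1,B:1):1,C:1);")
        t2 = tree_from_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(ValueError):
            robinson_foulds(t1, t2)


def test_t92_rate_matrix_is_proper():
    m = PhyloModel(gc_content=0.3)
    Q = rate_matrix(m)
    assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
    pi = m.base_frequencies
    assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)
    # stationarity: pi Q = 0
    assert np.allclose(pi @ Q, 0, atol=1e-12)
    P = transition_probability(m, 1000.0)
    assert np.allclose(P, np.tile(pi, (4, 1)), atol=1e-6)
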