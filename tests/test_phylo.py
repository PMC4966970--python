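import math
import random

import numpy as np
import pytest

from gvkit.phylo import (
    DistanceMatrix,
    Supermatrix,
    TreeNode,
    bipartitions,
    bootstrap_support,
    concatenate_alignments,
    distance_matrix,
    nj_tree,
    simulate_protein_evolution,
)


def random_topology(rng, taxa):
    """Random binary unrooted tree with positive branch lengths."""
    nodes = [TreeNode(name=t, length=rng.uniform(0.05, 0.5)) for t in taxa]
    while len(nodes) > 3:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        parent = TreeNode(children=[a, b], length=rng.uniform(0.05, 0.5))
        nodes.append(parent)
    return TreeNode(children=nodes)


def additive_matrix(tree):
    """Leaf-to-leaf path-length matrix of a tree (the oracle construction)."""
    dists = {}

    def walk(node, acc):
        if node.is_leaf:
            dists[node.name] = acc
            return
        for c in node.children:
            walk(c, acc + [(c, c.length)])

    paths = {}

    def collect(node, path):
        if node.is_leaf:
            paths[node.name] = path
            return
        for c in node.children:
            collect(c, path + [c])

    collect(tree, [])
    taxa = sorted(paths)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = paths[taxa[i]], paths[taxa[j]]
            k = 0
            while k < min(len(pi), len(pj)) and pi[k] is pj[k]:
                k += 1
            dist = sum(x.length for x in pi[k:]) + sum(x.length for x in pj[k:])
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa, d)


class TestConcatenate:
    def test_two_genes_concatenate_columnwise(self):
        g1 = ("gene1", {t: "ACDEFGHIKL" for t in "ABCD"})
        g2 = ("gene2", {t: "MNPQRSTVWY" for t in "ABCD"})
        sm, warnings = concatenate_alignments([g1, g2])
        assert sm.n_columns == 20 and not warnings
        assert sm.partitions == [("gene1", 0, 10), ("gene2", 10, 20)]

    def test_missing_taxon_gap_filled_with_warning(self):
        g1 = ("gene1", {"A": "MKV", "B": "MKV", "C": "MKV"})
        g2 = ("gene2", {"A": "WYF", "C": "WYF"})
        sm, warnings = concatenate_alignments([g1, g2])
        row_b = sm.rows[sm.taxa.index("B")]
        assert row_b == "MKV---"
        assert any("B" in w for w in warnings)


class TestDistances:
    def make_sm(self, rows):
        return Supermatrix(list("ABCDEFG")[: len(rows)], rows, [("g", 0, len(rows[0]))])

    def test_identical_rows_zero_distance(self):
        sm = self.make_sm(["MKVLA" * 2] * 3)
        assert distance_matrix(sm).values.max() == 0.0

    def test_p_distance_one_difference_in_ten(self):
        sm = self.make_sm(["MKVLAWQERT", "MKVLAWQERS", "MKVLAWQERT"])
        d = distance_matrix(sm, "p-distance")
        assert d.values[0, 1] == pytest.approx(0.1)

    def test_poisson_correction_closed_form(self):
        sm = self.make_sm(["MKVLAWQERT", "MKVLAWQERS", "MKVLAWQERT"])
        d = distance_matrix(sm, "poisson")
        assert d.values[0, 1] == pytest.approx(-math.log(0.9))

    def test_gamma_correction_requires_shape_and_exceeds_poisson(self):
        sm = self.make_sm(["MKVLAWQERT", "MKVLAWQERS", "MKVVAWQERS"])
        with pytest.raises(ValueError):
            distance_matrix(sm, "gamma")
        g = distance_matrix(sm, "gamma", gamma_shape=0.5)
        p = distance_matrix(sm, "poisson")
        assert (g.values >= p.values - 1e-12).all()

    def test_poisson_dominates_p_distance_elementwise(self):
        rng = random.Random(2)
        rows = ["".join(rng.choice("ACDEFGHIKL") for _ in range(60)) for _ in range(4)]
        p = distance_matrix(self.make_sm(rows), "p-distance").values
        q = distance_matrix(self.make_sm(rows), "poisson").values
        assert (q >= p - 1e-12).all()

    def test_pairwise_deletion_of_gap_sites(self):
        sm = self.make_sm(["MKVLA-QERT", "MKVLAWQERS", "MKVLAWQERT"])
        d = distance_matrix(sm, "p-distance")
        assert d.values[0, 1] == pytest.approx(1 / 9)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovers_exact_lengths(self):
        taxa = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 7, 5], [3, 0, 8, 6], [7, 8, 0, 4], [5, 6, 4, 0]], float)
        t = nj_tree(DistanceMatrix(taxa, d))
        assert bipartitions(t) == {frozenset({"A", "B"})}
        lengths = {l.name: l.length for l in t.leaves()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 1.0}

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        t = nj_tree(DistanceMatrix(["X", "Y", "Z"], d))
        lengths = {l.name: l.length for l in t.leaves()}
        assert lengths == {"X": 0.5, "Y": 1.5, "Z": 2.5}

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrices_recover_generating_topology(self, seed):
        rng = random.Random(seed)
        tree = random_topology(rng, [f"t{i}" for i in range(8)])
        dm = additive_matrix(tree)
        inferred = nj_tree(dm)
        assert bipartitions(inferred) == bipartitions(tree)

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_dendropy_on_additive_input(self, seed):
        dendropy = pytest.importorskip("dendropy")
        rng = random.Random(50 + seed)
        tree = random_topology(rng, [f"t{i}" for i in range(7)])
        dm = additive_matrix(tree)
        ours = nj_tree(dm)
        csv = "," + ",".join(dm.taxa) + "\n"
        for i, t in enumerate(dm.taxa):
            csv += t + "," + ",".join(str(x) for x in dm.values[i]) + "\n"
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(io.StringIO(csv))
        theirs = pdm.nj_tree()
        their_bps = set()
        theirs.encode_bipartitions()
        taxa = frozenset(dm.taxa)
        for edge in theirs.preorder_edge_iter():
            if edge.head_node.is_leaf() or edge.head_node.parent_node is None:
                continue
            side = frozenset(l.taxon.label for l in edge.head_node.leaf_iter())
            if 1 < len(side) < len(taxa) - 1:
                their_bps.add(min(side, taxa - side, key=lambda s: sorted(s)))
        assert bipartitions(ours) == their_bps


class TestBootstrap:
    def make_clade_matrix(self, seed=4, length=300):
        tree = TreeNode(children=[
            TreeNode(children=[TreeNode(name="a", length=0.05), TreeNode(name="b", length=0.05)], length=0.6),
            TreeNode(children=[TreeNode(name="c", length=0.05), TreeNode(name="d", length=0.05)], length=0.6),
            TreeNode(name="e", length=0.7),
        ])
        seqs = simulate_protein_evolution(tree, length, seed=seed)
        taxa = sorted(seqs)
        return Supermatrix(taxa, [seqs[t] for t in taxa], [("sim", 0, length)])

    def test_single_replicate_supports_are_all_or_nothing(self):
        sm = self.make_clade_matrix()
        t = bootstrap_support(sm, reps=1, seed=0)
        sup = [n.support for n in t.leaves()[0].children] if False else []
        def collect(node):
            for c in node.children:
                if not c.is_leaf:
                    sup.append(c.support)
                    collect(c)
        collect(t)
        assert sup and all(s in (0.0, 100.0) for s in sup)

    def test_same_seed_gives_identical_supports(self):
        sm = self.make_clade_matrix()
        t1 = bootstrap_support(sm, reps=25, seed=9)
        t2 = bootstrap_support(sm, reps=25, seed=9)
        assert t1.newick() == t2.newick()

    def test_supports_invariant_under_taxon_permutation(self):
        sm = self.make_clade_matrix()
        perm = [3, 1, 4, 0, 2]
        sm2 = Supermatrix([sm.taxa[i] for i in perm], [sm.rows[i] for i in perm], sm.partitions)
        def supmap(tree):
            out = {}
            all_taxa = frozenset(tree.leaf_names())
            def walk(n):
                for c in n.children:
                    if not c.is_leaf:
                        side = frozenset(c.leaf_names())
                        out[min(side, all_taxa - side, key=lambda s: sorted(s))] = c.support
                        walk(c)
            walk(tree)
            return out
        assert supmap(bootstrap_support(sm, reps=30, seed=3)) == supmap(
            bootstrap_support(sm2, reps=30, seed=3))


class TestSimulation:
    def test_zero_length_branches_give_identical_sequences(self):
        tree = TreeNode(children=[TreeNode(name="a", length=0.0), TreeNode(name="b", length=0.0),
                                  TreeNode(name="c", length=0.0)])
        seqs = simulate_protein_evolution(tree, 200, seed=1)
        assert seqs["a"] == seqs["b"] == seqs["c"]

    def test_p_distance_grows_with_branch_length(self):
        def pdist(t, seed):
            tree = TreeNode(children=[TreeNode(name="a", length=t), TreeNode(name="b", length=t),
                                      TreeNode(name="c", length=0.01)])
            seqs = simulate_protein_evolution(tree, 2000, seed=seed)
            return sum(1 for x, y in zip(seqs["a"], seqs["b"]) if x != y) / 2000

        short = sum(pdist(0.05, s) for s in range(3)) / 3
        long = sum(pdist(0.6, s) for s in range(3)) / 3
        assert long > short
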