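"""Step distances, barcode-gap summaries, NJ, bootstrap, monophyly."""

import itertools
import random

import dendropy
import numpy as np
import pytest

from ribosplit.distances import (bootstrap_support, divergence_summary,
                                 leaf_bipartitions, monophyly, nj_tree,
                                 pairwise_steps)
from ribosplit.seqio import MultipleAlignment, SeqRecord


class TestPairwiseSteps:
    def test_single_difference(self, aln_factory):
        dm = pairwise_steps(aln_factory({"a": "ACGT", "b": "ACGA"}))
        assert dm.steps_between("a", "b") == 1

    def test_gap_excluded_from_steps_and_sites(self, aln_factory):
        dm = pairwise_steps(aln_factory({"a": "AC-T", "b": "ACGT"}))
        assert dm.steps_between("a", "b") == 0
        assert dm.compared_sites[0, 1] == 3

    def test_matches_double_loop_oracle(self, aln_factory):
        rnd = random.Random(5)
        rows = {f"s{i}": "".join(rnd.choice("ACGT-N") for _ in range(50))
                for i in range(5)}
        aln = aln_factory(rows)
        dm = pairwise_steps(aln)
        for i, j in itertools.combinations(range(5), 2):
            ri, rj = aln.records[i].residues, aln.records[j].residues
            exp = sum(1 for x, y in zip(ri, rj)
                      if x not in "-N" and y not in "-N" and x != y)
            assert dm.steps[i, j] == exp
        assert np.array_equal(dm.steps, dm.steps.T)
        assert np.all(np.diag(dm.steps) == 0)
        assert np.all((0 <= dm.p_dist) & (dm.p_dist <= 1))

    def test_zero_comparable_sites_names_pair(self, aln_factory):
        with pytest.raises(ValueError, match="a.*b"):
            pairwise_steps(aln_factory({"a": "AC--", "b": "--GT"}))


class TestDivergenceSummary:
    def test_clean_gap_both_groups(self, aln_factory):
        aln = aln_factory({"x1": "AAAAAAAAAA", "x2": "AAAAAAAAAA",
                           "y1": "CCCCCAAAAA"})
        div = divergence_summary(pairwise_steps(aln),
                                 {"x1": "X", "x2": "X", "y1": "Y"})
        assert div.barcode_gap == {"X": True, "Y": True}
        assert div.max_intra == {"X": 0, "Y": 0}
        assert div.min_inter[("X", "Y")] == 5

    def test_overlap_flagged_with_witness(self):
        # intra-group spread (17) exceeding nearest-neighbour distance (9)
        L = 60
        base = "A" * L
        rows = {"g1": base,
                "g2": "C" * 17 + base[17:],
                "e1": base[:40] + "G" * 9 + base[49:]}
        aln = MultipleAlignment(tuple(
            SeqRecord(id=k, residues=v) for k, v in rows.items()))
        div = divergence_summary(pairwise_steps(aln),
                                 {"g1": "G", "g2": "G", "e1": "E"})
        assert div.max_intra["G"] == 17
        assert div.min_inter[("E", "G")] == 9
        assert div.barcode_gap["E"] is False
        assert ((("E", "G"), 9, 17)) in div.overlap_witnesses

    def test_singleton_group_zero_intra(self, aln_factory):
        aln = aln_factory({"a": "AAAA", "b": "TTTT"})
        div = divergence_summary(pairwise_steps(aln), {"a": "A", "b": "B"})
        assert div.max_intra == {"A": 0, "B": 0}

    def test_unknown_label_errors(self, aln_factory):
        aln = aln_factory({"a": "AAAA", "b": "TTTT"})
        with pytest.raises(KeyError):
            divergence_summary(pairwise_steps(aln), {"a": "A"})


def _random_tree_distances(n_leaves, rnd):
    """A random binary tree with positive branch lengths and its additive
    leaf-to-leaf distance matrix."""
    taxa = [f"t{i}" for i in range(n_leaves)]
    nodes = {t: {t} for t in taxa}
    dist = {frozenset((a, b)): 0.0 for a, b in itertools.combinations(taxa, 2)}
    depth = {t: 0.0 for t in taxa}
    clusters = dict(nodes)
    bips = set()
    while len(clusters) > 1:
        a, b = rnd.sample(sorted(clusters), 2)
        la, lb = rnd.uniform(0.05, 1.0), rnd.uniform(0.05, 1.0)
        for x in clusters[a]:
            depth[x] += la
        for x in clusters[b]:
            depth[x] += lb
        for x in clusters[a]:
            for y in clusters[b]:
                dist[frozenset((x, y))] = depth[x] + depth[y]
        merged = clusters.pop(a) | clusters.pop(b)
        if 2 <= len(merged) <= n_leaves - 2:
            bips.add(frozenset(merged))
        clusters["+".join(sorted(merged))] = merged
    # additive matrix in the order of taxa
    m = np.zeros((n_leaves, n_leaves))
    for i, j in itertools.combinations(range(n_leaves), 2):
        m[i, j] = m[j, i] = dist[frozenset((taxa[i], taxa[j]))]
    return taxa, m, bips


def _dm(labels, matrix):
    from ribosplit.distances import DistanceMatrix
    steps = np.rint(matrix * 1000).astype(int)
    return DistanceMatrix(labels=tuple(labels), steps=steps,
                          compared_sites=np.full_like(steps, 1000),
                          p_dist=matrix)


def _canon_bips(bips, all_leaves):
    ref = min(all_leaves)
    out = set()
    for s in bips:
        s = frozenset(s)
        if ref in s:
            s = frozenset(all_leaves) - s
        if 2 <= len(s) <= len(all_leaves) - 2:
            out.add(s)
    return out


class TestNeighborJoining:
    def test_four_taxon_additive_recovery_with_branch_lengths(self):
        # tree ((a:1,b:2):3,(c:4,d:5)) -> additive distances
        labels = ["a", "b", "c", "d"]
        m = np.array([[0, 3, 8, 9],
                      [3, 0, 9, 10],
                      [8, 9, 0, 9],
                      [9, 10, 9, 0]], dtype=float)
        tree = nj_tree(_dm(labels, m))
        bips = leaf_bipartitions(tree)
        assert frozenset({"c", "d"}) in bips
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)

    def test_three_taxa_closed_form(self):
        labels = ["a", "b", "c"]
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(_dm(labels, m))
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_two_cluster_bipartition_present(self):
        labels = [f"t{i}" for i in range(8)]
        m = np.zeros((8, 8))
        for i, j in itertools.combinations(range(8), 2):
            same = (i < 4) == (j < 4)
            m[i, j] = m[j, i] = (0.1 * abs(i - j)) if same else 5.0 + 0.01 * (i + j)
        tree = nj_tree(_dm(labels, m))
        assert frozenset({"t4", "t5", "t6", "t7"}) in leaf_bipartitions(tree)

    @pytest.mark.parametrize("seed", range(15))
    def test_additive_matrix_topology_recovery(self, seed):
        rnd = random.Random(seed)
        n = rnd.randint(4, 10)
        taxa, m, true_bips = _random_tree_distances(n, rnd)
        tree = nj_tree(_dm(taxa, m))
        assert leaf_bipartitions(tree) == _canon_bips(true_bips, taxa)

    def test_agrees_with_scikit_bio_on_additive_matrix(self):
        """Independent cross-check: scikit-bio's NJ yields the same
        unrooted topology on an additive matrix."""
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj
        rnd = random.Random(99)
        taxa, m, _ = _random_tree_distances(7, rnd)
        mine = leaf_bipartitions(nj_tree(_dm(taxa, m)))
        sk = sknj(SkDM(m, ids=taxa))
        sk_dp = dendropy.Tree.get(data=str(sk), schema="newick")
        assert leaf_bipartitions(sk_dp) == mine

    def test_non_symmetric_matrix_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(_dm(["a", "b", "c"], m))

    def test_needs_three_labels(self):
        with pytest.raises(ValueError):
            nj_tree(_dm(["a", "b"], np.array([[0, 1.0], [1.0, 0]])))


def _two_clade_alignment(n_per=4, n_cols=120, div=30, seed=3):
    rnd = random.Random(seed)
    base = "".join(rnd.choice("ACGT") for _ in range(n_cols))
    other = list(base)
    for p in rnd.sample(range(n_cols), div):
        other[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[other[p]]
    other = "".join(other)
    rows = {}
    for i in range(n_per):
        a = list(base)
        b = list(other)
        p = rnd.randrange(n_cols)
        a[p] = "A"
        q = rnd.randrange(n_cols)
        b[q] = "T"
        rows[f"x{i}"] = "".join(a)
        rows[f"y{i}"] = "".join(b)
    return MultipleAlignment(tuple(
        SeqRecord(id=k, residues=v) for k, v in rows.items()))


class TestBootstrap:
    def test_seed_reproducibility(self):
        aln = _two_clade_alignment()
        t1 = bootstrap_support(aln, n_reps=25, seed=11)
        t2 = bootstrap_support(aln, n_reps=25, seed=11)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_single_replicate_supports_binary(self):
        aln = _two_clade_alignment()
        tree = bootstrap_support(aln, n_reps=1, seed=0)
        sup = [float(n.label) for n in tree.preorder_internal_node_iter()
               if n.label is not None]
        assert sup and all(s in (0.0, 100.0) for s in sup)

    def test_well_separated_clades_high_support(self):
        aln = _two_clade_alignment()
        tree = bootstrap_support(aln, n_reps=100, seed=5)
        all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
        ref = min(all_leaves)
        want = frozenset(l for l in all_leaves if l.startswith("y"))
        if ref in want:
            want = all_leaves - want
        supports = {}
        for node in tree.preorder_internal_node_iter():
            if node.label is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if ref in side:
                side = all_leaves - side
            supports[side] = float(node.label)
        assert supports[want] >= 95


class TestMonophyly:
    def _tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_clean_groups_monophyletic(self):
        t = self._tree("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        got = monophyly(t, lambda leaf: leaf[0])
        assert got["a"] == (True, 2) and got["b"] == (True, 2)

    def test_split_group_reports_covering_clade(self):
        t = self._tree("(((a1:1,b1:1):1,a2:1):1,b2:1);")
        got = monophyly(t, lambda leaf: leaf[0])
        assert got["a"][0] is False and got["a"][1] > 2

    def test_singleton_group_trivially_monophyletic(self):
        t = self._tree("((a1:1,a2:1):1,z:1);")
        got = monophyly(t, lambda leaf: "Z" if leaf == "z" else "a")
        assert got["Z"] == (True, 1)

    def test_unlabeled_leaf_errors(self):
        t = self._tree("((a:1,b:1):1,c:1);")
        with pytest.raises(ValueError, match="unlabeled"):
            monophyly(t, {"a": "X", "b": "X"})
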