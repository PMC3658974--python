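import numpy as np
import pytest

import type3copper as t3
from type3copper.errors import DataError, TreeError
from type3copper.phylo import AnchoredAlignment, DistanceMatrix
from type3copper.trees import Node, Tree

from oracles import minimum_evolution_topology, random_additive_tree


def dm(ids, mat):
    return DistanceMatrix(tuple(ids), np.array(mat, float))


# -- anchored alignment ----------------------------------------------------


def test_identical_templates_align_without_gaps(templates):
    tpl = templates["alpha"]
    recs = [t3.ProteinRecord("a", tpl.record.sequence),
            t3.ProteinRecord("b", tpl.record.sequence)]
    sites = {r.id: t3.best_binuclear_site(r) for r in recs}
    aln = t3.anchor_align(recs, sites)
    assert "-" not in aln.rows[0] and "-" not in aln.rows[1]
    assert aln.rows[0] == aln.rows[1]
    for col in aln.anchor_columns:
        assert aln.rows[0][col] == "H"


def test_spacing_difference_pads_the_shorter_block(templates):
    a, b = templates["alpha"], templates["beta"]   # Cu(A) s23: 8 vs 10
    recs = [t3.ProteinRecord("a", a.record.sequence),
            t3.ProteinRecord("b", b.record.sequence)]
    sites = {r.id: t3.best_binuclear_site(r) for r in recs}
    aln = t3.anchor_align(recs, sites)
    assert aln.row("a").count("-") == 2
    assert aln.row("b").count("-") == 0


def test_single_record_alignment_is_its_region(templates):
    tpl = templates["alpha"]
    rec = t3.ProteinRecord("solo", tpl.record.sequence)
    sites = {"solo": t3.best_binuclear_site(rec)}
    aln = t3.anchor_align([rec], sites, flank=10)
    site = sites["solo"]
    region = tpl.record.sequence[site.cuA.h1 - 10:site.cuB.h3 + 11]
    assert aln.rows[0] == region


def test_missing_site_is_structured_error(templates):
    rec = t3.ProteinRecord("a", templates["alpha"].record.sequence)
    with pytest.raises(DataError, match="a"):
        t3.anchor_align([rec], {})


def test_degapped_row_recovers_original_region(phylo_fixture):
    records, labels, sites, aln = phylo_fixture
    by_id = {r.id: r for r in records}
    for rec_id, row, start in zip(aln.ids, aln.rows, aln.region_starts):
        site = sites[rec_id]
        seq = by_id[rec_id].sequence
        region = seq[start:min(len(seq), site.cuB.h3 + 11)]
        assert row.replace("-", "") == region


# -- distances -------------------------------------------------------------


def test_identical_rows_have_zero_distance():
    aln = AnchoredAlignment(("a", "b"), ("MKV", "MKV"), (), (0, 0))
    assert t3.distances(aln, "p").value("a", "b") == 0.0


def test_p_distance_arithmetic():
    aln = AnchoredAlignment(("a", "b"),
                            ("AAAAAAAAAA", "AACCAAAAAA"), (), (0, 0))
    assert t3.distances(aln, "p").value("a", "b") == pytest.approx(0.2)
    assert t3.distances(aln, "poisson").value("a", "b") == \
        pytest.approx(-np.log(0.8))


def test_gap_and_x_columns_pairwise_deleted():
    aln = AnchoredAlignment(("a", "b"),
                            ("AA-CXAAAAA", "AACCCAAAAC"), (), (0, 0))
    # comparable: 8 columns (positions 2 and 4 dropped), 1 mismatch
    assert t3.distances(aln, "p").value("a", "b") == pytest.approx(1 / 8)


def test_saturated_pair_under_poisson_is_error():
    aln = AnchoredAlignment(("a", "b"), ("AAAA", "CCCC"), (), (0, 0))
    with pytest.raises(DataError, match="p"):
        t3.distances(aln, "poisson")


def test_no_comparable_columns_is_error():
    aln = AnchoredAlignment(("a", "b"), ("AA--", "--AA"), (), (0, 0))
    with pytest.raises(DataError):
        t3.distances(aln, "p")


# -- neighbor joining ------------------------------------------------------


def test_nj_four_taxon_additive_recovery():
    # tree ((A:1,B:2):1,(C:3,D:4)): AB=3 AC=5 AD=6 BC=6 BD=7 CD=7
    tree = t3.nj_tree(dm("ABCD", [[0, 3, 5, 6], [3, 0, 6, 7],
                                  [5, 6, 0, 7], [6, 7, 7, 0]]))
    assert t3.is_monophyletic(tree, {"A", "B"})
    assert not t3.is_monophyletic(tree, {"A", "C"})
    d = tree.tip_distances()
    assert d[("A", "B")] == pytest.approx(3)
    assert d[("C", "D")] == pytest.approx(7)
    assert d[("A", "D")] == pytest.approx(6)


def test_nj_three_taxon_closed_form():
    tree = t3.nj_tree(dm("ABC", [[0, 3, 4], [3, 0, 5], [4, 5, 0]]))
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
    assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
    assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)


def test_nj_requires_three_taxa():
    with pytest.raises(DataError):
        t3.nj_tree(dm("AB", [[0, 1], [1, 0]]))


def test_nj_matches_minimum_evolution_oracle_on_additive_matrices():
    """100 random additive matrices, n <= 6: NJ topology equals the
    exhaustive minimum-evolution search result."""
    rng = np.random.default_rng(2024)
    for trial in range(100):
        n = int(rng.integers(4, 7))
        taxa = [f"t{i}" for i in range(n)]
        dist, true_parts = random_additive_tree(taxa, rng)
        mat = np.zeros((n, n))
        for (a, b), v in dist.items():
            i, j = taxa.index(a), taxa.index(b)
            mat[i, j] = mat[j, i] = v
        tree = t3.nj_tree(dm(taxa, mat))
        oracle_parts = minimum_evolution_topology(dist, taxa)
        assert tree.bipartitions() == set(oracle_parts) == set(true_parts)
        # additivity: path lengths reproduce the input to 1e-9
        d = tree.tip_distances()
        assert all(abs(d[p] - dist[p]) < 1e-9 for p in dist)


def test_nj_clamps_negative_branches_to_zero():
    # strongly non-additive matrix provokes negative estimates
    tree = t3.nj_tree(dm("ABCD", [[0, 1, 9, 9], [1, 0, 1, 9],
                                  [9, 1, 0, 1], [9, 9, 1, 0]]))
    for node in tree.preorder():
        assert node.length >= 0


# -- midpoint rooting ------------------------------------------------------


def test_midpoint_on_longest_path():
    x = Node()
    y = Node(name="Y", length=1.0)
    x.add(Node(name="A", length=1.0))
    x.add(Node(name="B", length=2.0))
    x.add(y)
    y.add(Node(name="C", length=3.0))
    y.add(Node(name="D", length=4.0))
    rooted = t3.midpoint_root(Tree(x))
    # longest path B-D (7); root on the Y-D edge, 0.5 from Y
    dist = rooted.tip_distances()
    root_children = {c.name or "internal": c.length
                     for c in rooted.root.children}
    assert rooted.rooted
    assert root_children.get("D") == pytest.approx(3.5)
    assert dist[("B", "D")] == pytest.approx(7)


def test_midpoint_balanced_quartet_roots_on_central_edge():
    left, right = Node(length=1.0), Node(length=1.0)
    root = Node()
    for name, parent in (("A", left), ("B", left), ("C", right),
                         ("D", right)):
        parent.add(Node(name=name, length=2.0))
    root.add(left)
    root.add(right)
    rooted = t3.midpoint_root(Tree(root))
    sides = [frozenset(t.name for t in _tips(c))
             for c in rooted.root.children]
    assert frozenset({"A", "B"}) in sides
    assert frozenset({"C", "D"}) in sides


def _tips(node):
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        (out.append(n) if n.is_tip else stack.extend(n.children))
    return out


def test_midpoint_two_tip_tree():
    root = Node()
    root.add(Node(name="A", length=1.0))
    root.add(Node(name="B", length=3.0))
    rooted = t3.midpoint_root(Tree(root))
    lengths = {t.name: t.length for t in rooted.tips()}
    assert lengths == {"A": pytest.approx(2.0), "B": pytest.approx(2.0)}


def test_midpoint_zero_length_tree_is_error():
    root = Node()
    root.add(Node(name="A", length=0.0))
    root.add(Node(name="B", length=0.0))
    with pytest.raises(TreeError):
        t3.midpoint_root(Tree(root))


def test_midpoint_matches_pairwise_enumeration(phylo_fixture):
    *_, aln = phylo_fixture
    tree = t3.nj_tree(t3.distances(aln, "p"))
    rooted = t3.midpoint_root(tree)
    # oracle: the root-to-tip height equals half the tree diameter
    diameter = max(tree.tip_distances().values())
    heights = {}
    for tip in rooted.tips():
        h, node = 0.0, tip
        while node.parent is not None:
            h += node.length
            node = node.parent
        heights[tip.name] = h
    assert max(heights.values()) == pytest.approx(diameter / 2)


# -- bootstrap -------------------------------------------------------------


def test_bootstrap_reproducible_for_fixed_seed(phylo_fixture):
    *_, aln = phylo_fixture
    t1 = t3.bootstrap_support(aln, replicates=25, seed=5)
    t2 = t3.bootstrap_support(aln, replicates=25, seed=5)
    assert t3.to_newick(t1) == t3.to_newick(t2)


def test_single_replicate_supports_are_zero_or_hundred(phylo_fixture):
    *_, aln = phylo_fixture
    tree = t3.bootstrap_support(aln, replicates=1, seed=2)
    supports = [n.support for n in tree.preorder()
                if n.support is not None]
    assert supports and all(s in (0.0, 100.0) for s in supports)


def test_degenerate_duplicate_rows_complete():
    row = "MKVAASTNQ" * 5
    aln = AnchoredAlignment(("a", "b", "c", "d"), (row,) * 4, (),
                            (0, 0, 0, 0))
    tree = t3.bootstrap_support(aln, replicates=10, seed=1)
    assert sorted(tree.tip_names()) == ["a", "b", "c", "d"]


def test_subclass_clades_supported_on_low_noise_fixture(phylo_fixture):
    records, labels, sites, aln = phylo_fixture
    tree = t3.bootstrap_support(aln, replicates=100, seed=17)
    rooted = t3.midpoint_root(tree)
    for sub in ("alpha", "beta", "gamma"):
        tips = [i for i, s in labels.items() if s == sub]
        assert t3.is_monophyletic(rooted, tips), sub
        assert t3.clade_support(tree, tips) >= 90, sub


# -- monophyly and divergence ----------------------------------------------


def test_monophyly_on_quartet():
    tree = t3.nj_tree(dm("ABCD", [[0, 2, 6, 6], [2, 0, 6, 6],
                                  [6, 6, 0, 2], [6, 6, 2, 0]]))
    assert t3.is_monophyletic(tree, {"A", "B"})
    assert not t3.is_monophyletic(tree, {"A", "C"})
    assert t3.is_monophyletic(tree, {"A", "B", "C", "D"})


def test_monophyly_unknown_tip_is_error():
    tree = t3.nj_tree(dm("ABC", [[0, 1, 2], [1, 0, 2], [2, 2, 0]]))
    with pytest.raises(DataError):
        t3.is_monophyletic(tree, {"Z"})


def test_interclass_divergence_hand_computed():
    labels = {"a": "x", "b": "y", "c": "z"}
    matrix = dm("abc", [[0, 1, 2], [1, 0, 4], [2, 4, 0]])
    div = t3.mean_interclass_divergence(matrix, labels)
    assert div == {"x": pytest.approx(1.5), "y": pytest.approx(2.5),
                   "z": pytest.approx(3.0)}


def test_equal_distances_give_equal_divergence():
    labels = {"a": "x", "b": "x", "c": "y", "d": "y"}
    matrix = dm("abcd", [[0, 1, 1, 1], [1, 0, 1, 1],
                         [1, 1, 0, 1], [1, 1, 1, 0]])
    div = t3.mean_interclass_divergence(matrix, labels)
    assert div["x"] == div["y"] == pytest.approx(1.0)


def test_beta_is_most_divergent_subclass(phylo_fixture):
    records, labels, sites, aln = phylo_fixture
    div = t3.mean_interclass_divergence(t3.distances(aln, "p"), labels)
    assert div["beta"] > div["alpha"]
    assert div["beta"] > div["gamma"]
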