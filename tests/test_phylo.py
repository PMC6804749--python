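"""Distances, neighbor joining, delimitation, haplotype networks, K-score."""
import itertools
import math
import random

import dendropy
import networkx as nx
import numpy as np
import pytest

from panplastome.matrix import AlignedMatrix
from panplastome.phylo import (DistanceMatrix, compare_trees, delimit_species,
                               minimum_spanning_network, nj_tree,
                               pdistance_matrix)
from panplastome.sites import collapse_haplotypes


# ---------------------------------------------------------------------------
# p-distances


def test_pdistance_examples():
    m = AlignedMatrix(["a", "b", "c"], ["ACGT", "ACGA", "AC-T"])
    d = pdistance_matrix(m)
    assert d.values[0, 0] == 0
    assert math.isclose(d.values[0, 1], 0.25)
    assert d.values[0, 2] == 0.0  # pairwise deletion: 3 comparable sites


def test_pdistance_no_comparable_sites_error():
    m = AlignedMatrix(["a", "b"], ["A-", "-A"])
    with pytest.raises(ValueError, match="a.*b"):
        pdistance_matrix(m)


# ---------------------------------------------------------------------------
# neighbor joining


def test_three_taxon_closed_form():
    # d(a,b)=3, d(a,c)=5, d(b,c)=6 -> la=1, lb=2, lc=4
    d = DistanceMatrix(["a", "b", "c"],
                       np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0.0]]))
    t = nj_tree(d)
    lengths = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
    assert math.isclose(lengths["a"], 1) and math.isclose(lengths["b"], 2)
    assert math.isclose(lengths["c"], 4)


def _patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda x: x.label)
    k = len(taxa)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return out


def test_nj_recovers_additive_trees():
    for rep in range(20):
        k = 5 + rep % 8
        tree = dendropy.simulate.treesim.birth_death_tree(
            1.0, 0.0, num_extant_tips=k, rng=random.Random(rep))
        for i, tx in enumerate(tree.taxon_namespace):
            tx.label = f"t{i}"
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length = round(float(e.length), 3) + 0.01
        labels = sorted(x.label for x in tree.taxon_namespace)
        d = _patristic(tree)
        nj = nj_tree(DistanceMatrix(labels, d))
        comp = compare_trees(tree, nj)
        assert comp.rf_distance == 0
        assert comp.k_score < 1e-9 and math.isclose(comp.k_factor, 1.0)


def test_identical_rows_give_zero_length_cherry():
    d = np.array([[0, 0, 4, 4], [0, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0.0]])
    t = nj_tree(DistanceMatrix(list("abcd"), d))
    lengths = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
    assert lengths["a"] == 0.0 and lengths["b"] == 0.0


def test_nj_requires_symmetry():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0.0]]))


# ---------------------------------------------------------------------------
# species delimitation


def test_delimitation_on_hand_computed_balanced_tree():
    # two groups of two tips; within-group path 2a, between 2a+2b
    a, b = 0.5, 1.5
    nwk = f"((x1:{a},x2:{a}):{b},(y1:{a},y2:{a}):{b},out:3.0);"
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    groups = {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y", "out": "OUT"}
    rows = {r.group: r for r in delimit_species(tree, groups, "OUT")}
    assert rows["X"].monophyletic and rows["Y"].monophyletic
    assert math.isclose(rows["X"].intra_dist, 2 * a)
    assert math.isclose(rows["X"].inter_dist_closest, 2 * a + 2 * b)
    assert rows["X"].closest_group == "Y"
    assert math.isclose(rows["X"].intra_over_inter, a / (a + b))
    assert math.isclose(rows["X"].av_mrca_tips, a)
    # singleton outgroup row
    assert rows["OUT"].intra_dist == 0 and rows["OUT"].intra_over_inter == 0
    assert rows["OUT"].av_mrca_tips == 0


def test_delimitation_detects_non_monophyly():
    nwk = "((x1:1,y1:1):1,(x2:1,y2:1):1,out:3);"
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    groups = {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y", "out": "OUT"}
    rows = {r.group: r for r in delimit_species(tree, groups, "OUT")}
    assert not rows["X"].monophyletic and not rows["Y"].monophyletic


def test_delimitation_missing_group_errors():
    tree = dendropy.Tree.get(data="((x1:1,x2:1):1,out:1);", schema="newick")
    with pytest.raises(ValueError):
        delimit_species(tree, {"x1": "X", "x2": "X", "out": "OUT"}, "MISSING")


def test_monophyly_agrees_with_exhaustive_bipartition_check(preset):
    m, _, _ = preset
    tree = nj_tree(pdistance_matrix(m))
    rows = delimit_species(tree, m.groups, "CP")
    tree2 = dendropy.Tree.get(data=tree.as_string(schema="newick"),
                              schema="newick", preserve_underscores=True)
    tree2.is_rooted = False
    tree2.encode_bipartitions()
    tip_labels = {t.label for t in tree2.taxon_namespace}
    splits = set()
    for e in tree2.preorder_edge_iter():
        if e.bipartition:
            side = {lf.taxon.label for lf in e.head_node.leaf_iter()}
            splits.add(frozenset(side))
            splits.add(frozenset(tip_labels - side))
    for r in rows:
        tips = frozenset(a for a, g in m.groups.items() if g == r.group)
        assert r.monophyletic == (tips in splits)


# ---------------------------------------------------------------------------
# minimum spanning network


def haps_from(seqs):
    m = AlignedMatrix([f"h{i}" for i in range(len(seqs))], seqs)
    return collapse_haplotypes(m)


def test_tied_edges_form_a_triangle():
    net = minimum_spanning_network(haps_from(["AAC", "ACA", "CAA"]))
    assert net.number_of_edges() == 3
    assert all(w == 2 for _, _, w in net.edges(data="weight"))


def test_chain_has_no_shortcut_edge():
    net = minimum_spanning_network(haps_from(["AAAA", "AAAT", "AATT"]))
    assert sorted((u, v) for u, v, _ in net.edges(data="weight")) == [
        ("h0", "h1"), ("h1", "h2")]


def test_star_topology_recovered():
    # a central haplotype two steps from six satellites that are >=4 apart
    center = "A" * 12
    sats = []
    for i in range(6):
        s = list(center)
        s[2 * i] = "C"
        s[2 * i + 1] = "C"
        sats.append("".join(s))
    net = minimum_spanning_network(haps_from([center] + sats))
    assert net.number_of_edges() == 6
    assert all(net.has_edge("h0", f"h{i}") for i in range(1, 7))


def test_msn_contains_every_random_tiebreak_mst():
    rng = np.random.default_rng(0)
    seqs = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(7)]
    haps = haps_from(sorted(set(seqs)))
    net = minimum_spanning_network(haps)
    g = nx.Graph()
    names = [h.members[0] for h in haps]
    from panplastome.phylo import substitution_distances
    d = substitution_distances(
        AlignedMatrix(names, [h.representative for h in haps])).values
    for i in range(len(names) - 1):
        for j in range(i + 1, len(names)):
            g.add_edge(names[i], names[j], weight=d[i, j])
    for rep in range(50):
        order = list(g.edges)
        rng.shuffle(order)
        shuffled = nx.Graph()
        for u, v in order:
            shuffled.add_edge(u, v, weight=g[u][v]["weight"])
        mst = nx.minimum_spanning_tree(shuffled, algorithm="kruskal")
        for u, v in mst.edges:
            assert net.has_edge(u, v)


def test_epsilon_adds_near_threshold_edges():
    # path A-B-C with d(A,B)=1, d(B,C)=1, d(A,C)=2: epsilon 1 admits A-C
    net = minimum_spanning_network(haps_from(["AAAA", "AAAT", "AATT"]), epsilon=1)
    assert net.number_of_edges() == 3


# ---------------------------------------------------------------------------
# tree congruence


def test_identity_and_scaling_properties():
    a = dendropy.Tree.get(data="((a:1,b:2):0.5,(c:1,d:3):0.25);", schema="newick")
    same = compare_trees(a, a)
    assert (same.k_factor, same.k_score, same.rf_distance) == (1.0, 0.0, 0)
    b = dendropy.Tree.get(data="((a:2,b:4):1,(c:2,d:6):0.5);", schema="newick")
    doubled = compare_trees(a, b)
    assert math.isclose(doubled.k_factor, 0.5)
    assert doubled.k_score < 1e-12 and doubled.rf_distance == 0


@pytest.mark.parametrize("c", [0.1, 3.0, 42.0])
def test_k_factor_recovers_arbitrary_scalings(c):
    a = dendropy.Tree.get(data="((a:1,b:2):0.5,(c:1.5,d:3):0.25,e:2);",
                          schema="newick")
    b = dendropy.Tree.get(data=a.as_string(schema="newick"), schema="newick")
    for e in b.preorder_edge_iter():
        if e.length is not None:
            e.length *= c
    comp = compare_trees(a, b)
    assert math.isclose(comp.k_factor, 1 / c, rel_tol=1e-9)
    assert comp.k_score < 1e-9


def test_k_score_matches_bruteforce_least_squares_on_random_pairs():
    for rep in range(10):
        t1 = dendropy.simulate.treesim.birth_death_tree(
            1.0, 0.0, num_extant_tips=8, rng=random.Random(rep))
        t2 = dendropy.simulate.treesim.birth_death_tree(
            1.0, 0.0, num_extant_tips=8, rng=random.Random(100 + rep))
        for t in (t1, t2):
            for i, tx in enumerate(t.taxon_namespace):
                tx.label = f"t{i}"
        comp = compare_trees(t1, t2)
        da, db = _patristic(t1), _patristic(t2)
        iu = np.triu_indices(8, k=1)
        va, vb = da[iu], db[iu]
        k = float(va @ vb / (vb @ vb))
        score = float(np.sqrt(np.mean((va - k * vb) ** 2)))
        assert math.isclose(comp.k_factor, k, rel_tol=1e-9)
        assert math.isclose(comp.k_score, score, rel_tol=1e-9, abs_tol=1e-12)


def test_tip_set_mismatch_lists_symmetric_difference():
    a = dendropy.Tree.get(data="((a:1,b:1):1,c:1);", schema="newick")
    b = dendropy.Tree.get(data="((a:1,b:1):1,d:1);", schema="newick")
    with pytest.raises(ValueError, match="c.*d"):
        compare_trees(a, b)
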