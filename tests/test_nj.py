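"""Neighbor-joining construction, bootstrap supports, clusters, monophyly."""

import numpy as np
import pytest

import barcodelim as bl
from barcodelim.errors import DistanceError, TreeError
from barcodelim.records import BarcodeAlignment, DistanceMatrix
from barcodelim.tree import Node, Tree
from treegen import all_unrooted_topologies, random_additive_tree


def test_three_taxon_closed_form():
    v = np.array([[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]])
    tree = bl.nj(DistanceMatrix(["a", "b", "c"], v, "K2P"))
    lengths = {leaf.label: leaf.length for leaf in tree.root.leaves()}
    assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.4))
    assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.4 - 0.5))
    assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.4 - 0.3))


def test_four_taxon_additive_recovery(rng):
    topo = all_unrooted_topologies(["a", "b", "c", "d"])[0]
    truth, dmat = random_additive_tree(topo, rng)
    rec = bl.nj(dmat)
    assert rec.bipartition_set() == truth.bipartition_set()
    want, got = truth.edge_lengths(), rec.edge_lengths()
    for key in want:
        assert got[key] == pytest.approx(want[key], abs=1e-9)


def test_five_taxon_exhaustive_topology_recovery(rng):
    labels = [f"t{i}" for i in range(5)]
    topologies = all_unrooted_topologies(labels)
    assert len(topologies) == 15
    for topo in topologies:
        for _ in range(3):
            truth, dmat = random_additive_tree(topo, rng)
            assert bl.nj(dmat).bipartition_set() == truth.bipartition_set()


def test_path_lengths_reproduce_additive_input(rng):
    topo = all_unrooted_topologies([f"t{i}" for i in range(6)])[17]
    truth, dmat = random_additive_tree(topo, rng)
    labels, got = bl.nj(dmat).leaf_distances()
    order = [labels.index(lab) for lab in dmat.labels]
    assert np.allclose(got[np.ix_(order, order)], dmat.values, atol=1e-9)


def test_matches_independent_nj_implementation(default_k2p):
    """Same unrooted topology as scikit-bio's NJ on a real-size matrix."""
    import skbio

    ours = bl.nj(default_k2p).bipartition_set()
    sk_tree = skbio.tree.nj(
        skbio.DistanceMatrix(default_k2p.values, ids=default_k2p.labels)
    )
    all_labels = frozenset(default_k2p.labels)
    ref = min(all_labels)
    theirs = set()
    for node in sk_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(all_labels) - 2:
            theirs.add(side if ref not in side else all_labels - side)
    assert ours == theirs


def test_negative_estimates_clamped_but_raw_kept():
    # triangle-violating matrix: the three-point formula for leaf a goes
    # negative ((0.1 + 0.1 - 0.3) / 2 = -0.05)
    v = np.array([[0.0, 0.1, 0.1], [0.1, 0.0, 0.3], [0.1, 0.3, 0.0]])
    tree = bl.nj(DistanceMatrix(list("abc"), v, "K2P"))
    nodes = [n for n in tree.preorder() if n is not tree.root]
    assert all(n.length >= 0 for n in nodes)
    assert any(n.raw_length < 0 for n in nodes)


def test_nj_requires_defined_pairs():
    v = np.array([[0, np.nan, 0.1], [np.nan, 0, 0.1], [0.1, 0.1, 0]])
    dmat = DistanceMatrix(
        list("abc"), v, "K2P", undefined_pairs={frozenset(("a", "b"))}
    )
    with pytest.raises(DistanceError, match="undefined"):
        bl.nj(dmat)


def test_nj_needs_three_taxa():
    with pytest.raises(TreeError):
        bl.nj(DistanceMatrix(["a", "b"], np.array([[0, 0.1], [0.1, 0]]), "K2P"))


# -- bootstrap -------------------------------------------------------------


def test_single_replicate_supports_are_all_or_nothing(small_dataset):
    aln, _, _ = small_dataset
    tree = bl.bootstrap_support(aln, replicates=1, seed=5)
    supports = [n.support for n in tree.internal_nodes()]
    assert supports and all(s in (0, 100) for s in supports)


def test_bootstrap_reproducible_and_order_invariant(small_dataset, rng):
    aln, _, _ = small_dataset
    t1 = bl.bootstrap_support(aln, replicates=25, seed=11)
    t2 = bl.bootstrap_support(aln, replicates=25, seed=11)
    sup1 = {b: n.support for b, n in t1.bipartitions().items()}
    sup2 = {b: n.support for b, n in t2.bipartitions().items()}
    assert sup1 == sup2
    shuffled = BarcodeAlignment([aln.records[i] for i in rng.permutation(len(aln))])
    t3 = bl.bootstrap_support(shuffled, replicates=25, seed=11)
    sup3 = {b: n.support for b, n in t3.bipartitions().items()}
    assert sup1 == sup3


def test_separated_clusters_get_high_support():
    """Deep divergence between two clusters yields support >= 97."""
    config = bl.SimConfig(
        n_families=1,
        genera_per_family=1,
        species_per_genus=2,
        seqs_per_species=4,
        seed=13,
    )
    aln, _, _ = bl.simulate_dataset(config)
    tree = bl.bootstrap_support(aln, replicates=100, seed=13)
    split = frozenset(f"Sp001_{k}" for k in range(1, 5))
    bips = tree.bipartitions()
    ref = min(tree.leaf_label_set)
    canon = split if ref not in split else tree.leaf_label_set - split
    assert canon in bips
    assert bips[canon].support >= 97


# -- cluster extraction ----------------------------------------------------


def _supported_tree_from(aln, seed=3):
    tree = bl.bootstrap_support(aln, replicates=50, seed=seed)
    dmat = bl.distance_matrix(aln, "K2P")
    return tree, dmat


def test_no_supported_edges_means_all_singletons(small_dataset):
    aln, _, _ = small_dataset
    tree, dmat = _supported_tree_from(aln)
    for node in tree.internal_nodes():
        node.support = 0
    part = bl.extract_nj_clusters(tree, dmat)
    assert part.n_groups == len(aln)


def test_degenerate_thresholds_give_one_cluster(small_dataset):
    aln, _, _ = small_dataset
    tree, dmat = _supported_tree_from(aln)
    part = bl.extract_nj_clusters(tree, dmat, support_min=0, intra_max=np.inf)
    assert part.n_groups == 1


def test_cluster_extraction_is_partition(default_dataset, default_k2p):
    aln, _, _ = default_dataset
    tree = bl.bootstrap_support(aln, replicates=50, seed=2)
    part = bl.extract_nj_clusters(tree, default_k2p)
    assert sorted(part.assignment) == sorted(aln.ids)
    assert part.n_groups == len(set(part.assignment.values()))
    assert set(part.assignment.values()) == set(range(part.n_groups))


# -- monophyly -------------------------------------------------------------


def _manual_tree(newick_like):
    """Build ((A1,A2),(B1,B2)) or ((A1,B1),(A2,B2)) shapes by hand."""
    left, right = newick_like
    ln = Node(children=[Node(label=x, length=0.1) for x in left], length=0.1)
    rn = Node(children=[Node(label=x, length=0.1) for x in right], length=0.1)
    return Tree(Node(children=[ln, rn]))


@pytest.fixture
def family_taxonomy():
    import pandas as pd

    return pd.DataFrame(
        {
            "species": ["a1", "a2", "b1", "b2"],
            "genus": ["GA", "GA", "GB", "GB"],
            "family": ["A", "A", "B", "B"],
        },
        index=pd.Index(["A1", "A2", "B1", "B2"], name="id"),
    )


def test_monophyly_concordant_tree(family_taxonomy):
    tree = _manual_tree((("A1", "A2"), ("B1", "B2")))
    out = {m.taxon: m.monophyletic for m in bl.monophyly_report(tree, family_taxonomy, "family")}
    assert out == {"A": True, "B": True}


def test_monophyly_interleaved_tree(family_taxonomy):
    tree = _manual_tree((("A1", "B1"), ("A2", "B2")))
    out = {m.taxon: m.monophyletic for m in bl.monophyly_report(tree, family_taxonomy, "family")}
    assert out == {"A": False, "B": False}


def test_families_monophyletic_on_concordant_simulation(default_dataset, default_k2p):
    _, tax, _ = default_dataset
    tree = bl.nj(default_k2p)
    out = bl.monophyly_report(tree, tax, "family")
    assert all(m.monophyletic for m in out)
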