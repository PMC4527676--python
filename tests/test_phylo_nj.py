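"""Poisson distances, neighbor joining, bootstrap and consensus."""

import numpy as np
import pytest

from globinsp.io_formats import SequenceRecord, read_newick, write_newick
from globinsp.phylo_nj import (
    DistanceMatrix,
    bootstrap_support,
    distance_matrix_from_msa,
    majority_consensus,
    nj_tree,
    p_distance,
    poisson_correct,
)
from globinsp.synthetic_data import (
    SimulationConfig,
    random_topology,
    simulate_family,
)


def test_p_distance_hand_counts():
    assert p_distance("ACDEFGHIKL", "ACDEFGHIKL") == 0.0
    assert p_distance("ACDEFGHIKL", "AAAAAFGHIK") == pytest.approx(
        sum(a != b for a, b in zip("ACDEFGHIKL", "AAAAAFGHIK")) / 10
    )
    assert p_distance("AAAAAAAAAA", "CCCCCAAAAA") == 0.5
    # X and gaps excluded pairwise: 1 of 2 comparable columns differ
    assert p_distance("AC-X", "AG-A") == 0.5
    assert np.isnan(p_distance("--XX", "AAAA"))


def test_poisson_correction_closed_forms():
    assert poisson_correct(0.0) == 0.0
    assert poisson_correct(0.5) == pytest.approx(np.log(2), abs=1e-12)
    assert poisson_correct(0.99) == pytest.approx(4.60517, abs=1e-5)
    with pytest.raises(ValueError, match="saturated"):
        poisson_correct(1.0)
    assert np.isnan(poisson_correct(float("nan")))


def test_nj_recovers_four_taxon_additive_tree():
    """Additive matrix from ((A:1,B:2):1,(C:3,D:4)): split and lengths."""
    ids = ["A", "B", "C", "D"]
    values = np.array([
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0],
    ], dtype=float)
    tree = nj_tree(DistanceMatrix(ids, values))
    assert frozenset({"C", "D"}) in tree.bipartitions()  # AB|CD split
    dist = tree.leaf_distances()
    assert np.allclose(dist.loc[ids, ids].values, values, atol=1e-9)


def test_nj_three_taxa_closed_form():
    values = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
    tree = nj_tree(DistanceMatrix(["a", "b", "c"], values))
    lengths = {n.name: n.length for n in tree.root.children}
    assert lengths == {"a": pytest.approx(0.5), "b": pytest.approx(1.5),
                       "c": pytest.approx(2.5)}


@pytest.mark.parametrize("n_taxa,seed", [(4, 0), (6, 1), (8, 2), (12, 3)])
def test_nj_exact_on_random_additive_matrices(n_taxa, seed):
    """Path distances of the NJ tree reproduce the generating tree's to 1e-9."""
    true_tree = random_topology(n_taxa, seed)
    truth = true_tree.leaf_distances()
    tree = nj_tree(DistanceMatrix(list(truth.index), truth.values))
    recovered = tree.leaf_distances().loc[truth.index, truth.columns]
    assert np.max(np.abs(recovered.values - truth.values)) < 1e-9
    assert set(tree.bipartitions()) == set(true_tree.bipartitions())


def test_nj_agrees_with_skbio_on_random_matrix():
    """Independent cross-check of the NJ topology against scikit-bio."""
    import skbio

    truth = random_topology(7, seed=5).leaf_distances()
    ids = list(truth.index)
    ours = nj_tree(DistanceMatrix(ids, truth.values))
    theirs = skbio.tree.nj(skbio.DistanceMatrix(truth.values, ids))
    ref = min(ids)
    their_splits = set()
    for node in theirs.non_tips():
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = frozenset(ids) - side
        if 2 <= len(side) <= len(ids) - 2:
            their_splits.add(frozenset(side))
    assert set(ours.bipartitions()) == their_splits


def test_nj_ultrametric_topology_matches_upgma():
    """On an ultrametric matrix NJ and UPGMA give the same topology."""
    from scipy.cluster.hierarchy import average, cut_tree
    from scipy.spatial.distance import squareform

    values = np.array([
        [0, 2, 6, 6],
        [2, 0, 6, 6],
        [6, 6, 0, 4],
        [6, 6, 4, 0],
    ], dtype=float)
    ids = ["A", "B", "C", "D"]
    tree = nj_tree(DistanceMatrix(ids, values))
    linkage = average(squareform(values))
    first_pair = sorted(int(i) for i in linkage[0, :2])
    # UPGMA joins {A,B} first, and 2-clusters are {A,B} vs {C,D}
    assert first_pair == [0, 1]
    labels = cut_tree(linkage, n_clusters=2).ravel()
    assert labels[0] == labels[1] and labels[2] == labels[3]
    assert set(tree.bipartitions()) == {frozenset({"C", "D"})}


def test_nj_errors():
    with pytest.raises(ValueError, match="at least 3"):
        nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
    values = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
    with pytest.raises(ValueError, match="a.*c|\\('a', 'c'\\)"):
        nj_tree(DistanceMatrix(["a", "b", "c"], values))


def test_distance_matrix_from_msa_pairwise_deletion():
    msa = [SequenceRecord("a", "AAAA"), SequenceRecord("b", "AACC"),
           SequenceRecord("c", "AA--")]
    dm = distance_matrix_from_msa(msa, correction="none")
    i, j = dm.ids.index("a"), dm.ids.index("b")
    assert dm.values[i, j] == 0.5
    k = dm.ids.index("c")
    assert dm.values[i, k] == 0.0  # only the two shared columns compared


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_deterministic_and_supported():
    tree = random_topology(6, seed=21)
    msa, _ = simulate_family(SimulationConfig(tree, 400, seed=21))
    b1 = bootstrap_support(msa, replicates=100, seed=7)
    b2 = bootstrap_support(msa, replicates=100, seed=7)
    assert write_newick(b1) == write_newick(b2)
    supports = [s for s in b1.bipartitions().values() if s is not None]
    assert supports and all(0 <= s <= 100 for s in supports)


def test_bootstrap_strong_split_high_support():
    """Two 3-taxon clusters across a long internal branch: the central split
    should be supported in nearly every replicate."""
    newick = ("((a1:0.05,a2:0.05,a3:0.05):0.5,"
              "(b1:0.05,b2:0.05,b3:0.05):0.5);")
    tree = read_newick(newick)
    for seed in (0, 1, 2):
        msa, _ = simulate_family(SimulationConfig(tree, 500, seed=seed))
        boot = bootstrap_support(msa, replicates=200, seed=seed)
        central = frozenset({"b1", "b2", "b3"})
        assert boot.bipartitions()[central] >= 95.0


def test_bootstrap_no_variation_errors():
    msa = [SequenceRecord(f"s{i}", "ACDEF") for i in range(4)]
    with pytest.raises(ValueError, match="no variation"):
        bootstrap_support(msa, replicates=10, seed=0)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def test_consensus_of_identical_trees():
    trees = [read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);") for _ in range(3)]
    cons = majority_consensus(trees)
    assert set(cons.bipartitions()) == set(trees[0].bipartitions())
    assert all(s == 100.0 for s in cons.bipartitions().values())


def test_consensus_majority_split_retained_at_67():
    trees = [
        read_newick("((A:1,B:1):1,C:1,D:1);"),
        read_newick("((A:1,B:1):1,C:1,D:1);"),
        read_newick("((A:1,C:1):1,B:1,D:1);"),
    ]
    cons = majority_consensus(trees)
    splits = cons.bipartitions()
    assert set(splits) == {frozenset({"C", "D"})}  # canonical side omits A
    assert round(splits[frozenset({"C", "D"})]) == 67


def test_consensus_all_conflicting_gives_star():
    trees = [
        read_newick("((A:1,B:1):1,C:1,D:1);"),
        read_newick("((A:1,C:1):1,B:1,D:1);"),
        read_newick("((A:1,D:1):1,B:1,C:1);"),
    ]
    cons = majority_consensus(trees)
    assert cons.bipartitions() == {}
    assert len(cons.root.children) == 4


def test_consensus_agrees_with_dendropy():
    """Cross-check against dendropy's majority-rule consensus."""
    import dendropy

    rng_trees = [random_topology(6, seed=s) for s in range(7)]
    newicks = [write_newick(t) for t in rng_trees]
    ours = majority_consensus(rng_trees)
    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList.get(data="".join(newicks), schema="newick",
                               taxon_namespace=tns)
    theirs = tl.consensus(min_freq=0.5)
    ids = sorted(rng_trees[0].leaf_names())
    ref = ids[0]
    their_splits = set()
    for node in theirs.preorder_internal_node_iter():
        side = frozenset(t.taxon.label for t in node.leaf_iter())
        if ref in side:
            side = frozenset(ids) - side
        if 2 <= len(side) <= len(ids) - 2:
            their_splits.add(side)
    assert set(ours.bipartitions()) == their_splits


def test_consensus_errors():
    with pytest.raises(ValueError, match="empty"):
        majority_consensus([])
    with pytest.raises(ValueError, match="leaf sets"):
        majority_consensus([
            read_newick("(A:1,B:1,C:1);"),
            read_newick("(A:1,B:1,D:1);"),
        ])


def test_consensus_bipartitions_mutually_compatible():
    trees = [random_topology(8, seed=s) for s in range(9)]
    cons = majority_consensus(trees)
    splits = list(cons.bipartitions())
    for i, s1 in enumerate(splits):
        for s2 in splits[i + 1:]:
            assert s1 <= s2 or s2 <= s1 or not (s1 & s2)
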