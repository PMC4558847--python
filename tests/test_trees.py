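import dendropy
import numpy as np
import pytest

import msabias as mb


def test_balanced_tree_shape():
    tree = mb.make_balanced_tree(6.0)
    assert sorted(tree.leaf_names()) == [f"t{i}" for i in range(1, 9)]
    assert np.isclose(tree.tree_length(), 6.0)
    classes = {}
    for node in tree.postorder():
        if node is tree.root:
            continue
        classes[node.branch_class] = classes.get(node.branch_class, 0) + 1
    assert classes == {"external": 8, "middle": 4, "root": 2}
    # 13 equal unrooted branches; the root splits the central one in half
    b = 6.0 / 13.0
    depths = tree.depths()
    assert np.allclose(list(depths.values()), b / 2 + 2 * b)


def test_polytomy_tree_shape():
    tree = mb.make_polytomy_tree()
    assert len(tree.root.children) == 4
    assert np.isclose(tree.tree_length(), 6 * 0.06 + 6 * 0.7)  # 4.56
    depths = set(np.round(list(tree.depths().values()), 10))
    assert depths == {0.12, 1.4}


def test_resolve_polytomy():
    base = mb.make_polytomy_tree()
    cands, lba = mb.resolve_polytomy(base)
    assert len(cands) == 3
    for c in cands:
        assert sorted(c.leaf_names()) == sorted(base.leaf_names())
        # resolution adds only a zero-length internal branch
        assert np.isclose(c.tree_length(), base.tree_length())
        assert max(len(n.children) for n in c.postorder()) <= 3
    for i in range(3):
        for j in range(i + 1, 3):
            assert mb.rf_distance(cands[i], cands[j]) == 2
    # the LBA candidate pairs the two deep (long) subtrees
    lba_tree = cands[lba]
    deep = frozenset(nm for nm, d in lba_tree.depths().items() if d > 0.5)
    bips = set(lba_tree.bipartitions())
    assert deep in bips or frozenset(lba_tree.leaf_names()) - deep in bips


def test_felsenstein_candidates():
    cands, correct, lba = mb.felsenstein_candidates(0.1, 1.0, 0.1, 8)
    assert len(cands) == 3 and correct != lba
    depths = cands[correct].depths()
    longs = sorted(d for nm, d in depths.items() if nm.startswith("L"))
    shorts = sorted(d for nm, d in depths.items() if nm.startswith("S"))
    # the root sits at one end of the internal branch, so the far pair of
    # subtrees is deeper by exactly that branch (0.1 here)
    assert np.allclose(sorted(set(np.round(longs, 10))), [1.0, 1.1])
    assert np.allclose(sorted(set(np.round(shorts, 10))), [0.1, 0.2])
    assert max(shorts) < min(longs)
    # the LBA candidate places the two long subtrees as sisters
    bips = cands[lba].bipartitions()
    long_names = frozenset(n for n in cands[lba].leaf_names() if n.startswith("L"))
    assert long_names in bips or (
        frozenset(cands[lba].leaf_names()) - long_names in bips
    )


def test_newick_round_trip():
    tree = mb.make_balanced_tree(3.5)
    again = mb.read_newick(mb.write_newick(tree))
    assert mb.rf_distance(tree, again) == 0
    n1, d1 = tree.path_length_matrix()
    n2, d2 = again.path_length_matrix()
    assert n1 == n2
    assert np.allclose(d1, d2)


def test_newick_parse_error():
    with pytest.raises(mb.NewickParseError):
        mb.read_newick("((a,b,(c);")


def test_rf_distance_against_dendropy():
    import random as _random

    taxa = [f"x{i}" for i in range(10)]
    tns = dendropy.TaxonNamespace(taxa)

    def random_newick(seed):
        t = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=10,
            rng=_random.Random(seed),
        )
        for leaf, name in zip(t.leaf_node_iter(), taxa):
            leaf.taxon.label = name
        return t.as_string(schema="newick").replace("[&R] ", "").strip()

    for seed in range(5):
        s1, s2 = random_newick(seed), random_newick(seed + 100)
        mine = mb.rf_distance(mb.read_newick(s1), mb.read_newick(s2))
        d1 = dendropy.Tree.get(data=s1, schema="newick", taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=s2, schema="newick", taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        ref = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert mine == ref


def test_embed_in_supertree_preserves_core_paths():
    core = mb.make_balanced_tree(6.0)
    names_ref, d_ref = core.path_length_matrix()
    big, core_names = mb.embed_in_supertree(core, 64, seed=3)
    assert sorted(core_names) == sorted(core.leaf_names())
    assert len(big.leaf_names()) == 64
    from msabias.trees import induced_subtree_path_lengths

    names_big, d_big = induced_subtree_path_lengths(big, names_ref)
    assert names_big == names_ref
    assert np.allclose(d_big, d_ref, atol=1e-10)


def test_scale_to():
    tree = mb.make_balanced_tree(2.0)
    tree.scale_to(5.0)
    assert np.isclose(tree.tree_length(), 5.0)
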