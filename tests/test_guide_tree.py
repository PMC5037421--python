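import itertools

import numpy as np
import pytest

from lcsalign.guide_tree import (
    GuideTree,
    chained_tree,
    covering_fraction,
    mc_covering_fraction,
    parse_newick,
    sackin_index,
    slink_tree,
    upgma_tree,
    write_newick,
)

from .oracles import linkage_heights


def rows_from_matrix(d):
    return [d[i, :i].copy() for i in range(len(d))]


def random_distance_matrix(rng, k):
    d = rng.uniform(0.1, 10.0, size=(k, k))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return d


def test_slink_hand_example():
    d = np.array([[0, 1, 5], [1, 0, 2], [5, 2, 0]], dtype=float)
    t = slink_tree(rows_from_matrix(d), 3)
    assert sorted(t.leaves_under(3)) == [0, 1]
    assert t.height[3] == 1.0
    assert t.height[4] == 2.0


def test_slink_two_leaves():
    d = np.array([[0, 3.5], [3.5, 0]])
    t = slink_tree(rows_from_matrix(d), 2)
    assert t.height[t.root] == 3.5
    assert sorted(t.leaves_under(t.root)) == [0, 1]


@pytest.mark.parametrize("k", [5, 20, 50])
def test_slink_heights_match_bruteforce(rng, k):
    for _ in range(3):
        d = random_distance_matrix(rng, k)
        t = slink_tree(rows_from_matrix(d), k)
        mine = sorted(t.height[k:].tolist())
        expected = sorted(linkage_heights(d, "single"))
        assert np.allclose(mine, expected)


def test_slink_heights_match_scipy(rng):
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    for _ in range(5):
        d = random_distance_matrix(rng, 30)
        t = slink_tree(rows_from_matrix(d), 30)
        Z = linkage(squareform(d), method="single")
        assert np.allclose(sorted(t.height[30:].tolist()), sorted(Z[:, 2]))


def test_slink_consumes_stream_without_full_matrix(rng):
    # rows are handed over one at a time by a generator that discards them
    k = 40
    d = random_distance_matrix(rng, k)

    def stream():
        for i in range(k):
            yield d[i, :i].copy()

    t = slink_tree(stream(), k)
    assert len(list(t.merges())) == k - 1


def test_upgma_hand_example():
    d = np.array([[0, 1, 5], [1, 0, 2], [5, 2, 0]], dtype=float)
    t = upgma_tree(rows_from_matrix(d), 3)
    assert t.height[3] == 1.0
    assert t.height[4] == pytest.approx(3.5)  # (5 + 2) / 2


@pytest.mark.parametrize("k", [5, 15, 30])
def test_upgma_heights_match_scipy(rng, k):
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    for _ in range(3):
        d = random_distance_matrix(rng, k)
        t = upgma_tree(rows_from_matrix(d), k)
        Z = linkage(squareform(d), method="average")
        assert np.allclose(sorted(t.height[k:].tolist()), sorted(Z[:, 2]))


def test_ultrametric_slink_equals_upgma(rng):
    # build an ultrametric matrix from a random dendrogram
    from scipy.cluster.hierarchy import cophenet, linkage
    from scipy.spatial.distance import squareform

    x = rng.normal(size=(12, 3))
    Z = linkage(x, method="average")
    d = squareform(cophenet(Z))
    ts = slink_tree(rows_from_matrix(d), 12)
    tu = upgma_tree(rows_from_matrix(d), 12)
    assert np.allclose(sorted(ts.height[12:]), sorted(tu.height[12:]))


def test_chained_tree_depths_and_sackin():
    t = chained_tree(4, [0, 1, 2, 3])
    assert t.leaf_depths().tolist() == [3, 3, 2, 1]
    raw, norm = sackin_index(t)
    assert raw == 9 and norm == pytest.approx(2.25)


@pytest.mark.parametrize("k", [2, 5, 17])
def test_chained_sackin_closed_form(k):
    raw, norm = sackin_index(chained_tree(k))
    assert norm == pytest.approx((k * k + k - 2) / (2 * k))


def test_chained_tree_seed_deterministic():
    a = chained_tree(10, 7)
    b = chained_tree(10, 7)
    assert np.array_equal(a.left, b.left) and np.array_equal(a.right, b.right)


def test_chained_tree_invalid_permutation():
    with pytest.raises(ValueError, match="permutation"):
        chained_tree(4, [0, 1, 1, 3])


def test_balanced_sackin():
    # ((0,1),(2,3)): all depths 2
    t = GuideTree(
        4,
        left=[-1, -1, -1, -1, 0, 2, 4],
        right=[-1, -1, -1, -1, 1, 3, 5],
        height=[0, 0, 0, 0, 1, 1, 2],
    )
    raw, norm = sackin_index(t)
    assert raw == 8 and norm == 2.0


def test_sackin_two_leaves():
    raw, norm = sackin_index(chained_tree(2))
    assert raw == 2 and norm == 1.0


def test_newick_roundtrip_and_cherry(tmp_path):
    labels = ["a", "b", "c"]
    p = tmp_path / "t.nwk"
    p.write_text("((a,b),c);\n")
    t = parse_newick(p, labels)
    assert sorted(t.leaves_under(3)) == [0, 1]
    out = tmp_path / "o.nwk"
    write_newick(t, labels, out)
    t2 = parse_newick(out, labels)
    assert np.array_equal(t.left, t2.left) and np.array_equal(t.right, t2.right)


def test_newick_unknown_label():
    with pytest.raises(ValueError, match="unknown leaf label"):
        parse_newick("((a,b),d);", ["a", "b", "c"])


def test_newick_missing_label():
    with pytest.raises(ValueError, match="missing"):
        parse_newick("(a,b);", ["a", "b", "c"])


def test_newick_multifurcation_rejected():
    with pytest.raises(ValueError, match="non-binary"):
        parse_newick("(a,b,c);", ["a", "b", "c"])


def _random_binary_tree(rng, k):
    nodes = list(range(k))
    left = [-1] * (2 * k - 1)
    right = [-1] * (2 * k - 1)
    nxt = k
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        left[nxt], right[nxt] = a, b
        nodes = [n for n in nodes if n not in (a, b)] + [nxt]
        nxt += 1
    return GuideTree(k, left, right, np.zeros(2 * k - 1))


def test_newick_roundtrip_random_trees(tmp_path, rng):
    for trial in range(100):
        k = int(rng.integers(2, 12))
        labels = [f"s{i}" for i in range(k)]
        t = _random_binary_tree(rng, k)
        p = tmp_path / f"t{trial}.nwk"
        write_newick(t, labels, p)
        t2 = parse_newick(p, labels)
        for node in range(k, 2 * k - 1):
            assert t.leaves_under(node) in [
                t2.leaves_under(m) for m in range(k, 2 * k - 1)
            ]


def test_newick_export_readable_by_dendropy(tmp_path):
    import dendropy

    labels = ["a", "b", "c", "d"]
    t = chained_tree(4)
    p = tmp_path / "t.nwk"
    write_newick(t, labels, p)
    dt = dendropy.Tree.get(path=str(p), schema="newick")
    assert sorted(x.taxon.label for x in dt.leaf_node_iter()) == labels


def test_covering_fraction_cherry_and_full():
    t = GuideTree(
        4,
        left=[-1, -1, -1, -1, 0, 2, 4],
        right=[-1, -1, -1, -1, 1, 3, 5],
        height=[0, 0, 0, 0, 1, 1, 2],
    )
    assert covering_fraction(t, [0, 1]) == 0.5
    assert covering_fraction(t, [0, 1, 2, 3]) == 1.0
    assert covering_fraction(t, [0]) == 0.25


def test_covering_fraction_errors():
    t = chained_tree(4)
    with pytest.raises(ValueError, match="empty"):
        covering_fraction(t, [])
    with pytest.raises(ValueError, match="unknown leaf"):
        covering_fraction(t, [9])


def test_mc_covering_matches_exhaustive_enumeration():
    t = chained_tree(6)
    m = 2
    exact = np.mean(
        [covering_fraction(t, list(c)) for c in itertools.combinations(range(6), m)]
    )
    mc = mc_covering_fraction(t, m, trials=4000, seed=3)
    assert mc == pytest.approx(exact, abs=0.03)
    assert mc_covering_fraction(t, m, trials=100, seed=5) == pytest.approx(
        mc_covering_fraction(t, m, trials=100, seed=5)
    )


def test_merge_heights_nondecreasing_to_root(rng):
    d = random_distance_matrix(rng, 20)
    for t in (slink_tree(rows_from_matrix(d), 20), upgma_tree(rows_from_matrix(d), 20)):
        for node, l, r in t.merges():
            for child in (l, r):
                if not t.is_leaf(child):
                    assert t.height[child] <= t.height[node] + 1e-12
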