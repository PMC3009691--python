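import math
import random

import pytest

from enzpat.clustering import (
    ClusterNode,
    annotate_ec_sets,
    complete_linkage,
    read_forest,
    singleton_trees,
    to_newick,
    tree_variability,
    write_forest,
)
from enzpat.ec import ECNumber
from enzpat.similarity import DistanceEntry

from oracles import canonical_tree, oracle_complete_linkage


def entries(*triples):
    return [DistanceEntry(a, b, d) for a, b, d in triples]


def random_distance_entries(rng, ids, density=0.8):
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if rng.random() < density:
                out.append(
                    DistanceEntry(ids[i], ids[j], 10 ** rng.uniform(-60, 0))
                )
    return out


class TestCompleteLinkage:
    def test_single_pair_and_singleton(self):
        forest = complete_linkage(entries(("A", "B", 1e-50)), ["A", "B", "C"])
        assert len(forest.trees) == 1
        assert forest.trees[0].members == {"A", "B"}
        assert forest.trees[0].merge_evalue == 1e-50
        assert [t.members for t in forest.singletons] == [frozenset({"C"})]

    def test_multidomain_sequence_does_not_bridge_families(self):
        # A and B are both similar to the two-domain sequence AB, but not
        # to each other: complete linkage must not merge A with B.
        forest = complete_linkage(
            entries(("A", "AB", 1e-40), ("AB", "B", 1e-38)), ["A", "AB", "B"]
        )
        assert len(forest.trees) == 1
        assert forest.trees[0].members == {"A", "AB"}
        assert [t.members for t in forest.singletons] == [frozenset({"B"})]

    def test_merge_heights_are_exact_cross_maxima(self):
        forest = complete_linkage(
            entries(("A", "B", 1e-30), ("A", "C", 1e-10), ("B", "C", 1e-5)),
            ["A", "B", "C"],
        )
        (tree,) = forest.trees
        assert tree.merge_evalue == 1e-5
        inner = [c for c in tree.children if not c.is_leaf]
        assert inner[0].merge_evalue == 1e-30

    def test_cutoff_is_inclusive(self):
        forest = complete_linkage(entries(("A", "B", 1e-3)), ["A", "B"])
        assert len(forest.trees) == 1
        forest = complete_linkage(entries(("A", "B", 2e-3)), ["A", "B"])
        assert forest.trees == []

    def test_duplicate_distance_entry_is_an_error(self):
        with pytest.raises(ValueError):
            complete_linkage(
                entries(("A", "B", 1e-5), ("A", "B", 1e-7)), ["A", "B"]
            )

    def test_no_distances_gives_all_singletons(self):
        forest = complete_linkage([], ["A", "B", "C"])
        assert forest.trees == []
        assert len(forest.singletons) == 3

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = random.Random(42)
        for trial in range(60):
            n = rng.randint(2, 12)
            ids = [f"R{i:02d}" for i in range(n)]
            dist = random_distance_entries(rng, ids)
            forest = complete_linkage(dist, ids, cutoff=1e-3)
            partition = {t.members for t in forest.trees} | {
                t.members for t in forest.singletons
            }
            trees = {canonical_tree(t) for t in forest.trees}
            oracle_partition, oracle_trees = oracle_complete_linkage(
                dist, ids, cutoff=1e-3
            )
            assert partition == oracle_partition, f"trial {trial}"
            assert trees == oracle_trees, f"trial {trial}"

    def test_monotone_heights_toward_leaves(self):
        rng = random.Random(9)
        ids = [f"R{i}" for i in range(10)]
        forest = complete_linkage(random_distance_entries(rng, ids), ids)

        def check(node, bound):
            if node.is_leaf:
                return
            assert node.merge_evalue <= bound
            for child in node.children:
                check(child, node.merge_evalue)

        for tree in forest.trees:
            check(tree, math.inf)

    def test_cut_consistency(self):
        # raising the cutoff never splits a cluster; lowering never merges
        rng = random.Random(13)
        ids = [f"R{i}" for i in range(10)]
        dist = random_distance_entries(rng, ids)
        low = complete_linkage(dist, ids, cutoff=1e-10)
        high = complete_linkage(dist, ids, cutoff=1e-3)
        high_clusters = [t.members for t in high.all_trees]
        for cluster in low.all_trees:
            assert any(cluster.members <= big for big in high_clusters)


def test_singleton_trees_completes_the_forest():
    forest = complete_linkage(entries(("A", "B", 1e-9)), ["A", "B"])
    singleton_trees(["A", "B", "C", "D"], forest)
    assert forest.member_ids() == {"A", "B", "C", "D"}
    assert len(forest.singletons) == 2
    # idempotent
    singleton_trees(["A", "B", "C", "D"], forest)
    assert len(forest.singletons) == 2


class TestVariability:
    def make_forest(self, groups):
        forest = complete_linkage([], [])
        forest.trees = []
        for members in groups:
            if len(members) == 1:
                forest.singletons.append(
                    ClusterNode(node_id=members[0], members=frozenset(members))
                )
            else:
                leaves = [
                    ClusterNode(node_id=m, members=frozenset({m})) for m in members
                ]
                root = ClusterNode(
                    node_id="+".join(members),
                    members=frozenset(members),
                    children=(leaves[0], leaves[1]),
                    merge_evalue=1e-9,
                )
                # shape does not matter for variability; fake a flat root
                root.children = tuple(leaves[:2])
                forest.trees.append(root)
        return forest

    def test_ratio_matches_sequences_over_trees(self):
        ec = ECNumber.parse("3.1.21.4")
        # 94 sequences of one EC spread over 73 trees -> ratio 1.29 (2 dp)
        groups, ec_by_id, counter = [], {}, 0
        for t in range(73):
            size = 2 if t < 21 else 1
            members = [f"S{counter + k}" for k in range(size)]
            counter += size
            groups.append(members)
            for m in members:
                ec_by_id[m] = frozenset({ec})
        forest = self.make_forest(groups)
        (row,) = tree_variability(forest, ec_by_id)
        assert (row.n_trees, row.n_sequences) == (73, 94)
        assert round(row.ratio, 2) == 1.29

    def test_single_tree_many_sequences(self):
        ec = ECNumber.parse("2.8.1.8")
        members = [f"S{i}" for i in range(389)]
        forest = self.make_forest([members])
        forest.trees[0] = ClusterNode(node_id="root", members=frozenset(members))
        forest.trees[0].children = ()
        (row,) = tree_variability(forest, {m: frozenset({ec}) for m in members})
        assert row.ratio == 389.0

    def test_singleton_tree_ratio_one(self):
        ec = ECNumber.parse("1.1.1.1")
        forest = self.make_forest([["S0"]])
        (row,) = tree_variability(forest, {"S0": frozenset({ec})})
        assert row.ratio == 1.0

    def test_truncation_level_groups_sub_subclasses(self):
        e1, e2 = ECNumber.parse("1.1.1.1"), ECNumber.parse("1.1.1.2")
        forest = self.make_forest([["S0"], ["S1"]])
        rows = tree_variability(
            forest, {"S0": frozenset({e1}), "S1": frozenset({e2})}, level=3
        )
        assert len(rows) == 1 and rows[0].ec_key == "1.1.1.-"


def test_forest_json_round_trip(tmp_path):
    forest = complete_linkage(
        entries(("A", "B", 1e-30), ("A", "C", 1e-10), ("B", "C", 1e-5)),
        ["A", "B", "C", "D"],
    )
    annotate_ec_sets(forest, {"A": frozenset({ECNumber.parse("1.1.1.1")})})
    path = tmp_path / "forest.json"
    write_forest(forest, path)
    loaded = read_forest(path)
    assert {canonical_tree(t) for t in loaded.trees} == {
        canonical_tree(t) for t in forest.trees
    }
    assert loaded.trees[0].ec_set == forest.trees[0].ec_set


def test_newick_rendering_contains_all_leaves():
    forest = complete_linkage(
        entries(("A", "B", 1e-30), ("A", "C", 1e-10), ("B", "C", 1e-5)),
        ["A", "B", "C"],
    )
    text = to_newick(forest.trees[0])
    assert text.endswith(";")
    for leaf in "ABC":
        assert leaf in text
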