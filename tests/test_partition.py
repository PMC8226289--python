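import math
import random

import pytest

from nlrdiv import (
    PartitionConfig,
    allelic_series_stats,
    enumerate_clades,
    initial_assignment,
    midpoint_root,
    read_tree,
    refine_clade,
    root_between,
)
from nlrdiv.errors import InputError
from nlrdiv.partition import CladePartition

from conftest import random_newick


# ---------------------------------------------------------------------------
# Independent brute-force oracle for the selection + de-nesting rule
# ---------------------------------------------------------------------------

def brute_force_partition(ptree, cfg):
    """Direct set-arithmetic restatement of the assignment rule: for each
    leaf, among all containing clades pick (max support, then max size,
    then min depth); fall back to clades below the minimum size; drop any
    selected clade strictly contained in another."""
    clades = []  # (leafset, support, depth)
    depth = {}
    for node in ptree.tree.preorder_node_iter():
        depth[id(node)] = (
            0 if node.parent_node is None else depth[id(node.parent_node)] + 1
        )
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        support = None if node.is_leaf() else node.support
        clades.append((leaves, support, depth[id(node)]))

    def best(cands):
        return max(
            cands,
            key=lambda c: (c[1] if c[1] is not None else 0.0, len(c[0]), -c[2]),
        )

    selected = set()
    for leaf in ptree.leaf_labels():
        containing = [c for c in clades if leaf in c[0]]
        eligible = [
            c for c in containing
            if cfg.min_clade_size <= len(c[0]) <= cfg.max_clade_size
        ]
        if not eligible:
            eligible = [c for c in containing if len(c[0]) < cfg.min_clade_size]
        selected.add(best(eligible)[0])
    return {
        s for s in selected
        if not any(s < other for other in selected)
    }


@pytest.mark.parametrize("n_trees", [120])
def test_initial_assignment_matches_bruteforce_oracle(n_trees):
    """On random small trees the implementation reproduces an exhaustive
    enumeration of the size-bounded maximal-support, de-nested rule."""
    rng = random.Random(1234)
    cfg = PartitionConfig(min_clade_size=2, max_clade_size=5)
    for _ in range(n_trees):
        n = rng.randint(4, 12)
        tree = read_tree(data=random_newick(rng, n))
        part = initial_assignment(tree, cfg)
        got = set(part.clades.values())
        expected = brute_force_partition(tree, cfg)
        assert got == expected
        part.validate(all_leaves=tree.leaf_labels())


def test_partition_invariants_on_random_trees():
    rng = random.Random(99)
    cfg = PartitionConfig(min_clade_size=3, max_clade_size=8)
    for _ in range(50):
        tree = read_tree(data=random_newick(rng, rng.randint(5, 20)))
        part = initial_assignment(tree, cfg)
        part.validate(all_leaves=tree.leaf_labels())  # disjoint+exhaustive+non-nesting


class TestEnumerateClades:
    def test_caterpillar_counts(self):
        t = read_tree(data="(((A:1,B:1):1,C:1):1,D:1);")
        entries = enumerate_clades(t)
        internal = [e for e in entries if e.size > 1]
        singles = [e for e in entries if e.size == 1]
        assert len(internal) == 3 and len(singles) == 4

    def test_star_counts(self):
        t = read_tree(data="(A:1,B:1,C:1,D:1,E:1);")
        entries = enumerate_clades(t)
        assert len([e for e in entries if e.size > 1]) == 1
        assert len([e for e in entries if e.size == 1]) == 5

    def test_leafsets_nested_in_ancestors(self):
        t = read_tree(data="(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        entries = {e.node_index: e for e in enumerate_clades(t)}
        for node in t.tree.preorder_node_iter():
            for anc in node.ancestor_iter():
                assert entries[node.index].leaves <= entries[anc.index].leaves


class TestInitialAssignmentRules:
    def test_root_clade_dominates_when_in_bounds(self):
        newick = "((A:1,B:1)50:1,(C:1,D:1)60:1)100;"
        t = read_tree(data=newick)
        cfg = PartitionConfig(min_clade_size=2, max_clade_size=4)
        part = initial_assignment(t, cfg)
        assert list(part.clades.values()) == [frozenset("ABCD")]

    def test_fallback_to_small_clades(self):
        newick = "(((A:1,B:1)90:1,C:1)95:1,((D:1,E:1)80:1,F:1)99:1);"
        t = read_tree(data=newick)
        cfg = PartitionConfig(min_clade_size=4, max_clade_size=10)
        # root (6 leaves in bounds? no: root has no support -> 0; size 6 is
        # within [4,10] so the root *is* eligible with support 0, and the
        # size-3 clades are not; the root clade wins.
        part = initial_assignment(t, cfg)
        assert set(part.clades.values()) == {frozenset("ABCDEF")}
        # with max below the leaf count, only sub-minimum clades remain
        cfg2 = PartitionConfig(min_clade_size=4, max_clade_size=5)
        part2 = initial_assignment(t, cfg2)
        assert set(part2.clades.values()) == {frozenset("ABC"), frozenset("DEF")}

    def test_unrooted_tree_rejected(self):
        t = read_tree(data="(A:1,B:1,C:1);")
        with pytest.raises(InputError, match="unrooted"):
            initial_assignment(t, PartitionConfig(min_clade_size=1, max_clade_size=3))


class TestRootBetween:
    def test_bipartition_rooting(self):
        t = read_tree(data="((A:1,B:1)90:2,(C:1,D:1)80:2);")
        rooted = root_between(t, ({"A", "B"}, {"C", "D"}))
        kids = rooted.root.child_nodes()
        sets = {rooted.leaf_set(k) for k in kids}
        assert sets == {frozenset("AB"), frozenset("CD")}

    def test_total_length_conserved(self):
        t = read_tree(data="(((A:1,B:2)90:3,C:4)70:5,D:6);")
        before = t.total_length()
        rooted = root_between(t, ({"A", "B"}, {"C", "D"}))
        assert math.isclose(rooted.total_length(), before, rel_tol=1e-9)

    def test_idempotent_on_topology(self):
        t = read_tree(data="((A:1,B:1)90:2,(C:1,D:1)80:2);")
        r1 = root_between(t, ({"A", "B"}, {"C", "D"}))
        r2 = root_between(r1, ({"A", "B"}, {"C", "D"}))
        sets1 = {r1.leaf_set(k) for k in r1.root.child_nodes()}
        sets2 = {r2.leaf_set(k) for k in r2.root.child_nodes()}
        assert sets1 == sets2

    def test_non_branch_bipartition_rejected(self):
        t = read_tree(data="((A:1,B:1)90:2,(C:1,D:1)80:2);")
        with pytest.raises(InputError):
            root_between(t, ({"A", "C"}, {"B", "D"}))


class TestRefineClade:
    def test_long_branch_cut(self):
        t = read_tree(data="((A:0.01,B:0.01)90:0.35,(C:0.01,D:0.01)90:0.01);")
        subs, log = refine_clade(t, PartitionConfig())
        assert frozenset("AB") in subs and frozenset("CD") in subs

    def test_all_short_branches_unchanged(self):
        t = read_tree(data="((A:0.05,B:0.05)90:0.08,(C:0.05,D:0.05)90:0.02);")
        subs, _ = refine_clade(t, PartitionConfig())
        assert subs == [frozenset("ABCD")]

    def test_intermediate_cut_on_disjoint_ecotypes(self):
        t = read_tree(data="((e1|a:0.01,e2|a:0.01)100:0.2,(e3|b:0.01,e4|b:0.01)100:0.01);")
        eco = {lf: lf.split("|")[0] for lf in t.leaf_labels()}
        subs, log = refine_clade(t, PartitionConfig(), eco)
        assert len(subs) == 2
        inter = log[log.rule == "intermediate"]
        assert inter.cut.any()

    def test_intermediate_retained_on_full_overlap(self):
        # same ecotypes on both sides -> Jaccard 1 -> keep
        t = read_tree(data="((e1|a:0.01,e2|a:0.01)100:0.2,(e1|b:0.01,e2|b:0.01)100:0.01);")
        eco = {lf: lf.split("|")[0] for lf in t.leaf_labels()}
        subs, _ = refine_clade(t, PartitionConfig(), eco)
        assert subs == [frozenset(t.leaf_labels())]

    def test_missing_ecotypes_with_intermediate_branch_errors(self):
        t = read_tree(data="((A:0.01,B:0.01)100:0.2,(C:0.01,D:0.01)100:0.01);")
        with pytest.raises(InputError, match="cotype"):
            refine_clade(t, PartitionConfig(), None)

    def test_branch_rules_hold_on_random_trees(self):
        """Branches >0.3 always cut; branches <=0.1 never cut."""
        rng = random.Random(4321)
        cfg = PartitionConfig()
        for _ in range(120):
            n = rng.randint(4, 15)
            t = read_tree(data=random_newick(rng, n, blen=(0.0, 0.6)))
            eco = {lf: f"e{rng.randint(0, 4)}" for lf in t.leaf_labels()}
            subs, log = refine_clade(t, cfg, eco)
            assert log.loc[log.branch_length > cfg.long_branch_cutoff, "cut"].all()
            assert not log.loc[
                log.branch_length <= cfg.short_branch_cutoff, "cut"
            ].any()
            # monotone: subclades partition the leaves
            union = frozenset().union(*subs)
            assert union == frozenset(t.leaf_labels())
            assert sum(len(s) for s in subs) == len(union)

    def test_infinite_cutoffs_are_identity(self):
        rng = random.Random(5)
        cfg = PartitionConfig(
            long_branch_cutoff=math.inf, short_branch_cutoff=math.inf
        )
        for _ in range(10):
            t = read_tree(data=random_newick(rng, 8, blen=(0.0, 2.0)))
            subs, _ = refine_clade(t, cfg)
            assert subs == [frozenset(t.leaf_labels())]

    def test_decisions_invariant_to_leaf_order(self):
        a = read_tree(data="((e1|a:0.01,e2|b:0.01)100:0.2,(e3|c:0.01,e4|d:0.01)100:0.01);")
        b = read_tree(data="(((e4|d:0.01,e3|c:0.01)100:0.01,(e2|b:0.01,e1|a:0.01)100:0.2));")
        eco = {f"e{i}|{g}": f"e{i}" for i, g in zip(range(1, 5), "abcd")}
        subs_a, _ = refine_clade(a, PartitionConfig(), eco)
        subs_b, _ = refine_clade(b, PartitionConfig(), eco)
        assert set(subs_a) == set(subs_b)


class TestMidpointRoot:
    def test_midpoint_balances_longest_path(self):
        t = read_tree(data="((A:1,B:1)90:1,C:5);")
        rooted = midpoint_root(t)
        # the longest leaf-to-leaf path (C..A/B = 7) is split evenly
        assert rooted.is_rooted()
        kids = rooted.root.child_nodes()
        assert {rooted.leaf_set(k) for k in kids} == {
            frozenset("AB"), frozenset("C")
        }


class TestAllelicStats:
    def test_all_allelic(self):
        part = CladePartition(clades={
            "c1": frozenset({"e1|a", "e2|a"}),
            "c2": frozenset({"e1|b", "e2|b"}),
        })
        eco = {lf: lf.split("|")[0] for cl in part.clades.values() for lf in cl}
        st = allelic_series_stats(part, eco)
        assert st.allelic_fraction == 1.0

    def test_mixed_partition_hand_count(self):
        part = CladePartition(clades={
            "C1": frozenset({"ea|x", "eb|y"}),      # 2 ecotypes x 1 gene
            "C2": frozenset({"ea|u", "ea|v"}),      # ecotype ea x 2 genes
        })
        eco = {lf: lf.split("|")[0] for cl in part.clades.values() for lf in cl}
        st = allelic_series_stats(part, eco)
        assert st.allelic_fraction == 0.5
        assert st.max_genes_per_ecotype == {"C1": 1, "C2": 2}

    def test_large_clade_fraction_boundary(self):
        part = CladePartition(clades={
            "c": frozenset(f"e{i}|g" for i in range(19)),
        })
        eco = {lf: lf.split("|")[0] for lf in part.clades["c"]}
        st = allelic_series_stats(part, eco)
        assert st.fraction_in_large_clades == 0.0
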