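import pytest

from oracles import four_point_metric_tree_distances

from hgtscreen.alignment import Alignment
from hgtscreen.search import (
    ConstraintSet,
    SearchConfig,
    bootstrap_support,
    constrained_search,
    exhaustive_search,
    exhaustive_topologies,
    nj_start_tree,
    nni_search,
)
from hgtscreen.simulate import evolve_alignment, inject_hgt
from hgtscreen.tree import Tree, neighbor_joining


class TestTreeBasics:
    def test_newick_round_trip_preserves_splits(self):
        nwk = "((a:0.1,b:0.2)90:0.05,(c:0.3,d:0.1)75:0.07,e:0.2);"
        t = Tree.from_newick(nwk)
        back = Tree.from_newick(t.to_newick(support=True))
        assert back.bipartitions() == t.bipartitions()
        supports = {n.support for n in back.postorder() if n.support is not None}
        assert supports == {90, 75}

    def test_monophyly_on_quartet(self):
        t = Tree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert t.is_monophyletic({"a", "b"})
        assert not t.is_monophyletic({"a", "c"})
        assert t.is_monophyletic({"a"})  # singleton
        assert t.is_monophyletic({"a", "b", "c", "d"})  # full set
        with pytest.raises(ValueError, match="zzz"):
            t.is_monophyletic({"zzz"})

    def test_reroot_preserves_unrooted_splits_and_total_length(self):
        t = Tree.from_newick("((a:0.1,b:0.2):0.05,(c:0.3,d:0.1):0.07,e:0.2);")
        before = (t.bipartitions(), pytest.approx(t.total_length()))
        target = [n for n in t.postorder() if not n.is_leaf and n.parent][0]
        t.reroot_at(target)
        assert t.bipartitions() == before[0]
        assert t.total_length() == before[1]


class TestNeighborJoining:
    def test_three_taxa_unique_topology(self):
        aln = Alignment(["a", "b", "c"], ["ARNDQ", "ARNDE", "ARNEE"])
        t = nj_start_tree(aln)
        assert sorted(t.leaf_names()) == ["a", "b", "c"]
        assert t.bipartitions() == set()

    def test_additive_distances_recover_true_topology(self):
        names, D, true_splits = four_point_metric_tree_distances()
        t = neighbor_joining(names, D)
        assert t.bipartitions() == true_splits

    def test_identical_sequences_give_zero_lengths(self):
        aln = Alignment(["a", "b", "c", "d"], ["ARND"] * 4)
        t = nj_start_tree(aln)
        assert t.total_length() == pytest.approx(0.0, abs=1e-12)

    def test_saturated_pair_warns_and_caps(self):
        aln = Alignment(
            ["a", "b", "c"], ["AAAAAAAAAAAAAAAAAAAA", "RNDCQEGHILKMFPSTWYVR", "AAAAAAAAAARNDCQEGHIL"]
        )
        with pytest.warns(UserWarning, match="saturated"):
            nj_start_tree(aln)


class TestTopologyEnumeration:
    @pytest.mark.parametrize("n,count", [(3, 1), (4, 3), (5, 15), (6, 105)])
    def test_counts_match_double_factorial(self, n, count):
        taxa = [f"t{i}" for i in range(n)]
        topos = list(exhaustive_topologies(taxa))
        assert len(topos) == count
        splits = {frozenset(t.bipartitions()) for t in topos}
        assert len(splits) == count  # all distinct


class TestNNISearch:
    def test_five_taxon_search_matches_exhaustive(self, lg_g):
        true = Tree.from_newick("((a:0.2,b:0.3):0.15,c:0.25,(d:0.2,e:0.3):0.2);")
        aln = evolve_alignment(true, lg_g, 500, seed=3)
        bt, bl = exhaustive_search(aln, lg_g, tol=1e-4)
        nt, nl = nni_search(aln, lg_g, nj_start_tree(aln), SearchConfig(tol=1e-4))
        assert nl == pytest.approx(bl, abs=1e-5)
        assert nt.bipartitions() == bt.bipartitions()

    def test_start_at_optimum_does_not_decrease(self, six_taxon_tree, lg_g):
        aln = evolve_alignment(six_taxon_tree, lg_g, 400, seed=5)
        from hgtscreen.likelihood import optimize_branch_lengths

        _, start_lnl = optimize_branch_lengths(aln, six_taxon_tree, lg_g)
        _, lnl = nni_search(aln, lg_g, six_taxon_tree, SearchConfig())
        assert lnl >= start_lnl - 1e-6

    def test_leaf_order_invariance(self, six_taxon_tree, lg_g):
        aln = evolve_alignment(six_taxon_tree, lg_g, 300, seed=6)
        perm = Alignment(list(reversed(aln.ids)), list(reversed(aln.rows)))
        cfg = SearchConfig(tol=1e-6)
        _, l1 = nni_search(aln, lg_g, nj_start_tree(aln), cfg)
        _, l2 = nni_search(perm, lg_g, nj_start_tree(perm), cfg)
        assert l1 == pytest.approx(l2, abs=1e-4)


class TestConstrainedSearch:
    def test_vacuous_constraint_matches_unconstrained(self, six_taxon_tree, lg_g):
        aln = evolve_alignment(six_taxon_tree, lg_g, 300, seed=8)
        cs = ConstraintSet(groups={"all": frozenset(aln.ids)})
        _, l_con = constrained_search(aln, lg_g, cs, SearchConfig())
        _, l_un = nni_search(aln, lg_g, nj_start_tree(aln), SearchConfig())
        assert l_con == pytest.approx(l_un, abs=1e-3)

    def test_satisfied_constraint_costs_nothing(self, six_taxon_tree, lg_g):
        aln = evolve_alignment(six_taxon_tree, lg_g, 400, seed=9)
        cs = ConstraintSet(groups={"ab": frozenset({"a", "b"})})
        _, l_con = constrained_search(aln, lg_g, cs, SearchConfig())
        _, l_un = nni_search(aln, lg_g, nj_start_tree(aln), SearchConfig())
        assert l_con == pytest.approx(l_un, abs=1e-2)

    def test_result_always_satisfies_groups(self, hgt_benchmark, lg_g):
        cs = hgt_benchmark.vertical_constraint
        tree, _ = constrained_search(
            hgt_benchmark.alignment, lg_g, cs, SearchConfig(tol=1e-3)
        )
        assert cs.satisfied_by(tree)

    def test_displaced_taxon_forced_home_loses_likelihood(self, lg_g):
        # 6-taxon tree, one taxon SPR-displaced into the far clade before evolving
        base = Tree.from_newick(
            "((a:0.1,b:0.1):0.3,(c:0.1,d:0.1):0.3,(e:0.1,f:0.1):0.3);"
        )
        moved = inject_hgt(base, "a", {"e", "f"}, stalk=0.02)
        aln = evolve_alignment(moved, lg_g, 400, seed=10)
        cs = ConstraintSet(groups={"ab": frozenset({"a", "b"})})
        _, l_con = exhaustive_search(aln, lg_g, constraints=cs)
        _, l_un = exhaustive_search(aln, lg_g)
        assert l_con < l_un - 2.0

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ConstraintSet(groups={"x": {"a", "b"}, "y": {"b", "c"}})


class TestBootstrap:
    def test_supports_bounded_and_deterministic(self, lg_g):
        tree = Tree.from_newick(
            "((a:0.1,b:0.15):0.3,(c:0.1,d:0.12):0.3,e:0.2);"
        )
        aln = evolve_alignment(tree, lg_g, 300, seed=21)
        cfg = SearchConfig(n_bootstrap=10, seed=77)
        t1 = bootstrap_support(aln, lg_g, cfg)
        t2 = bootstrap_support(aln, lg_g, cfg)
        s1 = [n.support for n in t1.postorder() if n.support is not None]
        s2 = [n.support for n in t2.postorder() if n.support is not None]
        assert s1 and s1 == s2
        assert all(0 <= s <= 100 for s in s1)

    def test_long_internal_branch_gets_high_support(self, lg_g):
        tree = Tree.from_newick(
            "((a:0.05,b:0.05):0.5,(c:0.05,d:0.05):0.5,e:0.1);"
        )
        aln = evolve_alignment(tree, lg_g, 1000, seed=23)
        out = bootstrap_support(aln, lg_g, SearchConfig(n_bootstrap=20, seed=5))
        supports = {
            frozenset(x.name for x in Tree(n).leaves()): n.support
            for n in out.postorder()
            if n.support is not None
        }
        key = min((k for k in supports), key=lambda k: sorted(k))
        assert max(supports.values()) >= 95


def test_search_config_validation():
    with pytest.raises(ValueError):
        SearchConfig(n_bootstrap=0)
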