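import numpy as np
import pytest

from conftest import random_gene_tree
from genechron.reconcile import (
    EventRecord,
    PenaltyScheme,
    count_events,
    reconcile,
    reconcile_bootstraps,
    slice_tree,
)
from genechron.synthetic import SimulationParams, simulate_dated_tree, simulate_gene_family
from genechron.trees import DatedTree, GeneTree
from oracles import dtl_min_cost_oracle

DEFAULT = PenaltyScheme(3, 2, 1, 0)


# ---------------------------------------------------------------------------
# time slicing
# ---------------------------------------------------------------------------

class TestSliceTree:
    def test_three_leaf_slices(self, three_leaf_sliced):
        s = three_leaf_sliced
        assert s.boundaries == [3.0, 1.0, 0.0]
        assert {b.id for b in s.segments[0]} == {"n0", "C"}
        assert {b.id for b in s.segments[1]} == {"A", "B", "C"}

    def test_slice_count_is_leaves_minus_one(self):
        for seed in range(5):
            tree = simulate_dated_tree(7, 1e-3, 3e-4, 500.0, seed=seed)
            assert slice_tree(tree).n_slices == 6  # distinct internal ages

    def test_tied_ages_merge_boundaries(self):
        tree = DatedTree.from_newick("((A:1.0,B:1.0):2.0,(C:1.0,D:1.0):2.0);")
        sliced = slice_tree(tree)
        assert sliced.boundaries == [3.0, 1.0, 0.0]
        assert sliced.n_slices == 2

    def test_segment_counts_grow_towards_present(self, species_10):
        sliced = slice_tree(species_10)
        sizes = [len(s) for s in sliced.segments]
        assert sizes[0] == 2
        assert sizes[-1] == len(species_10.leaves)
        assert all(b - a >= 0 for a, b in zip(sizes, sizes[1:]))

    def test_non_ultrametric_rejected(self):
        tree = simulate_dated_tree(4, 1e-3, 0.0, 100.0, seed=1)
        internal = next(n for n in tree.postorder()
                        if not n.is_leaf and n.parent is not None)
        internal.age = internal.parent.age + 5.0
        with pytest.raises(ValueError):
            slice_tree(tree)


# ---------------------------------------------------------------------------
# single-tree reconciliation
# ---------------------------------------------------------------------------

class TestReconcile:
    def test_congruent_tree_costs_zero(self, three_leaf_sliced):
        gene = GeneTree.from_newick("((A,B),C);")
        res = reconcile(gene, three_leaf_sliced, DEFAULT)
        assert res.total_penalty == 0
        counts = res.class_counts()
        assert counts == {"BIRTH": 1, "SPC": 2, "DUP": 0, "HGT": 0, "LOS": 0}

    def test_subclade_birth_needs_no_losses(self, three_leaf_sliced):
        gene = GeneTree.from_newick("(A,B);")
        res = reconcile(gene, three_leaf_sliced, DEFAULT)
        assert res.total_penalty == 0
        births = [e for e in res.events if e.event_class == "BIRTH"]
        assert births[0].branch == "n0"          # the AB stem branch
        assert (births[0].older, births[0].younger) == (3.0, 1.0)
        assert not [e for e in res.events if e.event_class == "LOS"]

    def test_discordant_three_leaf_worked_example(self, three_leaf_sliced):
        # ((A,C),B) vs species ((A,B),C): one transfer after the AB split
        # is the cheapest explanation (frozen against the scenario oracle)
        gene = GeneTree.from_newick("((A,C),B);")
        res = reconcile(gene, three_leaf_sliced, DEFAULT)
        assert res.total_penalty == 3.0
        counts = res.class_counts()
        assert counts["HGT"] == 1 and counts["DUP"] == 0 and counts["LOS"] == 0

    def test_unmappable_leaf_named_in_error(self, three_leaf_sliced):
        gene = GeneTree.from_newick("((A,Z),B);")
        with pytest.raises(ValueError, match="Z"):
            reconcile(gene, three_leaf_sliced, DEFAULT)

    def test_single_leaf_family(self, three_leaf_sliced):
        gene = GeneTree.from_newick("C;")
        res = reconcile(gene, three_leaf_sliced, DEFAULT)
        assert res.total_penalty == 0
        assert count_events(res).sum() == 0

    def test_hgt_events_respect_time_consistency(self, species_10):
        sliced = slice_tree(species_10)
        rng = np.random.default_rng(17)
        for _ in range(20):
            gene = random_gene_tree(rng, species_10.leaf_labels, 6)
            res = reconcile(gene, sliced, DEFAULT)
            for ev in res.events:
                if ev.event_class != "HGT":
                    continue
                donor = species_10.node_by_id(ev.branch)
                recipient = species_10.node_by_id(ev.recipient)
                # donor and recipient both alive throughout the slice
                for seg in (donor, recipient):
                    assert seg.parent.age >= ev.older - 1e-6
                    assert seg.age <= ev.younger + 1e-6

    def test_total_penalty_equals_weighted_counts(self, species_10):
        sliced = slice_tree(species_10)
        rng = np.random.default_rng(23)
        for _ in range(10):
            gene = random_gene_tree(rng, species_10.leaf_labels, 5)
            res = reconcile(gene, sliced, DEFAULT)
            c = res.class_counts()
            assert res.total_penalty == pytest.approx(
                3 * c["HGT"] + 2 * c["DUP"] + 1 * c["LOS"])

    def test_oracle_equivalence_spot_check(self):
        # deeper sweep lives in the acceptance suite
        rng = np.random.default_rng(3)
        for trial in range(10):
            species = simulate_dated_tree(int(rng.integers(2, 6)), 1e-3, 3e-4,
                                          100.0, seed=trial)
            sliced = slice_tree(species)
            gene = random_gene_tree(rng, species.leaf_labels,
                                    int(rng.integers(1, 6)))
            dp = reconcile(gene, sliced, DEFAULT).total_penalty
            assert dp == pytest.approx(dtl_min_cost_oracle(gene, sliced, DEFAULT))


class TestRootingSearch:
    def test_search_never_beats_by_less(self, species_10):
        sliced = slice_tree(species_10)
        rng = np.random.default_rng(5)
        for _ in range(5):
            gene = random_gene_tree(rng, species_10.leaf_labels, 5)
            rooted_cost = reconcile(gene, sliced, DEFAULT).total_penalty
            unrooted = GeneTree(gene.root.copy(), rooted=False)
            searched = reconcile(unrooted, sliced, DEFAULT)
            assert searched.total_penalty <= rooted_cost + 1e-9

    def test_search_recovers_zero_cost_under_misrooting(self, three_leaf_sliced):
        # the unrooted topology of ((A,B),C) rerooted on A's branch
        gene = GeneTree.from_newick("(A,(B,C));", rooted=False)
        res = reconcile(gene, three_leaf_sliced, DEFAULT)
        assert res.total_penalty == 0

    def test_search_is_deterministic(self, species_10):
        sliced = slice_tree(species_10)
        rng = np.random.default_rng(11)
        gene = random_gene_tree(rng, species_10.leaf_labels, 5)
        gene.rooted = False
        a = reconcile(gene, sliced, DEFAULT)
        b = reconcile(gene, sliced, DEFAULT)
        assert a.gene_tree.to_newick() == b.gene_tree.to_newick()
        assert [e.key() for e in a.events] == [e.key() for e in b.events]


# ---------------------------------------------------------------------------
# bootstrap consensus
# ---------------------------------------------------------------------------

class TestBootstraps:
    def test_single_replicate_equals_plain_reconcile(self, three_leaf_sliced):
        gene = GeneTree.from_newick("((A,C),B);")
        single = reconcile(gene, three_leaf_sliced, DEFAULT)
        boot = reconcile_bootstraps([gene], three_leaf_sliced, DEFAULT)
        assert boot.total_penalty == single.total_penalty
        assert sorted(e.key() for e in boot.events) == sorted(
            e.key() for e in single.events)
        assert all(e.support == 1.0 for e in boot.events)

    def test_identical_replicates_have_full_support(self, three_leaf_sliced):
        gene = GeneTree.from_newick("((A,B),C);")
        boot = reconcile_bootstraps([gene] * 10, three_leaf_sliced, DEFAULT)
        assert all(e.support == 1.0 for e in boot.events)

    def test_support_threshold_semantics(self, three_leaf_sliced):
        with_hgt = GeneTree.from_newick("((A,C),B);")
        without = GeneTree.from_newick("((A,B),C);")
        replicates = [with_hgt] * 5 + [without] * 5
        at_half = reconcile_bootstraps(replicates, three_leaf_sliced, DEFAULT,
                                       support_threshold=0.5)
        hgts = [e for e in at_half.events if e.event_class == "HGT"]
        assert len(hgts) == 1 and hgts[0].support == pytest.approx(0.5)
        at_60 = reconcile_bootstraps(replicates, three_leaf_sliced, DEFAULT,
                                     support_threshold=0.6)
        assert not [e for e in at_60.events if e.event_class == "HGT"]

    def test_empty_replicates_rejected(self, three_leaf_sliced):
        with pytest.raises(ValueError):
            reconcile_bootstraps([], three_leaf_sliced, DEFAULT)


# ---------------------------------------------------------------------------
# event counting
# ---------------------------------------------------------------------------

class TestCountEvents:
    def test_congruent_counts(self):
        species = simulate_dated_tree(5, 1e-3, 0.0, 100.0, seed=9)
        gene, _ = simulate_gene_family(species, SimulationParams(seed=1))
        res = reconcile(gene, slice_tree(species), DEFAULT)
        counts = count_events(res)
        assert counts["SPC"] == 4
        assert counts["HGT"] == counts["LOS"] == counts["DUP"] == 0

    def test_counts_match_event_list_recount(self, species_10):
        sliced = slice_tree(species_10)
        rng = np.random.default_rng(41)
        gene = random_gene_tree(rng, species_10.leaf_labels, 6)
        res = reconcile(gene, sliced, DEFAULT)
        counts = count_events(res)
        for cls in ("HGT", "SPC", "LOS", "DUP"):
            assert counts[cls] == sum(e.event_class == cls for e in res.events)
        assert "BIRTH" not in counts.index


def test_event_record_midpoint_invariant():
    ev = EventRecord("DUP", "b", 10.0, 4.0)
    assert ev.midpoint == pytest.approx(7.0)
    with pytest.raises(ValueError):
        EventRecord("DUP", "b", 4.0, 10.0)
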