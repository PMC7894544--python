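import math

import numpy as np
import pytest

from genechron.synthetic import (
    SimulationParams,
    forward_lineage_count,
    perturb_gene_tree,
    simulate_alignment,
    simulate_dated_tree,
    simulate_gene_family,
    simulate_hit_table,
)
from genechron.trees import robinson_foulds
from oracles import jc_expected_difference


# ---------------------------------------------------------------------------
# dated species trees
# ---------------------------------------------------------------------------

def test_two_tip_tree_is_a_cherry_at_root_age():
    tree = simulate_dated_tree(2, 1e-3, 2e-4, 3800.0, seed=0)
    assert len(tree.leaves) == 2
    assert tree.root.age == pytest.approx(3800.0)
    assert all(leaf.age == 0.0 for leaf in tree.leaves)


def test_simulated_trees_are_ultrametric_and_sized():
    # invariant sweep over many random trees
    for seed in range(60):
        n = 2 + seed % 7
        tree = simulate_dated_tree(n, 1e-3, 4e-4, 1000.0, seed=seed)
        tree.validate()  # leaves at 0, strict age ordering, binary
        assert len(tree.leaves) == n
        assert tree.root_age == pytest.approx(1000.0)


def test_same_seed_gives_identical_newick():
    a = simulate_dated_tree(9, 1e-3, 4e-4, 3800.0, seed=77).to_newick()
    b = simulate_dated_tree(9, 1e-3, 4e-4, 3800.0, seed=77).to_newick()
    assert a == b


def test_yule_growth_matches_closed_form():
    """Unconditioned pure-birth process: E[N(t)] = exp(birth_rate * t)."""
    lam, t = 0.02, 100.0
    rng = np.random.default_rng(12345)
    counts = np.array([forward_lineage_count(lam, 0.0, t, rng)
                       for _ in range(2000)], dtype=float)
    expected = math.exp(lam * t)
    se = counts.std(ddof=1) / math.sqrt(len(counts))
    assert abs(counts.mean() - expected) < 3 * se


def test_impossible_conditioning_raises():
    with pytest.raises(RuntimeError):
        # death dominates birth so 8 survivors are essentially unreachable
        simulate_dated_tree(8, 1e-4, 5e-2, 100.0, seed=3, max_attempts=50)


# ---------------------------------------------------------------------------
# gene families
# ---------------------------------------------------------------------------

def test_no_events_gives_congruent_family(species_10):
    gene, log = simulate_gene_family(species_10, SimulationParams(seed=5))
    assert gene is not None
    counts = log.counts()
    assert counts["BIRTH"] == 1
    assert counts["SPC"] == len(species_10.leaves) - 1
    assert counts["DUP"] == counts["HGT"] == counts["LOS"] == 0
    # topology identical: same splits as the species tree
    from genechron.trees import GeneTree
    species_as_gene = GeneTree.from_newick(species_10.to_newick())
    assert robinson_foulds(gene, species_as_gene) == 0


def test_loss_only_family_is_a_species_subset(species_10):
    taxa = species_10.taxa
    n_surviving = 0
    for seed in range(12):
        params = SimulationParams(loss_rate=4e-4, seed=seed)
        gene, log = simulate_gene_family(species_10, params)
        if gene is None:
            continue  # extinction is a legitimate outcome at this rate
        n_surviving += 1
        assert set(gene.leaf_labels) <= taxa
        for ev in log.of_class("LOS"):
            branch = species_10.node_by_id(ev.branch)
            assert branch.age <= ev.time <= branch.parent.age
    assert n_surviving > 0


def test_hgt_events_connect_coexisting_branches(species_10):
    for seed in range(10):
        params = SimulationParams(hgt_rate=3e-4, seed=seed)
        gene, log = simulate_gene_family(species_10, params)
        for ev in log.of_class("HGT"):
            assert ev.donor != ev.recipient
            recipient = species_10.node_by_id(ev.recipient)
            assert recipient.age < ev.time < recipient.parent.age
            if ev.donor != "root":
                donor = species_10.node_by_id(ev.donor)
                assert donor.age < ev.time < donor.parent.age


def test_hgt_count_matches_poisson_thinning(species_10):
    """E[HGT count] = rate x realized gene-lineage time.

    With no duplication or loss the realized lineage-time integral follows
    from the log alone: the birth lineage lives root_age, and every SPC or
    HGT at time t adds one lineage that lives t more Myr.  The count minus
    rate x time is then a mean-zero martingale increment per replicate.
    """
    h = 2e-4
    diffs = []
    for seed in range(1000):
        params = SimulationParams(hgt_rate=h, seed=seed)
        _, log = simulate_gene_family(species_10, params)
        realized = species_10.root_age + sum(
            e.time for e in log.events if e.event_class in ("SPC", "HGT"))
        n_hgt = len(log.of_class("HGT"))
        diffs.append(n_hgt - h * realized)
    diffs = np.array(diffs)
    se = diffs.std(ddof=1) / math.sqrt(len(diffs))
    assert abs(diffs.mean()) < 3 * se


def test_invalid_birth_branch_raises(species_10):
    with pytest.raises(KeyError):
        simulate_gene_family(species_10, SimulationParams(birth_branch="nope"))
    # a birth time above the span of the chosen branch is invalid
    leaf = next(n for n in species_10.leaves
                if n.parent.age < species_10.root_age)
    with pytest.raises(ValueError):
        simulate_gene_family(
            species_10,
            SimulationParams(birth_branch=leaf.id,
                             birth_time=species_10.root_age))


# ---------------------------------------------------------------------------
# topological noise
# ---------------------------------------------------------------------------

def test_nni_noise_properties(species_10):
    gene, _ = simulate_gene_family(species_10, SimulationParams(seed=5))
    same = perturb_gene_tree(gene, 0, seed=1)
    assert robinson_foulds(gene, same) == 0
    moved = perturb_gene_tree(gene, 1, seed=1)
    assert robinson_foulds(gene, moved) > 0
    again = perturb_gene_tree(gene, 1, seed=1)
    assert moved.to_newick() == again.to_newick()
    assert sorted(moved.leaf_labels) == sorted(gene.leaf_labels)


def test_single_nni_on_four_leaves_changes_topology():
    from genechron.trees import GeneTree
    gene = GeneTree.from_newick("((a,b),(c,d));")
    for seed in range(8):
        moved = perturb_gene_tree(gene, 1, seed=seed)
        assert robinson_foulds(gene, moved) > 0


def test_nni_requires_four_leaves():
    from genechron.trees import GeneTree
    small = GeneTree.from_newick("((A,B),C);")
    with pytest.raises(ValueError):
        perturb_gene_tree(small, 1, seed=0)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def test_tiny_rate_alignment_is_nearly_invariant(species_10):
    aln = simulate_alignment(species_10, rate=1e-9, sites=2000, seed=8)
    variable = (aln.matrix != aln.matrix[0]).any(axis=0).mean()
    assert variable < 0.01


def test_two_leaf_divergence_matches_jukes_cantor():
    tree = simulate_dated_tree(2, 1e-3, 0.0, 1000.0, seed=2)
    rate = 2e-4
    aln = simulate_alignment(tree, rate=rate, sites=10_000, seed=3)
    observed = (aln.matrix[0] != aln.matrix[1]).mean()
    expected = jc_expected_difference(rate, 2 * tree.root_age, K=4)
    se = math.sqrt(expected * (1 - expected) / aln.n_sites)
    assert abs(observed - expected) < 3 * se


def test_alignment_deterministic_and_fasta_round_trip(tmp_path, species_10):
    a = simulate_alignment(species_10, rate=1e-4, sites=100, seed=4)
    b = simulate_alignment(species_10, rate=1e-4, sites=100, seed=4)
    assert np.array_equal(a.matrix, b.matrix)
    path = tmp_path / "aln.fasta"
    a.to_fasta(path)
    from genechron.synthetic import Alignment
    c = Alignment.from_fasta(path)
    assert c.labels == a.labels
    assert np.array_equal(c.matrix, a.matrix)


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

def test_empty_hit_table():
    table = simulate_hit_table(0, seed=0)
    assert len(table) == 0


def test_hit_table_labels_match_independent_predicate():
    table = simulate_hit_table(500, seed=11)
    # independently coded filter predicate
    recomputed = [
        (e <= 1e-12) and (al / ql >= 0.5)
        for e, al, ql in zip(table["evalue"], table["length"], table["query_length"])
    ]
    assert list(table["truth_label"]) == recomputed
    assert 0 < table["truth_label"].sum() < len(table)
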