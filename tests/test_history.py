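"""Dollo parsimony dating and LCA reconciliation."""

import pandas as pd
import pytest

from lsgf.history import dollo_gain_map, dollo_loss_count, reconcile_gene_tree, root_gene_tree
from lsgf.oracles import brute_force_dollo, brute_force_min_duplications
from lsgf.trees import parse_tree

SPECIES = "((s1:1,s2:1)A:1,(s3:1,s4:1)B:1)R;"


def _presence(tree_cols, rows):
    return pd.DataFrame(rows, index=[f"fam{i}" for i in range(len(rows))], columns=tree_cols)


def test_family_in_all_leaves_gains_at_root():
    tree = parse_tree(SPECIES)
    presence = _presence(["s1", "s2", "s3", "s4"], [[1, 1, 1, 1]])
    gains, births = dollo_gain_map(presence, tree)
    assert births["fam0"] == "R"
    assert gains["R"] == 1


def test_single_leaf_family_gains_on_terminal_branch():
    tree = parse_tree(SPECIES)
    gains, births = dollo_gain_map(_presence(["s1", "s2", "s3", "s4"], [[0, 0, 1, 0]]), tree)
    assert births["fam0"] == "s3"
    assert gains["s3"] == 1


def test_total_gains_equal_number_of_families():
    tree = parse_tree(SPECIES)
    rows = [[1, 1, 0, 0], [0, 1, 1, 0], [1, 0, 0, 1], [0, 0, 1, 1]]
    gains, births = dollo_gain_map(_presence(["s1", "s2", "s3", "s4"], rows), tree)
    assert sum(gains.values()) == len(rows) == len(births)


def test_zero_presence_family_skipped_with_warning():
    tree = parse_tree(SPECIES)
    with pytest.warns(UserWarning, match="zero presence"):
        gains, births = dollo_gain_map(_presence(["s1", "s2", "s3", "s4"], [[0, 0, 0, 0]]), tree)
    assert births == {}


def test_loss_counts_hand_cases():
    tree = parse_tree(SPECIES)
    assert dollo_loss_count(["s1", "s2", "s3", "s4"], tree, "R") == 0
    assert dollo_loss_count(["s1"], tree, "A") == 1  # sibling s2 lost
    assert dollo_loss_count(["s1"], tree, "R") == 2  # s2 and the whole B clade


def test_loss_count_precondition():
    tree = parse_tree(SPECIES)
    with pytest.raises(ValueError, match="ancestral"):
        dollo_loss_count(["s3"], tree, "A")


def test_dollo_matches_exhaustive_enumeration(rng):
    from lsgf.experiments import _random_tree

    for _ in range(40):
        n = int(rng.integers(3, 8))
        tree = _random_tree(n, rng)
        leaves = [f"L{i}" for i in range(n)]
        present = [l for l in leaves if rng.random() < 0.5] or [leaves[0]]
        presence = pd.DataFrame([[int(l in present) for l in leaves]], index=["f"], columns=leaves)
        _, births = dollo_gain_map(presence, tree)
        losses = dollo_loss_count(present, tree, births["f"])
        oracle_birth, oracle_losses = brute_force_dollo(tree, set(present))
        assert births["f"] == oracle_birth
        assert losses == oracle_losses


# ---------------------------------------------------------------------- #


def test_congruent_gene_tree_has_no_duplications():
    species = parse_tree(SPECIES)
    gene = parse_tree("((s1.g1:1,s2.g1:1):1,(s3.g1:1,s4.g1:1):1);")
    rm = reconcile_gene_tree(gene, species)
    assert rm.n_duplications == 0
    assert all(e in ("speciation", "leaf") for e in rm.events.values())
    assert rm.n_losses == 0


def test_two_full_copies_give_one_root_duplication():
    species = parse_tree(SPECIES)
    two = "(((s1.g1:1,s2.g1:1):1,(s3.g1:1,s4.g1:1):1):1,((s1.g2:1,s2.g2:1):1,(s3.g2:1,s4.g2:1):1):1);"
    rm = reconcile_gene_tree(parse_tree(two), species)
    assert rm.n_duplications == 1
    assert rm.duplications == {"R": 1}


def test_duplication_lower_bound_when_all_species_present():
    # n gene copies over s species force at least n - s duplications
    species = parse_tree(SPECIES)
    gene = parse_tree("(((s1.g1:1,s1.g2:1):1,(s2.g1:1,s2.g2:1):1):1,(s3.g1:1,s4.g1:1):1);")
    rm = reconcile_gene_tree(gene, species)
    assert rm.n_duplications >= 6 - 4


def test_unmapped_gene_leaf_raises_with_name():
    species = parse_tree(SPECIES)
    gene = parse_tree("(s1.g1:1,sX.g1:1);")
    with pytest.raises(KeyError, match="sX"):
        reconcile_gene_tree(gene, species)


def test_reconciliation_matches_brute_force_minimizer(rng):
    from lsgf.experiments import _gene_tree_newick, _random_topology

    species = parse_tree(SPECIES)
    for _ in range(60):
        n = int(rng.integers(2, 7))
        top = _random_topology([f"s{int(rng.integers(1, 5))}" for _ in range(n)], rng)
        newick = _gene_tree_newick(top, {}) + ";"
        rm = reconcile_gene_tree(parse_tree(newick), species)
        assert rm.n_duplications == brute_force_min_duplications(parse_tree(newick), species)


def test_midpoint_rooting_produces_rooted_tree():
    tree = parse_tree("(s1.g1:1,s2.g1:4,(s3.g1:1,s4.g1:1):1);")
    rooted = root_gene_tree(tree, method="midpoint")
    assert len(rooted.seed_node.child_nodes()) == 2
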