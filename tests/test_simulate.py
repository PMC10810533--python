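"""Synthetic-data generator: determinism, apportionment, ground truth."""

import numpy as np
import pytest

from lsgf.composition import gc3s
from lsgf.orf import call_orfs, dedupe_allelic_variants
from lsgf.simulate import (
    FamilyHistory,
    SimulationConfig,
    emit_transcriptomes,
    simulate_codon_alignments,
    simulate_family_histories,
    simulate_species_tree,
    taxon_profiles,
)
from lsgf.trees import newick_string, node_id, nodes_by_id


def test_two_taxon_tree_is_a_cherry_with_one_leaf_per_category():
    sim = simulate_species_tree(2, {"EF": 0.5, "NEF": 0.5}, seed=1)
    cats = sorted(sim.leaf_categories.values())
    assert cats == ["EF", "NEF"]
    assert len(sim.tree.seed_node.child_nodes()) == 2


def test_seed_determinism_byte_identical_newick():
    a = simulate_species_tree(20, seed=7)
    b = simulate_species_tree(20, seed=7)
    assert newick_string(a.tree) == newick_string(b.tree)
    assert a.leaf_categories == b.leaf_categories
    c = simulate_species_tree(20, seed=8)
    assert newick_string(c.tree) != newick_string(a.tree)


def test_exact_category_apportionment():
    sim = simulate_species_tree(40, {"EF": 0.5, "NEF": 0.25, "HE": 0.125, "KA": 0.125}, seed=3)
    counts = {}
    for cat in sim.leaf_categories.values():
        counts[cat] = counts.get(cat, 0) + 1
    assert counts == {"EF": 20, "NEF": 10, "HE": 5, "KA": 5}


def test_categories_are_monophyletic_by_default():
    sim = simulate_species_tree(16, seed=5)
    by_cat = {}
    for taxon, cat in sim.leaf_categories.items():
        by_cat.setdefault(cat, []).append(taxon)
    from lsgf.trees import mrca

    for cat, taxa in by_cat.items():
        node = mrca(sim.tree, taxa)
        below = {node_id(l) for l in node.leaf_iter()}
        assert below == set(taxa)


def test_invalid_arguments_rejected():
    with pytest.raises(ValueError):
        simulate_species_tree(1, {"EF": 1.0})
    with pytest.raises(ValueError):
        simulate_species_tree(4, {"EF": 0.6, "HE": 0.3})


def test_no_loss_no_duplication_presence_covers_birth_subtree():
    sim = simulate_species_tree(10, seed=2)
    cfg = SimulationConfig(loss_rate=0.0, duplication_rate=0.0, seed=4)
    nodes = nodes_by_id(sim.tree)
    for h in simulate_family_histories(sim, cfg, 50):
        expected = {node_id(l) for l in nodes[h.birth_node].leaf_iter()}
        assert h.surviving_leaves == expected
        assert not h.loss_branches and not h.duplication_events and not h.extinct


def test_loss_event_count_matches_closed_form_expectation():
    sim = simulate_species_tree(12, seed=6)
    rate = 0.5
    cfg = SimulationConfig(loss_rate=rate, duplication_rate=0.0, seed=8)
    n_fam = 1000
    hists = simulate_family_histories(sim, cfg, n_fam)
    mean = np.mean([len(h.loss_branches) for h in hists])

    # closed form: births are branch-length weighted; below a birth a branch
    # records a loss with prob 1 - exp(-rate * len) and shields its subtree
    def expected_losses(node):
        e = 0.0
        for child in node.child_nodes():
            p_loss = 1 - np.exp(-rate * (child.edge.length or 0.0))
            e += p_loss + (1 - p_loss) * expected_losses(child)
        return e

    root = sim.tree.seed_node
    branches = [n for n in sim.tree.preorder_node_iter() if n.parent_node]
    weights = np.array([cfg.mean_branch_length] + [n.edge.length for n in branches])
    weights = weights / weights.sum()
    expect = weights[0] * expected_losses(root) + sum(
        w * expected_losses(n) for w, n in zip(weights[1:], branches)
    )
    se = np.sqrt(expect / n_fam)  # Poisson-scale error bound on the mean
    assert abs(mean - expect) < 3 * max(se, 0.02)


def test_simulated_alignment_deterministic_and_stop_free():
    sim = simulate_species_tree(8, seed=3)
    cfg = SimulationConfig(n_taxa=8, seed=5)
    h = FamilyHistory("fam0000", "N0", set(), [], set(sim.leaf_categories))
    a1, t1 = simulate_codon_alignments(h, cfg, n_codons=40, seed=11, sim=sim)
    a2, t2 = simulate_codon_alignments(h, cfg, n_codons=40, seed=11, sim=sim)
    assert a1 == a2
    assert newick_string(t1) == newick_string(t2)
    stops = cfg.code.stop_codons
    for seq in a1.values():
        assert all(seq[i : i + 3] not in stops for i in range(0, len(seq), 3))


def test_gene_tree_matches_species_subtree_without_loss_or_duplication():
    sim = simulate_species_tree(10, seed=9)
    cfg = SimulationConfig(loss_rate=0.0, duplication_rate=0.0, seed=2)
    hists = simulate_family_histories(sim, cfg, 20)
    h = next(x for x in hists if len(x.surviving_leaves) >= 3)
    aln, gene_tree = simulate_codon_alignments(h, cfg, n_codons=10, seed=3, sim=sim)
    gene_taxa = {node_id(l).split(".")[0] for l in gene_tree.leaf_node_iter()}
    assert gene_taxa == h.surviving_leaves
    # topology check: taxon bipartitions of the gene tree are a subset of
    # the species tree's
    species_clades = set()
    nodes = nodes_by_id(sim.tree)
    for n in nodes[h.birth_node].preorder_iter():
        species_clades.add(frozenset(node_id(l) for l in n.leaf_iter()))
    for n in gene_tree.preorder_node_iter():
        clade = frozenset(node_id(l).split(".")[0] for l in n.leaf_iter())
        assert clade in species_clades


def test_duplication_events_multiply_leaf_copies():
    sim = simulate_species_tree(6, {"EF": 0.5, "HE": 0.5}, seed=4)
    root_id = node_id(sim.tree.seed_node)
    first_child = sim.tree.seed_node.child_nodes()[0]
    h = FamilyHistory(
        "fam0000",
        root_id,
        set(),
        [(node_id(first_child), 1)],
        set(sim.leaf_categories),
    )
    cfg = SimulationConfig(n_taxa=6, seed=1)
    aln, gene_tree = simulate_codon_alignments(h, cfg, n_codons=5, seed=2, sim=sim)
    dup_taxa = {node_id(l) for l in first_child.leaf_iter()}
    for leaf in dup_taxa:
        assert sum(1 for name in aln if name.startswith(leaf + ".")) == 2
    for other in set(sim.leaf_categories) - dup_taxa:
        assert sum(1 for name in aln if name.startswith(other + ".")) == 1


# ---------------------------------------------------------------------- #


def _records_for(sim, cfg, n_fam=10, n_codons=220):
    hists = simulate_family_histories(sim, cfg, n_fam)
    records = {t: [] for t in sim.leaf_categories}
    for i, h in enumerate(hists):
        if h.extinct:
            continue
        aln, _ = simulate_codon_alignments(h, cfg, n_codons=n_codons, seed=100 + i, sim=sim)
        for name, cds in aln.items():
            records[name.split(".")[0]].append((h.family_id, name, cds))
    return records


def test_truth_table_classes_and_determinism(tmp_path):
    sim = simulate_species_tree(6, seed=2)
    cfg = SimulationConfig(n_taxa=6, contaminant_fraction=0.0, allelic_variant_rate=0.0, seed=3)
    records = _records_for(sim, cfg)
    t1 = emit_transcriptomes(records, cfg, tmp_path / "a", seed=5)
    t2 = emit_transcriptomes(records, cfg, tmp_path / "b", seed=5)
    assert set(t1["class"]) == {"genuine"}
    assert t1.equals(t2)
    fa = (tmp_path / "a").glob("*.fasta")
    for f in fa:
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


def test_allele_apportionment_is_deterministic_floor(tmp_path):
    sim = simulate_species_tree(4, {"EF": 0.5, "HE": 0.5}, seed=2)
    cfg = SimulationConfig(n_taxa=4, contaminant_fraction=0.0, allelic_variant_rate=0.2, seed=3)
    records = _records_for(sim, cfg, n_fam=20)
    truth = emit_transcriptomes(records, cfg, tmp_path, seed=5)
    per_taxon = truth.groupby("taxon")["class"].value_counts().unstack(fill_value=0)
    for taxon, row in per_taxon.iterrows():
        assert row.get("allele", 0) == int(0.2 * row["genuine"])


def test_alleles_recovered_and_collapsed_by_dedup(tmp_path):
    from Bio import SeqIO

    sim = simulate_species_tree(4, {"EF": 0.5, "HE": 0.5}, seed=7)
    cfg = SimulationConfig(n_taxa=4, contaminant_fraction=0.0, allelic_variant_rate=0.25, seed=3)
    records = _records_for(sim, cfg, n_fam=20)
    truth = emit_transcriptomes(records, cfg, tmp_path, seed=5)
    code = cfg.code
    for taxon in sorted(set(truth.taxon)):
        orfs = []
        for rec in SeqIO.parse(str(tmp_path / f"{taxon}.fasta"), "fasta"):
            orfs.extend(call_orfs(str(rec.seq), code, min_aa=100, record_id=rec.id, taxon=taxon))
        reps, _ = dedupe_allelic_variants(orfs)
        n_genuine = int((truth[truth.taxon == taxon]["class"] == "genuine").sum())
        assert len(reps) == n_genuine


def test_contaminants_have_lower_gc3s(tmp_path):
    from Bio import SeqIO

    sim = simulate_species_tree(4, {"EF": 0.5, "HE": 0.5}, seed=2)
    cfg = SimulationConfig(n_taxa=4, contaminant_fraction=0.4, allelic_variant_rate=0.0, seed=3)
    records = _records_for(sim, cfg, n_fam=15)
    truth = emit_transcriptomes(records, cfg, tmp_path, seed=5)
    classes = dict(zip(truth.record_id, truth["class"]))
    code = cfg.code
    vals = {"genuine": [], "contaminant": []}
    for taxon in sorted(set(truth.taxon)):
        for rec in SeqIO.parse(str(tmp_path / f"{taxon}.fasta"), "fasta"):
            orfs = call_orfs(str(rec.seq), code, min_aa=100, record_id=rec.id)
            if orfs:
                vals[classes[rec.id]].append(gc3s(orfs[0].nucleotide, code))
    assert np.mean(vals["contaminant"]) < np.mean(vals["genuine"])


def test_taxon_profiles_give_at_least_two_genera_per_category():
    sim = simulate_species_tree(16, seed=5)
    profiles = taxon_profiles(sim)
    by_cat = {}
    for p in profiles:
        by_cat.setdefault(p.category, set()).add(p.genus)
    for cat, genera in by_cat.items():
        assert len(genera) >= 2
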