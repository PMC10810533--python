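"""Validation and calibration experiments.

Each function generates its own synthetic inputs, runs the corresponding
package operation, and scores it against either an independent brute-force
oracle (``lsgf.oracles``) or the simulator's ground truth.  They are used
by the test suite and by ``scripts/acceptance.py``; problem sizes default
to the scales documented in docs/methods.md.
"""

from __future__ import annotations

import math
import tempfile
from pathlib import Path

import numpy as np

from . import oracles
from .codes import get_code
from .composition import PercentileBand, composition_band_filter, composition_stats
from .families import FamilyMember, GeneFamily, refine_family
from .history import dollo_gain_map, dollo_loss_count, reconcile_gene_tree
from .orf import call_orfs
from .selection import adjust_fdr, fit_busted_s, fit_relax_groups, label_branches
from .simulate import (
    FamilyHistory,
    SimulationConfig,
    emit_transcriptomes,
    simulate_codon_alignments,
    simulate_family_histories,
    simulate_reference_gc3s,
    simulate_species_tree,
)
from .trees import is_ancestor_or_equal, nodes_by_id, parse_tree


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


# ---------------------------------------------------------------------- #
# 1. ORF caller vs exhaustive scanner
# ---------------------------------------------------------------------- #


def orf_oracle_experiment(n_seqs: int = 100, length_range=(5000, 10000), codes=(1, 6, 10), seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    agree = total = 0
    for _ in range(n_seqs):
        n = int(rng.integers(*length_range))
        gc = rng.uniform(0.25, 0.7)
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seq = "".join(rng.choice(list("ACGT"), size=n, p=p))
        for code_id in codes:
            code = get_code(code_id)
            impl = call_orfs(seq, code, min_aa=0)
            oracle = oracles.brute_force_largest_orf(seq, code, min_aa=0)
            total += 1
            if not impl and oracle is None:
                agree += 1
            elif impl and oracle is not None:
                cds, frame, _ = oracle
                if impl[0].nucleotide == cds and impl[0].frame == frame:
                    agree += 1
    return {"agreement": agree / total, "n": total}


# ---------------------------------------------------------------------- #
# 2. ENc analytic limits
# ---------------------------------------------------------------------- #


def enc_limits_experiment() -> dict:
    code = get_code(1)
    uniform = "".join(c * 10 for c in code.sense_codons)
    enc_uniform = composition_stats(uniform, code).enc
    one_per_aa = "".join(fam[0] * 3 for aa, fam in sorted(code.synonymous_families.items()))
    enc_biased = composition_stats(one_per_aa, code).enc
    return {
        "enc_uniform": float(enc_uniform),
        "enc_uniform_gap": float(abs(enc_uniform - 61.0)),
        "enc_one_codon_per_aa": float(enc_biased),
        "n": len(code.sense_codons) * 10,
    }


# ---------------------------------------------------------------------- #
# 3. Composition-filter contaminant recovery
# ---------------------------------------------------------------------- #


def composition_recovery_experiment(seed: int = 0) -> dict:
    cfg = SimulationConfig(
        n_taxa=8,
        category_scheme={"EF": 0.5, "HE": 0.5},
        contaminant_fraction=0.25,
        allelic_variant_rate=0.0,
        n_families=60,
        n_codons=250,
        seed=seed,
    )
    sim = simulate_species_tree(cfg.n_taxa, cfg.category_scheme, seed=seed)
    hists = simulate_family_histories(sim, cfg, cfg.n_families)
    seeds = _spawn_seeds(seed + 1, len(hists))
    records: dict = {t: [] for t in sim.leaf_categories}
    for h, s in zip(hists, seeds):
        if h.extinct:
            continue
        aln, _ = simulate_codon_alignments(h, cfg, seed=int(s), sim=sim)
        for name, cds in aln.items():
            records[name.split(".")[0]].append((h.family_id, name, cds))

    code = cfg.code
    with tempfile.TemporaryDirectory() as tmp:
        truth = emit_transcriptomes(records, cfg, tmp, seed=seed + 2)
        classes = dict(zip(truth.record_id, truth["class"]))
        stats = []
        from Bio import SeqIO

        for fasta in sorted(Path(tmp).glob("*.fasta")):
            for rec in SeqIO.parse(str(fasta), "fasta"):
                orfs = call_orfs(str(rec.seq), code, min_aa=150, record_id=rec.id)
                if orfs:
                    stats.append(composition_stats(orfs[0], code))
    reference = simulate_reference_gc3s(cfg, seed=seed + 3)
    band = PercentileBand.from_reference(reference)
    kept, discarded = composition_band_filter(stats, reference, band=band)
    kept_ids = {s.record_id for s in kept}
    genuine = [s.record_id for s in stats if classes.get(s.record_id) == "genuine"]
    contaminant = [s.record_id for s in stats if classes.get(s.record_id) == "contaminant"]
    return {
        "contaminant_discard_rate": 1 - len(kept_ids & set(contaminant)) / len(contaminant),
        "genuine_retention_rate": len(kept_ids & set(genuine)) / len(genuine),
        "n_contaminant": len(contaminant),
        "n_genuine": len(genuine),
    }


# ---------------------------------------------------------------------- #
# 4. Family-filter hand example and monotonicity
# ---------------------------------------------------------------------- #


def family_filter_experiment(n_families: int = 200, seed: int = 0) -> dict:
    fam = GeneFamily(
        "hand",
        [FamilyMember(f"r{i}", f"t{i}", L) for i, L in enumerate([100, 100, 100, 100, 400])],
    )
    hand = refine_family(fam)
    rng = np.random.default_rng(seed)
    families = []
    for i in range(n_families):
        k = int(rng.integers(2, 12))
        members = [
            FamilyMember(
                f"f{i}r{j}",
                f"t{rng.integers(0, 6)}",
                int(rng.integers(50, 500)),
                ciliate=bool(rng.random() < 0.9),
            )
            for j in range(k)
        ]
        families.append(GeneFamily(f"f{i}", members))

    def kept_count(**kw):
        return sum(refine_family(f, **kw).kept for f in families)

    base = kept_count()
    violations = 0
    violations += kept_count(min_members=6) > base
    violations += kept_count(min_genera=3) > base
    violations += kept_count(min_ciliate_prop=1.0) > base
    violations += kept_count(size_band=(0.7, 1.3)) > base
    return {
        "hand_example_rejected": not hand.kept,
        "hand_example_reason": hand.reason,
        "monotonicity_violations": int(violations),
        "n": n_families,
    }


# ---------------------------------------------------------------------- #
# 5. Dollo oracle and birth recovery
# ---------------------------------------------------------------------- #


def _random_tree(n_leaves: int, rng):
    items = [f"L{i}" for i in range(n_leaves)]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        a, b = items[i], items[j]
        items = [x for k, x in enumerate(items) if k not in (i, j)]
        items.append(f"({a}:0.1,{b}:0.1)")
    return parse_tree(items[0] + ";")


def dollo_oracle_experiment(n_instances: int = 500, max_leaves: int = 8, seed: int = 0) -> dict:
    import pandas as pd

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(3, max_leaves + 1))
        tree = _random_tree(n, rng)
        leaves = [f"L{i}" for i in range(n)]
        present = [l for l in leaves if rng.random() < 0.5]
        if not present:
            present = [leaves[int(rng.integers(n))]]
        presence = pd.DataFrame([[1 if l in present else 0 for l in leaves]], index=["fam"], columns=leaves)
        gains, births = dollo_gain_map(presence, tree)
        birth = births["fam"]
        losses = dollo_loss_count(present, tree, birth)
        oracle_birth, oracle_losses = oracles.brute_force_dollo(tree, set(present))
        if birth == oracle_birth and losses == oracle_losses:
            agree += 1
    return {"agreement": agree / n_instances, "n": n_instances}


def dollo_recovery_experiment(n_families: int = 300, seed: int = 0) -> dict:
    import pandas as pd

    sim = simulate_species_tree(12, seed=seed)
    taxa = sorted(sim.leaf_categories)
    nodes = nodes_by_id(sim.tree)

    def run(loss_rate):
        cfg = SimulationConfig(n_taxa=12, loss_rate=loss_rate, duplication_rate=0.0, seed=seed + 1)
        hists = [h for h in simulate_family_histories(sim, cfg, n_families) if not h.extinct]
        presence = pd.DataFrame(
            [[1 if t in h.surviving_leaves else 0 for t in taxa] for h in hists],
            index=[h.family_id for h in hists],
            columns=taxa,
        )
        _, births = dollo_gain_map(presence, sim.tree)
        equal = desc = 0
        for h in hists:
            inferred = births[h.family_id]
            if inferred == h.birth_node:
                equal += 1
            if is_ancestor_or_equal(nodes[h.birth_node], nodes[inferred]):
                desc += 1
        return equal / len(hists), desc / len(hists), len(hists)

    eq0, desc0, n0 = run(0.0)
    eq1, desc1, n1 = run(0.6)
    return {
        "no_loss_birth_equal_rate": eq0,
        "no_loss_n": n0,
        "with_loss_descendant_rate": desc1,
        "with_loss_n": n1,
    }


# ---------------------------------------------------------------------- #
# 6. Reconciliation oracle
# ---------------------------------------------------------------------- #

_SPECIES_4 = "((s1:1,s2:1)A:1,(s3:1,s4:1)B:1)R;"


def _gene_tree_newick(top, counters) -> str:
    if isinstance(top, tuple):
        return "(" + ",".join(_gene_tree_newick(t, counters) + ":1" for t in top) + ")"
    counters[top] = counters.get(top, 0) + 1
    return f"{top}.g{counters[top]}"


def reconciliation_oracle_experiment(seed: int = 0, exhaustive_max: int = 4, n_sampled: int = 400) -> dict:
    rng = np.random.default_rng(seed)
    species = parse_tree(_SPECIES_4)
    agree = total = 0

    def check(newick):
        nonlocal agree, total
        gene = parse_tree(newick)
        rm = reconcile_gene_tree(gene, species)
        oracle = oracles.brute_force_min_duplications(parse_tree(newick), species)
        total += 1
        agree += rm.n_duplications == oracle

    # exhaustive: all topologies x all species labelings, n <= exhaustive_max
    for n in range(2, exhaustive_max + 1):
        for top in oracles.all_rooted_topologies(tuple(range(n))):
            for labels in np.ndindex(*(4,) * n):
                named = _relabel(top, [f"s{i + 1}" for i in labels])
                check(_gene_tree_newick(named, {}) + ";")
    # sampled larger trees
    for _ in range(n_sampled):
        n = int(rng.integers(5, 7))
        items = [f"s{int(rng.integers(1, 5))}" for _ in range(n)]
        top = _random_topology(items, rng)
        check(_gene_tree_newick(top, {}) + ";")

    # two full copies of the species tree joined at the root
    two = "(((s1.g1:1,s2.g1:1):1,(s3.g1:1,s4.g1:1):1):1,((s1.g2:1,s2.g2:1):1,(s3.g2:1,s4.g2:1):1):1);"
    rm = reconcile_gene_tree(parse_tree(two), species)
    return {
        "agreement": agree / total,
        "n": total,
        "two_copy_duplications": rm.n_duplications,
        "two_copy_at_root": rm.duplications.get("R", 0),
    }


def _relabel(top, labels):
    it = iter(labels)

    def walk(t):
        if isinstance(t, tuple):
            return tuple(walk(x) for x in t)
        return next(it)

    return walk(top)


def _random_topology(items, rng):
    items = list(items)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        a, b = items[i], items[j]
        items = [x for k, x in enumerate(items) if k not in (i, j)]
        items.append((a, b))
    return items[0]


# ---------------------------------------------------------------------- #
# 7. Likelihood oracle
# ---------------------------------------------------------------------- #


def likelihood_oracle_experiment(seed: int = 0, n_codons: int = 10) -> dict:
    from .codonmodel import CompiledTree, MG94Model, encode_alignment, log_likelihood
    from .codonmodel import frequencies_from_positions, gc_biased_positions

    rng = np.random.default_rng(seed)
    rel_errs = []
    cases = [
        (1, "((a:0.3,b:0.7)ab:0.2,c:0.5)r;", n_codons),
        (6, "((a:0.8,b:0.1)ab:0.4,c:0.3)r;", n_codons),
        (6, "(((a:0.4,b:0.3)ab:0.2,c:0.6)abc:0.1,d:0.5)r;", 3),
    ]
    dist_a = (np.array([0.05, 0.5, 1.5]), np.array([0.5, 0.3, 0.2]))
    dist_b = (np.array([0.2, 1.0]), np.array([0.6, 0.4]))
    for code_id, newick, nc in cases:
        code = get_code(code_id)
        pi = frequencies_from_positions(gc_biased_positions(0.6), code)
        rho = np.array([1.0, 2.0, 0.8, 1.2, 2.5, 1.0])
        model = MG94Model(code, pi, rho)
        tree = parse_tree(newick)
        ctree = CompiledTree.from_dendropy(tree)

        def dist_for_label(label):
            return dist_a if label in ("a", "c", "ab") else dist_b

        def dist_for_branch(i):
            return dist_for_label(ctree.labels[i])

        from .codonmodel import simulate_alignment

        aln = simulate_alignment(ctree, model, dist_for_branch, nc, rng)
        encoded = encode_alignment(aln, code)
        impl = log_likelihood(encoded, ctree, model, dist_for_branch)
        oracle = oracles.exhaustive_codon_likelihood(aln, parse_tree(newick), code, pi, rho, dist_for_label)
        rel_errs.append(abs(impl - oracle) / abs(oracle))

    # zero-branch-length limit: lnL = sum over sites of log pi(observed codon)
    code = get_code(6)
    pi = frequencies_from_positions(gc_biased_positions(0.6), code)
    model = MG94Model(code, pi)
    tree = parse_tree("(a:0.0,b:0.0)r;")
    ctree = CompiledTree.from_dendropy(tree)
    one = (np.array([1.0]), np.array([1.0]))
    from .codonmodel import simulate_alignment

    aln = simulate_alignment(ctree, model, lambda i: one, 20, rng)
    encoded = encode_alignment(aln, code)
    lnl = log_likelihood(encoded, ctree, model, lambda i: one)
    expected = float(np.sum(np.log(model.pi[encoded["a"]])))
    zero_err = abs(lnl - expected)
    return {
        "max_rel_error": float(max(rel_errs)),
        "zero_length_abs_error": float(zero_err),
        "n": len(cases),
    }


# ---------------------------------------------------------------------- #
# 8-9. RELAX calibration and K recovery
# ---------------------------------------------------------------------- #


def _relax_replicate(rep_seed: int, k_by_group: dict, n_taxa: int, n_codons: int):
    scheme = {"EF": 0.5, "HE": 0.5}
    sim = simulate_species_tree(n_taxa, scheme, seed=rep_seed)
    cfg = SimulationConfig(
        n_taxa=n_taxa,
        category_scheme=scheme,
        k_by_group=k_by_group,
        n_codons=n_codons,
        seed=rep_seed + 1,
    )
    history = FamilyHistory("fam0000", "N0", set(), [], set(sim.leaf_categories))
    aln, gene_tree = simulate_codon_alignments(history, cfg, seed=rep_seed + 2, sim=sim)
    partition = label_branches(gene_tree, sim.leaf_categories)
    return fit_relax_groups(aln, gene_tree, partition, code=cfg.genetic_code, seed=rep_seed + 3, fit_descriptive=False)


def relax_null_calibration(n_reps: int = 24, seed: int = 0, n_taxa: int = 16, n_codons: int = 300, alpha: float = 0.05) -> dict:
    seeds = _spawn_seeds(seed, n_reps)
    ps, lrts = [], []
    for s in seeds:
        res = _relax_replicate(int(s), {}, n_taxa, n_codons)
        ps.append(res.p)
        lrts.append(res.lrt)
    ps = np.array(ps)
    return {
        "rejection_rate": float(np.mean(ps <= alpha)),
        "n": n_reps,
        "min_lrt": float(np.min(lrts)),
        "alpha": alpha,
    }


def relax_k_recovery(k_true: float, n_reps: int = 12, seed: int = 0, n_taxa: int = 16, n_codons: int = 300) -> dict:
    seeds = _spawn_seeds(seed + int(1000 * k_true), n_reps)
    k_hats = []
    for s in seeds:
        res = _relax_replicate(int(s), {"HE": k_true}, n_taxa, n_codons)
        k_hats.append(res.k["HE"])
    return {"k_true": k_true, "median_k_hat": float(np.median(k_hats)), "n": n_reps}


# ---------------------------------------------------------------------- #
# 10. BUSTED calibration and power
# ---------------------------------------------------------------------- #


def _busted_replicate(rep_seed: int, omega_values, omega_weights, n_taxa: int, n_codons: int, mean_bl: float = 0.25):
    scheme = {"EF": 1.0}
    sim = simulate_species_tree(n_taxa, scheme, seed=rep_seed, mean_branch_length=mean_bl)
    cfg = SimulationConfig(
        n_taxa=n_taxa,
        category_scheme=scheme,
        omega_values=omega_values,
        omega_weights=omega_weights,
        n_codons=n_codons,
        mean_branch_length=mean_bl,
        seed=rep_seed + 1,
    )
    history = FamilyHistory("fam0000", "N0", set(), [], set(sim.leaf_categories))
    aln, gene_tree = simulate_codon_alignments(history, cfg, seed=rep_seed + 2, sim=sim)
    partition = label_branches(gene_tree, sim.leaf_categories)
    return fit_busted_s(aln, gene_tree, partition, "EF", code=cfg.genetic_code, seed=rep_seed + 3, n_starts=1)


def busted_null_calibration(n_reps: int = 20, seed: int = 0, n_taxa: int = 12, n_codons: int = 300, alpha: float = 0.05) -> dict:
    seeds = _spawn_seeds(seed, n_reps)
    ps = [
        _busted_replicate(int(s), (0.05, 0.3, 0.8), (0.5, 0.3, 0.2), n_taxa, n_codons).p
        for s in seeds
    ]
    return {"rejection_rate": float(np.mean(np.array(ps) <= alpha)), "n": n_reps, "alpha": alpha}


def busted_power(n_reps: int = 10, seed: int = 0, n_taxa: int = 12, n_codons: int = 300, alpha: float = 0.05) -> dict:
    seeds = _spawn_seeds(seed + 77, n_reps)
    ps = [
        _busted_replicate(int(s), (0.05, 0.3, 4.0), (0.5, 0.4, 0.1), n_taxa, n_codons, mean_bl=0.3).p
        for s in seeds
    ]
    return {"rejection_rate": float(np.mean(np.array(ps) <= alpha)), "n": n_reps, "alpha": alpha}


# ---------------------------------------------------------------------- #
# 11. BH-FDR worked example
# ---------------------------------------------------------------------- #


def fdr_experiment(seed: int = 0, n_random: int = 200) -> dict:
    q = adjust_fdr([0.01, 0.02, 0.03, 0.04])
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=n_random)
    qr = adjust_fdr(p)
    return {
        "worked_example_q": [float(x) for x in q],
        "q_ge_p_everywhere": bool(np.all(qr >= p - 1e-12)),
        "n": n_random,
    }
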