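"""Synthetic data with the statistical structure the analysis assumes.

Generates: a rooted species tree with genome-architecture categories
assigned clade-wise (mirroring a monophyletic NEF/He/Ka and an EF clade);
gene-family histories (single birth, Poisson losses and duplications below
it); codon alignments evolved under group-specific omega distributions and
selection-intensity exponents K; and transcriptome-like FASTA files with
UTR-ish flanks, allelic variants at >= 97% identity and a contaminant
fraction with divergent GC3s.  Ground truth for every downstream stage is
recorded in truth tables.

Birth/loss/duplication rate magnitudes are not constrained by any
published estimate; the defaults are arbitrary but chosen so most births
land near the tips (length-weighted branch choice on a tree dominated by
terminal branch length), matching the qualitative shape the analysis
expects.  The default genetic code is the ciliate TAA/TAG=Gln code
(table 6); most ciliate classes use it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .codes import get_code
from .codonmodel import (
    CompiledTree,
    MG94Model,
    frequencies_from_positions,
    gc_biased_positions,
    simulate_alignment,
)
from .families import TaxonProfile
from .selection import UNCLASSIFIED, OmegaDistribution, label_branches
from .trees import ensure_node_ids, node_id, nodes_by_id, parse_tree

CATEGORY_ORDER = ("EF", "NEF", "HE", "KA")
#: clade nesting used for the scaffold, deepest split first
_SCAFFOLD = ("KA", "HE", "NEF", "EF")
CLASS_OF_CATEGORY = {
    "EF": "Spirotrichea",
    "NEF": "Oligohymenophorea",
    "HE": "Heterotrichea",
    "KA": "Karyorelictea",
}

DEFAULT_SCHEME = {"EF": 0.375, "NEF": 0.25, "HE": 0.25, "KA": 0.125}


@dataclass
class SpeciesTreeSim:
    tree: dendropy.Tree
    leaf_categories: dict
    seed: int


@dataclass
class FamilyHistory:
    family_id: str
    birth_node: str
    loss_branches: set
    duplication_events: list  # (branch id, count)
    surviving_leaves: set
    extinct: bool = False


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic runs (defaults are the
    conditions every recovery/calibration experiment assumes)."""

    n_taxa: int = 16
    category_scheme: dict = field(default_factory=lambda: dict(DEFAULT_SCHEME))
    loss_rate: float = 0.3  # per unit branch length
    duplication_rate: float = 0.1
    omega_values: tuple = (0.05, 0.35, 1.2)  # reference distribution
    omega_weights: tuple = (0.6, 0.35, 0.05)
    k_by_group: dict = field(default_factory=dict)  # group -> K, default 1
    exchangeabilities: tuple = (1.0, 2.5, 1.0, 1.0, 2.5, 1.0)  # HKY-style kappa=2.5
    codon_frequencies: np.ndarray | None = None  # explicit pi over sense codons
    contaminant_fraction: float = 0.05
    allelic_variant_rate: float = 0.1
    gc3s_ciliate: float = 0.70
    gc3s_contaminant: float = 0.25
    gc3s_reference_sd: float = 0.06  # between-family spread of the conserved reference set
    genetic_code: int = 6
    mean_branch_length: float = 0.2
    root_branch_length: float | None = None
    n_families: int = 100
    n_codons: int = 300
    seed: int = 0

    def __post_init__(self):
        self.omega_values = tuple(float(v) for v in self.omega_values)
        self.omega_weights = tuple(float(w) for w in self.omega_weights)
        self.exchangeabilities = tuple(float(r) for r in self.exchangeabilities)
        w = np.asarray(self.omega_weights, dtype=float)
        if abs(w.sum() - 1) > 1e-9 or np.any(w < 0):
            raise ValueError("omega weights must be nonnegative and sum to 1")
        if np.any(np.asarray(self.omega_values) < 0):
            raise ValueError("omega category values must be >= 0")
        for name in ("loss_rate", "duplication_rate", "allelic_variant_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.contaminant_fraction <= 1:
            raise ValueError("contaminant_fraction must be in [0, 1]")
        code = get_code(self.genetic_code)
        if self.codon_frequencies is not None:
            pi = np.asarray(self.codon_frequencies, dtype=float)
            if abs(pi.sum() - 1) > 1e-6 or len(pi) != len(code.sense_codons):
                raise ValueError("codon_frequencies must sum to 1 over the code's sense codons")

    @property
    def code(self):
        return get_code(self.genetic_code)

    def pi(self, gc3: float | None = None) -> np.ndarray:
        if gc3 is None and self.codon_frequencies is not None:
            return np.asarray(self.codon_frequencies, dtype=float)
        target = self.gc3s_ciliate if gc3 is None else gc3
        return frequencies_from_positions(gc_biased_positions(target), self.code)

    def reference_distribution(self) -> OmegaDistribution:
        return OmegaDistribution(np.asarray(self.omega_values, dtype=float), np.asarray(self.omega_weights, dtype=float))

    def group_distribution(self, group: str) -> OmegaDistribution:
        ref = self.reference_distribution()
        k = float(self.k_by_group.get(group, 1.0))
        return ref.powered(k)


# ---------------------------------------------------------------------- #
# Species tree
# ---------------------------------------------------------------------- #


def _apportion(n: int, scheme: dict) -> dict:
    cats = [c for c in CATEGORY_ORDER if c in scheme] + sorted(set(scheme) - set(CATEGORY_ORDER))
    props = np.array([scheme[c] for c in cats], dtype=float)
    if abs(props.sum() - 1) > 1e-9:
        raise ValueError("category proportions must sum to 1")
    base = np.floor(props * n).astype(int)
    rem = n - base.sum()
    order = sorted(range(len(cats)), key=lambda i: (-(props[i] * n - base[i]), i))
    for i in order[:rem]:
        base[i] += 1
    return {c: int(k) for c, k in zip(cats, base) if k > 0}


def _random_clade(leaves: list, rng, mean_bl: float) -> str:
    """Random sequential-join topology over leaf names, as a Newick fragment."""
    items = [(name, None) for name in leaves]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        (a, _), (b, _) = items[i], items[j]
        la, lb = rng.exponential(mean_bl) + 1e-4, rng.exponential(mean_bl) + 1e-4
        merged = f"({a}:{la:.6f},{b}:{lb:.6f})"
        items = [it for k, it in enumerate(items) if k not in (i, j)] + [(merged, None)]
    return items[0][0]


def simulate_species_tree(
    n_taxa: int,
    category_scheme: dict | None = None,
    seed: int = 0,
    mean_branch_length: float = 0.2,
    cladewise: bool = True,
) -> SpeciesTreeSim:
    """Rooted binary species tree with clade-wise category assignment.

    Categories are monophyletic by default, nested as
    (KA,(HE,(NEF,EF))); ``cladewise=False`` shuffles categories over
    leaves for stress tests.  Same seed, same arguments: identical Newick.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    scheme = dict(category_scheme or DEFAULT_SCHEME)
    counts = _apportion(n_taxa, scheme)
    rng = np.random.default_rng(seed)

    leaf_names = {c: [f"{c}{i + 1:02d}" for i in range(k)] for c, k in counts.items()}
    clade_order = [c for c in _SCAFFOLD if c in counts] + sorted(set(counts) - set(_SCAFFOLD))
    clades = [_random_clade(leaf_names[c], rng, mean_branch_length) for c in clade_order]
    # ladderised scaffold: deepest category first
    newick = clades[-1]
    for frag in reversed(clades[:-1]):
        la, lb = rng.exponential(mean_branch_length) + 1e-4, rng.exponential(mean_branch_length) + 1e-4
        newick = f"({frag}:{la:.6f},{newick}:{lb:.6f})"
    tree = parse_tree(newick + ";")
    ensure_node_ids(tree)

    categories = {}
    if cladewise:
        for c, names in leaf_names.items():
            for name in names:
                categories[name] = c
    else:
        all_names = [n for c in clade_order for n in leaf_names[c]]
        cats = [c for c in clade_order for _ in leaf_names[c]]
        rng.shuffle(cats)
        categories = dict(zip(all_names, cats))
    return SpeciesTreeSim(tree=tree, leaf_categories=categories, seed=seed)


def taxon_profiles(sim: SpeciesTreeSim) -> list:
    """Taxon metadata consistent with the simulated tree: genera shared by
    consecutive leaf pairs within a category, class from the category."""
    by_cat: dict[str, list] = {}
    for taxon in sorted(sim.leaf_categories):
        by_cat.setdefault(sim.leaf_categories[taxon], []).append(taxon)
    profiles = []
    for cat, taxa in sorted(by_cat.items()):
        for i, taxon in enumerate(taxa):
            # genera come in sister pairs; small categories still get two
            genus_idx = (i // 2 + 1) if len(taxa) >= 4 else (i % 2 + 1)
            profiles.append(
                TaxonProfile(
                    taxon_id=taxon,
                    genus=f"{cat}g{genus_idx}",
                    taxon_class=CLASS_OF_CATEGORY.get(cat, cat),
                    category=cat,
                    data_type="genome" if i % 4 == 3 else "transcriptome",
                )
            )
    return sorted(profiles, key=lambda p: p.taxon_id)


# ---------------------------------------------------------------------- #
# Family histories
# ---------------------------------------------------------------------- #

ROOT_BRANCH = "<root>"


def simulate_family_histories(sim: SpeciesTreeSim, cfg: SimulationConfig, n_families: int, seed: int | None = None) -> list:
    """Single length-weighted birth per family, Poisson losses and
    duplications strictly below it; fully-lost families are flagged."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    tree = sim.tree
    ensure_node_ids(tree)
    nodes = list(tree.preorder_node_iter())
    root = tree.seed_node
    root_bl = cfg.root_branch_length if cfg.root_branch_length is not None else cfg.mean_branch_length

    branch_nodes = [n for n in nodes if n is not root]
    lengths = np.array([root_bl] + [n.edge.length or 0.0 for n in branch_nodes])
    weights = lengths / lengths.sum()

    histories = []
    for i in range(n_families):
        fid = f"fam{i:04d}"
        pick = rng.choice(len(lengths), p=weights)
        birth = root if pick == 0 else branch_nodes[pick - 1]

        losses: set = set()
        dups: list = []
        dead: set = set()
        for node in birth.preorder_iter():
            if node is birth:
                continue
            nid = node_id(node)
            if node.parent_node is not birth and node_id(node.parent_node) in dead:
                dead.add(nid)
                continue
            bl = node.edge.length or 0.0
            if rng.poisson(cfg.loss_rate * bl) > 0:
                losses.add(nid)
                dead.add(nid)
                continue
            nd = rng.poisson(cfg.duplication_rate * bl)
            if nd > 0:
                dups.append((nid, int(nd)))
        surviving = {node_id(l) for l in birth.leaf_iter() if node_id(l) not in dead and _alive(l, birth, dead)}
        histories.append(
            FamilyHistory(
                family_id=fid,
                birth_node=node_id(birth),
                loss_branches=losses,
                duplication_events=dups,
                surviving_leaves=surviving,
                extinct=not surviving,
            )
        )
    return histories


def _alive(leaf, birth, dead) -> bool:
    node = leaf
    while node is not birth and node is not None:
        if node_id(node) in dead:
            return False
        node = node.parent_node
    return True


# ---------------------------------------------------------------------- #
# Gene trees and codon alignments
# ---------------------------------------------------------------------- #


def build_gene_tree(history: FamilyHistory, sim: SpeciesTreeSim, rng) -> dendropy.Tree | None:
    """Gene tree implied by a family history.

    Copies created by duplication evolve independently below the
    duplication point (which sits at a uniform position on its species
    branch); losses apply at species-branch granularity to every copy
    passing through that branch.  Unifurcations are suppressed; returns
    None for extinct families.
    """
    if history.extinct:
        return None
    tree = sim.tree
    birth = nodes_by_id(tree)[history.birth_node]
    losses = history.loss_branches
    dups = dict(history.duplication_events)
    copy_counter: dict[str, int] = {}

    taxon_ns = dendropy.TaxonNamespace()

    def leaf_node(taxon: str):
        copy_counter[taxon] = copy_counter.get(taxon, 0) + 1
        label = f"{taxon}.{history.family_id}.c{copy_counter[taxon]}"
        node = dendropy.Node()
        node.taxon = taxon_ns.new_taxon(label)
        return node

    def below(sp_node, with_dups: bool):
        """(gene node, pending length above it) for the lineage sitting at
        sp_node, or None if nothing survives."""
        if sp_node.is_leaf():
            return leaf_node(node_id(sp_node)), 0.0
        parts = []
        for child in sp_node.child_nodes():
            if node_id(child) in losses:
                continue
            sub = along_edge(child, with_dups)
            if sub is not None:
                parts.append(sub)
        if not parts:
            return None
        if len(parts) == 1:
            node, pending = parts[0]
            return node, pending
        node = dendropy.Node()
        for child, pending in parts:
            node.add_child(child)
            child.edge.length = round(pending, 8)
        return node, 0.0

    def along_edge(sp_node, with_dups: bool):
        """Lineage entering the top of sp_node's edge."""
        sub = below(sp_node, with_dups)
        if sub is None:
            return None
        L = sp_node.edge.length or 0.0
        node, pending = sub
        n_dup = dups.get(node_id(sp_node), 0) if with_dups else 0
        if n_dup == 0:
            return node, pending + L
        positions = np.sort(rng.uniform(0.0, L, size=n_dup))  # 0 = top of edge
        prev = L
        for p in positions[::-1]:
            copy = below(sp_node, with_dups=False)
            if copy is None:
                prev = p
                continue
            g = dendropy.Node()
            g.add_child(node)
            node.edge.length = round(pending + (prev - p), 8)
            cnode, cpend = copy
            g.add_child(cnode)
            cnode.edge.length = round(cpend + (L - p), 8)
            node, pending, prev = g, 0.0, p
        return node, pending + prev

    result = below(birth, with_dups=True)
    if result is None:
        return None
    root, pending = result
    gene_tree = dendropy.Tree(taxon_namespace=taxon_ns)
    gene_tree.seed_node = root
    root.edge.length = round(pending, 8) if pending > 0 else None
    gene_tree.is_rooted = True
    ensure_node_ids(gene_tree)
    return gene_tree


def simulate_codon_alignments(
    history: FamilyHistory,
    cfg: SimulationConfig,
    n_codons: int | None = None,
    seed: int | None = None,
    sim: SpeciesTreeSim | None = None,
):
    """Codon alignment + labeled gene tree for one family history.

    Each branch-site draws omega from the branch's group distribution
    (reference values raised to the group's K); unclassified branches use
    the reference distribution.  Returns (alignment dict, gene tree).
    """
    if sim is None:
        raise ValueError("species-tree simulation context (sim=) is required")
    n_codons = n_codons or cfg.n_codons
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    gene_tree = build_gene_tree(history, sim, rng)
    if gene_tree is None:
        raise ValueError(f"family {history.family_id} is extinct; nothing to simulate")

    model = MG94Model(cfg.code, cfg.pi(), cfg.exchangeabilities)
    leaves = [l for l in gene_tree.leaf_node_iter()]
    if len(leaves) == 1:
        codons = model.code.sense_codons
        states = rng.choice(len(codons), size=n_codons, p=model.pi)
        label = node_id(leaves[0])
        return {label: "".join(codons[s] for s in states)}, gene_tree

    partition = label_branches(gene_tree, sim.leaf_categories)
    ctree = CompiledTree.from_dendropy(gene_tree).with_groups(partition)
    dists = {g: cfg.group_distribution(g) for g in set(partition.values()) if g != UNCLASSIFIED}
    dists[UNCLASSIFIED] = cfg.reference_distribution()

    def dist_for_branch(i):
        d = dists[ctree.groups[i]]
        return d.values, d.weights

    aln = simulate_alignment(ctree, model, dist_for_branch, n_codons, rng)
    return aln, gene_tree


# ---------------------------------------------------------------------- #
# Transcriptome emission
# ---------------------------------------------------------------------- #

_FLANK_BASES = np.array(list("ATCG"))
_FLANK_PROBS = np.array([0.35, 0.35, 0.15, 0.15])  # AT-rich UTR-like flanks


def random_cds(n_codons: int, pi: np.ndarray, code, rng) -> str:
    codons = code.sense_codons
    states = rng.choice(len(codons), size=n_codons, p=pi)
    return "".join(codons[s] for s in states)


def _mutate_allele(cds: str, code, rng, rate: float = 0.015) -> str:
    """Point-mutated copy at >= 97% identity with no internal stops."""
    seq = list(cds)
    n_mut = max(1, int(math.floor(rate * len(seq))))
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    for pos in positions:
        choices = [b for b in "ACGT" if b != seq[pos]]
        for base in rng.permutation(choices):
            old = seq[pos]
            seq[pos] = base
            codon_start = 3 * (pos // 3)
            if "".join(seq[codon_start : codon_start + 3]) not in code.stop_codons:
                break
            seq[pos] = old
    return "".join(seq)


def emit_transcriptomes(
    records: dict,
    cfg: SimulationConfig,
    outdir,
    birth_nodes: dict | None = None,
    seed: int | None = None,
):
    """Write per-taxon transcript FASTA files plus a truth table.

    ``records`` maps taxon -> list of (family_id, record_id, cds).  Each
    CDS is wrapped as flank + stop + ATG + CDS + stop + flank so the ORF
    caller recovers it; allelic variants (floor(rate * n) point-mutated
    copies) and contaminant ORFs drawn at the contaminant GC3s target are
    injected.  Returns the truth table as a DataFrame (also written as
    truth.tsv).
    """
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    code = cfg.code
    stop = sorted(code.stop_codons)[-1]  # TGA under tables 1 and 6
    pi_cont = cfg.pi(cfg.gc3s_contaminant)
    birth_nodes = birth_nodes or {}

    rows = []
    for taxon in sorted(records):
        entries = []  # (record_id, family_id, klass, cds)
        genuine = [(rid, fid, cds) for fid, rid, cds in records[taxon]]
        for rid, fid, cds in genuine:
            entries.append((rid, fid, "genuine", cds))
        n_alleles = int(math.floor(cfg.allelic_variant_rate * len(genuine)))
        if n_alleles:
            picked = rng.choice(len(genuine), size=n_alleles, replace=False)
            for idx in sorted(picked):
                rid, fid, cds = genuine[idx]
                entries.append((f"{rid}.allele", fid, "allele", _mutate_allele(cds, code, rng)))
        n_cont = int(round(cfg.contaminant_fraction * len(entries)))
        lengths = [len(cds) // 3 for _, _, cds in genuine] or [cfg.n_codons]
        for k in range(n_cont):
            n_codons = int(lengths[rng.integers(len(lengths))])
            entries.append((f"{taxon}.cont{k + 1}", "", "contaminant", random_cds(n_codons, pi_cont, code, rng)))

        with open(outdir / f"{taxon}.fasta", "w") as fh:
            for rid, fid, klass, cds in entries:
                f5 = "".join(rng.choice(_FLANK_BASES, size=int(rng.integers(20, 80)), p=_FLANK_PROBS))
                f3 = "".join(rng.choice(_FLANK_BASES, size=int(rng.integers(20, 80)), p=_FLANK_PROBS))
                transcript = f5 + stop + "ATG" + cds + stop + f3
                fh.write(f">{rid}\n{transcript}\n")
                rows.append(
                    {
                        "record_id": rid,
                        "taxon": taxon,
                        "family_id": fid,
                        "class": klass,
                        "birth_node": birth_nodes.get(fid, ""),
                    }
                )
    truth = pd.DataFrame(rows, columns=["record_id", "taxon", "family_id", "class", "birth_node"])
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return truth


def simulate_reference_gc3s(cfg: SimulationConfig, n: int = 200, n_codons: int = 300, seed: int | None = None) -> np.ndarray:
    """GC3s values of a synthetic conserved-gene reference set (stands in
    for the conserved-family reference of the real analysis).

    Each reference gene draws its own composition target around the
    ciliate GC3s (sd ``gc3s_reference_sd``), emulating the between-family
    and between-taxon compositional variance of real conserved families.
    """
    from .composition import gc3s as _gc3s

    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 104729)
    values = []
    for _ in range(n):
        target = float(np.clip(rng.normal(cfg.gc3s_ciliate, cfg.gc3s_reference_sd), 0.05, 0.95))
        pi = cfg.pi(target)
        values.append(_gc3s(random_cds(n_codons, pi, cfg.code, rng), cfg.code))
    return np.array(values)
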