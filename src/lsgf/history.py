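"""Dating family births by Dollo parsimony and mapping duplications by
LCA gene-tree/species-tree reconciliation.

Under Dollo parsimony a family is gained exactly once and may be lost many
times, so its birth maps to the MRCA of the taxa possessing it; loss counts
are computed only as an internal diagnostic, since transcriptome-biased
sampling makes inferred losses unreliable.  Reconciliation is fixed-topology
LCA mapping (no topology search): each gene-tree node maps to the LCA of
its children's mappings and is a duplication when it maps to the same
species node as one of its children.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .trees import ensure_node_ids, is_ancestor_or_equal, mrca, node_id, nodes_by_id


# ---------------------------------------------------------------------- #
# Dollo parsimony
# ---------------------------------------------------------------------- #


def dollo_gain_map(presence: pd.DataFrame, tree: dendropy.Tree) -> tuple[dict, dict]:
    """Per-branch gain counts and per-family birth node.

    ``presence`` is a families x taxa matrix (nonzero = present).  The gain
    of a family is assigned to the branch subtending the MRCA of its
    present leaves (identified by the child node's id; root births land on
    the root's own id).  Returns (gain_counts, birth_nodes).
    """
    ensure_node_ids(tree)
    gain_counts = {node_id(n): 0 for n in tree.preorder_node_iter()}
    birth_nodes = {}
    for fam, row in presence.iterrows():
        present = [t for t in presence.columns if row[t] > 0]
        if not present:
            warnings.warn(f"family {fam} has zero presence; skipped")
            continue
        birth = mrca(tree, present)
        bid = node_id(birth)
        birth_nodes[fam] = bid
        gain_counts[bid] += 1
    return gain_counts, birth_nodes


def dollo_loss_count(presence_taxa, tree: dendropy.Tree, birth_node) -> int:
    """Minimal number of loss edges below the birth node explaining all
    absences (one loss per maximal absent subtree)."""
    ensure_node_ids(tree)
    if isinstance(birth_node, str):
        birth_node = nodes_by_id(tree)[birth_node]
    present = set(presence_taxa)
    leaves_below = {node_id(l) for l in birth_node.leaf_iter()}
    if not present <= leaves_below:
        raise ValueError("birth node is not ancestral to all present leaves")

    def _count(node):
        sub_leaves = {node_id(l) for l in node.leaf_iter()}
        if not sub_leaves & present:
            return None  # whole subtree absent: one loss on its stem
        losses = 0
        for child in node.child_nodes():
            c = _count(child)
            losses += 1 if c is None else c
        return losses

    result = _count(birth_node)
    return 0 if result is None else result


# ---------------------------------------------------------------------- #
# LCA reconciliation
# ---------------------------------------------------------------------- #


@dataclass
class ReconciliationMap:
    mapping: dict  # gene-tree node id -> species-tree node id
    events: dict  # gene-tree node id -> "leaf" | "speciation" | "duplication"
    duplications: dict  # species node id -> count
    speciations: dict  # species node id -> count
    n_duplications: int = 0
    n_losses: int = 0  # computed internally; excluded from default reports


def _species_lca(a: dendropy.Node, b: dendropy.Node, depth: dict) -> dendropy.Node:
    while a is not b:
        if depth[a] >= depth[b]:
            a = a.parent_node
        else:
            b = b.parent_node
    return a


def reconcile_gene_tree(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    leaf_to_species=None,
) -> ReconciliationMap:
    """Fixed-topology LCA reconciliation of a rooted gene tree.

    ``leaf_to_species`` maps gene leaf labels to species leaf labels; by
    default the leading dot-separated field of the gene leaf label is taken
    as the species/taxon id (the simulator's record-id convention).
    """
    ensure_node_ids(species_tree)
    ensure_node_ids(gene_tree)
    if leaf_to_species is None:
        leaf_to_species = lambda label: label.split(".")[0]
    elif isinstance(leaf_to_species, dict):
        table = leaf_to_species
        leaf_to_species = lambda label: table[label]

    sp_nodes = nodes_by_id(species_tree)
    depth = {}
    for node in species_tree.preorder_node_iter():
        depth[node] = 0 if node.parent_node is None else depth[node.parent_node] + 1

    mapping_nodes: dict = {}
    events: dict = {}
    dup_tally: dict = {}
    spec_tally: dict = {}
    n_losses = 0

    for gnode in gene_tree.postorder_node_iter():
        gid = node_id(gnode)
        if gnode.is_leaf():
            sp = leaf_to_species(gid)
            if sp not in sp_nodes or not sp_nodes[sp].is_leaf():
                raise KeyError(f"gene leaf {gid!r} maps to unknown species {sp!r}")
            mapping_nodes[gnode] = sp_nodes[sp]
            events[gid] = "leaf"
            continue
        children = gnode.child_nodes()
        m = mapping_nodes[children[0]]
        for c in children[1:]:
            m = _species_lca(m, mapping_nodes[c], depth)
        mapping_nodes[gnode] = m
        is_dup = any(mapping_nodes[c] is m for c in children)
        events[gid] = "duplication" if is_dup else "speciation"
        sid = node_id(m)
        if is_dup:
            dup_tally[sid] = dup_tally.get(sid, 0) + 1
            n_losses += sum(depth[mapping_nodes[c]] - depth[m] for c in children)
        else:
            spec_tally[sid] = spec_tally.get(sid, 0) + 1
            n_losses += sum(depth[mapping_nodes[c]] - depth[m] - 1 for c in children)

    return ReconciliationMap(
        mapping={node_id(g): node_id(s) for g, s in mapping_nodes.items()},
        events=events,
        duplications=dup_tally,
        speciations=spec_tally,
        n_duplications=sum(dup_tally.values()),
        n_losses=n_losses,
    )


def root_gene_tree(tree: dendropy.Tree, method: str = "midpoint", outgroup=None) -> dendropy.Tree:
    """Root an unrooted gene tree by midpoint (default) or by an outgroup leaf."""
    if method == "midpoint":
        tree.reroot_at_midpoint(update_bipartitions=False)
    elif method == "outgroup":
        leaves = {node_id(l): l for l in tree.leaf_node_iter()}
        if outgroup not in leaves:
            raise KeyError(f"outgroup leaf {outgroup!r} not in tree")
        edge = leaves[outgroup].edge
        tree.reroot_at_edge(edge, update_bipartitions=False)
    else:
        raise ValueError(f"unknown rooting method {method!r}")
    tree.is_rooted = True
    return tree


def branch_event_table(gain_counts: dict, recon_maps: list) -> pd.DataFrame:
    """Per-branch table of gains, duplications and speciations.

    Branch id = child node id; gains come from ``dollo_gain_map`` and the
    duplication/speciation tallies are summed across reconciliations.
    Losses are deliberately not reported.
    """
    dup: dict = {}
    spec: dict = {}
    for rm in recon_maps:
        for sid, c in rm.duplications.items():
            dup[sid] = dup.get(sid, 0) + c
        for sid, c in rm.speciations.items():
            spec[sid] = spec.get(sid, 0) + c
    branches = sorted(set(gain_counts) | set(dup) | set(spec))
    return pd.DataFrame(
        {
            "branch": branches,
            "gains": [gain_counts.get(b, 0) for b in branches],
            "duplications": [dup.get(b, 0) for b in branches],
            "speciations": [spec.get(b, 0) for b in branches],
        }
    ).set_index("branch")
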