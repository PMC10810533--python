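"""Thin helpers over dendropy trees: stable node ids, ancestry, Newick I/O.

Branches are identified by their child node's id throughout the package
(gain/duplication tallies, partition labels), so every internal node needs
a stable label; ``ensure_node_ids`` assigns ``N<k>`` labels in preorder to
unlabeled internal nodes.
"""

from __future__ import annotations

import dendropy


def parse_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def read_tree(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True, unquoted_underscores=True)


def node_id(node: dendropy.Node) -> str:
    if node.is_leaf() and node.taxon is not None:
        return node.taxon.label
    return node.label


def ensure_node_ids(tree: dendropy.Tree) -> dendropy.Tree:
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if not node.label:
            node.label = f"N{k}"
        k += 1
    return tree


def nodes_by_id(tree: dendropy.Tree) -> dict:
    return {node_id(n): n for n in tree.preorder_node_iter()}


def leaf_ids(tree: dendropy.Tree) -> list:
    return [node_id(l) for l in tree.leaf_node_iter()]


def is_ancestor_or_equal(anc: dendropy.Node, node: dendropy.Node) -> bool:
    while node is not None:
        if node is anc:
            return True
        node = node.parent_node
    return False


def mrca(tree: dendropy.Tree, labels) -> dendropy.Node:
    labels = set(labels)
    leaves = [l for l in tree.leaf_node_iter() if node_id(l) in labels]
    if len(leaves) != len(labels):
        found = {node_id(l) for l in leaves}
        raise KeyError(f"leaves not in tree: {sorted(labels - found)}")
    if len(leaves) == 1:
        return leaves[0]
    node = tree.mrca(taxa=[l.taxon for l in leaves])
    return node


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True).strip()
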