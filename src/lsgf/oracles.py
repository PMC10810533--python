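"""Independent brute-force reference implementations used for validation.

Each function here recomputes a quantity by exhaustive enumeration or
direct summation, deliberately sharing no code path with the production
implementations: the ORF scanner enumerates (frame, start, stop) triples;
the Dollo oracle enumerates loss-edge subsets; the reconciliation oracle
minimises duplications over all valid species-node assignments; the codon
likelihood sums over every ancestral state assignment with scipy's matrix
exponential.  They are intended for small instances only.
"""

from __future__ import annotations

import itertools
from bisect import bisect_right

import numpy as np
from scipy.linalg import expm

from .codes import GeneticCode, normalize
from .orf import FRAME_ORDER, reverse_complement
from .trees import node_id

# ---------------------------------------------------------------------- #
# ORF caller oracle
# ---------------------------------------------------------------------- #


def brute_force_largest_orf(transcript: str, code: GeneticCode, min_aa: int = 200, complete_only: bool = True):
    """Largest complete ORF by enumerating candidate (frame, start, stop)
    triples; ties by frame order then 5'-most start.  Returns
    (cds, frame, start_codon_index) or None."""
    seq = normalize(transcript)
    best = None
    for rank, frame in enumerate(FRAME_ORDER):
        s = seq if frame > 0 else reverse_complement(seq)
        off = abs(frame) - 1
        codons = [s[off + 3 * i : off + 3 * i + 3] for i in range((len(s) - off) // 3)]
        stops = [i for i, c in enumerate(codons) if c in code.stop_codons]
        if complete_only:
            candidates = [i for i, c in enumerate(codons) if c == "ATG"]
        else:
            candidates = [0] + [i + 1 for i in stops]
        for i in candidates:
            j_pos = bisect_right(stops, i - 1)
            if j_pos >= len(stops):
                continue  # no in-frame stop: not a complete ORF
            j = stops[j_pos]
            if j <= i:
                continue
            aa_len = j - i
            key = (-aa_len, rank, i)
            if best is None or key < best[0]:
                best = (key, frame, "".join(codons[i:j]), i)
    if best is None or -best[0][0] < min_aa:
        return None
    _, frame, cds, start = best
    return cds, frame, start


# ---------------------------------------------------------------------- #
# Dollo oracle
# ---------------------------------------------------------------------- #


def brute_force_dollo(tree, present: set):
    """Optimal single-gain / multi-loss scenario by exhaustive enumeration.

    Tries every candidate gain node covering the present leaves and every
    subset of edges strictly below it as losses; returns
    (best gain node id, minimal loss count).
    """
    present = set(present)
    best = None
    for gain in tree.preorder_node_iter():
        leaves_below = {node_id(l) for l in gain.leaf_iter()}
        if not present <= leaves_below:
            continue
        edges = [n for n in gain.preorder_iter() if n is not gain]
        e_index = {id(n): b for b, n in enumerate(edges)}
        path_mask = {}
        for leaf in gain.leaf_iter():
            mask = 0
            node = leaf
            while node is not gain:
                mask |= 1 << e_index[id(node)]
                node = node.parent_node
            path_mask[node_id(leaf)] = mask
        n_edges = len(edges)
        subsets = np.arange(1 << n_edges, dtype=np.uint64)
        valid = np.ones(subsets.shape, dtype=bool)
        for leaf in leaves_below:
            alive = (subsets & np.uint64(path_mask[leaf])) == 0
            valid &= alive if leaf in present else ~alive
        if not valid.any():
            continue
        sizes = np.bitwise_count(subsets[valid])
        losses = int(sizes.min())
        if best is None or losses < best[1]:
            best = (node_id(gain), losses)
    return best


# ---------------------------------------------------------------------- #
# Reconciliation oracle
# ---------------------------------------------------------------------- #


def brute_force_min_duplications(gene_tree, species_tree, leaf_to_species=None) -> int:
    """Minimal duplication count over all valid species-node assignments.

    A valid assignment maps each internal gene node to a species node
    ancestral to (or equal to) the species of all its descendant leaves,
    weakly descending along the gene tree; a node is a duplication when it
    maps to the same species node as one of its children.
    """
    if leaf_to_species is None:
        leaf_to_species = lambda label: label.split(".")[0]
    sp = {node_id(n): n for n in species_tree.preorder_node_iter()}
    ancestors = {}
    for name, node in sp.items():
        chain = []
        cur = node
        while cur is not None:
            chain.append(cur)
            cur = cur.parent_node
        ancestors[name] = chain  # node itself first, root last

    gene_nodes = list(gene_tree.postorder_node_iter())
    internal = [n for n in gene_nodes if not n.is_leaf()]
    fixed = {}
    allowed = {}
    for n in gene_nodes:
        if n.is_leaf():
            fixed[id(n)] = sp[leaf_to_species(node_id(n))]
        else:
            # LCA of descendant leaf species, then everything above it
            leaf_sets = [set(id(a) for a in ancestors[leaf_to_species(node_id(l))]) for l in n.leaf_iter()]
            common = set.intersection(*leaf_sets)
            first_leaf = next(n.leaf_iter())
            chain = ancestors[leaf_to_species(node_id(first_leaf))]
            lca = next(a for a in chain if id(a) in common)
            lca_chain = []
            cur = lca
            while cur is not None:
                lca_chain.append(cur)
                cur = cur.parent_node
            allowed[id(n)] = lca_chain

    depth = {}
    for node in species_tree.preorder_node_iter():
        depth[id(node)] = 0 if node.parent_node is None else depth[id(node.parent_node)] + 1

    best = None
    for combo in itertools.product(*(allowed[id(n)] for n in internal)):
        M = dict(fixed)
        for n, s in zip(internal, combo):
            M[id(n)] = s
        ok = True
        dups = 0
        for n in internal:
            mv = M[id(n)]
            arrival = []  # child of mv through which each gene child descends (None if equal)
            for c in n.child_nodes():
                a = M[id(c)]
                prev = None
                while a is not None and a is not mv:
                    prev = a
                    a = a.parent_node
                if a is None:
                    ok = False  # parent must map at or above the child's mapping
                    break
                arrival.append(prev)
            if not ok:
                break
            # speciation only if the children descend through pairwise
            # distinct child lineages of mv; anything else is a duplication
            if any(p is None for p in arrival) or len({id(p) for p in arrival}) < len(arrival):
                dups += 1
        if ok and (best is None or dups < best):
            best = dups
    return best


def all_rooted_topologies(leaves: tuple):
    """All rooted binary topologies over labeled leaves, as nested tuples."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    # the block containing the first leaf, to avoid double counting
    for k in range(len(rest) + 1):
        for combo in itertools.combinations(rest, k):
            left = (first,) + combo
            right = tuple(l for l in rest if l not in combo)
            if not right:
                continue
            for lt in all_rooted_topologies(left):
                for rt in all_rooted_topologies(right):
                    yield (lt, rt)


def topology_to_newick(top) -> str:
    if isinstance(top, tuple):
        return "(" + ",".join(topology_to_newick(t) for t in top) + ")"
    return str(top)


# ---------------------------------------------------------------------- #
# Codon likelihood oracle
# ---------------------------------------------------------------------- #


def _oracle_rate_matrix(code: GeneticCode, pi: np.ndarray, rho: np.ndarray, omega: float) -> np.ndarray:
    """MG94 generator rebuilt by direct looping (no shared code path),
    scaled so one expected substitution per codon at omega = 1."""
    pairs = {frozenset(p): k for k, p in enumerate((("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T")))}
    codons = code.sense_codons
    S = len(codons)

    def q(i, j, om):
        diffs = [p for p in range(3) if codons[i][p] != codons[j][p]]
        if len(diffs) != 1:
            return 0.0
        p = diffs[0]
        rate = rho[pairs[frozenset((codons[i][p], codons[j][p]))]] * pi[j]
        if code.forward[codons[i]] != code.forward[codons[j]]:
            rate *= om
        return rate

    flow = sum(pi[i] * q(i, j, 1.0) for i in range(S) for j in range(S) if i != j)
    Q = np.array([[q(i, j, omega) for j in range(S)] for i in range(S)])
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q / flow


def exhaustive_codon_likelihood(aln: dict, tree, code: GeneticCode, pi, rho, dist_for_label) -> float:
    """Total log-likelihood by summing over all ancestral codon
    assignments, with per-branch mixture transition probabilities obtained
    from scipy.linalg.expm.

    ``dist_for_label(branch id)`` returns (omegas, weights).  Feasible for
    trees with at most 3 internal nodes and short alignments.
    """
    pi = np.asarray(pi, dtype=float)
    rho = np.asarray(rho, dtype=float)
    idx = {c: i for i, c in enumerate(code.sense_codons)}
    S = len(pi)

    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    n_sites = len(next(iter(aln.values()))) // 3
    obs = {}
    for leaf in leaves:
        seq = aln[node_id(leaf)]
        obs[id(leaf)] = [idx[seq[3 * s : 3 * s + 3]] for s in range(n_sites)]

    P = {}
    for n in nodes:
        if n.parent_node is None:
            continue
        omegas, weights = dist_for_label(node_id(n))
        t = n.edge.length or 0.0
        mat = np.zeros((S, S))
        for w, om in zip(weights, omegas):
            mat += w * expm(_oracle_rate_matrix(code, pi, rho, om) * t)
        P[id(n)] = mat

    total = 0.0
    for s in range(n_sites):
        like = 0.0
        for combo in itertools.product(range(S), repeat=len(internal)):
            state = {id(n): c for n, c in zip(internal, combo)}
            for leaf in leaves:
                state[id(leaf)] = obs[id(leaf)][s]
            term = pi[state[id(tree.seed_node)]]
            for n in nodes:
                if n.parent_node is not None:
                    term *= P[id(n)][state[id(n.parent_node)], state[id(n)]]
                if term == 0.0:
                    break
            like += term
        total += np.log(like)
    return float(total)


# ---------------------------------------------------------------------- #
# Neutral substitution-flux oracle
# ---------------------------------------------------------------------- #


def neutral_neighbor_flux_ratio(code: GeneticCode) -> float:
    """Nonsynonymous / synonymous single-nucleotide neighbor count ratio
    (the neutral substitution-flux ratio under uniform frequencies and
    exchangeabilities)."""
    codons = code.sense_codons
    nonsyn = syn = 0
    for a in codons:
        for b in codons:
            if a >= b:
                continue
            diffs = sum(x != y for x, y in zip(a, b))
            if diffs != 1:
                continue
            if code.forward[a] == code.forward[b]:
                syn += 1
            else:
                nonsyn += 1
    return nonsyn / syn
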