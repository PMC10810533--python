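"""MG94 x GTR codon substitution model with branch-site random effects.

The instantaneous rate between codons differing at exactly one nucleotide
is the GTR exchangeability of the nucleotide pair times the target codon's
equilibrium frequency, multiplied by omega when the change is
nonsynonymous; multi-nucleotide changes have rate zero.  The generator is
scaled so a branch length of 1 equals one expected substitution per codon
at omega = 1.  Random effects enter at the branch-site level: every
(branch, site) pair draws omega independently from the branch's discrete
distribution, so the per-branch transition matrix is the weighted mixture
of the per-category matrices and the likelihood factorises over sites.

State space, degeneracy and stop exclusion all follow the active genetic
code (under the ciliate TAA/TAG=Gln code there are 63 sense codons).
"""

from __future__ import annotations

import numpy as np

from .codes import GeneticCode, get_code

# GTR exchangeability order
NUC_PAIRS = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))
_PAIR_INDEX = {frozenset(p): i for i, p in enumerate(NUC_PAIRS)}


def f3x4_frequencies(seqs, code: GeneticCode, pseudocount: float = 0.5) -> np.ndarray:
    """Empirical F3x4 codon frequencies over the code's sense codons."""
    counts = np.full((3, 4), pseudocount)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for seq in seqs:
        for i, ch in enumerate(seq):
            if ch in base_idx:
                counts[i % 3, base_idx[ch]] += 1
    pos = counts / counts.sum(axis=1, keepdims=True)
    return frequencies_from_positions(pos, code)


def frequencies_from_positions(pos_freqs, code: GeneticCode) -> np.ndarray:
    """F3x4-style sense-codon frequencies from 3x4 positional base frequencies."""
    pos = np.asarray(pos_freqs, dtype=float)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    pi = np.array(
        [pos[0, base_idx[c[0]]] * pos[1, base_idx[c[1]]] * pos[2, base_idx[c[2]]] for c in code.sense_codons]
    )
    if pi.sum() <= 0:
        raise ValueError("degenerate positional frequencies")
    return pi / pi.sum()


def gc_biased_positions(gc3: float, gc12: float = 0.5) -> np.ndarray:
    """Positional base frequencies with a target third-position G+C fraction."""
    row12 = np.array([(1 - gc12) / 2, gc12 / 2, gc12 / 2, (1 - gc12) / 2])  # A,C,G,T
    row3 = np.array([(1 - gc3) / 2, gc3 / 2, gc3 / 2, (1 - gc3) / 2])
    return np.vstack([row12, row12, row3])


class MG94Model:
    """Precompiled generator split Q(omega) = (A + omega * B) / c."""

    def __init__(self, code, pi, exchangeabilities=(1.0, 1.0, 1.0, 1.0, 1.0, 1.0)):
        self.code = get_code(code)
        S = len(self.code.sense_codons)
        pi = np.asarray(pi, dtype=float)
        if pi.shape != (S,):
            raise ValueError(f"pi must have length {S}")
        if np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("pi must be positive and sum to 1 over sense codons")
        rho = np.asarray(exchangeabilities, dtype=float)
        if rho.shape != (6,) or np.any(rho <= 0):
            raise ValueError("exchangeabilities must be 6 positive values")
        self.pi = pi
        self.rho = rho

        codons = self.code.sense_codons
        aa = [self.code.forward[c] for c in codons]
        A = np.zeros((S, S))
        B = np.zeros((S, S))
        for i in range(S):
            ci = codons[i]
            for j in range(S):
                if i == j:
                    continue
                cj = codons[j]
                diff = [p for p in range(3) if ci[p] != cj[p]]
                if len(diff) != 1:
                    continue
                p = diff[0]
                r = rho[_PAIR_INDEX[frozenset((ci[p], cj[p]))]] * pi[j]
                if aa[i] == aa[j]:
                    A[i, j] = r
                else:
                    B[i, j] = r
        M1 = A + B
        np.fill_diagonal(M1, 0.0)
        self.scale = float(pi @ M1.sum(axis=1))  # substitution flow at omega = 1
        self.A = A
        self.B = B
        self._sqrt_pi = np.sqrt(pi)
        self._eig_cache: dict = {}

    # ------------------------------------------------------------------ #

    def rate_matrix(self, omega: float) -> np.ndarray:
        if omega < 0:
            raise ValueError("omega category value must be >= 0")
        Q = self.A + omega * self.B
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q / self.scale

    def _eig(self, omega: float):
        key = float(omega)
        hit = self._eig_cache.get(key)
        if hit is not None:
            return hit
        Q = self.rate_matrix(omega)
        d = self._sqrt_pi
        Sym = (d[:, None] * Q) / d[None, :]
        Sym = (Sym + Sym.T) / 2
        lam, U = np.linalg.eigh(Sym)
        right = U / d[:, None]  # D^-1 U
        left = U.T * d[None, :]  # U^T D
        if len(self._eig_cache) > 4096:
            self._eig_cache.clear()
        self._eig_cache[key] = (lam, right, left)
        return lam, right, left

    def transition(self, omega: float, t: float) -> np.ndarray:
        """P(t) for a single omega; rows renormalised after clipping."""
        lam, right, left = self._eig(omega)
        P = (right * np.exp(lam * t)[None, :]) @ left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_batch(self, omega: float, ts: np.ndarray) -> np.ndarray:
        """P(t) for one omega and many branch lengths, shape (T, S, S)."""
        lam, right, left = self._eig(omega)
        E = np.exp(np.outer(ts, lam))  # (T, S)
        P = (right[None, :, :] * E[:, None, :]) @ left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P

    def mixture_transition(self, omegas, weights, t: float) -> np.ndarray:
        """Branch-site mixture transition matrix sum_k w_k P(omega_k, t)."""
        P = np.zeros((len(self.pi), len(self.pi)))
        for w, om in zip(weights, omegas):
            if w > 0:
                P += w * self.transition(om, t)
        return P

    def mixture_transition_batch(self, omegas, weights, ts: np.ndarray) -> np.ndarray:
        P = np.zeros((len(ts), len(self.pi), len(self.pi)))
        for w, om in zip(weights, omegas):
            if w > 0:
                P += w * self.transition_batch(om, ts)
        return P


# ---------------------------------------------------------------------- #
# Tree compilation and pruning
# ---------------------------------------------------------------------- #


class CompiledTree:
    """Array form of a rooted tree for fast repeated pruning.

    Node order is postorder; ``groups[i]`` is the branch label of the edge
    above node i (None at the root).
    """

    def __init__(self, labels, parent, lengths, children, leaf_names, groups=None):
        self.labels = labels
        self.parent = np.asarray(parent)
        self.lengths = np.asarray(lengths, dtype=float)
        self.children = children
        self.leaf_names = leaf_names  # node index -> leaf label (leaves only)
        self.leaf_index = {name: i for i, name in leaf_names.items()}
        self.groups = groups or [None] * len(labels)
        self.n_nodes = len(labels)
        self.root = int(np.where(self.parent < 0)[0][0])
        self.postorder = self._postorder()

    def _postorder(self):
        order, stack = [], [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        return order

    @classmethod
    def from_dendropy(cls, tree, default_length: float = 0.0):
        from .trees import ensure_node_ids, node_id

        ensure_node_ids(tree)
        nodes = list(tree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        labels = [node_id(n) for n in nodes]
        parent = [index[id(n.parent_node)] if n.parent_node else -1 for n in nodes]
        lengths = [n.edge.length if n.edge.length is not None else default_length for n in nodes]
        children = [[index[id(c)] for c in n.child_nodes()] for n in nodes]
        leaf_names = {i: labels[i] for i, n in enumerate(nodes) if n.is_leaf()}
        return cls(labels, parent, lengths, children, leaf_names)

    def with_groups(self, partition: dict, default="unclassified"):
        """Attach branch labels keyed by child-node id (root stays None)."""
        groups = []
        for i, lab in enumerate(self.labels):
            groups.append(None if i == self.root else partition.get(lab, default))
        return CompiledTree(self.labels, self.parent, self.lengths, self.children, dict(self.leaf_names), groups)

    def scaled(self, factor: float):
        ct = CompiledTree(self.labels, self.parent, self.lengths * factor, self.children, dict(self.leaf_names), list(self.groups))
        return ct


def encode_alignment(aln: dict, code: GeneticCode) -> dict:
    """Map codon strings to sense-codon indices (-1 = unknown/ambiguous)."""
    idx = code.codon_index
    out = {}
    for name, seq in aln.items():
        if len(seq) % 3:
            raise ValueError(f"{name}: alignment length not divisible by 3")
        out[name] = np.array([idx.get(seq[i : i + 3], -1) for i in range(0, len(seq), 3)], dtype=int)
    return out


def site_log_likelihoods(encoded: dict, ctree: CompiledTree, model: MG94Model, dist_for_branch) -> np.ndarray:
    """Per-site log-likelihood by pruning with mixture transition matrices.

    ``dist_for_branch(i)`` returns (omegas, weights) for the edge above
    node i.  Leaf names of the tree must match alignment names exactly.
    """
    S = len(model.pi)
    missing = [ctree.leaf_names[i] for i in ctree.leaf_names if ctree.leaf_names[i] not in encoded]
    if missing:
        raise KeyError(f"alignment missing sequences for leaves: {missing}")
    n_sites = len(next(iter(encoded.values())))

    # batch transition matrices over branches sharing a distribution
    P = [None] * ctree.n_nodes
    by_dist: dict = {}
    for i in range(ctree.n_nodes):
        if i == ctree.root:
            continue
        omegas, weights = dist_for_branch(i)
        omegas = np.asarray(omegas, dtype=float)
        weights = np.asarray(weights, dtype=float)
        key = (omegas.tobytes(), weights.tobytes())
        by_dist.setdefault(key, (omegas, weights, []))[2].append(i)
    for omegas, weights, idxs in by_dist.values():
        batch = model.mixture_transition_batch(omegas, weights, ctree.lengths[idxs])
        for k, i in enumerate(idxs):
            P[i] = batch[k]

    partial = [None] * ctree.n_nodes
    log_scale = np.zeros(n_sites)
    for i in ctree.postorder:
        if not ctree.children[i]:
            states = encoded[ctree.leaf_names[i]]
            L = np.zeros((S, n_sites))
            known = states >= 0
            L[states[known], np.nonzero(known)[0]] = 1.0
            L[:, ~known] = 1.0
            partial[i] = L
        else:
            L = np.ones((S, n_sites))
            for c in ctree.children[i]:
                L *= P[c] @ partial[c]
                partial[c] = None
            m = L.max(axis=0)
            m[m == 0] = 1.0
            L /= m
            log_scale += np.log(m)
            partial[i] = L
    site_like = model.pi @ partial[ctree.root]
    return np.log(np.maximum(site_like, 1e-300)) + log_scale


def log_likelihood(encoded, ctree, model, dist_for_branch, syn_rates=None) -> float:
    """Total log-likelihood; optional site-level synonymous rate mixture.

    ``syn_rates`` is (rates, weights) with mean-1 rates; each site mixes
    over rates applied as branch-length multipliers across the whole tree.
    """
    if syn_rates is None:
        return float(site_log_likelihoods(encoded, ctree, model, dist_for_branch).sum())
    rates, weights = syn_rates
    per_rate = []
    for r in rates:
        per_rate.append(site_log_likelihoods(encoded, ctree.scaled(r), model, dist_for_branch))
    M = np.stack(per_rate)  # (R, sites)
    mx = M.max(axis=0)
    mix = mx + np.log(np.tensordot(np.asarray(weights), np.exp(M - mx), axes=1))
    return float(mix.sum())


# ---------------------------------------------------------------------- #
# Simulation
# ---------------------------------------------------------------------- #


def draw_site_omegas(omegas, weights, n: int, rng) -> np.ndarray:
    """Independent per-site omega draws from a discrete distribution."""
    omegas = np.asarray(omegas, dtype=float)
    if np.any(omegas < 0):
        raise ValueError("omega category value must be >= 0")
    cats = rng.choice(len(omegas), size=n, p=np.asarray(weights, dtype=float))
    return omegas[cats]


def simulate_alignment(ctree: CompiledTree, model: MG94Model, dist_for_branch, n_codons: int, rng) -> dict:
    """Evolve codon sequences down the tree; returns {leaf name: codon string}.

    Sites are independent; each (branch, site) draws its omega category
    independently.  Stop codons cannot arise because the state space is
    restricted to the code's sense codons.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    S = len(model.pi)
    states = {ctree.root: rng.choice(S, size=n_codons, p=model.pi)}
    preorder = list(reversed(ctree.postorder))
    for i in preorder:
        if i == ctree.root:
            continue
        parent_states = states[ctree.parent[i]]
        omegas, weights = dist_for_branch(i)
        omegas = np.asarray(omegas, dtype=float)
        if np.any(omegas < 0):
            raise ValueError("omega category value must be >= 0")
        cats = rng.choice(len(omegas), size=n_codons, p=np.asarray(weights, dtype=float))
        child = np.empty(n_codons, dtype=int)
        for k in range(len(omegas)):
            mask = cats == k
            if not mask.any():
                continue
            P = model.transition(omegas[k], ctree.lengths[i])
            cum = np.cumsum(P, axis=1)
            r = rng.random(mask.sum())
            rows = cum[parent_states[mask]]
            child[mask] = np.minimum((rows < r[:, None]).sum(axis=1), S - 1)
        states[i] = child
    codons = model.code.sense_codons
    out = {}
    for i, name in ctree.leaf_names.items():
        out[name] = "".join(codons[s] for s in states[i])
    return out
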