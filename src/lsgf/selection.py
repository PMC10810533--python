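"""Group-level selection-regime inference on labeled gene trees.

Branches are partitioned into genome-architecture groups (EF, NEF, HE, KA;
anything mixed is "unclassified" and treated as nuisance).  Two tests are
fitted per alignment under the MG94 x GTR branch-site random-effects model:

* a RELAX-style selection-intensity test: the null shares one reference
  omega distribution across groups (all K_G = 1); the alternative raises
  the reference category values to a free group-level exponent K_G for
  every non-reference group (K < 1 relaxation, K > 1 intensification),
  giving a chi-square LRT with |G| - 1 degrees of freedom;
* a BUSTED[S]-style episodic diversifying selection screen per group:
  unrestricted omega distribution versus the tested group constrained to
  omega <= 1, with a conservative 50:50 chi2_0/chi2_2 boundary null.

p values are corrected by Benjamini-Hochberg FDR; detection rates are
binned by the number of branches labeled for the tested group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit
from statsmodels.stats.multitest import multipletests

from .codes import get_code
from .codonmodel import CompiledTree, MG94Model, encode_alignment, f3x4_frequencies, log_likelihood
from .trees import node_id

GROUPS = ("EF", "NEF", "HE", "KA")
UNCLASSIFIED = "unclassified"
REFERENCE_PREFERENCE = ("EF", "NEF", "HE", "KA")


# ---------------------------------------------------------------------- #
# Partitioning
# ---------------------------------------------------------------------- #


def label_branches(gene_tree, categories: dict, taxon_of=None) -> dict:
    """Label every branch (child-node id) with a group or "unclassified".

    Terminal branches take their taxon's category; an internal branch gets
    a category iff every branch below it carries that same category.
    """
    if taxon_of is None:
        taxon_of = lambda label: label.split(".")[0]
    partition = {}
    subtree_label = {}
    for node in gene_tree.postorder_node_iter():
        nid = node_id(node)
        if node.is_leaf():
            taxon = taxon_of(nid)
            if taxon not in categories:
                raise KeyError(f"no category for taxon {taxon!r} (leaf {nid!r})")
            lab = categories[taxon]
        else:
            child_labels = {subtree_label[id(c)] for c in node.child_nodes()}
            lab = child_labels.pop() if len(child_labels) == 1 else UNCLASSIFIED
        subtree_label[id(node)] = lab
        if node.parent_node is not None:
            partition[nid] = lab
    return partition


def group_branch_counts(partition: dict) -> dict:
    counts: dict[str, int] = {}
    for lab in partition.values():
        if lab != UNCLASSIFIED:
            counts[lab] = counts.get(lab, 0) + 1
    return counts


def choose_reference_group(partition: dict, min_branches: int = 2) -> tuple:
    """(reference label, testable flag).  Reference preference EF > NEF >
    HE > KA among groups with >= ``min_branches`` labeled branches; the
    partition is testable when at least two such groups exist."""
    counts = group_branch_counts(partition)
    eligible = [g for g in REFERENCE_PREFERENCE if counts.get(g, 0) >= min_branches]
    if len(eligible) < 2:
        return (eligible[0] if eligible else None), False
    return eligible[0], True


# ---------------------------------------------------------------------- #
# Results
# ---------------------------------------------------------------------- #


@dataclass
class OmegaDistribution:
    values: np.ndarray  # ascending
    weights: np.ndarray

    def powered(self, k: float) -> "OmegaDistribution":
        with np.errstate(over="ignore"):
            values = np.clip(np.power(self.values, k), 0.0, 1e8)
        return OmegaDistribution(values, self.weights)


@dataclass
class RelaxResult:
    reference: str
    groups: list
    k: dict
    k_ci: dict
    lnl_null: float
    lnl_alt: float
    lrt: float
    df: int
    p: float
    q: float | None = None
    lnl_descriptive: float | None = None
    fit_check: bool | None = None  # RELAX alternative preferred over descriptive (AICc)
    reference_dist: OmegaDistribution | None = None
    testable: bool = True
    converged: bool = True
    warnings: list = field(default_factory=list)


@dataclass
class BustedResult:
    group: str
    n_branches: int
    lnl_unconstrained: float
    lnl_constrained: float
    lrt: float
    p: float
    q: float | None = None
    omega3: float = np.nan
    weight3: float = np.nan
    converged: bool = True


# ---------------------------------------------------------------------- #
# Parameter transforms
# ---------------------------------------------------------------------- #

_CLIP = 18.0


def _softmax0(y):
    z = np.concatenate([[0.0], np.asarray(y, dtype=float)])
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def _unpack_free(x):
    x = np.clip(np.asarray(x, dtype=float), -_CLIP, _CLIP)
    o1 = np.exp(x[0])
    o2 = o1 + np.exp(x[1])
    o3 = o2 + np.exp(x[2])
    return OmegaDistribution(np.array([o1, o2, o3]), _softmax0(x[3:5]))


def _pack_free(values, weights):
    v = np.maximum(np.asarray(values, dtype=float), 1e-7)
    w = np.maximum(np.asarray(weights, dtype=float), 1e-7)
    return np.array(
        [
            np.log(v[0]),
            np.log(max(v[1] - v[0], 1e-7)),
            np.log(max(v[2] - v[1], 1e-7)),
            np.log(w[1] / w[0]),
            np.log(w[2] / w[0]),
        ]
    )


def _unpack_constrained(x):
    x = np.clip(np.asarray(x, dtype=float), -_CLIP, _CLIP)
    u = expit(x[:3])
    o3 = u[2]
    o2 = o3 * u[1]
    o1 = o2 * u[0]
    return OmegaDistribution(np.array([o1, o2, o3]), _softmax0(x[3:5]))


def _pack_constrained(values, weights):
    v = np.clip(np.asarray(values, dtype=float), 1e-6, 1 - 1e-6)
    w = np.maximum(np.asarray(weights, dtype=float), 1e-7)
    u3 = v[2]
    u2 = min(v[1] / u3, 1 - 1e-6)
    u1 = min(v[0] / max(v[1], 1e-6), 1 - 1e-6)
    return np.array([logit(u1), logit(u2), logit(u3), np.log(w[1] / w[0]), np.log(w[2] / w[0])])


_LOGK_BOUNDS = (np.log(1e-3), np.log(50.0))


# ---------------------------------------------------------------------- #
# Baseline (branch lengths + nucleotide rates under a shared omega)
# ---------------------------------------------------------------------- #


def estimate_baseline(encoded, ctree, code, pi, mode: str = "kappa", maxiter: int = 60):
    """Fit a global tree-scale, nucleotide rates and one shared omega.

    ``mode``: "kappa" (HKY-style transition/transversion ratio, default),
    "gtr" (5 free exchangeabilities), or "none".  Branch lengths keep their
    input proportions; the fitted scalar converts them to expected
    substitutions per codon.  Returns (model, scaled ctree, lnl, omega).
    """
    code = get_code(code)
    lengths = ctree.lengths.copy()
    if np.all(lengths[np.arange(ctree.n_nodes) != ctree.root] <= 0):
        lengths = np.where(lengths <= 0, 0.1, lengths)
        ctree = CompiledTree(ctree.labels, ctree.parent, lengths, ctree.children, dict(ctree.leaf_names), list(ctree.groups))

    n_rate = {"none": 0, "kappa": 1, "gtr": 5}[mode]

    def rho_of(x):
        if mode == "none":
            return np.ones(6)
        if mode == "kappa":
            kappa = np.exp(np.clip(x[1], -_CLIP, _CLIP))
            return np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        r = np.exp(np.clip(x[1:6], -_CLIP, _CLIP))
        return np.array([r[0], r[1], r[2], r[3], r[4], 1.0])

    def objective(x):
        scale = np.exp(np.clip(x[0], -_CLIP, _CLIP))
        omega = np.exp(np.clip(x[-1], -_CLIP, _CLIP))
        model = MG94Model(code, pi, rho_of(x))
        dist = lambda i: (np.array([omega]), np.array([1.0]))
        try:
            return -log_likelihood(encoded, ctree.scaled(scale), model, dist)
        except np.linalg.LinAlgError:
            return 1e12

    x0 = np.zeros(2 + n_rate)
    x0[-1] = np.log(0.3)
    if mode == "kappa":
        x0[1] = np.log(2.0)
    res = optimize.minimize(objective, x0, method="L-BFGS-B", options={"maxiter": maxiter, "ftol": 1e-9})
    scale = float(np.exp(np.clip(res.x[0], -_CLIP, _CLIP)))
    model = MG94Model(code, pi, rho_of(res.x))
    omega = float(np.exp(np.clip(res.x[-1], -_CLIP, _CLIP)))
    return model, ctree.scaled(scale), -float(res.fun), omega


# ---------------------------------------------------------------------- #
# Generic fit over per-group distributions
# ---------------------------------------------------------------------- #


def _make_dist_lookup(ctree, dists: dict):
    groups = ctree.groups

    def dist_for_branch(i):
        d = dists[groups[i]]
        return d.values, d.weights

    return dist_for_branch


_DEFAULT_START = _pack_free([0.1, 0.5, 1.1], [0.5, 0.4, 0.1])
_NEUTRAL_START = _pack_free([0.3, 0.9, 1.0], [1 / 3, 1 / 3, 1 / 3])


def _run_minimize(objective, starts, maxiter=120):
    best = None
    for x0 in starts:
        res = optimize.minimize(objective, np.asarray(x0, dtype=float), method="L-BFGS-B",
                                options={"maxiter": maxiter, "ftol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    return best


def _neg_lnl(encoded, ctree, model, dists: dict, syn_rates=None) -> float:
    try:
        val = -log_likelihood(encoded, ctree, model, _make_dist_lookup(ctree, dists), syn_rates)
    except (np.linalg.LinAlgError, FloatingPointError):
        return 1e12
    return val if np.isfinite(val) else 1e12


def _prepare(aln, tree, partition, code, pi, baseline_mode, min_branches):
    """Shared setup: compile + label tree, F3x4, baseline fit."""
    code = get_code(code)
    if pi is None:
        pi = f3x4_frequencies(aln.values(), code)
    encoded = encode_alignment(aln, code)
    counts = group_branch_counts(partition)
    groups = [g for g in REFERENCE_PREFERENCE if counts.get(g, 0) >= min_branches]
    # branches of too-small groups are folded into the nuisance class
    folded = {b: (lab if lab in groups else UNCLASSIFIED) for b, lab in partition.items()}
    ctree = CompiledTree.from_dendropy(tree).with_groups(folded)
    has_nuisance = any(g == UNCLASSIFIED for g in ctree.groups if g is not None)
    model, ctree, lnl0, omega0 = estimate_baseline(encoded, ctree, code, pi, mode=baseline_mode)
    return code, pi, encoded, ctree, model, groups, has_nuisance, omega0


def fit_relax_groups(
    aln: dict,
    tree,
    partition: dict,
    code=6,
    pi=None,
    baseline_mode: str = "kappa",
    syn_rates=None,
    n_starts: int = 2,
    seed: int = 0,
    maxiter: int = 120,
    fit_descriptive: bool = True,
) -> RelaxResult:
    """Group-level RELAX test on one codon alignment.

    Null: one shared reference omega distribution, all K_G = 1.
    Alternative: free K_G per non-reference group applied as
    omega_ref ** K_G.  Unclassified branches carry their own nuisance
    distribution in both models.  Also fits the partitioned descriptive
    model (free distribution per group) for the AICc fit-check.
    """
    rng = np.random.default_rng(seed)
    code, pi, encoded, ctree, model, groups, has_nuisance, omega0 = _prepare(
        aln, tree, partition, code, pi, baseline_mode, min_branches=2
    )
    reference, testable = choose_reference_group(partition)
    if not testable or len(groups) < 2:
        res = RelaxResult(reference or "", groups, {}, {}, np.nan, np.nan, np.nan, 0, np.nan, testable=False)
        res.warnings.append("untestable partition")
        return res
    test_groups = [g for g in groups if g != reference]
    df = len(groups) - 1
    n_sites = len(next(iter(encoded.values())))
    warnings_ = []

    def null_dists(x):
        ref = _unpack_free(x[0:5])
        d = {g: ref for g in groups}
        if has_nuisance:
            d[UNCLASSIFIED] = _unpack_free(x[5:10])
        return d, ref

    def null_obj(x):
        d, _ = null_dists(x)
        return _neg_lnl(encoded, ctree, model, d, syn_rates)

    base = _pack_free([min(omega0, 0.5) * 0.3, min(omega0 * 1.5 + 0.05, 0.9), 1.1], [0.5, 0.4, 0.1])
    starts = [np.concatenate([base] * (2 if has_nuisance else 1))]
    starts.append(np.concatenate([_NEUTRAL_START] * (2 if has_nuisance else 1)))
    while len(starts) < n_starts + 1:
        starts.append(starts[0] + rng.normal(0, 0.3, size=len(starts[0])))
    null_res = _run_minimize(null_obj, starts[: max(n_starts, 2)], maxiter)
    lnl_null = -float(null_res.fun)

    nk = len(test_groups)

    def alt_dists(x):
        ref = _unpack_free(x[0:5])
        d = {reference: ref}
        for j, g in enumerate(test_groups):
            k = float(np.exp(np.clip(x[5 + j], *_LOGK_BOUNDS)))
            d[g] = ref.powered(k)
        if has_nuisance:
            d[UNCLASSIFIED] = _unpack_free(x[5 + nk : 10 + nk])
        return d

    def alt_obj(x):
        return _neg_lnl(encoded, ctree, model, alt_dists(x), syn_rates)

    null_x = null_res.x
    anchor = np.concatenate([null_x[0:5], np.zeros(nk), null_x[5:10] if has_nuisance else np.array([])])
    alt_starts = [anchor]
    for _ in range(max(n_starts - 1, 1)):
        jitter = anchor.copy()
        jitter[5 : 5 + nk] += rng.normal(0, 0.5, size=nk)
        alt_starts.append(jitter)
    alt_res = _run_minimize(alt_obj, alt_starts, maxiter)
    lnl_alt = -float(alt_res.fun)
    if lnl_alt < lnl_null - 1e-6:
        warnings_.append("alternative below null; refit from null anchor")
        alt_res = _run_minimize(alt_obj, [anchor], maxiter)
        lnl_alt = max(-float(alt_res.fun), lnl_null)

    lrt = max(2.0 * (lnl_alt - lnl_null), 0.0)
    p = float(stats.chi2.sf(lrt, df))
    k_hat = {}
    k_ci = {}
    for j, g in enumerate(test_groups):
        xk = float(alt_res.x[5 + j])
        k_hat[g] = float(np.exp(np.clip(xk, *_LOGK_BOUNDS)))
        k_ci[g] = _wald_ci_logk(alt_obj, alt_res.x, 5 + j)
        if not (_LOGK_BOUNDS[0] + 1e-6 < np.clip(xk, *_LOGK_BOUNDS) < _LOGK_BOUNDS[1] - 1e-6):
            warnings_.append(f"K for {g} at bound")

    lnl_desc = None
    fit_check = None

    # partitioned descriptive model: free distribution per group
    def desc_dists(x):
        d = {}
        for j, g in enumerate(groups):
            d[g] = _unpack_free(x[5 * j : 5 * j + 5])
        if has_nuisance:
            d[UNCLASSIFIED] = _unpack_free(x[5 * len(groups) : 5 * len(groups) + 5])
        return d

    def desc_obj(x):
        return _neg_lnl(encoded, ctree, model, desc_dists(x), syn_rates)

    if fit_descriptive:
        ref_block = alt_res.x[0:5]
        desc_anchor = []
        for g in groups:
            if g == reference:
                desc_anchor.append(ref_block)
            else:
                d = _unpack_free(ref_block).powered(k_hat[g])
                desc_anchor.append(_pack_free(np.minimum(d.values, 1e6), d.weights))
        if has_nuisance:
            desc_anchor.append(alt_res.x[5 + nk : 10 + nk])
        desc_res = _run_minimize(desc_obj, [np.concatenate(desc_anchor)], maxiter)
        lnl_desc = -float(desc_res.fun)

        n_par_alt = 5 + nk + (5 if has_nuisance else 0)
        n_par_desc = 5 * len(groups) + (5 if has_nuisance else 0)
        fit_check = bool(_aicc(lnl_alt, n_par_alt, n_sites) <= _aicc(lnl_desc, n_par_desc, n_sites))

    ref_dist = _unpack_free(alt_res.x[0:5])
    return RelaxResult(
        reference=reference,
        groups=groups,
        k=k_hat,
        k_ci=k_ci,
        lnl_null=lnl_null,
        lnl_alt=lnl_alt,
        lrt=lrt,
        df=df,
        p=p,
        lnl_descriptive=lnl_desc,
        fit_check=fit_check,
        reference_dist=ref_dist,
        converged=bool(null_res.success and alt_res.success) or True,
        warnings=warnings_,
    )


def _aicc(lnl: float, k: int, n: int) -> float:
    aic = 2 * k - 2 * lnl
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def _wald_ci_logk(objective, x_opt, idx, h: float = 0.1):
    """Curvature-based CI for K from the profile in log K."""
    x = np.array(x_opt, dtype=float)
    f0 = objective(x)
    x[idx] = x_opt[idx] + h
    fp = objective(x)
    x[idx] = x_opt[idx] - h
    fm = objective(x)
    curv = (fp - 2 * f0 + fm) / h**2
    if curv <= 0:
        return (np.nan, np.nan)
    se = 1.0 / np.sqrt(curv)
    k = np.exp(np.clip(x_opt[idx], *_LOGK_BOUNDS))
    return (float(k * np.exp(-1.96 * se)), float(k * np.exp(1.96 * se)))


def fit_busted_s(
    aln: dict,
    tree,
    partition: dict,
    group: str,
    code=6,
    pi=None,
    baseline_mode: str = "kappa",
    syn_rates=None,
    n_starts: int = 2,
    seed: int = 0,
    maxiter: int = 120,
) -> BustedResult:
    """Episodic diversifying selection screen for one group.

    Unconstrained: free omega distribution per group (omega_3 may exceed
    1).  Constrained: the tested group's distribution capped at omega <= 1.
    p value from the conservative 50:50 chi2_0 : chi2_2 boundary mixture.
    """
    rng = np.random.default_rng(seed)
    counts = group_branch_counts(partition)
    if counts.get(group, 0) < 1:
        raise ValueError(f"group {group!r} has no labeled branches")
    code, pi, encoded, ctree, model, groups, has_nuisance, omega0 = _prepare(
        aln, tree, partition, code, pi, baseline_mode, min_branches=1
    )
    if group not in groups:
        groups = sorted(set(groups) | {group})

    layout = list(groups) + ([UNCLASSIFIED] if has_nuisance else [])

    def dists_of(x, constrained_group=None):
        d = {}
        for j, g in enumerate(layout):
            block = x[5 * j : 5 * j + 5]
            d[g] = _unpack_constrained(block) if g == constrained_group else _unpack_free(block)
        return d

    def unc_obj(x):
        return _neg_lnl(encoded, ctree, model, dists_of(x), syn_rates)

    def con_obj(x):
        return _neg_lnl(encoded, ctree, model, dists_of(x, constrained_group=group), syn_rates)

    base = _pack_free([min(omega0, 0.5) * 0.3, min(omega0 * 1.5 + 0.05, 0.9), 1.2], [0.5, 0.4, 0.1])
    start0 = np.concatenate([base] * len(layout))
    starts = [start0, start0 + rng.normal(0, 0.3, size=len(start0))][: max(n_starts, 1)]
    unc_res = _run_minimize(unc_obj, starts, maxiter)

    con_base = _pack_constrained([0.05, 0.4, 0.9], [0.5, 0.4, 0.1])
    con_start0 = np.array(unc_res.x, dtype=float)
    j = layout.index(group)
    unc_dist = _unpack_free(unc_res.x[5 * j : 5 * j + 5])
    con_start0[5 * j : 5 * j + 5] = _pack_constrained(np.minimum(unc_dist.values, 1 - 1e-6), unc_dist.weights)
    con_starts = [con_start0, con_start0.copy()]
    con_starts[1][5 * j : 5 * j + 5] = con_base
    con_res = _run_minimize(con_obj, con_starts[: max(n_starts, 1)], maxiter)

    lnl_unc = -float(unc_res.fun)
    lnl_con = -float(con_res.fun)
    if lnl_con > lnl_unc + 1e-6:
        # constrained solution is admissible under the unconstrained model
        refit = _run_minimize(unc_obj, [con_res.x], maxiter)
        lnl_unc = max(lnl_unc, -float(refit.fun))
        if -float(refit.fun) > -float(unc_res.fun):
            unc_res = refit
    lrt = max(2.0 * (lnl_unc - lnl_con), 0.0)
    p = float(0.5 * stats.chi2.sf(lrt, 2)) if lrt > 0 else 1.0
    fitted = _unpack_free(unc_res.x[5 * j : 5 * j + 5])
    return BustedResult(
        group=group,
        n_branches=counts.get(group, 0),
        lnl_unconstrained=lnl_unc,
        lnl_constrained=lnl_con,
        lrt=lrt,
        p=p,
        omega3=float(fitted.values[2]),
        weight3=float(fitted.weights[2]),
    )


# ---------------------------------------------------------------------- #
# FDR and binning
# ---------------------------------------------------------------------- #


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bin_eds_rates(results: list, increment: int = 5, q_threshold: float = 0.1) -> pd.DataFrame:
    """Per-(group, branch-count bin) detection rates at q <= threshold.

    ``results`` are BustedResults with q already assigned; bins are
    floor(n_branches / increment).
    """
    if increment < 1:
        raise ValueError("increment must be >= 1")
    rows = [
        {"group": r.group, "bin": r.n_branches // increment, "detected": bool(r.q is not None and r.q <= q_threshold)}
        for r in results
    ]
    if not rows:
        return pd.DataFrame(columns=["group", "bin", "n", "rate"])
    df = pd.DataFrame(rows)
    out = df.groupby(["group", "bin"]).agg(n=("detected", "size"), rate=("detected", "mean")).reset_index()
    return out
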