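"""MG94 codon model: generator structure, pruning likelihood, simulation."""

import numpy as np
import pytest

from lsgf.codes import get_code
from lsgf.codonmodel import (
    CompiledTree,
    MG94Model,
    draw_site_omegas,
    encode_alignment,
    f3x4_frequencies,
    frequencies_from_positions,
    gc_biased_positions,
    log_likelihood,
    simulate_alignment,
)
from lsgf.oracles import neutral_neighbor_flux_ratio
from lsgf.trees import parse_tree


def _model(code_id=6, gc3=0.6, rho=(1, 2, 1, 1, 2, 1)):
    code = get_code(code_id)
    pi = frequencies_from_positions(gc_biased_positions(gc3), code)
    return MG94Model(code, pi, rho)


def test_generator_rows_sum_to_zero_and_detailed_balance():
    model = _model()
    Q = model.rate_matrix(0.7)
    assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
    F = model.pi[:, None] * Q
    assert np.allclose(F, F.T, atol=1e-12)  # reversibility


def test_transition_matrix_is_stochastic_and_stationary():
    model = _model()
    P = model.transition(0.5, 0.3)
    assert np.allclose(P.sum(axis=1), 1, atol=1e-10)
    assert np.allclose(model.pi @ P, model.pi, atol=1e-10)


def test_multi_nucleotide_changes_have_zero_rate():
    model = _model(1)
    codons = model.code.sense_codons
    Q = model.rate_matrix(1.0)
    for i, a in enumerate(codons[:10]):
        for j, b in enumerate(codons):
            if sum(x != y for x, y in zip(a, b)) > 1:
                assert Q[i, j] == 0.0


def test_zero_branch_length_likelihood_is_log_pi(rng):
    model = _model()
    tree = parse_tree("(a:0.0,b:0.0)r;")
    ctree = CompiledTree.from_dendropy(tree)
    one = (np.array([1.0]), np.array([1.0]))
    aln = simulate_alignment(ctree, model, lambda i: one, 50, rng)
    assert aln["a"] == aln["b"]  # zero length: identical to root
    encoded = encode_alignment(aln, model.code)
    lnl = log_likelihood(encoded, ctree, model, lambda i: one)
    assert lnl == pytest.approx(float(np.log(model.pi[encoded["a"]]).sum()), abs=1e-9)


def test_likelihood_invariant_under_column_reordering(rng):
    model = _model()
    tree = parse_tree("((a:0.2,b:0.4)ab:0.1,c:0.3)r;")
    ctree = CompiledTree.from_dendropy(tree)
    dist = (np.array([0.1, 1.0]), np.array([0.5, 0.5]))
    aln = simulate_alignment(ctree, model, lambda i: dist, 30, rng)
    base = log_likelihood(encode_alignment(aln, model.code), ctree, model, lambda i: dist)
    perm = rng.permutation(30)
    shuffled = {k: "".join(v[3 * p : 3 * p + 3] for p in perm) for k, v in aln.items()}
    again = log_likelihood(encode_alignment(shuffled, model.code), ctree, model, lambda i: dist)
    assert again == pytest.approx(base, abs=1e-8)


def test_leaf_name_mismatch_reported():
    model = _model()
    ctree = CompiledTree.from_dendropy(parse_tree("(a:0.1,b:0.1)r;"))
    with pytest.raises(KeyError, match="b"):
        log_likelihood({"a": np.zeros(3, dtype=int)}, ctree, model, lambda i: ([1.0], [1.0]))


def test_simulated_sequences_contain_no_stop_codons(rng):
    model = _model(6)
    tree = parse_tree("((a:0.9,b:0.9)ab:0.9,c:0.9)r;")
    ctree = CompiledTree.from_dendropy(tree)
    dist = (np.array([0.5, 2.0]), np.array([0.5, 0.5]))
    aln = simulate_alignment(ctree, model, lambda i: dist, 200, rng)
    stops = model.code.stop_codons
    for seq in aln.values():
        assert all(seq[i : i + 3] not in stops for i in range(0, len(seq), 3))


def test_negative_omega_rejected(rng):
    model = _model()
    ctree = CompiledTree.from_dendropy(parse_tree("(a:0.1,b:0.1)r;"))
    with pytest.raises(ValueError, match="omega"):
        simulate_alignment(ctree, model, lambda i: (np.array([-0.5]), np.array([1.0])), 5, rng)


def test_site_omega_draws_match_weights_chisquare(rng):
    # with K = 1 the group draws are distributionally identical to the
    # reference draws: chi-square goodness of fit on 10,000 draws
    from scipy import stats

    values = np.array([0.1, 0.5, 1.3])
    weights = np.array([0.5, 0.3, 0.2])
    draws = draw_site_omegas(values ** 1.0, weights, 10_000, rng)
    counts = [np.sum(draws == v) for v in values]
    p = stats.chisquare(counts, f_exp=weights * 10_000).pvalue
    assert p > 0.01


def test_neutral_substitution_flux_matches_neighbor_enumeration(rng):
    # omega = 1, uniform frequencies and exchangeabilities: the N/S ratio of
    # observed changes on short branches matches the neighbor-count ratio
    code = get_code(1)
    S = len(code.sense_codons)
    model = MG94Model(code, np.full(S, 1 / S))
    tree = parse_tree("(a:0.02,b:0.02)r;")
    ctree = CompiledTree.from_dendropy(tree)
    one = (np.array([1.0]), np.array([1.0]))
    aln = simulate_alignment(ctree, model, lambda i: one, 150_000, rng)
    n_count = s_count = 0
    for x, y in zip(
        (aln["a"][i : i + 3] for i in range(0, len(aln["a"]), 3)),
        (aln["b"][i : i + 3] for i in range(0, len(aln["b"]), 3)),
    ):
        if sum(a != b for a, b in zip(x, y)) != 1:
            continue  # identical, or a multi-hit difference
        if code.forward[x] == code.forward[y]:
            s_count += 1
        else:
            n_count += 1
    expected = neutral_neighbor_flux_ratio(code)
    assert n_count / s_count == pytest.approx(expected, rel=0.05)


def test_f3x4_frequencies_sum_to_one_over_sense_codons():
    code = get_code(6)
    pi = f3x4_frequencies(["ATGGCAGGATTT", "ATGAAACCC"], code)
    assert pi.shape == (63,)
    assert pi.sum() == pytest.approx(1.0)
    assert np.all(pi > 0)
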