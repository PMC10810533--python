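"""Branch labeling, reference-group rule, model consistency, FDR, binning."""

import numpy as np
import pytest

from lsgf.selection import (
    BustedResult,
    OmegaDistribution,
    adjust_fdr,
    bin_eds_rates,
    choose_reference_group,
    fit_relax_groups,
    group_branch_counts,
    label_branches,
)
from lsgf.trees import parse_tree


def _cats(**kw):
    base = {"e1": "EF", "e2": "EF", "h1": "HE", "h2": "HE", "k1": "KA", "n1": "NEF"}
    base.update(kw)
    return base


def test_cherry_of_same_category_labels_internal_branch():
    tree = parse_tree("((e1.x:1,e2.x:1)I:1,h1.x:1)R;")
    part = label_branches(tree, _cats())
    assert part["I"] == "EF"
    assert part["e1.x"] == "EF" and part["h1.x"] == "HE"


def test_mixed_clade_is_unclassified():
    tree = parse_tree("((e1.x:1,h1.x:1)I:1,(e2.x:1,h2.x:1)J:1)R;")
    part = label_branches(tree, _cats())
    assert part["I"] == "unclassified" and part["J"] == "unclassified"


def test_uniform_tree_has_zero_unclassified():
    tree = parse_tree("((e1.x:1,e2.x:1)I:1,(e1.y:1,e2.y:1)J:1)R;")
    part = label_branches(tree, _cats())
    assert set(part.values()) == {"EF"}


def test_unknown_taxon_is_named_in_error():
    tree = parse_tree("(zz.x:1,e1.x:1)R;")
    with pytest.raises(KeyError, match="zz"):
        label_branches(tree, _cats())


@pytest.mark.parametrize(
    "labels,expected",
    [
        (["EF"] * 2 + ["HE"] * 2, "EF"),
        (["NEF"] * 2 + ["KA"] * 2, "NEF"),
        (["HE"] * 2 + ["KA"] * 2, "HE"),
    ],
)
def test_reference_group_preference_rule(labels, expected):
    partition = {f"b{i}": lab for i, lab in enumerate(labels)}
    ref, testable = choose_reference_group(partition)
    assert testable and ref == expected


def test_untestable_partition_is_flagged_not_raised():
    ref, testable = choose_reference_group({"b0": "EF", "b1": "EF", "b2": "HE"})
    assert not testable  # only one group with >= 2 branches
    ref, testable = choose_reference_group({"b0": "EF", "b1": "unclassified"})
    assert not testable


def test_relax_alternative_at_k1_reproduces_null(rng):
    # nesting consistency: the alternative model evaluated at K = 1 equals
    # the null, so the optimised LRT can never be negative
    from lsgf.simulate import FamilyHistory, SimulationConfig, simulate_codon_alignments, simulate_species_tree

    sim = simulate_species_tree(8, {"EF": 0.5, "HE": 0.5}, seed=3)
    cfg = SimulationConfig(n_taxa=8, category_scheme={"EF": 0.5, "HE": 0.5}, n_codons=120, seed=5)
    h = FamilyHistory("fam0000", "N0", set(), [], set(sim.leaf_categories))
    aln, gt = simulate_codon_alignments(h, cfg, seed=9, sim=sim)
    part = label_branches(gt, sim.leaf_categories)
    res = fit_relax_groups(aln, gt, part, code=6, seed=2, fit_descriptive=True)
    assert res.lrt >= 0.0
    assert res.lnl_alt >= res.lnl_null - 1e-6
    assert res.df == 1
    assert set(res.k) == {"HE"}
    # descriptive model nests the RELAX alternative
    assert res.lnl_descriptive >= res.lnl_alt - 1e-6


def test_untestable_alignment_returns_flagged_result():
    from lsgf.simulate import FamilyHistory, SimulationConfig, simulate_codon_alignments, simulate_species_tree

    sim = simulate_species_tree(4, {"EF": 1.0}, seed=3)
    cfg = SimulationConfig(n_taxa=4, category_scheme={"EF": 1.0}, n_codons=60, seed=5)
    h = FamilyHistory("fam0000", "N0", set(), [], set(sim.leaf_categories))
    aln, gt = simulate_codon_alignments(h, cfg, seed=9, sim=sim)
    part = label_branches(gt, sim.leaf_categories)
    res = fit_relax_groups(aln, gt, part, code=6)
    assert not res.testable


def test_omega_power_transform_direction():
    dist = OmegaDistribution(np.array([0.25, 1.0, 2.0]), np.array([0.5, 0.3, 0.2]))
    relaxed = dist.powered(0.5)
    intensified = dist.powered(2.0)
    assert relaxed.values[0] > dist.values[0] and relaxed.values[2] < dist.values[2]
    assert intensified.values[0] < dist.values[0] and intensified.values[2] > dist.values[2]
    assert np.all(dist.powered(1.0).values == dist.values)


# ---------------------------------------------------------------------- #


def test_bh_fdr_worked_example():
    q = adjust_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_fdr_trivial_cases():
    assert np.allclose(adjust_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
    assert adjust_fdr([0.123])[0] == pytest.approx(0.123)


def test_bh_fdr_q_at_least_p_and_monotone(rng):
    p = rng.uniform(size=300)
    q = adjust_fdr(p)
    assert np.all(q >= p - 1e-12)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


def test_bh_fdr_rejects_invalid_p():
    with pytest.raises(ValueError):
        adjust_fdr([0.5, 1.2])
    with pytest.raises(ValueError):
        adjust_fdr([-0.1])


def _bres(group, n_branches, q):
    return BustedResult(group, n_branches, 0.0, 0.0, 0.0, q, q=q)


def test_bin_eds_rates_floor_rule_and_recount():
    results = [
        _bres("EF", 3, 0.05),
        _bres("EF", 7, 0.5),
        _bres("EF", 12, 0.02),
        _bres("HE", 7, 0.01),
    ]
    table = bin_eds_rates(results, increment=5, q_threshold=0.1)
    assert sorted(table["bin"].unique().tolist()) == [0, 1, 2]
    ef1 = table[(table.group == "EF") & (table["bin"] == 1)].iloc[0]
    assert ef1.n == 1 and ef1.rate == 0.0
    ef0 = table[(table.group == "EF") & (table["bin"] == 0)].iloc[0]
    assert ef0.rate == 1.0
    # brute recount of detections
    assert table["n"].sum() == len(results)
    assert (table.n * table.rate).sum() == sum(r.q <= 0.1 for r in results)


def test_bin_eds_rates_empty_and_validation():
    assert len(bin_eds_rates([])) == 0
    with pytest.raises(ValueError):
        bin_eds_rates([], increment=0)
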