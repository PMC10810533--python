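"""Family clustering stand-in, refinement rules, and sharing summaries."""

import numpy as np
import pandas as pd
import pytest

from lsgf.families import (
    FamilyMember,
    GeneFamily,
    TaxonProfile,
    cluster_orfs,
    presence_matrix,
    refine_family,
    sharing_summary,
)

from conftest import make_orf


def _family(lengths, taxa=None, ciliate=None):
    members = [
        FamilyMember(
            f"r{i}",
            (taxa or [f"t{i}" for i in range(len(lengths))])[i],
            L,
            ciliate=True if ciliate is None else ciliate[i],
        )
        for i, L in enumerate(lengths)
    ]
    return GeneFamily("fam", members)


def test_comparable_family_is_kept():
    res = refine_family(_family([200] * 6))
    assert res.kept and res.reason is None


def test_ciliate_proportion_below_95_percent_rejects():
    fam = _family([200] * 10, ciliate=[True] * 8 + [False] * 2)
    res = refine_family(fam)
    assert not res.kept and res.reason == "ciliate_proportion"


def test_length_band_then_member_count_hand_example():
    # mean length 160 -> band [80, 240]; the 400-aa member is dropped and
    # only 4 members remain, below the >= 5 member rule
    res = refine_family(_family([100, 100, 100, 100, 400]))
    assert not res.kept
    assert res.reason == "min_members"
    assert len(res.dropped_members) == 1 and res.dropped_members[0].length == 400


def test_min_genera_requires_two_ciliate_genera():
    taxa = {f"t{i}": TaxonProfile(f"t{i}", "SameGenus", "ClassX", "EF") for i in range(6)}
    res = refine_family(_family([200] * 6, taxa=list(taxa)), taxa=taxa)
    assert not res.kept and res.reason == "min_genera"


def test_refinement_is_order_invariant(rng):
    lengths = [100, 150, 200, 250, 90, 400, 210]
    base = refine_family(_family(lengths))
    for _ in range(5):
        perm = list(rng.permutation(len(lengths)))
        fam = GeneFamily("fam", [_family(lengths).members[i] for i in perm])
        res = refine_family(fam)
        assert res.kept == base.kept and res.reason == base.reason


def test_tightening_thresholds_never_keeps_more(rng):
    families = []
    for i in range(80):
        k = int(rng.integers(2, 10))
        families.append(
            GeneFamily(
                f"f{i}",
                [
                    FamilyMember(f"f{i}r{j}", f"t{int(rng.integers(0, 5))}", int(rng.integers(50, 400)),
                                 ciliate=bool(rng.random() < 0.9))
                    for j in range(k)
                ],
            )
        )

    def kept(**kw):
        return sum(refine_family(f, **kw).kept for f in families)

    base = kept()
    assert kept(min_members=6) <= base
    assert kept(min_genera=3) <= base
    assert kept(min_ciliate_prop=1.0) <= base
    assert kept(size_band=(0.8, 1.2)) <= base


# ---------------------------------------------------------------------- #


def _random_cds(rng, n_codons=100):
    # sense codons only (no TGA), so table-6 translation is stop-free
    safe = [a + b + c for a in "ACG" for b in "ACGT" for c in "ACGT"]
    return "".join(rng.choice(safe, size=n_codons))


def test_single_linkage_joins_through_intermediates(rng):
    # a~b and b~c above threshold while a and c are not: one family of 3
    b = _random_cds(rng, 120)
    a = b[:240] + _random_cds(rng, 40)
    c = _random_cds(rng, 40) + b[120:]
    orfs = [make_orf("a", a), make_orf("b", b), make_orf("c", c)]
    from lsgf.families import protein_identity

    pid = {(x.record_id, y.record_id): protein_identity(x.protein, y.protein) for x in orfs for y in orfs}
    thr = 0.55
    assert pid[("a", "b")] >= thr and pid[("b", "c")] >= thr and pid[("a", "c")] < thr
    assert len(cluster_orfs(orfs, threshold=thr)) == 1


def test_dissimilar_orfs_become_singletons(rng):
    orfs = [make_orf(f"r{i}", _random_cds(rng)) for i in range(4)]
    assert len(cluster_orfs(orfs, threshold=0.95)) == 4


# ---------------------------------------------------------------------- #


def _profiles():
    return [
        TaxonProfile("e1", "Eg1", "Spirotrichea", "EF"),
        TaxonProfile("e2", "Eg2", "Spirotrichea", "EF"),
        TaxonProfile("h1", "Hg1", "Heterotrichea", "HE"),
        TaxonProfile("k1", "Kg1", "Karyorelictea", "KA"),
    ]


def test_sharing_summary_counts_and_partition():
    taxa = _profiles()
    matrix = pd.DataFrame(
        [[1, 1, 1, 1], [2, 1, 0, 0], [0, 0, 3, 0]],
        index=["famA", "famB", "famC"],
        columns=["e1", "e2", "h1", "k1"],
    )
    summary = sharing_summary(matrix, taxa)
    assert summary["upset"]["EF&HE&KA"] == 1
    assert summary["upset"]["EF"] == 1
    assert summary["upset"]["HE"] == 1
    assert sum(summary["upset"].values()) == 3  # partition over families
    assert summary["per_category"]["EF"]["n_families"] == 2
    assert summary["per_category"]["EF"]["mean_size"] == pytest.approx(2.5)  # (2, 3) members
    assert summary["per_taxon"]["h1"]["n_families"] == 2


def test_presence_matrix_roundtrip():
    taxa = _profiles()
    fam = GeneFamily("famA", [FamilyMember("r1", "e1", 100), FamilyMember("r2", "e1", 120), FamilyMember("r3", "h1", 90)])
    matrix = presence_matrix([fam], taxa)
    assert list(matrix.columns) == ["e1", "e2", "h1", "k1"]
    assert matrix.loc["famA"].tolist() == [2, 0, 1, 0]
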