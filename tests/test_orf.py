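"""ORF calling under alternative stop codons and allelic-variant collapse."""

import numpy as np
import pytest

from lsgf.codes import get_code
from lsgf.oracles import brute_force_largest_orf
from lsgf.orf import call_orfs, dedupe_allelic_variants, pairwise_identity, reverse_complement

from conftest import make_orf


def test_simple_complete_orf_under_ciliate_code(ciliate_code):
    transcript = "ATG" + "AAA" * 200 + "TGA"
    orfs = call_orfs(transcript, ciliate_code, min_aa=200)
    assert len(orfs) == 1
    orf = orfs[0]
    assert orf.protein == "M" + "K" * 200
    assert len(orf.protein) == 201
    assert orf.nucleotide == "ATG" + "AAA" * 200  # terminal stop excluded
    assert (orf.start, orf.end) == (0, 603)


def test_taa_is_stop_under_table1_but_gln_under_table6(standard_code, ciliate_code):
    # stop codon usage varies widely among ciliates: TAA terminates the ORF
    # under the standard code but reads through as Gln under table 6
    transcript = "ATG" + "AAA" * 30 + "TAA" + "CCC" * 30 + "TGA"
    under_1 = call_orfs(transcript, standard_code, min_aa=10)
    under_6 = call_orfs(transcript, ciliate_code, min_aa=10)
    assert len(under_1[0].protein) == 31
    assert under_6[0].protein == "M" + "K" * 30 + "Q" + "P" * 30


def test_reverse_strand_orf_coordinates(ciliate_code):
    fwd = "ATG" + "GAA" * 50 + "TGA"
    transcript = "CCCCC" + reverse_complement(fwd) + "CC"
    orfs = call_orfs(transcript, ciliate_code, min_aa=20)
    assert orfs and orfs[0].frame < 0
    a, b = orfs[0].start, orfs[0].end
    assert reverse_complement(transcript[a:b]) == "ATG" + "GAA" * 50


def test_min_aa_filter_drops_short_orfs(ciliate_code):
    transcript = "ATG" + "AAA" * 50 + "TGA"
    assert call_orfs(transcript, ciliate_code, min_aa=200) == []
    assert len(call_orfs(transcript, ciliate_code, min_aa=50)) == 1


def test_empty_and_invalid_inputs(ciliate_code):
    assert call_orfs("", ciliate_code) == []
    with pytest.raises(ValueError, match="position"):
        call_orfs("ACGT!ACGT", ciliate_code)


def test_output_invariant_under_downstream_flanks(ciliate_code, rng):
    core = "ATG" + "GAA" * 120 + "TGA"
    transcript = "TTTT" + core
    base = call_orfs(transcript, ciliate_code, min_aa=100)[0]
    flank = "".join(rng.choice(list("AT"), size=30))
    extended = call_orfs(transcript + flank, ciliate_code, min_aa=100)[0]
    assert extended.nucleotide == base.nucleotide
    assert (extended.start, extended.end) == (base.start, base.end)


@pytest.mark.parametrize("code_id", [1, 6, 10])
def test_call_orfs_matches_exhaustive_scanner_on_random_sequences(code_id, rng):
    code = get_code(code_id)
    for _ in range(15):
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(2000, 4000))))
        impl = call_orfs(seq, code, min_aa=0)
        oracle = brute_force_largest_orf(seq, code, min_aa=0)
        if oracle is None:
            assert impl == []
        else:
            cds, frame, _ = oracle
            assert impl[0].nucleotide == cds
            assert impl[0].frame == frame


# ---------------------------------------------------------------------- #


def test_identical_sequences_collapse_to_one_representative():
    a = make_orf("a", "ATG" + "AAA" * 80)
    b = make_orf("b", "ATG" + "AAA" * 80)
    reps, clusters = dedupe_allelic_variants([a, b])
    assert len(reps) == 1
    assert sorted(clusters[reps[0].record_id]) == ["a", "b"]


def test_diverged_sequences_stay_separate(rng):
    cds = "ATG" + "".join(rng.choice(list("ACG"), size=300))
    other = list(cds)
    for i in rng.choice(len(cds), size=45, replace=False):  # ~85% identity
        other[i] = {"A": "C", "C": "G", "G": "A", "T": "A"}[other[i]]
    reps, _ = dedupe_allelic_variants([make_orf("a", cds), make_orf("b", "".join(other))])
    assert len(reps) == 2


def test_partition_property_and_representative_lengths(rng):
    orfs = []
    for i in range(12):
        orfs.append(make_orf(f"r{i}", "ATG" + "".join(rng.choice(list("ACG"), size=3 * int(rng.integers(60, 120))))))
    reps, clusters = dedupe_allelic_variants(orfs)
    members = sorted(m for c in clusters.values() for m in c)
    assert members == sorted(o.record_id for o in orfs)  # partition
    by_id = {o.record_id: o for o in orfs}
    for rep_id, cluster in clusters.items():
        assert all(len(by_id[rep_id].nucleotide) >= len(by_id[m].nucleotide) for m in cluster)


def test_identity_threshold_validation():
    with pytest.raises(ValueError):
        dedupe_allelic_variants([], identity=0.0)


def test_pairwise_identity_counts_gaps_as_mismatches():
    assert pairwise_identity("AAAA", "AAAA") == 1.0
    assert pairwise_identity("AACA", "AAAA") == 0.75
    # query aligns within the longer target (infix semantics)
    assert pairwise_identity("AAAA", "GGGAAAAGGG") == 1.0
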