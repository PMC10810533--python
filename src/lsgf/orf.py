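"""ORF curation: largest-complete-ORF calling and allelic-variant collapse.

Transcript ORFs are predicted under the taxon's genetic code (stop usage
varies widely across ciliates), keeping one ORF per transcript — the
largest complete one, i.e. running from an ATG to an in-frame stop — and
discarding short ORFs (< 200 aa by default).  Putative allelic variants
(somatic haplotypes of the same locus) are then collapsed by greedy
longest-first clustering at 97% nucleotide identity with full coverage of
the shorter sequence, mirroring CD-HIT-EST's ``-G 0 -c 0.97 -aS 1.00``
semantics without its word-filter heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .codes import GeneticCode, get_code, normalize, validate_nucleotides

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

FRAME_ORDER = (1, 2, 3, -1, -2, -3)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class OrfRecord:
    """A curated coding sequence (terminal stop excluded, so 3n length)."""

    record_id: str
    taxon: str
    nucleotide: str
    protein: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    source_id: str
    start: int  # 0-based, half-open, on the forward strand of the transcript
    end: int

    def __post_init__(self):
        if len(self.nucleotide) != 3 * len(self.protein):
            raise ValueError("CDS length must be 3 x protein length")
        if "*" in self.protein:
            raise ValueError("protein must not contain a stop symbol")


def call_orfs(
    transcript: str,
    code: GeneticCode | int = 6,
    min_aa: int = 200,
    complete_only: bool = True,
    record_id: str = "orf",
    taxon: str = "",
    source_id: str = "",
) -> list[OrfRecord]:
    """Return the single largest ORF of a transcript (empty list if none).

    Scans all six frames.  In ``complete_only`` mode (default) a candidate
    runs from the first ATG after a stop (or after the frame start) to the
    next in-frame stop; both the ATG and the stop are required.  With
    ``complete_only=False`` the ATG requirement is dropped (stop-to-stop
    ORFs), the terminal stop is still required.  Ties between frames break
    by frame order +1,+2,+3,-1,-2,-3, then by 5'-most start.
    """
    code = get_code(code)
    if not transcript:
        return []
    validate_nucleotides(transcript)
    seq = normalize(transcript)
    n = len(seq)

    best = None  # (aa_len, frame_rank, start_codon_idx, frame, codons, seg)
    for rank, frame in enumerate(FRAME_ORDER):
        strand_seq = seq if frame > 0 else reverse_complement(seq)
        offset = abs(frame) - 1
        n_codons = (len(strand_seq) - offset) // 3
        codons = [strand_seq[offset + 3 * i : offset + 3 * i + 3] for i in range(n_codons)]
        stop_idx = [i for i, c in enumerate(codons) if c in code.stop_codons]
        seg_start = 0
        for s in stop_idx:
            cand = _candidate_in_segment(codons, seg_start, s, complete_only)
            if cand is not None:
                aa_len = s - cand
                key = (-aa_len, rank, cand)
                if best is None or key < best[0]:
                    best = (key, frame, offset, cand, s, codons)
            seg_start = s + 1
        # trailing segment has no stop: never complete, skipped

    if best is None:
        return []
    _, frame, offset, start_codon, stop_codon, codons = best
    aa_len = stop_codon - start_codon
    if aa_len < min_aa:
        return []
    cds = "".join(codons[start_codon:stop_codon])
    protein = code.translate(cds)
    a = offset + 3 * start_codon
    b = offset + 3 * stop_codon
    if frame < 0:  # map back onto the forward strand of the transcript
        a, b = n - b, n - a
    return [
        OrfRecord(
            record_id=record_id,
            taxon=taxon,
            nucleotide=cds,
            protein=protein,
            frame=frame,
            source_id=source_id or record_id,
            start=a,
            end=b,
        )
    ]


def _candidate_in_segment(codons, seg_start, seg_stop, complete_only):
    """Start codon index of the candidate ORF in codons[seg_start:seg_stop]."""
    if not complete_only:
        return seg_start if seg_stop > seg_start else None
    for i in range(seg_start, seg_stop):
        if codons[i] == "ATG":
            return i
    return None


# ---------------------------------------------------------------------- #
# Allelic-variant collapse
# ---------------------------------------------------------------------- #


def pairwise_identity(query: str, target: str) -> float:
    """Identity of ``query`` aligned within ``target`` (infix alignment),
    with the full shorter sequence as denominator; gaps count as mismatches."""
    if len(query) > len(target):
        query, target = target, query
    if not query:
        return 0.0
    res = edlib.align(query, target, mode="HW", task="distance")
    return max(0.0, 1.0 - res["editDistance"] / len(query))


def dedupe_allelic_variants(
    orfs: list[OrfRecord],
    identity: float = 0.97,
    cover_shorter: float = 1.00,
) -> tuple[list[OrfRecord], dict]:
    """Greedy longest-first clustering of one taxon's ORFs.

    Each sequence joins the first existing cluster whose representative
    matches it at ``>= identity`` over the shorter sequence (which, given
    the length ordering, is always the candidate); otherwise it founds a
    new cluster.  Returns (representatives, {rep_id: [member ids]}).
    """
    if not 0 < identity <= 1:
        raise ValueError("identity must be in (0, 1]")
    if not 0 < cover_shorter <= 1:
        raise ValueError("cover_shorter must be in (0, 1]")
    ordered = sorted(orfs, key=lambda o: (-len(o.nucleotide), o.record_id))
    reps: list[OrfRecord] = []
    clusters: dict[str, list] = {}
    for orf in ordered:
        home = None
        for rep in reps:
            if pairwise_identity(orf.nucleotide, rep.nucleotide) >= identity:
                home = rep
                break
        if home is None:
            reps.append(orf)
            clusters[orf.record_id] = [orf.record_id]
        else:
            clusters[home.record_id].append(orf.record_id)
    return reps, clusters
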