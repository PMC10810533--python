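"""Codon-composition statistics (GC3s, Wright's ENc) and the band filter.

Lineage-specific ORFs from transcriptomes risk being contamination (prey,
bacteria) rather than ciliate genes.  Because ciliate genomes tend to have
strongly skewed third-position composition, candidate ORFs are compared to
the GC3s distribution of a conserved-gene reference set: candidates within
the reference's 10–90th percentile band are retained.

GC3s is the G+C fraction at third positions of codons belonging to
four-fold degenerate quartets of the active genetic code.  ENc is Wright's
effective number of codons generalised to arbitrary codes: per amino acid
``a`` with ``n`` observations and usage proportions ``p_i``, homozygosity
``F_a = (n * sum(p_i^2) - 1) / (n - 1)``; ``F̄_k`` averages ``F_a`` over
observed amino acids of degeneracy ``k``; ``ENc = N_1 + sum_k N_k / F̄_k``
with ``N_k`` the number of amino acids in class ``k`` under the code,
clamped to the code's sense-codon count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .codes import GeneticCode, get_code, normalize


@dataclass
class CompositionStats:
    record_id: str
    gc3s: float  # NaN when the sequence has no four-fold quartet codons
    enc: float  # NaN when no degeneracy family is observable
    n_codons: int
    fbar: dict = field(default_factory=dict)  # degeneracy class k -> F̄_k


def gc3s(cds: str, code: GeneticCode) -> float:
    seq = normalize(cds)
    third_gc = 0
    third_total = 0
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in code.fourfold_codons:
            third_total += 1
            if codon[2] in "GC":
                third_gc += 1
    return third_gc / third_total if third_total else math.nan


def effective_number_of_codons(cds: str, code: GeneticCode) -> tuple[float, dict]:
    """Wright's ENc under the active code; returns (enc, F̄ per class).

    Amino-acid families with fewer than 2 observations or F <= 0 are
    treated as missing.  A degeneracy class with no observed family gets
    its F̄ imputed from the mean of the flanking observed classes; classes
    absent from the code contribute nothing.
    """
    seq = normalize(cds)
    counts: dict[str, dict] = {}
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        aa = code.forward.get(codon)
        if aa is None or aa == "*":
            continue  # ambiguous codons are uninformative for usage bias
        counts.setdefault(aa, {}).setdefault(codon, 0)
        counts[aa][codon] += 1

    # homozygosity per observed amino acid family
    f_by_class: dict[int, list] = {}
    for aa, usage in counts.items():
        k = len(code.synonymous_families.get(aa, ()))
        if k < 2:
            continue
        n = sum(usage.values())
        if n < 2:
            continue
        sum_p2 = sum((c / n) ** 2 for c in usage.values())
        f_a = (n * sum_p2 - 1) / (n - 1)
        if f_a <= 0:
            continue
        f_by_class.setdefault(k, []).append(f_a)

    fbar = {k: float(np.mean(v)) for k, v in sorted(f_by_class.items())}
    class_sizes = code.degeneracy_class_sizes
    multi = sorted(k for k in class_sizes if k >= 2)
    if not fbar:
        return math.nan, {}

    observed = sorted(fbar)
    enc = float(class_sizes.get(1, 0))
    for k in multi:
        if k in fbar:
            f = fbar[k]
        else:
            lower = [fbar[j] for j in observed if j < k]
            upper = [fbar[j] for j in observed if j > k]
            flanks = ([lower[-1]] if lower else []) + ([upper[0]] if upper else [])
            f = float(np.mean(flanks))
        enc += class_sizes[k] / f
    enc = min(enc, float(len(code.sense_codons)))
    return enc, fbar


def composition_stats(orf, code: GeneticCode | int = 6, record_id: str | None = None) -> CompositionStats:
    """Compute GC3s and ENc for an OrfRecord or a raw CDS string."""
    code = get_code(code)
    if isinstance(orf, str):
        cds, rid = orf, record_id or ""
    else:
        cds, rid = orf.nucleotide, orf.record_id
    cds = normalize(cds)
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    for i in range(0, len(cds), 3):
        if cds[i : i + 3] in code.stop_codons:
            raise ValueError(f"internal stop codon at position {i}")
    enc, fbar = effective_number_of_codons(cds, code)
    return CompositionStats(
        record_id=rid,
        gc3s=gc3s(cds, code),
        enc=enc,
        n_codons=len(cds) // 3,
        fbar=fbar,
    )


# ---------------------------------------------------------------------- #


@dataclass
class PercentileBand:
    lower_pct: float
    upper_pct: float
    lower: float
    upper: float
    n_reference: int

    @classmethod
    def from_reference(cls, values, lower_pct: float = 10.0, upper_pct: float = 90.0) -> "PercentileBand":
        values = np.asarray(list(values), dtype=float)
        if values.size == 0:
            raise ValueError("reference value set is empty")
        if not (0 <= lower_pct <= upper_pct <= 100):
            raise ValueError("percentiles must satisfy 0 <= lower <= upper <= 100")
        lo, hi = np.percentile(values, [lower_pct, upper_pct], method="linear")
        return cls(lower_pct, upper_pct, float(lo), float(hi), int(values.size))

    def contains(self, value: float) -> bool:
        return not math.isnan(value) and self.lower <= value <= self.upper


def composition_band_filter(
    candidates: list[CompositionStats],
    reference,
    band: PercentileBand | None = None,
    lower_pct: float = 10.0,
    upper_pct: float = 90.0,
    enc_band: tuple | None = None,
) -> tuple[list, list]:
    """Partition candidates into (kept, discarded) on the reference GC3s band.

    ``discarded`` holds (stats, reason) pairs.  The retention rule is on
    GC3s (closed interval); an ENc band may optionally be supplied as
    (low, high) and is off by default.
    """
    if band is None:
        band = PercentileBand.from_reference(reference, lower_pct, upper_pct)
    kept, discarded = [], []
    for stats in candidates:
        if math.isnan(stats.gc3s):
            discarded.append((stats, "gc3s_undefined"))
        elif stats.gc3s < band.lower:
            discarded.append((stats, "gc3s_below_band"))
        elif stats.gc3s > band.upper:
            discarded.append((stats, "gc3s_above_band"))
        elif enc_band is not None and not (enc_band[0] <= stats.enc <= enc_band[1]):
            discarded.append((stats, "enc_outside_band"))
        else:
            kept.append(stats)
    return kept, discarded
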