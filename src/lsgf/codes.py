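"""Genetic codes, including the ciliate stop-codon reassignments.

Ciliate nuclear genomes rarely use the standard code: most classes read
TAA/TAG as glutamine (NCBI translation table 6, "ciliate/dasycladacean"),
while *Euplotes* reads TGA as cysteine (table 10).  Every downstream
computation — ORF calling, GC3s/ENc, the codon substitution model — is
parameterised by one of these code objects, so degeneracy classes and the
sense-codon state space are always derived from the active code rather than
hard-wired to the standard one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

from Bio.Data import CodonTable

BASES = "TCAG"
CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

#: IUPAC nucleotide symbols accepted in transcripts (plus U, mapped to T).
IUPAC_NUCLEOTIDES = frozenset("ACGTURYSWKMBDHVN")


@dataclass(frozen=True)
class GeneticCode:
    """A 64-codon translation table with an explicit stop set."""

    name: str
    table_id: int | None
    forward: dict  # codon -> one-letter amino acid, stops mapped to '*'

    def __post_init__(self):
        if set(self.forward) != set(CODONS):
            missing = set(CODONS) - set(self.forward)
            raise ValueError(f"genetic code must cover all 64 codons; missing {sorted(missing)[:3]}...")

    # ------------------------------------------------------------------ #

    @classmethod
    def from_ncbi_id(cls, table_id: int) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        forward = {c: table.forward_table.get(c, "*") for c in CODONS}
        for stop in table.stop_codons:
            forward[stop] = "*"
        return cls(name=table.names[0], table_id=table_id, forward=forward)

    @classmethod
    def from_file(cls, path) -> "GeneticCode":
        """Load a custom code: 64 lines of ``codon<TAB>aa-or-*``."""
        forward = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                codon, aa = line.split("\t")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: expected 'codon<TAB>aa'") from exc
            codon = codon.upper().replace("U", "T")
            if codon not in CODONS or len(aa) != 1:
                raise ValueError(f"{path}:{lineno}: bad entry {line!r}")
            forward[codon] = aa.upper()
        return cls(name=f"custom:{path}", table_id=None, forward=forward)

    # ------------------------------------------------------------------ #

    @cached_property
    def stop_codons(self) -> frozenset:
        return frozenset(c for c, aa in self.forward.items() if aa == "*")

    @cached_property
    def sense_codons(self) -> tuple:
        return tuple(c for c in CODONS if self.forward[c] != "*")

    @cached_property
    def codon_index(self) -> dict:
        return {c: i for i, c in enumerate(self.sense_codons)}

    @cached_property
    def synonymous_families(self) -> dict:
        """amino acid -> tuple of its sense codons."""
        fam: dict[str, list] = {}
        for c in self.sense_codons:
            fam.setdefault(self.forward[c], []).append(c)
        return {aa: tuple(cs) for aa, cs in fam.items()}

    @cached_property
    def degeneracy_class_sizes(self) -> dict:
        """degeneracy k -> number of amino acids with k synonymous codons."""
        sizes: dict[int, int] = {}
        for codons in self.synonymous_families.values():
            sizes[len(codons)] = sizes.get(len(codons), 0) + 1
        return sizes

    @cached_property
    def fourfold_codons(self) -> frozenset:
        """Codons in four-fold degenerate quartets (all third-position
        variants of the same prefix are sense and synonymous)."""
        out = set()
        for a in BASES:
            for b in BASES:
                quartet = [a + b + c for c in BASES]
                aas = {self.forward[q] for q in quartet}
                if len(aas) == 1 and "*" not in aas:
                    out.update(quartet)
        return frozenset(out)

    def translate(self, seq: str) -> str:
        """Translate an in-frame CDS; codons with ambiguity codes become 'X'."""
        seq = normalize(seq)
        if len(seq) % 3:
            raise ValueError("sequence length not divisible by 3")
        out = []
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            out.append(self.forward[codon] if codon in self.forward else "X")
        return "".join(out)


def normalize(seq: str) -> str:
    """Uppercase and map RNA U to T; leaves ambiguity codes untouched."""
    return seq.upper().replace("U", "T")


def validate_nucleotides(seq: str) -> None:
    """Raise ValueError naming the first non-IUPAC symbol."""
    for pos, ch in enumerate(seq.upper()):
        if ch not in IUPAC_NUCLEOTIDES:
            raise ValueError(f"non-IUPAC nucleotide symbol {ch!r} at position {pos}")


STANDARD = GeneticCode.from_ncbi_id(1)
CILIATE_TAA_TAG_GLN = GeneticCode.from_ncbi_id(6)
EUPLOTES_TGA_CYS = GeneticCode.from_ncbi_id(10)

_BUILTIN = {1: STANDARD, 6: CILIATE_TAA_TAG_GLN, 10: EUPLOTES_TGA_CYS}


def get_code(spec) -> GeneticCode:
    """Resolve a code from an int table id, ``custom:<file>`` string, or pass through."""
    if isinstance(spec, GeneticCode):
        return spec
    if isinstance(spec, int):
        return _BUILTIN.get(spec) or GeneticCode.from_ncbi_id(spec)
    if isinstance(spec, str):
        if spec.startswith("custom:"):
            return GeneticCode.from_file(spec[len("custom:"):])
        return get_code(int(spec))
    raise TypeError(f"cannot resolve genetic code from {spec!r}")
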