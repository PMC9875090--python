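"""Genetic-code model: codon→amino-acid mapping, synonymous families and
degeneracy classes.

Codon-usage indices (RSCU, ENC, CAI) operate on the *synonymous* codon
universe: for the standard code this is the 59 sense codons that encode the
18 amino acids with more than one codon — ATG (Met), TGG (Trp) and the three
stops are excluded, because single-codon families carry no usage information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

BASES = "TCAG"
ALL_CODONS: tuple[str, ...] = tuple("".join(c) for c in product(BASES, repeat=3))

#: Three-letter names keyed by one-letter amino-acid code.
AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}
AA1 = {v: k for k, v in AA3.items()}


def to_dna(codon: str) -> str:
    """Normalize a codon to the uppercase DNA alphabet (U→T)."""
    return codon.strip().upper().replace("U", "T")


def to_rna(codon: str) -> str:
    """Render a DNA codon in the RNA alphabet used in printed usage tables."""
    return codon.upper().replace("T", "U")


@dataclass(frozen=True)
class GeneticCode:
    """A translation table with its synonymous-family structure.

    Attributes
    ----------
    table_id : int
        NCBI translation-table number (1 = standard).
    codon_to_aa : dict
        Maps each of the 64 codons (DNA alphabet) to a one-letter amino
        acid, or ``"*"`` for stop codons.
    stops : frozenset
        The stop codons.
    families : dict
        amino acid → tuple of its codons (all sense codons, including
        single-codon families).
    """

    table_id: int
    codon_to_aa: dict[str, str]
    stops: frozenset[str]
    families: dict[str, tuple[str, ...]] = field(repr=False)

    def __post_init__(self):
        if set(self.codon_to_aa) != set(ALL_CODONS):
            raise ValueError("codon_to_aa must cover exactly the 64 codons")

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if c not in self.stops)

    @property
    def synonymous_families(self) -> dict[str, tuple[str, ...]]:
        """Families with degeneracy ≥ 2 (the RSCU/ENC/CAI universe)."""
        return {aa: cods for aa, cods in self.families.items() if len(cods) > 1}

    @property
    def synonymous_codons(self) -> tuple[str, ...]:
        """Codons of multi-codon families (59 for the standard code)."""
        return tuple(
            c for fam in self.synonymous_families.values() for c in fam
        )

    def degeneracy(self, codon: str) -> int:
        aa = self.codon_to_aa[to_dna(codon)]
        if aa == "*":
            return 0
        return len(self.families[aa])

    @property
    def degeneracy_classes(self) -> dict[int, frozenset[str]]:
        """Degeneracy k → amino acids whose family has exactly k codons."""
        out: dict[int, set[str]] = {}
        for aa, cods in self.synonymous_families.items():
            out.setdefault(len(cods), set()).add(aa)
        return {k: frozenset(v) for k, v in sorted(out.items())}

    def is_stop(self, codon: str) -> bool:
        return to_dna(codon) in self.stops

    def translate_codon(self, codon: str) -> str:
        return self.codon_to_aa[to_dna(codon)]


@lru_cache(maxsize=None)
def genetic_code(table_id: int = 1) -> GeneticCode:
    """Build a :class:`GeneticCode` from an NCBI translation table.

    Table 1 (standard) is the default; table 9 and others are available for
    non-standard genomes.
    """
    table = CodonTable.unambiguous_dna_by_id[table_id]
    codon_to_aa = {c: table.forward_table.get(c, "*") for c in ALL_CODONS}
    stops = frozenset(table.stop_codons)
    families: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = codon_to_aa[codon]
        if aa != "*":
            families.setdefault(aa, []).append(codon)
    return GeneticCode(
        table_id=table_id,
        codon_to_aa=codon_to_aa,
        stops=stops,
        families={aa: tuple(c) for aa, c in families.items()},
    )


STANDARD_CODE = genetic_code(1)
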