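"""The standard genetic code organised by synonymous-codon family.

Codon usage statistics (RSCU, CAI, ENc) operate on *synonymous families*:
the sets of codons encoding one amino acid. In the standard code, after
removing the three stop codons and the two singleton amino acids
(Met = ATG, Trp = TGG), 59 codons remain, distributed over 18 families
of degeneracy 2, 3, 4 or 6. Ser, Leu and Arg are treated as single
six-fold families rather than split 2+4 blocks, which yields the class
structure 9 two-fold, 1 three-fold (Ile), 5 four-fold and 3 six-fold
families used by Wright's effective-number-of-codons estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

BASES = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


def _standard_codon_map() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = {c.upper(): aa for c, aa in table.forward_table.items()}
    for stop in table.stop_codons:
        mapping[stop.upper()] = "*"
    return mapping


@dataclass(frozen=True)
class GeneticCode:
    """Codon→amino-acid map plus the synonymous-family structure.

    Attributes
    ----------
    codon_to_aa
        All 64 codons, stops mapped to ``"*"``.
    families
        Amino acid → tuple of codons, sense codons only, singleton
        amino acids (Met, Trp) included.
    """

    codon_to_aa: dict[str, str] = field(default_factory=_standard_codon_map)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.codon_to_aa.items() if aa != "*"))

    @property
    def families(self) -> dict[str, tuple[str, ...]]:
        fams: dict[str, list[str]] = {}
        for codon, aa in sorted(self.codon_to_aa.items()):
            if aa != "*":
                fams.setdefault(aa, []).append(codon)
        return {aa: tuple(cods) for aa, cods in fams.items()}

    @property
    def synonymous_families(self) -> dict[str, tuple[str, ...]]:
        """Families of size >= 2 (i.e. excluding Met and Trp)."""
        return {aa: c for aa, c in self.families.items() if len(c) > 1}

    @property
    def synonymous_codons(self) -> tuple[str, ...]:
        """The 59 codons carrying synonymous-usage information, in a fixed
        order: amino acids alphabetically, codons alphabetically within
        each family. This is the canonical column order of RSCU matrices."""
        out: list[str] = []
        for aa in sorted(self.synonymous_families):
            out.extend(self.synonymous_families[aa])
        return tuple(out)

    @property
    def degeneracy_classes(self) -> dict[int, tuple[str, ...]]:
        """Degeneracy (2, 3, 4, 6) → amino acids whose family has that size."""
        classes: dict[int, list[str]] = {}
        for aa, codons in self.synonymous_families.items():
            classes.setdefault(len(codons), []).append(aa)
        return {k: tuple(sorted(v)) for k, v in sorted(classes.items())}

    def family_of(self, codon: str) -> str:
        aa = self.codon_to_aa[codon]
        if aa == "*":
            raise ValueError(f"{codon} is a stop codon and has no family")
        return aa

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]


@lru_cache(maxsize=1)
def standard_code() -> GeneticCode:
    """The standard nuclear genetic code (shared immutable instance)."""
    return GeneticCode()
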