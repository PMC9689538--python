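"""Translation and the two protein-level covariates, GRAVY and aromaticity."""

from __future__ import annotations

from dataclasses import dataclass

from .genetic_code import GeneticCode, STOP_CODONS, standard_code
from .sequence_io import CdsRecord

# Kyte & Doolittle hydropathy values (J Mol Biol 157:105-132, 1982),
# positive = hydrophobic.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AROMATIC_RESIDUES = frozenset("FWY")


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    aa_seq: str


def translate(record: CdsRecord, code: GeneticCode | None = None) -> ProteinRecord:
    """Standard-code translation; start retained as M, terminal stop dropped."""
    code = code or standard_code()
    codons = record.codons
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    residues = []
    for i, codon in enumerate(codons):
        aa = code.translate(codon)
        if aa == "*":
            raise ValueError(f"internal stop codon {codon} at codon {i} in {record.id}")
        residues.append(aa)
    return ProteinRecord(id=record.id, aa_seq="".join(residues))


def gravy(protein: ProteinRecord) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle score per residue."""
    if not protein.aa_seq:
        raise ValueError("empty protein")
    try:
        return sum(KYTE_DOOLITTLE[aa] for aa in protein.aa_seq) / len(protein.aa_seq)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {protein.id}") from exc


def aroma(protein: ProteinRecord) -> float:
    """Aromaticity: fraction of Phe, Trp and Tyr residues."""
    if not protein.aa_seq:
        raise ValueError("empty protein")
    hits = sum(1 for aa in protein.aa_seq if aa in AROMATIC_RESIDUES)
    return hits / len(protein.aa_seq)
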