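"""FASTA input/output and coding-sequence validation.

A usable CDS for codon-usage work must read cleanly codon-by-codon:
it starts with ATG, ends with a stop codon, has length divisible by
three, contains no base outside {A, C, G, T} and no premature in-frame
stop. Records failing any rule are rejected with a machine-readable
report rather than an exception, so a mixed download can be filtered
and audited in one pass.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import START_CODON, STOP_CODONS

VALID_BASES = frozenset("ACGT")

# Validation rule identifiers, in report order.
TOO_SHORT = "TOO_SHORT"
NOT_MULTIPLE_OF_3 = "NOT_MULTIPLE_OF_3"
AMBIGUOUS_BASE = "AMBIGUOUS_BASE"
NO_START = "NO_START"
NO_STOP = "NO_STOP"
INTERNAL_STOP = "INTERNAL_STOP"


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence with its gene label (uppercase, A/C/G/T)."""

    id: str
    gene: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def codons(self) -> list[str]:
        """Frame-0 codons including the terminal stop."""
        return [self.seq[i : i + 3] for i in range(0, len(self.seq) - 2, 3)]


@dataclass(frozen=True)
class ValidationReport:
    id: str
    failures: tuple[str, ...] = field(default_factory=tuple)

    @property
    def accepted(self) -> bool:
        return not self.failures


def validate_cds(seq: str, *, allow_internal_stop: bool = False,
                 record_id: str = "") -> ValidationReport:
    """Check a nucleotide string against the CDS inclusion rules.

    All violated rules are reported together; nothing is raised. The
    internal-stop rule can be relaxed for sequences known to use
    read-through or selenocysteine recoding.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    failures: list[str] = []
    if len(s) < 6:
        failures.append(TOO_SHORT)
    if len(s) % 3 != 0:
        failures.append(NOT_MULTIPLE_OF_3)
    if set(s) - VALID_BASES:
        failures.append(AMBIGUOUS_BASE)
    if s[:3] != START_CODON:
        failures.append(NO_START)
    if s[-3:] not in STOP_CODONS:
        failures.append(NO_STOP)
    if not allow_internal_stop:
        internal = [s[i : i + 3] for i in range(0, len(s) - 5, 3)]
        if any(c in STOP_CODONS for c in internal):
            failures.append(INTERNAL_STOP)
    return ValidationReport(id=record_id, failures=tuple(failures))


def _gene_from_header(record_id: str, description: str) -> str:
    """Default header convention: ``id|gene``; falls back to the id."""
    if "|" in record_id:
        return record_id.split("|", 1)[1]
    return record_id


def read_fasta(path: str | Path, gene_map: dict[str, str] | None = None) -> list[CdsRecord]:
    """Read a (possibly wrapped, possibly lowercase) multi-FASTA of CDS.

    Gene labels come from ``gene_map`` when given, otherwise from the
    ``id|gene`` header convention. Raises on an empty file so that a
    failed download is not mistaken for an empty gene set.
    """
    path = Path(path)
    records: list[CdsRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw_id = rec.id
        if gene_map is not None and raw_id in gene_map:
            ident, gene = raw_id, gene_map[raw_id]
        elif "|" in raw_id:
            ident, gene = raw_id.split("|", 1)[0], _gene_from_header(raw_id, rec.description)
        else:
            ident, gene = raw_id, (gene_map or {}).get(raw_id, raw_id)
        records.append(CdsRecord(id=ident, gene=gene, seq=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[CdsRecord], path: str | Path, width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(r.seq), id=f"{r.id}|{r.gene}", description="") for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def read_gene_map(path: str | Path) -> dict[str, str]:
    """TSV with columns ``id`` and ``gene`` (header optional)."""
    mapping: dict[str, str] = {}
    with open(path, newline="") as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0].lower() == "id" and row[1].lower() == "gene":
                continue
            mapping[row[0]] = row[1]
    return mapping


def filter_transcripts(
    records: list[CdsRecord], *, allow_internal_stop: bool = False
) -> tuple[list[CdsRecord], list[ValidationReport]]:
    """Split records into accepted CDS and per-record validation reports.

    Order is preserved; every input record gets a report, so
    ``len(accepted) + len([r for r in reports if not r.accepted])``
    equals the input size.
    """
    accepted: list[CdsRecord] = []
    reports: list[ValidationReport] = []
    for rec in records:
        report = validate_cds(
            rec.seq, allow_internal_stop=allow_internal_stop, record_id=rec.id
        )
        reports.append(report)
        if report.accepted:
            accepted.append(rec)
    return accepted, reports


def write_validation_reports(reports: list[ValidationReport], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["id", "accepted", "failures"])
        for rep in reports:
            writer.writerow([rep.id, str(rep.accepted).lower(), ";".join(rep.failures)])
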