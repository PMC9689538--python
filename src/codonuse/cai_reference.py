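"""Loading CAI reference codon-usage tables.

The default reference is a bundled human codon-usage table (per-1000
frequencies); CAI weights are scale-invariant within each family, so
frequencies and raw counts are interchangeable. Users supply their own
reference as a two-column CSV, either ``codon,count`` (weights derived
via reference RSCU) or ``codon,weight`` (relative adaptiveness used
directly).
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

from .codon_metrics import CaiWeights, CodonCountTable, cai_weights
from .genetic_code import GeneticCode, standard_code

_BUNDLED = {"human": "human_codon_usage.csv"}


def _read_codon_csv(lines) -> dict[str, float]:
    values: dict[str, float] = {}
    header_seen = False
    for row in csv.reader(lines):
        if not row or row[0].startswith("#"):
            continue
        if not header_seen and not row[1].replace(".", "", 1).lstrip("-").isdigit():
            header_seen = True
            continue
        values[row[0].upper().replace("U", "T")] = float(row[1])
    return values


def load_reference_counts(source: str | Path = "human") -> CodonCountTable:
    """Read a ``codon,count`` (or per-1000 frequency) CSV into a count
    table; the bundled ``"human"`` table is used by name."""
    if isinstance(source, str) and source in _BUNDLED:
        text = (
            resources.files("codonuse.data").joinpath(_BUNDLED[source]).read_text()
        )
        values = _read_codon_csv(text.splitlines())
        name = source
    else:
        with open(source, newline="") as handle:
            values = _read_codon_csv(handle)
        name = str(source)
    # frequencies scale to pseudo-counts; x10 keeps one decimal of precision
    counts = {codon: int(round(v * 10)) for codon, v in values.items()}
    return CodonCountTable(counts=counts, source_ids=(name,))


def load_cai_weights(
    source: str | Path = "human", code: GeneticCode | None = None
) -> CaiWeights:
    """CAI relative-adaptiveness weights from a reference usage table."""
    code = code or standard_code()
    counts = load_reference_counts(source)
    name = counts.source_ids[0] if counts.source_ids else str(source)
    return cai_weights(counts, code, reference_name=name)
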