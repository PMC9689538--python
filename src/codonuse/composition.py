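"""Nucleotide composition of coding sequences, overall and per codon position.

All values are percentages on a 0–100 scale. Position ``p`` of codon
``i`` is base ``3*i + p``; GC12 is defined as the arithmetic mean of the
first- and second-position GC percentages. The terminal stop codon is
excluded by default so that third-position statistics describe only
codons with a synonymous role.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .genetic_code import STOP_CODONS


@dataclass(frozen=True)
class CompositionProfile:
    id: str
    pct_A: float
    pct_C: float
    pct_G: float
    pct_T: float
    pct_A1: float
    pct_C1: float
    pct_G1: float
    pct_T1: float
    pct_A2: float
    pct_C2: float
    pct_G2: float
    pct_T2: float
    pct_A3: float
    pct_C3: float
    pct_G3: float
    pct_T3: float
    pct_GC: float
    pct_AT: float
    pct_GC1: float
    pct_GC2: float
    pct_GC3: float
    pct_AT3: float
    pct_GC12: float
    n_codons: int

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


NUMERIC_FIELDS = [f.name for f in fields(CompositionProfile) if f.name != "id"]


def composition_profile(
    seq: str, *, include_stop: bool = False, record_id: str = ""
) -> CompositionProfile:
    """Per-position base percentages for one in-frame coding sequence."""
    codons = [seq[i : i + 3] for i in range(0, len(seq) - 2, 3)]
    if not include_stop and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if not codons:
        raise ValueError("no codons left after stop-codon exclusion")

    n = len(codons)
    pos_counts = {p: {b: 0 for b in "ACGT"} for p in (0, 1, 2)}
    for codon in codons:
        for p, base in enumerate(codon):
            pos_counts[p][base] += 1

    def pct(p: int, base: str) -> float:
        return 100.0 * pos_counts[p][base] / n

    total = 3 * n
    overall = {b: sum(pos_counts[p][b] for p in (0, 1, 2)) for b in "ACGT"}
    pct_overall = {b: 100.0 * c / total for b, c in overall.items()}

    gc1 = pct(0, "G") + pct(0, "C")
    gc2 = pct(1, "G") + pct(1, "C")
    gc3 = pct(2, "G") + pct(2, "C")
    gc = pct_overall["G"] + pct_overall["C"]

    return CompositionProfile(
        id=record_id,
        pct_A=pct_overall["A"], pct_C=pct_overall["C"],
        pct_G=pct_overall["G"], pct_T=pct_overall["T"],
        pct_A1=pct(0, "A"), pct_C1=pct(0, "C"), pct_G1=pct(0, "G"), pct_T1=pct(0, "T"),
        pct_A2=pct(1, "A"), pct_C2=pct(1, "C"), pct_G2=pct(1, "G"), pct_T2=pct(1, "T"),
        pct_A3=pct(2, "A"), pct_C3=pct(2, "C"), pct_G3=pct(2, "G"), pct_T3=pct(2, "T"),
        pct_GC=gc, pct_AT=100.0 - gc,
        pct_GC1=gc1, pct_GC2=gc2, pct_GC3=gc3,
        pct_AT3=100.0 - gc3,
        pct_GC12=(gc1 + gc2) / 2.0,
        n_codons=n,
    )


def profiles_table(profiles: list[CompositionProfile]) -> pd.DataFrame:
    """One row per transcript, columns = the profile fields."""
    return pd.DataFrame([p.as_dict() for p in profiles]).set_index("id")


def summarize_composition(profiles: list[CompositionProfile]) -> pd.DataFrame:
    """Mean and sample standard deviation (ddof=1) of every statistic.

    With a single profile the standard deviation is reported as 0 and
    the ``n`` column makes the degeneracy visible.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    table = profiles_table(profiles)
    n = len(table)
    means = table.mean(axis=0)
    sds = table.std(axis=0, ddof=1) if n > 1 else pd.Series(0.0, index=table.columns)
    out = pd.DataFrame({"mean": means, "sd": sds})
    out["n"] = n
    out.index.name = "statistic"
    return out


def gc3_fraction(profile: CompositionProfile) -> float:
    """GC3 on the [0, 1] scale used by the expected-ENc curve."""
    return profile.pct_GC3 / 100.0
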