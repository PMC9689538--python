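"""Codon counting and the three classic usage-bias statistics.

RSCU (relative synonymous codon usage) is the observed count of a codon
divided by the count expected if every codon in its synonymous family
were used equally::

    RSCU_c = x_c / ((1 / n_f) * sum(x_c' for c' in family f)),

so each family's RSCU values average to 1 regardless of family size.

CAI (codon adaptation index, Sharp & Li) is the geometric mean over a
gene's codons of relative-adaptiveness weights w_c, where w_c is the
codon's RSCU in a reference set divided by the maximum RSCU in its
family; genes built entirely from reference-preferred codons score 1.

ENc (effective number of codons, Wright) summarises bias as the number
of equally-used codons that would produce the observed family
homozygosities: F = (n * sum(p_i^2) - 1) / (n - 1) per family, averaged
within each degeneracy class, then

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6,

ranging from 20 (one codon per amino acid) to 61 (uniform usage).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .genetic_code import GeneticCode, STOP_CODONS, standard_code
from .sequence_io import CdsRecord

#: Default relative-adaptiveness floor for codons absent from the
#: reference set; avoids -inf logarithms in the CAI geometric mean.
ZERO_WEIGHT_FLOOR = 1e-3

ENC_MIN, ENC_MAX = 20.0, 61.0


@dataclass
class CodonCountTable:
    """64-codon integer counts, possibly pooled over several transcripts."""

    counts: dict[str, int]
    source_ids: tuple[str, ...] = ()

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = dict(self.counts)
        for codon, n in other.counts.items():
            merged[codon] = merged.get(codon, 0) + n
        return CodonCountTable(merged, self.source_ids + other.source_ids)


@dataclass(frozen=True)
class RscuVector:
    """RSCU over the 59 synonymous codons.

    Codons belonging to a family with zero total count are *absent* from
    ``rscu`` and their amino acid is listed in ``missing_families``;
    zero-count codons inside a present family genuinely have RSCU 0.
    """

    rscu: dict[str, float]
    missing_families: frozenset[str] = frozenset()


@dataclass(frozen=True)
class CaiWeights:
    w: dict[str, float]
    reference_name: str = ""
    floored: frozenset[str] = frozenset()


@dataclass(frozen=True)
class EncValue:
    nc: float
    raw_nc: float
    family_homozygosities: dict[int, float] = field(default_factory=dict)
    n_codons_used: int = 0


def count_codons(
    records: CdsRecord | list[CdsRecord], *, include_stop: bool = False
) -> CodonCountTable:
    """Count frame-0 codons, pooling over records; terminal stop excluded."""
    if isinstance(records, CdsRecord):
        records = [records]
    counts: dict[str, int] = {}
    ids: list[str] = []
    for rec in records:
        codons = rec.codons
        if not include_stop and codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        for codon in codons:
            counts[codon] = counts.get(codon, 0) + 1
        ids.append(rec.id)
    return CodonCountTable(counts, tuple(ids))


def rscu(counts: CodonCountTable, code: GeneticCode | None = None) -> RscuVector:
    """Relative synonymous codon usage from a count table."""
    code = code or standard_code()
    values: dict[str, float] = {}
    missing: set[str] = set()
    for aa, codons in code.synonymous_families.items():
        family_total = sum(counts.counts.get(c, 0) for c in codons)
        if family_total == 0:
            missing.add(aa)
            continue
        expected = family_total / len(codons)
        for c in codons:
            values[c] = counts.counts.get(c, 0) / expected
    return RscuVector(rscu=values, missing_families=frozenset(missing))


# Usage-category thresholds: values above 1.6 mark overrepresented codons,
# below 0.6 underrepresented; the closed interval between is "random" use.
RSCU_OVER = 1.6
RSCU_UNDER = 0.6


def classify_rscu(v: RscuVector, code: GeneticCode | None = None) -> dict[str, str]:
    """Label each of the 59 codons overrepresented / underrepresented /
    random / missing. Boundary values fall in the random class."""
    code = code or standard_code()
    out: dict[str, str] = {}
    for codon in code.synonymous_codons:
        if codon not in v.rscu:
            out[codon] = "missing"
        elif v.rscu[codon] > RSCU_OVER:
            out[codon] = "overrepresented"
        elif v.rscu[codon] < RSCU_UNDER:
            out[codon] = "underrepresented"
        else:
            out[codon] = "random"
    return out


def cai_weights(
    reference_counts: CodonCountTable,
    code: GeneticCode | None = None,
    *,
    reference_name: str = "",
    zero_floor: float = ZERO_WEIGHT_FLOOR,
) -> CaiWeights:
    """Relative adaptiveness w_c = RSCU_c / max family RSCU on a reference.

    Every multi-codon family must be represented in the reference;
    codons the reference never uses get the small floor weight instead
    of zero so their logarithm stays finite.
    """
    code = code or standard_code()
    ref = rscu(reference_counts, code)
    if ref.missing_families:
        missing = ", ".join(sorted(ref.missing_families))
        raise ValueError(f"reference set has no codons for amino acid(s): {missing}")
    w: dict[str, float] = {}
    floored: set[str] = set()
    for aa, codons in code.synonymous_families.items():
        fam_max = max(ref.rscu[c] for c in codons)
        for c in codons:
            weight = ref.rscu[c] / fam_max
            if weight == 0.0:
                weight = zero_floor
                floored.add(c)
            w[c] = weight
    if floored:
        warnings.warn(
            f"{len(floored)} codon(s) absent from the CAI reference; "
            f"weight floored at {zero_floor}",
            stacklevel=2,
        )
    return CaiWeights(w=w, reference_name=reference_name, floored=frozenset(floored))


def cai(counts: CodonCountTable, weights: CaiWeights,
        code: GeneticCode | None = None) -> float:
    """Geometric mean of adaptiveness weights over a gene's codons.

    Met, Trp and stop codons carry no choice and are excluded from both
    the sum and the codon count L.
    """
    code = code or standard_code()
    eligible = set(code.synonymous_codons)
    log_sum = 0.0
    length = 0
    for codon, n in counts.counts.items():
        if codon in eligible and n > 0:
            log_sum += n * math.log(weights.w[codon])
            length += n
    if length == 0:
        raise ValueError("no codons eligible for CAI (only Met/Trp/stop present)")
    return math.exp(log_sum / length)


def _family_homozygosity(family_counts: list[int]) -> float | None:
    """Wright's bias-corrected F = (n*sum(p^2) - 1)/(n - 1); None if n < 2."""
    n = sum(family_counts)
    if n < 2:
        return None
    sum_p2 = sum((c / n) ** 2 for c in family_counts)
    return (n * sum_p2 - 1.0) / (n - 1.0)


def enc(counts: CodonCountTable, code: GeneticCode | None = None) -> EncValue:
    """Wright's effective number of codons from a pooled count table.

    Families observed fewer than twice are left out of their class mean.
    When no isoleucine codons are observed (the only three-fold class)
    its mean is estimated as the average of the two- and four-fold class
    means, Wright's fallback for the singleton class. Sampling noise can
    push the estimator slightly outside [20, 61]; the capped value is
    reported with the raw value retained.
    """
    code = code or standard_code()
    class_f: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    used = 0
    for aa, codons in code.synonymous_families.items():
        fam_counts = [counts.counts.get(c, 0) for c in codons]
        f = _family_homozygosity(fam_counts)
        if f is not None:
            class_f[len(codons)].append(f)
            used += sum(fam_counts)
    if not any(class_f.values()):
        raise ValueError("ENc undefined: no synonymous family observed at least twice")

    class_sizes = {k: len(v) for k, v in code.degeneracy_classes.items()}
    means: dict[int, float] = {}
    for k in (2, 4, 6):
        if not class_f[k]:
            raise ValueError(f"ENc undefined: no {k}-fold family with n >= 2")
        means[k] = sum(class_f[k]) / len(class_f[k])
    if class_f[3]:
        means[3] = sum(class_f[3]) / len(class_f[3])
    else:
        means[3] = (means[2] + means[4]) / 2.0

    if any(means[k] <= 0 for k in means):
        # completely unbiased tiny samples can give F = 0; the estimator
        # then diverges and is reported at the no-bias ceiling
        raw = math.inf
    else:
        raw = 2.0 + sum(class_sizes[k] / means[k] for k in (2, 3, 4, 6))
    capped = min(max(raw, ENC_MIN), ENC_MAX)
    return EncValue(nc=capped, raw_nc=raw, family_homozygosities=means,
                    n_codons_used=used)
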