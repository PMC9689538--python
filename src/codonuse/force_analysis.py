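"""Mutation-versus-selection diagnostics for codon usage.

Three standard graphical analyses are computed as tables:

* **PR2 parity plot** — within a strand at mutational equilibrium,
  A should equal T and G equal C (parity rule 2). Plotting
  A3/(A3+T3) against G3/(G3+C3) per transcript places unbiased genes
  at (0.5, 0.5); systematic displacement indicates strand-asymmetric
  mutation or selection at the wobble position.

* **ENc–GC3 plot** — under pure compositional mutation pressure the
  effective number of codons is a deterministic function of GC3,
  Nc_exp(s) = 2 + s + 29/(s^2 + (1-s)^2). Genes falling well below
  the curve use fewer codons than composition alone explains,
  implicating selection.

* **Neutrality plot** — ordinary least squares of GC12 on GC3. A slope
  of 1 means first/second positions track third-position composition
  (mutation alone); the shortfall 1 - slope is read as the share of
  selective constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .composition import CompositionProfile


@dataclass(frozen=True)
class Pr2Point:
    id: str
    gc_bias: float | None   # G3 / (G3 + C3), None when G3 + C3 == 0
    at_bias: float | None   # A3 / (A3 + T3), None when A3 + T3 == 0


@dataclass(frozen=True)
class NeutralityFit:
    slope: float
    intercept: float
    r: float
    r2: float
    p_value: float
    n: int

    @property
    def mutation_share(self) -> float:
        return self.slope

    @property
    def selection_share(self) -> float:
        return 1.0 - self.slope


def pr2_point(profile: CompositionProfile) -> Pr2Point:
    gc_den = profile.pct_G3 + profile.pct_C3
    at_den = profile.pct_A3 + profile.pct_T3
    return Pr2Point(
        id=profile.id,
        gc_bias=profile.pct_G3 / gc_den if gc_den > 0 else None,
        at_bias=profile.pct_A3 / at_den if at_den > 0 else None,
    )


def pr2_table(profiles: list[CompositionProfile]) -> pd.DataFrame:
    rows = [pr2_point(p) for p in profiles]
    return pd.DataFrame(
        {
            "id": [r.id for r in rows],
            "gc_bias": [np.nan if r.gc_bias is None else r.gc_bias for r in rows],
            "at_bias": [np.nan if r.at_bias is None else r.at_bias for r in rows],
        }
    ).set_index("id")


def _fourfold_blocks(code) -> list[str]:
    """Codons in fully degenerate four-codon blocks (NNx sharing the
    first two bases and one amino acid): the classical PR2 site set."""
    by_prefix: dict[str, list[str]] = {}
    for codon, aa in code.codon_to_aa.items():
        if aa != "*":
            by_prefix.setdefault(codon[:2], []).append(codon)
    out = []
    for prefix, codons in by_prefix.items():
        if len(codons) == 4 and len({code.codon_to_aa[c] for c in codons}) == 1:
            out.extend(codons)
    return sorted(out)


def pr2_point_from_counts(counts, code, *, fourfold_only: bool = False,
                          record_id: str = "") -> Pr2Point:
    """PR2 coordinates from a codon count table; with ``fourfold_only``
    third positions are tallied over four-fold degenerate blocks only,
    where parity violations are not confounded by amino-acid choice."""
    keep = set(_fourfold_blocks(code)) if fourfold_only else {
        c for c, aa in code.codon_to_aa.items() if aa != "*"
    }
    base_counts = {b: 0 for b in "ACGT"}
    for codon, n in counts.counts.items():
        if codon in keep:
            base_counts[codon[2]] += n
    gc_den = base_counts["G"] + base_counts["C"]
    at_den = base_counts["A"] + base_counts["T"]
    return Pr2Point(
        id=record_id,
        gc_bias=base_counts["G"] / gc_den if gc_den > 0 else None,
        at_bias=base_counts["A"] / at_den if at_den > 0 else None,
    )


def enc_expected(gc3_fraction: float) -> float:
    """Expected ENc under mutation pressure alone at third-position
    GC fraction ``s``: 2 + s + 29/(s^2 + (1-s)^2)."""
    s = float(gc3_fraction)
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3 fraction must be in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))


def enc_gc3_table(
    ids: list[str], gc3_fractions: list[float], nc_observed: list[float]
) -> pd.DataFrame:
    """Per-transcript observed vs expected ENc and the departure below
    the mutation-only curve (positive = more biased than composition
    alone explains)."""
    expected = [enc_expected(s) for s in gc3_fractions]
    return pd.DataFrame(
        {
            "id": ids,
            "gc3_fraction": gc3_fractions,
            "nc_observed": nc_observed,
            "nc_expected": expected,
            "departure": [e - o for e, o in zip(expected, nc_observed)],
        }
    ).set_index("id")


def neutrality_fit(points: list[tuple[float, float]]) -> NeutralityFit:
    """OLS of GC12 (%) on GC3 (%) with Pearson r and its two-sided p."""
    if len(points) < 3:
        raise ValueError("neutrality regression needs at least 3 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("GC3 has zero variance; regression undefined")
    res = stats.linregress(x, y)
    return NeutralityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r2=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n=len(x),
    )


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return "NS"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def correlation_matrix(
    table: pd.DataFrame, variables: list[str] | None = None
) -> pd.DataFrame:
    """All pairwise Pearson correlations with two-sided p-values.

    Returns a tidy frame (var1, var2, r, p, stars, n). Constant columns
    yield undefined correlations, reported as NaN with stars "NS" and
    ``flag`` set.
    """
    variables = variables or list(table.columns)
    if len(table) < 3:
        raise ValueError("correlation needs at least 3 rows")
    rows = []
    for i, v1 in enumerate(variables):
        for v2 in variables[i + 1 :]:
            sub = table[[v1, v2]].dropna()
            x, y = sub[v1].to_numpy(float), sub[v2].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r, p, flag = np.nan, np.nan, "constant_column"
            else:
                r, p = stats.pearsonr(x, y)
                flag = ""
            rows.append(
                {"var1": v1, "var2": v2, "r": r, "p": p,
                 "stars": significance_stars(p), "n": len(sub), "flag": flag}
            )
    return pd.DataFrame(rows)


def correlation_square(tidy: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Square layout with Pearson r below the diagonal and significance
    stars above it (the conventional published presentation)."""
    out = pd.DataFrame("", index=variables, columns=variables, dtype=object)
    for _, row in tidy.iterrows():
        v1, v2 = row["var1"], row["var2"]
        i1, i2 = variables.index(v1), variables.index(v2)
        first, second = (v1, v2) if i1 < i2 else (v2, v1)
        out.loc[second, first] = "" if np.isnan(row["r"]) else f"{row['r']:.3f}"
        out.loc[first, second] = row["stars"]
    return out
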