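"""Synthetic coding-sequence generator with controllable codon bias.

Every downstream statistic in this package (composition, RSCU, CAI,
ENc, PR2, neutrality regression, PCA, clustering) needs input whose
true parameters are known. This module generates valid CDS sets with:

* a per-gene **GC3 preference**: within each synonymous family the
  probability of choosing a G/C-ending codon is interpolated between
  the uniform-usage value and the target, ``q = q0 + (1 - exp(-b)) *
  (t - q0)`` with ``b`` the bias strength — so ``b = 0`` reproduces
  exactly uniform synonymous usage and large ``b`` drives realized GC3
  to the target ``t`` rather than to saturation;
* a **GC12–GC3 coupling** (the neutrality slope): per-transcript
  target GC12 is a linear function of the GC3 target plus Gaussian
  noise, achieved by exponentially tilting the amino-acid composition
  toward residues whose codons are GC-rich at positions 1–2;
* **planted cluster structure**: groups of genes that share a
  per-family preferred codon, separated in RSCU space by a controlled
  effect size.

Amino acids default to uniform weight over the 18 multi-codon amino
acids with Met and Trp at low weight, keeping synonymous families
well-populated at moderate transcript lengths. All randomness flows
from one integer seed through `numpy.random.SeedSequence` spawning
(one child stream per gene), so per-gene output is reproducible in
isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genetic_code import GeneticCode, standard_code
from .sequence_io import CdsRecord

STOPS = ("TAA", "TAG", "TGA")

#: Relative sampling weight of each amino acid. Multi-codon amino acids
#: are uniform; the two singleton amino acids appear at low weight so
#: they neither dominate composition nor vanish entirely.
SINGLETON_AA_WEIGHT = 0.2

#: GC3 range sampled by the neutrality-set generator, matching the
#: spread typical of mammalian gene sets.
NEUTRALITY_GC3_RANGE = (0.35, 0.80)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for one CDS set.

    ``gc3_target`` and ``bias_strength`` may be scalars (shared by all
    genes) or per-gene sequences. When ``gc3_target`` is None the genes
    are spread evenly across 0.42–0.77, the GC3 range observed in
    mammalian disease-gene sets, so a default run exercises both
    AT-ending and GC-ending preferences.
    """

    n_genes: int = 5
    transcripts_per_gene: int = 6
    codons_per_transcript: int = 500
    gc3_target: float | Sequence[float] | None = None
    bias_strength: float | Sequence[float] = 2.0
    neutrality_slope: float | None = None
    gc12_intercept: float = 0.38
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.codons_per_transcript < 10:
            raise ValueError("codons_per_transcript must be >= 10")
        for t in self.gene_gc3_targets():
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"gc3_target {t} outside [0, 1]")
        for b in self.gene_bias_strengths():
            if b < 0:
                raise ValueError("bias_strength must be >= 0")

    def gene_gc3_targets(self) -> list[float]:
        if self.gc3_target is None:
            if self.n_genes == 1:
                return [0.595]
            return list(np.linspace(0.42, 0.77, self.n_genes))
        if np.isscalar(self.gc3_target):
            return [float(self.gc3_target)] * self.n_genes
        return [float(t) for t in self.gc3_target]

    def gene_bias_strengths(self) -> list[float]:
        if np.isscalar(self.bias_strength):
            return [float(self.bias_strength)] * self.n_genes
        return [float(b) for b in self.bias_strength]


def _aa_weights(code: GeneticCode) -> dict[str, float]:
    weights = {aa: 1.0 for aa in code.synonymous_families}
    for aa, codons in code.families.items():
        if len(codons) == 1:
            weights[aa] = SINGLETON_AA_WEIGHT
    return weights


def _family_codon_probs(
    code: GeneticCode, gc3_target: float, bias_strength: float
) -> dict[str, tuple[list[str], np.ndarray]]:
    """Per-family codon distributions implementing the GC3 preference."""
    shrink = 1.0 - np.exp(-bias_strength)
    out: dict[str, tuple[list[str], np.ndarray]] = {}
    for aa, codons in code.families.items():
        codons = list(codons)
        if len(codons) == 1:
            out[aa] = (codons, np.array([1.0]))
            continue
        is_gc = np.array([c[2] in "GC" for c in codons])
        q0 = is_gc.mean()
        q = q0 + shrink * (gc3_target - q0)
        q = float(np.clip(q, 0.0, 1.0))
        probs = np.where(is_gc, q / max(is_gc.sum(), 1),
                         (1.0 - q) / max((~is_gc).sum(), 1))
        out[aa] = (codons, probs / probs.sum())
    return out


def _aa_gc12(codon_probs: dict[str, tuple[list[str], np.ndarray]]) -> dict[str, float]:
    """Expected GC fraction at codon positions 1–2 for each amino acid,
    under the current within-family codon distribution."""
    out = {}
    for aa, (codons, probs) in codon_probs.items():
        gc12 = [sum(b in "GC" for b in c[:2]) / 2.0 for c in codons]
        out[aa] = float(np.dot(probs, gc12))
    return out


def _tilt_aa_weights(
    base_weights: dict[str, float],
    aa_gc12: dict[str, float],
    target_gc12: float,
) -> dict[str, float]:
    """Exponential tilt of amino-acid weights so the expected GC12
    matches the target; bisection on the tilt parameter, clamped to the
    feasible range of the composition."""
    aas = list(base_weights)
    w = np.array([base_weights[a] for a in aas])
    g = np.array([aa_gc12[a] for a in aas])

    def expected(gamma: float) -> float:
        tw = w * np.exp(gamma * g)
        return float(np.dot(tw, g) / tw.sum())

    lo, hi = -30.0, 30.0
    target = float(np.clip(target_gc12, expected(lo) + 1e-6, expected(hi) - 1e-6))
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if expected(mid) < target:
            lo = mid
        else:
            hi = mid
    gamma = (lo + hi) / 2.0
    tw = w * np.exp(gamma * g)
    return dict(zip(aas, tw / tw.sum()))


def _sample_transcript(
    rng: np.random.Generator,
    n_codons: int,
    aa_weights: dict[str, float],
    codon_probs: dict[str, tuple[list[str], np.ndarray]],
) -> str:
    aas = list(aa_weights)
    p = np.array([aa_weights[a] for a in aas], dtype=float)
    p /= p.sum()
    aa_idx = rng.choice(len(aas), size=n_codons, p=p)
    codons = np.empty(n_codons, dtype=object)
    for i, aa in enumerate(aas):
        pos = np.flatnonzero(aa_idx == i)
        if pos.size == 0:
            continue
        fam_codons, fam_p = codon_probs[aa]
        picks = rng.choice(len(fam_codons), size=pos.size, p=fam_p)
        for j, k in zip(pos, picks):
            codons[j] = fam_codons[k]
    stop = STOPS[rng.integers(0, 3)]
    return "ATG" + "".join(codons) + stop


def sample_cds(spec: SyntheticSpec, code: GeneticCode | None = None) -> list[CdsRecord]:
    """Generate a multi-gene CDS set under the spec's per-gene targets.

    Every record passes CDS validation by construction. With
    ``neutrality_slope`` set, each gene's amino-acid composition is
    tilted so its GC12 tracks ``slope * GC3 + intercept`` (fractions),
    plus per-transcript Gaussian noise of ``noise_sd``.
    """
    code = code or standard_code()
    targets = spec.gene_gc3_targets()
    biases = spec.gene_bias_strengths()
    if len(targets) != spec.n_genes or len(biases) != spec.n_genes:
        raise ValueError("per-gene parameter lists must have length n_genes")
    for t, b in zip(targets, biases):
        if b == 0 and abs(t - 0.5) > 0.2:
            warnings.warn(
                f"gc3_target={t} is unreachable with bias_strength=0; "
                "generating uniform synonymous usage",
                stacklevel=2,
            )
    base_weights = _aa_weights(code)
    gene_streams = np.random.SeedSequence(spec.seed).spawn(spec.n_genes)
    records: list[CdsRecord] = []
    for g, (t, b, stream) in enumerate(zip(targets, biases, gene_streams)):
        rng = np.random.default_rng(stream)
        gene = f"gene{g + 1:02d}"
        codon_probs = _family_codon_probs(code, t, b)
        for k in range(spec.transcripts_per_gene):
            weights = base_weights
            if spec.neutrality_slope is not None:
                target_gc12 = (
                    spec.neutrality_slope * t
                    + spec.gc12_intercept
                    + rng.normal(0.0, spec.noise_sd)
                )
                weights = _tilt_aa_weights(
                    base_weights, _aa_gc12(codon_probs), target_gc12
                )
            seq = _sample_transcript(rng, spec.codons_per_transcript, weights, codon_probs)
            records.append(CdsRecord(id=f"{gene}_t{k + 1}", gene=gene, seq=seq))
    return records


def truth_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Planted per-gene parameters, for test harnesses and output bundles."""
    return pd.DataFrame(
        {
            "gene": [f"gene{g + 1:02d}" for g in range(spec.n_genes)],
            "gc3_target": spec.gene_gc3_targets(),
            "bias_strength": spec.gene_bias_strengths(),
            "transcripts": spec.transcripts_per_gene,
            "codons_per_transcript": spec.codons_per_transcript,
        }
    )


def sample_neutrality_set(
    n: int,
    slope: float,
    intercept: float,
    noise_sd: float,
    seed: int,
    *,
    codons_per_transcript: int = 300,
    gc3_range: tuple[float, float] = NEUTRALITY_GC3_RANGE,
    code: GeneticCode | None = None,
) -> tuple[list[CdsRecord], pd.DataFrame]:
    """Transcripts whose GC12 is a noisy linear function of GC3.

    Per transcript, a GC3 target is drawn uniformly on ``gc3_range``
    and the GC12 target set to ``slope * gc3 + intercept + N(0,
    noise_sd)`` (all fractions); a strong within-family bias pins
    realized GC3 near its target, and amino-acid tilting pins GC12.
    Returns the records and the per-transcript planted targets.
    """
    if not 0.0 <= slope <= 1.0:
        raise ValueError("slope must be in [0, 1]")
    code = code or standard_code()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    base_weights = _aa_weights(code)
    records, rows = [], []
    for i in range(n):
        gc3 = rng.uniform(*gc3_range)
        target_gc12 = slope * gc3 + intercept + rng.normal(0.0, noise_sd)
        codon_probs = _family_codon_probs(code, gc3, bias_strength=6.0)
        weights = _tilt_aa_weights(base_weights, _aa_gc12(codon_probs), target_gc12)
        seq = _sample_transcript(rng, codons_per_transcript, weights, codon_probs)
        ident = f"nt{i + 1:03d}"
        records.append(CdsRecord(id=ident, gene=ident, seq=seq))
        rows.append({"id": ident, "gc3_target": gc3, "gc12_target": target_gc12})
    return records, pd.DataFrame(rows)


def sample_clustered_genes(
    k: int,
    separation: float,
    spec: SyntheticSpec,
    code: GeneticCode | None = None,
) -> tuple[list[CdsRecord], pd.DataFrame]:
    """CDS set with ``k`` planted gene groups in RSCU space.

    Each group draws one preferred codon per synonymous family; within
    a family the preferred codon carries weight ``exp(separation)``
    against 1 for the rest, so ``separation = 0`` yields no structure
    and large values give well-separated RSCU centroids. Genes are
    assigned to groups round-robin; transcripts within a gene share the
    group profile plus multinomial sampling noise.
    """
    if k < 2:
        raise ValueError("need at least 2 groups")
    code = code or standard_code()
    base_weights = _aa_weights(code)
    ss = np.random.SeedSequence(spec.seed)
    profile_rng = np.random.default_rng(ss.spawn(1)[0])
    group_probs: list[dict[str, tuple[list[str], np.ndarray]]] = []
    for _ in range(k):
        probs: dict[str, tuple[list[str], np.ndarray]] = {}
        for aa, codons in code.families.items():
            codons = list(codons)
            w = np.ones(len(codons))
            if len(codons) > 1:
                w[profile_rng.integers(0, len(codons))] = np.exp(separation)
            probs[aa] = (codons, w / w.sum())
        group_probs.append(probs)

    gene_streams = ss.spawn(spec.n_genes + 1)[1:]
    records, rows = [], []
    for g, stream in enumerate(gene_streams):
        rng = np.random.default_rng(stream)
        gene = f"gene{g + 1:02d}"
        group = g % k
        for t in range(spec.transcripts_per_gene):
            seq = _sample_transcript(
                rng, spec.codons_per_transcript, base_weights, group_probs[group]
            )
            records.append(CdsRecord(id=f"{gene}_t{t + 1}", gene=gene, seq=seq))
        rows.append({"gene": gene, "group": group})
    return records, pd.DataFrame(rows)
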