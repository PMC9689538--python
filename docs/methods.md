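# Methods

`codonuse` analyses synonymous codon usage in sets of protein-coding
transcripts and attributes the observed bias to mutational pressure,
selection and compositional constraint. This note records the models
implemented, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Input model and validation

A usable coding sequence (CDS) reads cleanly codon-by-codon: length a
multiple of three and at least six, ATG start, terminal stop in
{TAA, TAG, TGA}, alphabet {A, C, G, T}, and no internal in-frame stop.
The internal-stop rule is stricter than the minimal start/stop/alphabet
criteria; a transcript with a premature stop is not a protein-coding
sequence in the ordinary sense, so it is rejected by default and
`--allow-internal-stop` relaxes the rule for recoded genes. All rule
violations are reported together per record (a TSV audit trail), never
raised, so a mixed download can be filtered in one pass. Gene labels
come from an `id|gene` header convention or an explicit id→gene TSV.

## Composition

Percentages are on a 0–100 scale. Position *p* of codon *i* is base
3*i* + *p*; GC12 is the arithmetic mean of the GC percentages at
positions 1 and 2. The terminal stop codon is excluded from all codon
statistics by default — stop codons have no synonymous family, and
including them distorts third-position composition; `--include-stop`
reverses this for composition only. Summaries report the mean and the
sample standard deviation (n−1 denominator); with a single transcript
the sd is reported as 0 and n = 1 makes the degeneracy visible.

## RSCU

For codon *c* in a family of size *k* with counts *x*,
RSCU_c = x_c / ((1/k) Σ x), so every family sums to *k* and averages
to 1. Ser, Leu and Arg are single six-fold families (not 2+4 splits),
giving the class structure 9×2-fold, 1×3-fold (Ile), 5×4-fold and
3×6-fold over 59 codons (stops, Met, Trp excluded). Codons with zero
count inside an observed family have RSCU 0 — the observation is
genuinely zero; families never observed are recorded as *missing* and
left unset in per-gene reports. Only when assembling the 59-column
matrix for ordination are missing families imputed at the neutral
value 1.0, the fixed point of uniform usage, with a per-cell flag
retained. Classification uses the conventional thresholds: above 1.6
overrepresented, below 0.6 underrepresented, the closed interval
[0.6, 1.6] random.

Per-gene RSCU tables can pool codon counts across a gene's transcripts
(default, weighting transcripts by length) or average per-transcript
RSCU values (`--gene-aggregation mean`, weighting transcripts
equally). Both are exposed because published gene-level tables rarely
state which was used.

## CAI

Sharp–Li codon adaptation index: relative adaptiveness
w_c = RSCU_c / max-RSCU-in-family on a reference set, and
CAI = exp((1/L) Σ n_c ln w_c) over a gene's codons, excluding Met, Trp
and stops (they offer no choice). A gene built entirely from
reference-preferred codons scores exactly 1. Codons absent from the
reference receive a floor weight of 10⁻³ (flagged, with a warning)
rather than 0, avoiding −∞ logarithms — the conventional small-value
practice. The bundled default reference is the Kazusa human
codon-usage table (per-1000 frequencies scaled to pseudo-counts;
within-family ratios are scale-invariant, so frequencies and counts
are interchangeable). Any `codon,count` CSV replaces it; the test
suite constructs all its references explicitly so no result depends on
the bundled table.

## ENc

Wright's effective number of codons. Per family with total n ≥ 2 and
within-family frequencies p_i, the bias-corrected homozygosity is
F = (n Σ p_i² − 1)/(n − 1); class means F̄_k over the families of each
degeneracy give Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆. Families
observed fewer than twice are dropped from their class mean. The
three-fold class contains only Ile; when absent, its mean is estimated
as (F̄₂ + F̄₄)/2, Wright's fallback for the singleton class. An absent
two-, four- or six-fold class aborts with an error — no published
fallback exists and real CDS do not produce that case.

Finite-sample behaviour: under exactly uniform counts, F in a k-fold
family is (n/k − 1)/(n − 1), slightly *below* 1/k, so the raw
estimator lands slightly above 61 and only reaches 1/k as n → ∞.
Values are therefore capped to the theoretical range [20, 61] (raw
value retained in the record), which makes the uniform-usage ceiling
exactly 61 at any depth. Perfectly unbiased tiny samples can give
F = 0 (e.g. counts (1, 1)); the estimator then diverges and is
reported at the ceiling. The maximal-bias floor (one codon per family)
gives F = 1 and Nc = 20 exactly.

## Force diagnostics

**PR2 parity.** Coordinates A3/(A3+T3) against G3/(G3+C3), no-bias
center (0.5, 0.5). By default third positions are tallied over all
codons (stop excluded); `--pr2-fourfold-only` restricts to the eight
fully degenerate four-codon blocks (CTN, GTN, TCN, CCN, ACN, GCN, CGN,
GGN), where parity violations are not confounded by amino-acid
composition. Zero denominators are flagged undefined and excluded
from means.

**ENc–GC3.** Expected ENc under mutation pressure alone,
Nc_exp(s) = 2 + s + 29/(s² + (1−s)²) with s the GC3 fraction; the
per-transcript departure Nc_exp − Nc_obs (positive = more biased than
composition explains) is emitted alongside the curve coordinates.

**Neutrality plot.** Ordinary least squares of %GC12 on %GC3 with
Pearson r and its two-sided p. The slope is reported as the mutation
share and 1 − slope as the selection share; r² (variance explained) is
a distinct quantity from the slope split and both are emitted without
conflation. At least 3 points and nonzero GC3 variance are required.

**Correlations.** All pairwise Pearson r with two-sided p
(t = r√((n−2)/(1−r²))) and the star convention *** p<0.001,
** p<0.01, * p<0.05, NS otherwise; no multiple-testing correction is
applied, matching standard practice in this literature. Constant
columns yield undefined r, reported NS with an explicit flag. Output
is both tidy (long) and the square layout with r below and stars above
the diagonal.

## Ordination and clustering

PCA operates on the column-centred 59-column RSCU matrix without
scaling (covariance PCA): RSCU values share a common scale by
construction, so unit-variance scaling would only inflate
low-information codons; `--pca-scale` switches to correlation PCA.
Components are ordered by variance with a deterministic sign
convention (largest-magnitude loading positive). Variance fractions
are reported over all components and sum to 1. The biplot table ranks
all 59 codons by the Euclidean norm of their PC1/PC2 loadings — the
arrow length of a conventional biplot.

Clustering is Ward linkage in the D2 convention (squared-Euclidean
objective on Euclidean input — the scipy/R `ward.D2` behaviour; some
desktop packages implement `ward.D`, which differs). Leaves are
ordered lexicographically by id before linkage so results are
independent of input order and ties break deterministically. Node
confidence is assessed by resampling the 59 codon *columns* with
replacement — the codon-usage analogue of the phylogenetic bootstrap
over sites; resampling transcripts instead would test sampling of
taxa, a different hypothesis. A node's support is the fraction of
replicates whose tree contains the same unordered leaf bipartition
(compared canonically via the side containing the smallest leaf id;
node heights are not compared). Trees serialise to Newick with branch
lengths from merge-height differences and supports as internal node
labels, plus a JSON merge-history dump.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume:
per-gene third-position preference, a linear GC12–GC3 coupling, and
group-structured codon preferences.

*GC3 preference.* Within each family the probability of choosing a
G/C-ending codon is q = q₀ + (1 − e^(−b))(t − q₀), where q₀ is the
uniform-usage value, t the GC3 target and b ≥ 0 the bias strength;
codons are uniform within the chosen (GC/AT-ending) group. b = 0
reproduces exactly uniform synonymous usage; as b grows, realized GC3
converges to the *target*, not to saturation — a pure softmax in b
would drive GC3 to 0 or 1 and could never represent a gene with a
moderate preference. Amino acids default to uniform weight over the
18 multi-codon amino acids with Met/Trp at weight 0.2, keeping family
sizes balanced for RSCU stability.

*Neutrality sets.* Per transcript, a GC3 target is drawn uniformly on
0.35–0.80 (the spread typical of mammalian gene sets) and the GC12
target set to slope·GC3 + intercept + N(0, σ); the amino-acid
distribution is exponentially tilted (bisection on the tilt parameter)
so its expected position-1/2 GC matches the target within feasibility
limits. Realized values carry multinomial sampling jitter of order
√(p(1−p)/L) — at the default 300 codons roughly 2 GC12 percentage
points — plus GC3 measurement noise that attenuates fitted slopes by
a few percent (classical errors-in-x); recovery tolerances in the
tests account for both.

*Planted clusters.* Each of k groups draws one preferred codon per
family with log-odds `separation` against the rest; genes are assigned
to groups round-robin and transcripts add only multinomial noise.
Separation 0 yields no structure.

All randomness derives from one seed via `SeedSequence` spawning (one
child stream per gene), so any gene's output is reproducible in
isolation. Every generated record passes CDS validation by
construction. The generator does **not** imitate real human genes'
amino-acid composition, codon context, CpG depletion, isoform exon
sharing or length distributions — passing recovery tests shows the
estimators are correct under the stated model, not that any particular
real gene set will show a given bias pattern.

## Study-scale defaults

The default simulation design is 5 genes × 6 transcripts of 500 codons
(30 transcripts), the scale of a small disease-gene panel; GC3 targets
spread over 0.42–0.77. Neutrality-recovery tests use n = 30
transcripts of 300 codons with planted slope 0.15 and GC12 noise
σ = 0.0367 — the noise level at which the planted linear signal
explains roughly a fifth of the GC12 variance, a weak-coupling regime —
and check the median fitted slope over 200 seeds. Cluster-recovery
tests use 6 genes × 5 transcripts of 400 codons with separation 2.0
and 100 bootstrap replicates. A full simulate→analyze run at the
default design, including 1000 bootstrap replicates, takes a few
seconds on one CPU.

## Known limitations

- CAI depends entirely on the reference; the bundled human table is a
  genome-wide average and is not tissue-specific.
- ENc uses class means of family homozygosities; genes shorter than a
  few hundred codons give noisy F estimates, and the [20, 61] cap
  hides (but records) out-of-range noise.
- The neutrality regression is a single pooled OLS; no per-gene or
  errors-in-variables variant is provided.
- Bootstrap supports quantify stability under codon resampling only;
  they are not posterior probabilities.
- Dinucleotide (CpG) depletion is visible only through the RSCU of
  CG-containing codons; no odds-ratio statistic is computed.
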