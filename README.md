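# codonuse

Codon usage bias analysis for sets of protein-coding transcripts.

Synonymous codons are not used equally: within a gene, the choice among
the codons of each amino acid reflects the joint action of
compositional constraint, directional mutation pressure and natural
selection. `codonuse` takes a multi-FASTA of coding sequences (CDS),
validates them, and computes the standard toolbox for dissecting that
bias:

- **Composition** — base percentages overall and at each codon
  position (%A…%G, %A3…%G3, %GC, %GC1–3, %GC12), with mean ± sd
  summaries.
- **RSCU** — relative synonymous codon usage,
  RSCU_c = x_c / ((1/k)Σx over the family), per transcript and per
  gene, with over-/under-representation calls (>1.6 / <0.6).
- **CAI** — Sharp–Li codon adaptation index,
  CAI = exp((1/L)Σ n_c ln w_c) with w_c the relative adaptiveness
  against a configurable reference (bundled human table by default).
- **ENc** — Wright's effective number of codons,
  Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ from family homozygosities
  F = (nΣp² − 1)/(n − 1); 20 = maximal bias, 61 = no bias.
- **Force diagnostics** — PR2 parity coordinates A3/(A3+T3) vs
  G3/(G3+C3); the ENc–GC3 plot against the mutation-only curve
  Nc = 2 + s + 29/(s² + (1−s)²); the neutrality regression of %GC12 on
  %GC3 whose slope splits mutational (slope) from selective
  (1 − slope) influence; Pearson correlation matrices with
  significance stars.
- **Multivariate structure** — PCA of the 59-dimensional RSCU vectors
  (scores, loadings, variance fractions, ranked biplot arrows) and
  Ward (D2) hierarchical clustering with codon-column bootstrap
  supports, exported as Newick.
- **Synthetic data** — a generator of valid CDS with controllable GC3
  preference, bias strength, GC12–GC3 coupling and planted cluster
  structure, so every estimator can be verified against known truth
  without downloading anything.

See `docs/methods.md` for the models, defaults and numerical
conventions.

## Worked example

Simulate the default study design — 5 genes × 6 transcripts of 500
codons, GC3 targets spread over 0.42–0.77 — then analyse it:

```bash
codonuse simulate --mode basic --seed 7 --out demo/sim
codonuse analyze --input demo/sim/synthetic.fasta --n-boot 1000 --seed 7 \
    --out demo/run
```

`demo/run/metrics.csv` then starts:

```
id         gene    CAI     ENc  pct_GC3  GRAVY  AROMA
gene01_t1  gene01  0.718  57.449   45.709 -0.472  0.106
gene01_t2  gene01  0.687  58.267   44.112 -0.585  0.088
gene01_t3  gene01  0.686  60.100   45.110 -0.346  0.120
```

Across the 30 transcripts this run gives mean ENc 56.72 ± 3.89 —
weak bias, as expected at moderate bias strength — and mean CAI 0.736
against the bundled human reference. `neutrality.json` reports slope
0.020 (r² = 0.015, p = 0.51): the basic mode plants no GC12–GC3
coupling, so the regression correctly finds essentially none, and the
slope split attributes the usage pattern to selection/constraint
rather than directional mutation. `variance.csv` shows PC1 carrying
34.4% and PC2 8.0% of the RSCU variance, and `biplot.csv` ranks the
codons driving that separation (here CGC, CGG, CGA — arginine codons
whose usage differs most across the GC3 gradient). `tree.nwk` holds
the Ward dendrogram with bootstrap supports as internal labels:

```
(((gene01_t1:3.35,gene01_t3:3.35)0.589:1.65,((gene01_t4:3.76,...
```

Transcripts of the same gene cluster together; supports quantify how
stable each grouping is under codon resampling.

The same `analyze` command runs on any real CDS FASTA (headers
`id|gene`, or supply `--gene-map ids.tsv`).

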