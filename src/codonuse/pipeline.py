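"""End-to-end analysis and simulation runs.

`run_analyze` executes the full chain on a FASTA of coding
transcripts — validation, composition, RSCU/CAI/ENc, protein
properties, PR2/ENc–GC3/neutrality force diagnostics, correlation
matrices, PCA and Ward clustering with bootstrap supports — and writes
every result as a plot-ready CSV/JSON/Newick bundle plus a run log
sufficient to reproduce the run. `run_simulate` exposes the synthetic
generator in the same FASTA + truth-table formats so simulated output
feeds straight back into `run_analyze`.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cai_reference import load_cai_weights
from .codon_metrics import CodonCountTable, cai, count_codons, enc, rscu
from .composition import (
    composition_profile,
    gc3_fraction,
    profiles_table,
    summarize_composition,
)
from .force_analysis import (
    correlation_matrix,
    correlation_square,
    enc_gc3_table,
    neutrality_fit,
    pr2_point_from_counts,
    pr2_table,
)
from .genetic_code import standard_code
from .multivariate import (
    biplot_table,
    bootstrap_supports,
    build_rscu_matrix,
    pca,
    to_newick,
    tree_to_json,
    ward_cluster,
)
from .protein_properties import aroma, gravy, translate
from .sequence_io import (
    CdsRecord,
    filter_transcripts,
    read_fasta,
    read_gene_map,
    write_fasta,
    write_validation_reports,
)
from .synthetic_data import (
    SyntheticSpec,
    sample_cds,
    sample_clustered_genes,
    sample_neutrality_set,
    truth_table,
)

#: Variables of the metric-level correlation matrix.
METRIC_CORR_VARS = ["CAI", "ENc", "pct_GC", "pct_GC1", "pct_GC2", "pct_GC3"]

#: Variables correlated against PC1/PC2.
PC_CORR_VARS = [
    "pct_GC3", "CAI", "GRAVY", "AROMA",
    "pct_A", "pct_C", "pct_T", "pct_G",
    "pct_A3", "pct_C3", "pct_T3", "pct_G3",
    "pct_GC", "pct_AT", "pct_AT3",
]


@dataclass
class RunConfig:
    input: str | Path
    out_dir: str | Path
    gene_map: str | Path | None = None
    cai_reference: str | Path = "human"
    gene_aggregation: str = "pooled"  # or "mean"
    pr2_fourfold_only: bool = False
    include_stop: bool = False
    allow_internal_stop: bool = False
    pca_scale: bool = False
    n_boot: int = 1000
    seed: int = 7

    def __post_init__(self):
        if self.gene_aggregation not in ("pooled", "mean"):
            raise ValueError("gene_aggregation must be 'pooled' or 'mean'")
        if self.n_boot < 0:
            raise ValueError("n_boot must be >= 0")


def _gene_rscu_table(records: list[CdsRecord], aggregation: str) -> pd.DataFrame:
    """Per-gene RSCU, codons as rows grouped by amino acid, genes as
    columns. 'pooled' sums codon counts across a gene's transcripts;
    'mean' averages per-transcript RSCU values."""
    code = standard_code()
    genes = sorted({r.gene for r in records})
    columns: dict[str, dict[str, float]] = {}
    for gene in genes:
        members = [r for r in records if r.gene == gene]
        if aggregation == "pooled":
            vec = rscu(count_codons(members), code)
            columns[gene] = {c: vec.rscu.get(c, np.nan) for c in code.synonymous_codons}
        else:
            per = [rscu(count_codons(r), code) for r in members]
            columns[gene] = {
                c: float(np.nanmean([v.rscu.get(c, np.nan) for v in per]))
                for c in code.synonymous_codons
            }
    table = pd.DataFrame(columns)
    table.insert(0, "amino_acid", [code.family_of(c) for c in table.index])
    table.index.name = "codon"
    return table


def _metrics_table(records: list[CdsRecord], cai_weights_obj) -> pd.DataFrame:
    code = standard_code()
    rows = []
    for rec in records:
        counts = count_codons(rec)
        prof = composition_profile(rec.seq, record_id=rec.id)
        protein = translate(rec, code)
        rows.append(
            {
                "id": rec.id,
                "gene": rec.gene,
                "n_codons": prof.n_codons,
                "CAI": cai(counts, cai_weights_obj, code),
                "ENc": enc(counts, code).nc,
                "GRAVY": gravy(protein),
                "AROMA": aroma(protein),
                **{k: v for k, v in prof.as_dict().items() if k.startswith("pct_")},
            }
        )
    return pd.DataFrame(rows).set_index("id")


def run_analyze(config: RunConfig) -> dict[str, Path]:
    """Run the complete analysis; returns the output-file manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    code = standard_code()
    manifest: dict[str, Path] = {}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest[name] = path

    gene_map = read_gene_map(config.gene_map) if config.gene_map else None
    records = read_fasta(config.input, gene_map)
    accepted, reports = filter_transcripts(
        records, allow_internal_stop=config.allow_internal_stop
    )
    emit("validation.tsv", lambda p: write_validation_reports(reports, p))
    if not accepted:
        raise ValueError(
            "no transcript passed CDS validation; see validation.tsv in the output"
        )

    profiles = [
        composition_profile(r.seq, include_stop=config.include_stop, record_id=r.id)
        for r in accepted
    ]
    emit("composition.csv", lambda p: profiles_table(profiles).to_csv(p))
    emit("composition_summary.csv",
         lambda p: summarize_composition(profiles).to_csv(p))

    rscu_by_gene = _gene_rscu_table(accepted, config.gene_aggregation)
    emit("rscu_table.csv", lambda p: rscu_by_gene.to_csv(p))

    weights = load_cai_weights(config.cai_reference, code)
    metrics = _metrics_table(accepted, weights)

    if config.pr2_fourfold_only:
        points = [
            pr2_point_from_counts(count_codons(r), code, fourfold_only=True,
                                  record_id=r.id)
            for r in accepted
        ]
        pr2 = pd.DataFrame(
            {"id": [p.id for p in points],
             "gc_bias": [np.nan if p.gc_bias is None else p.gc_bias for p in points],
             "at_bias": [np.nan if p.at_bias is None else p.at_bias for p in points]}
        ).set_index("id")
    else:
        pr2 = pr2_table(profiles)
    emit("pr2_points.csv", lambda p: pr2.to_csv(p))

    enc_gc3 = enc_gc3_table(
        [r.id for r in accepted],
        [gc3_fraction(p) for p in profiles],
        list(metrics["ENc"]),
    )
    emit("enc_gc3.csv", lambda p: enc_gc3.to_csv(p))

    fit = neutrality_fit([(p.pct_GC3, p.pct_GC12) for p in profiles])
    neut_points = pd.DataFrame(
        {"id": [p.id for p in profiles],
         "pct_GC3": [p.pct_GC3 for p in profiles],
         "pct_GC12": [p.pct_GC12 for p in profiles]}
    ).set_index("id")
    emit("neutrality.csv", lambda p: neut_points.to_csv(p))
    fit_payload = {
        **asdict(fit),
        "mutation_share": fit.mutation_share,
        "selection_share": fit.selection_share,
    }
    emit("neutrality.json",
         lambda p: p.write_text(json.dumps(fit_payload, indent=1)))

    corr = correlation_matrix(metrics, METRIC_CORR_VARS)
    emit("correlations.csv", lambda p: corr.to_csv(p, index=False))
    emit("correlations_square.csv",
         lambda p: correlation_square(corr, METRIC_CORR_VARS).to_csv(p))

    vectors = [rscu(count_codons(r), code) for r in accepted]
    matrix = build_rscu_matrix(vectors, [r.id for r in accepted], code)
    pca_res = pca(matrix, n_components=2, scale=config.pca_scale)
    emit("scores.csv", lambda p: pca_res.scores.to_csv(p))
    emit("loadings.csv", lambda p: pca_res.loadings.to_csv(p))
    variance = pd.DataFrame(
        {"component": [f"PC{i+1}" for i in range(len(pca_res.variance_fraction))],
         "variance_fraction": pca_res.variance_fraction}
    )
    emit("variance.csv", lambda p: variance.to_csv(p, index=False))
    emit("biplot.csv", lambda p: biplot_table(pca_res).to_csv(p))

    pc_table = metrics.join(pca_res.scores)
    pc_corr = correlation_matrix(pc_table, ["PC1", "PC2"] + PC_CORR_VARS)
    pc_corr = pc_corr[pc_corr["var1"].isin(["PC1", "PC2"])]
    emit("pc_correlations.csv", lambda p: pc_corr.to_csv(p, index=False))

    if config.n_boot > 0:
        tree = bootstrap_supports(matrix, n_boot=config.n_boot, seed=config.seed)
    else:
        tree = ward_cluster(matrix)
    emit("tree.nwk", lambda p: p.write_text(to_newick(tree) + "\n"))
    emit("tree.json", lambda p: p.write_text(tree_to_json(tree)))

    emit("metrics.csv", lambda p: metrics.to_csv(p))

    log = {
        "codonuse_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "n_input": len(records),
        "n_accepted": len(accepted),
        "config": {k: str(v) for k, v in asdict(config).items()},
    }
    emit("run_log.json", lambda p: p.write_text(json.dumps(log, indent=1)))
    return manifest


def run_simulate(
    spec: SyntheticSpec,
    mode: str,
    out_dir: str | Path,
    *,
    k: int = 2,
    separation: float = 2.0,
    slope: float = 0.15,
    intercept: float = 0.38,
) -> dict[str, Path]:
    """Generate a synthetic CDS set (modes: basic, neutrality,
    clustered) and write FASTA plus the planted-truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if mode == "basic":
        records = sample_cds(spec)
        truth = truth_table(spec)
    elif mode == "neutrality":
        records, truth = sample_neutrality_set(
            n=spec.n_genes * spec.transcripts_per_gene,
            slope=slope,
            intercept=intercept,
            noise_sd=spec.noise_sd,
            seed=spec.seed,
            codons_per_transcript=spec.codons_per_transcript,
        )
    elif mode == "clustered":
        records, truth = sample_clustered_genes(k, separation, spec)
    else:
        raise ValueError(f"unknown simulation mode {mode!r}")
    fasta = out / "synthetic.fasta"
    write_fasta(records, fasta)
    truth_path = out / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return {"synthetic.fasta": fasta, "truth.tsv": truth_path}
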