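"""PCA on RSCU matrices and Ward clustering with bootstrap supports."""

import io

import dendropy
import numpy as np
import pytest

from codonuse.codon_metrics import RscuVector, count_codons, rscu
from codonuse.multivariate import (
    RscuMatrix,
    biplot_table,
    bootstrap_supports,
    build_rscu_matrix,
    pca,
    root_bipartition,
    to_newick,
    tree_to_json,
    ward_cluster,
)
from codonuse.synthetic_data import SyntheticSpec, sample_clustered_genes

import pandas as pd


def random_matrix(code, n_rows, seed, scale=1.0):
    rng = np.random.default_rng(seed)
    values = 1.0 + scale * rng.normal(size=(n_rows, 59))
    ids = [f"t{i:02d}" for i in range(n_rows)]
    df = pd.DataFrame(values, index=ids, columns=list(code.synonymous_codons))
    return RscuMatrix(values=df, imputed=df * 0 > 1)


# ------------------------------------------------------------ matrix build

def test_matrix_has_59_columns_and_imputes_missing(code):
    v1 = RscuVector(rscu={c: 1.0 for c in code.synonymous_codons})
    v2 = RscuVector(
        rscu={c: 1.0 for c in code.synonymous_codons
              if code.family_of(c) != "C"},
        missing_families=frozenset("C"),
    )
    m = build_rscu_matrix([v1, v2], ["a", "b"], code)
    assert m.values.shape == (2, 59)
    assert m.values.loc["b", "TGT"] == 1.0
    assert m.imputed.loc["b", "TGT"]
    assert not m.imputed.loc["a", "TGT"]


def test_matrix_rejects_duplicate_ids(code):
    v = RscuVector(rscu={c: 1.0 for c in code.synonymous_codons})
    with pytest.raises(ValueError, match="duplicate"):
        build_rscu_matrix([v, v], ["a", "a"], code)


def test_identical_transcripts_identical_rows(code):
    v = RscuVector(rscu={c: float(i % 3) for i, c in
                         enumerate(code.synonymous_codons)})
    m = build_rscu_matrix([v, v], ["a", "b"], code)
    assert (m.values.loc["a"] == m.values.loc["b"]).all()


# -------------------------------------------------------------------- PCA

def test_variance_fractions_sum_to_one(code):
    res = pca(random_matrix(code, 10, seed=0), n_components=2)
    assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)


def test_rank_one_matrix_single_component(code):
    rng = np.random.default_rng(1)
    base = rng.normal(size=59)
    direction = rng.normal(size=59)
    rows = np.array([base + t * direction for t in np.linspace(-2, 2, 8)])
    df = pd.DataFrame(rows, index=[f"t{i}" for i in range(8)],
                      columns=list(code.synonymous_codons))
    res = pca(RscuMatrix(values=df, imputed=df * 0 > 1), n_components=2)
    assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-9)


def test_pca_matches_eigendecomposition_oracle(code):
    """Independent oracle: eigendecomposition of the sample covariance."""
    for seed in range(3):
        m = random_matrix(code, 10, seed=seed)
        x = m.values.to_numpy()
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc / (x.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evecs = evecs[:, order]
        oracle_scores = xc @ evecs[:, :2]
        res = pca(m, n_components=2)
        for j in range(2):
            got = res.scores.iloc[:, j].to_numpy()
            want = oracle_scores[:, j]
            assert np.allclose(got, want, atol=1e-8) or np.allclose(
                got, -want, atol=1e-8
            )


def test_pca_reconstruction_and_centering_invariance(code):
    m = random_matrix(code, 8, seed=3)
    res = pca(m, n_components=59)
    xc = m.values.to_numpy() - res.centering.to_numpy()
    recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
    assert np.allclose(recon, xc, atol=1e-9)
    # adding a constant to one codon column changes no score
    shifted = m.values.copy()
    shifted["TTT"] += 5.0
    res2 = pca(RscuMatrix(values=shifted, imputed=m.imputed), n_components=2)
    assert np.allclose(res.scores.to_numpy()[:, :2],
                       res2.scores.to_numpy(), atol=1e-8)


def test_pca_loadings_orthonormal(code):
    res = pca(random_matrix(code, 12, seed=4), n_components=3)
    l = res.loadings.to_numpy()
    assert np.allclose(l.T @ l, np.eye(3), atol=1e-9)


def test_biplot_ranks_dominant_codon_first(code):
    rng = np.random.default_rng(5)
    values = 1.0 + 0.05 * rng.normal(size=(12, 59))
    df = pd.DataFrame(values, index=[f"t{i}" for i in range(12)],
                      columns=list(code.synonymous_codons))
    df["CTG"] += rng.normal(scale=1.0, size=12)  # 20x the sd of the rest
    res = pca(RscuMatrix(values=df, imputed=df * 0 > 1), n_components=2)
    table = biplot_table(res)
    assert table.index[0] == "CTG"
    assert sorted(table.index) == sorted(code.synonymous_codons)
    assert (table.loc[table["arrow_length"] == 0, "arrow_length"] == 0).all()


# -------------------------------------------------------------- clustering

def test_identical_rows_merge_first_at_height_zero(code):
    m = random_matrix(code, 4, seed=6)
    m.values.iloc[1] = m.values.iloc[0]
    tree = ward_cluster(m)
    assert tree.linkage[0, 2] == pytest.approx(0.0)
    merged = {int(tree.linkage[0, 0]), int(tree.linkage[0, 1])}
    ids = [tree.ids[i] for i in merged]
    assert set(ids) == {m.values.index[0], m.values.index[1]}


def test_near_pair_merges_before_distant_point(code):
    base = np.ones((3, 59))
    base[1] += 0.01
    base[2] += 5.0
    df = pd.DataFrame(base, index=["a", "b", "far"],
                      columns=list(code.synonymous_codons))
    tree = ward_cluster(RscuMatrix(values=df, imputed=df * 0 > 1))
    first = {tree.ids[int(tree.linkage[0, 0])], tree.ids[int(tree.linkage[0, 1])]}
    assert first == {"a", "b"}


def test_heights_monotone_nondecreasing(code):
    tree = ward_cluster(random_matrix(code, 15, seed=7))
    heights = tree.linkage[:, 2]
    assert (np.diff(heights) >= -1e-12).all()


def test_planted_two_groups_recovered_at_root(code):
    spec = SyntheticSpec(n_genes=6, transcripts_per_gene=4,
                         codons_per_transcript=300, seed=9)
    records, truth = sample_clustered_genes(2, 2.5, spec)
    vecs = [rscu(count_codons(r), code) for r in records]
    m = build_rscu_matrix(vecs, [r.id for r in records], code)
    tree = ward_cluster(m)
    group_of = dict(zip(truth.gene, truth.group))
    planted = {
        frozenset(r.id for r in records if group_of[r.gene] == g) for g in (0, 1)
    }
    assert set(root_bipartition(tree)) == planted


def test_bootstrap_deterministic_and_in_unit_interval(code):
    m = random_matrix(code, 8, seed=10)
    t1 = bootstrap_supports(m, n_boot=25, seed=3)
    t2 = bootstrap_supports(m, n_boot=25, seed=3)
    assert t1.supports == t2.supports
    assert all(0.0 <= s <= 1.0 for s in t1.supports.values())
    single = bootstrap_supports(m, n_boot=1, seed=3)
    assert set(single.supports.values()) <= {0.0, 1.0}


def test_bootstrap_invariant_to_input_row_order(code):
    m = random_matrix(code, 7, seed=11)
    perm = m.values.sample(frac=1.0, random_state=1)
    m_perm = RscuMatrix(values=perm, imputed=m.imputed.loc[perm.index])
    t1 = bootstrap_supports(m, n_boot=20, seed=5)
    t2 = bootstrap_supports(m_perm, n_boot=20, seed=5)
    assert t1.ids == t2.ids
    assert t1.supports == t2.supports


# ------------------------------------------------------------------ newick

def test_newick_two_leaves_shape(code):
    m = random_matrix(code, 2, seed=12)
    tree = ward_cluster(m)
    nwk = to_newick(tree)
    assert nwk.startswith("(") and nwk.endswith(";")
    assert set(tree.ids) <= set(nwk.replace("(", " ").replace(")", " ")
                                .replace(",", " ").replace(":", " ").split())


def test_newick_round_trip_topology_and_supports(code):
    spec = SyntheticSpec(n_genes=4, transcripts_per_gene=2,
                         codons_per_transcript=150, seed=13)
    records, _ = sample_clustered_genes(2, 2.0, spec)
    vecs = [rscu(count_codons(r), code) for r in records]
    m = build_rscu_matrix(vecs, [r.id for r in records], code)
    tree = bootstrap_supports(m, n_boot=10, seed=1)
    nwk = to_newick(tree)
    parsed = dendropy.Tree.get(data=nwk, schema="newick",
                               preserve_underscores=True)
    leaves = {l.taxon.label for l in parsed.leaf_node_iter()}
    assert leaves == set(tree.ids)
    # internal labels round-trip as supports
    labels = sorted(
        float(n.label) for n in parsed.preorder_internal_node_iter()
        if n.label is not None
    )
    expected = sorted(round(v, 3) for v in tree.supports.values())
    assert labels == pytest.approx(expected)
    json_dump = tree_to_json(tree)
    assert all(i in json_dump for i in tree.ids)
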