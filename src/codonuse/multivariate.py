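"""RSCU-space ordination and clustering.

Each transcript becomes a 59-dimensional RSCU vector (one slot per
synonymous codon of the standard code). PCA on the column-centred,
unscaled matrix extracts the major usage trends — RSCU values already
share a common scale by construction, so covariance PCA is the default
and correlation PCA an option. Hierarchical clustering uses Ward
linkage in the Ward.D2 convention (squared-Euclidean objective on
Euclidean input, the scipy/R ``ward.D2`` behaviour), with node
confidence assessed by bootstrap resampling of the 59 codon columns —
the codon-usage analogue of resampling alignment sites.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .codon_metrics import RscuVector
from .genetic_code import GeneticCode, standard_code

#: Neutral fill for codons of families a transcript never uses: RSCU 1
#: is the value every codon would take under uniform synonymous usage.
MISSING_FAMILY_FILL = 1.0


@dataclass(frozen=True)
class RscuMatrix:
    """Transcripts x 59 codons, complete after neutral imputation.

    ``imputed`` marks the cells filled because the transcript used no
    codon of that family at all.
    """

    values: pd.DataFrame
    imputed: pd.DataFrame

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def codons(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame          # transcripts x kept components
    loadings: pd.DataFrame        # codons x kept components (orthonormal)
    variance_fraction: np.ndarray  # over ALL components; sums to 1
    centering: pd.Series          # column means removed before rotation


@dataclass(frozen=True)
class ClusterTree:
    """Ward merge history with optional bootstrap supports.

    ``linkage`` is a scipy linkage matrix over ``ids`` (leaves indexed
    in that order); ``supports`` maps internal-node index (scipy
    convention: n + merge row) to the fraction of bootstrap replicates
    reproducing that node's leaf bipartition.
    """

    linkage: np.ndarray
    ids: tuple[str, ...]
    supports: dict[int, float] = field(default_factory=dict)

    @property
    def n_leaves(self) -> int:
        return len(self.ids)


def build_rscu_matrix(
    vectors: list[RscuVector], ids: list[str], code: GeneticCode | None = None
) -> RscuMatrix:
    """Assemble RSCU vectors into the canonical 59-column matrix."""
    code = code or standard_code()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript ids in RSCU matrix")
    if len(vectors) != len(ids):
        raise ValueError("vectors and ids length mismatch")
    codons = list(code.synonymous_codons)
    data = np.empty((len(ids), len(codons)))
    imputed = np.zeros((len(ids), len(codons)), dtype=bool)
    for i, vec in enumerate(vectors):
        for j, codon in enumerate(codons):
            if codon in vec.rscu:
                data[i, j] = vec.rscu[codon]
            else:
                data[i, j] = MISSING_FAMILY_FILL
                imputed[i, j] = True
    return RscuMatrix(
        values=pd.DataFrame(data, index=ids, columns=codons),
        imputed=pd.DataFrame(imputed, index=ids, columns=codons),
    )


def pca(m: RscuMatrix, n_components: int = 2, *, scale: bool = False) -> PcaResult:
    """Principal components of the RSCU matrix.

    Columns are mean-centred (and optionally standardised); components
    are ordered by decreasing variance with a deterministic sign
    convention — the largest-magnitude loading of each component is
    made positive.
    """
    x = m.values.to_numpy(float)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 transcripts")
    centering = m.values.mean(axis=0)
    if scale:
        sd = m.values.std(axis=0, ddof=1).replace(0.0, 1.0)
        x = (x - centering.to_numpy()) / sd.to_numpy()
        fit_input = x
    else:
        fit_input = x  # sklearn centres internally; explicit mean kept for the record

    model = PCA(n_components=None, svd_solver="full")
    scores_full = model.fit_transform(fit_input)
    loadings_full = model.components_.T  # codons x components

    # deterministic sign: largest |loading| per component positive
    for j in range(loadings_full.shape[1]):
        k = int(np.argmax(np.abs(loadings_full[:, j])))
        if loadings_full[k, j] < 0:
            loadings_full[:, j] *= -1
            scores_full[:, j] *= -1

    keep = min(n_components, loadings_full.shape[1])
    comp_names = [f"PC{i + 1}" for i in range(keep)]
    return PcaResult(
        scores=pd.DataFrame(scores_full[:, :keep], index=m.ids, columns=comp_names),
        loadings=pd.DataFrame(
            loadings_full[:, :keep], index=m.codons, columns=comp_names
        ),
        variance_fraction=model.explained_variance_ratio_.copy(),
        centering=centering,
    )


def biplot_table(p: PcaResult) -> pd.DataFrame:
    """Codon arrows for a PC1/PC2 biplot, ranked by arrow length.

    Arrow length (the Euclidean norm of the PC1/PC2 loadings) is the
    codon's contribution to the plane's variance structure; the longest
    arrow is the codon most responsible for separating transcripts.
    """
    if p.loadings.shape[1] < 2:
        raise ValueError("biplot needs at least 2 components")
    table = pd.DataFrame(
        {
            "PC1": p.loadings["PC1"],
            "PC2": p.loadings["PC2"],
        }
    )
    table["arrow_length"] = np.hypot(table["PC1"], table["PC2"])
    table = table.sort_values("arrow_length", ascending=False)
    table["rank"] = np.arange(1, len(table) + 1)
    table.index.name = "codon"
    return table


def _sorted_matrix(m: RscuMatrix) -> RscuMatrix:
    """Leaf order fixed lexicographically so results do not depend on
    input order (also the tie-break for equal-height merges)."""
    order = sorted(m.ids)
    return RscuMatrix(values=m.values.loc[order], imputed=m.imputed.loc[order])


def ward_cluster(m: RscuMatrix) -> ClusterTree:
    """Ward (D2) hierarchical clustering of transcripts in RSCU space."""
    if m.values.shape[0] < 2:
        raise ValueError("clustering needs at least 2 transcripts")
    ms = _sorted_matrix(m)
    z = hierarchy.linkage(ms.values.to_numpy(float), method="ward")
    return ClusterTree(linkage=z, ids=tuple(ms.ids))


def _clades(tree: ClusterTree) -> dict[int, frozenset[str]]:
    """Leaf set of every node, keyed by scipy node index."""
    n = tree.n_leaves
    clades: dict[int, frozenset[str]] = {
        i: frozenset([tree.ids[i]]) for i in range(n)
    }
    for row, (a, b, _, _) in enumerate(tree.linkage):
        clades[n + row] = clades[int(a)] | clades[int(b)]
    return clades


def _bipartition_keys(tree: ClusterTree) -> dict[int, frozenset[str]]:
    """Canonical unordered bipartition per internal node: the side of
    the split containing the lexicographically smallest leaf."""
    universe = frozenset(tree.ids)
    anchor = min(tree.ids)
    keys = {}
    for node, clade in _clades(tree).items():
        if node < tree.n_leaves:
            continue
        keys[node] = clade if anchor in clade else universe - clade
    return keys


def root_bipartition(tree: ClusterTree) -> tuple[frozenset[str], frozenset[str]]:
    """The two leaf sets separated by the final (root) merge."""
    n = tree.n_leaves
    clades = _clades(tree)
    a, b = int(tree.linkage[-1, 0]), int(tree.linkage[-1, 1])
    return clades[a], clades[b]


def bootstrap_supports(m: RscuMatrix, n_boot: int, seed: int) -> ClusterTree:
    """Column-bootstrap confidence for every internal node.

    The 59 codon columns are resampled with replacement ``n_boot``
    times, the tree rebuilt each time, and a node's support is the
    fraction of replicates containing the same unordered leaf
    bipartition. Reproducible for a fixed seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    base = ward_cluster(m)
    ms = _sorted_matrix(m)
    x = ms.values.to_numpy(float)
    rng = np.random.default_rng(seed)
    base_keys = _bipartition_keys(base)
    hits = {node: 0 for node in base_keys}
    n_cols = x.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, n_cols, size=n_cols)
        zb = hierarchy.linkage(x[:, cols], method="ward")
        rep = ClusterTree(linkage=zb, ids=base.ids)
        rep_keys = set(_bipartition_keys(rep).values())
        for node, key in base_keys.items():
            if key in rep_keys:
                hits[node] += 1
    supports = {node: hits[node] / n_boot for node in base_keys}
    return ClusterTree(linkage=base.linkage, ids=base.ids, supports=supports)


def to_newick(tree: ClusterTree, *, support_digits: int = 3) -> str:
    """Serialise a merge history as Newick, branch lengths taken from
    Ward merge heights and bootstrap supports as internal node labels."""
    node = hierarchy.to_tree(tree.linkage)

    def fmt(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{tree.ids[node.id]}:{parent_height:.6g}"
        length = parent_height - node.dist
        left = fmt(node.left, node.dist)
        right = fmt(node.right, node.dist)
        label = ""
        if node.id in tree.supports:
            label = f"{tree.supports[node.id]:.{support_digits}f}"
        return f"({left},{right}){label}:{length:.6g}"

    root = node
    left = fmt(root.left, root.dist)
    right = fmt(root.right, root.dist)
    label = f"{tree.supports[root.id]:.{support_digits}f}" if root.id in tree.supports else ""
    return f"({left},{right}){label};"


def tree_to_json(tree: ClusterTree) -> str:
    """Merge-history dump: rows of (child_a, child_b, height, size) plus
    leaf order and supports, for programmatic re-use."""
    payload = {
        "ids": list(tree.ids),
        "linkage": [
            {"a": int(a), "b": int(b), "height": float(h), "size": int(s)}
            for a, b, h, s in tree.linkage
        ],
        "supports": {str(k): v for k, v in sorted(tree.supports.items())},
    }
    return json.dumps(payload, indent=1)
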