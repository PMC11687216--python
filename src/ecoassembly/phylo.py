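"""Phylogenetic distances and phylogeny-aware community dissimilarities.

betaMNTD (beta mean nearest taxon distance) is the abundance-weighted mean,
over the taxa of each of two communities, of the patristic distance to the
closest relative in the other community:

    betaMNTD(A, B) = 0.5 * [ sum_{i in A} f_i * min_{j in B} d(i, j)
                           + sum_{j in B} f_j * min_{i in A} d(i, j) ]

with f the within-sample relative abundances. A taxon shared by both
communities is its own nearest taxon (distance 0). Weighted UniFrac and
cophenetic (tip-to-tip patristic) distances are delegated to scikit-bio.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from .io import OtuTable, ValidationError

__all__ = [
    "cophenetic_distances",
    "beta_mntd",
    "beta_mntd_matrix",
    "weighted_unifrac",
]


def cophenetic_distances(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip patristic distance matrix (sum of branch lengths on the path)."""
    return tree.tip_tip_distances()


def _align_table_to_dist(table: OtuTable, dist: DistanceMatrix) -> np.ndarray:
    """Phylogenetic distance submatrix in table OTU order; error on missing OTUs."""
    index = {o: i for i, o in enumerate(dist.ids)}
    missing = [o for o in table.otu_ids if o not in index]
    if missing:
        raise ValidationError(
            f"OTUs absent from the phylogenetic distance matrix: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    idx = np.array([index[o] for o in table.otu_ids])
    return np.ascontiguousarray(dist.data[np.ix_(idx, idx)])


def _pair_bmntd(fa: np.ndarray, fb: np.ndarray, ia: np.ndarray, ib: np.ndarray,
                d: np.ndarray) -> float:
    sub = d[np.ix_(ia, ib)]
    return 0.5 * (fa @ sub.min(axis=1) + fb @ sub.min(axis=0))


def beta_mntd(abund_a, abund_b, dist: DistanceMatrix,
              abundance_weighted: bool = True) -> float:
    """betaMNTD between two communities.

    Parameters
    ----------
    abund_a, abund_b : mapping otu_id -> abundance
        Raw or relative abundances; normalised internally over present OTUs.
    dist : DistanceMatrix
        Patristic distances covering every present OTU.
    abundance_weighted : bool
        If False, every present taxon gets weight 1/richness.
    """
    index = {o: i for i, o in enumerate(dist.ids)}

    def _prep(abund):
        ids = [o for o, v in abund.items() if v > 0]
        if not ids:
            raise ValidationError("community has no present OTUs")
        missing = [o for o in ids if o not in index]
        if missing:
            raise ValidationError(f"OTU {missing[0]!r} absent from distance matrix")
        idx = np.array([index[o] for o in ids])
        w = np.array([float(abund[o]) for o in ids])
        if not abundance_weighted:
            w = np.ones_like(w)
        return idx, w / w.sum()

    ia, fa = _prep(abund_a)
    ib, fb = _prep(abund_b)
    return float(_pair_bmntd(fa, fb, ia, ib, dist.data))


def beta_mntd_matrix(table: OtuTable, dist: DistanceMatrix,
                     abundance_weighted: bool = True) -> DistanceMatrix:
    """Pairwise betaMNTD over all samples of a table."""
    d = _align_table_to_dist(table, dist)
    rel = table.relative_abundance()
    n = table.n_samples
    present = [np.flatnonzero(table.counts[:, j] > 0) for j in range(n)]
    weights = []
    for j in range(n):
        if present[j].size == 0:
            raise ValidationError(f"sample {table.sample_ids[j]!r} is empty")
        w = rel[present[j], j] if abundance_weighted else np.full(present[j].size, 1.0)
        weights.append(w / w.sum())
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            v = _pair_bmntd(weights[a], weights[b], present[a], present[b], d)
            out[a, b] = out[b, a] = v
    return DistanceMatrix(out, ids=table.sample_ids)


def weighted_unifrac(table: OtuTable, tree: TreeNode,
                     normalized: bool = True) -> DistanceMatrix:
    """Pairwise weighted UniFrac dissimilarity over the samples of a table.

    Normalised by default so values are comparable across pairs (in [0, 1]).
    """
    tip_names = {t.name for t in tree.tips()}
    present = table.counts.sum(axis=1) > 0
    missing = [o for o, p in zip(table.otu_ids, present) if p and o not in tip_names]
    if missing:
        raise ValidationError(f"OTUs with reads missing from the tree: {missing[:5]}")
    keep = table.drop_empty_otus()
    return beta_diversity(
        "weighted_unifrac",
        keep.counts.T,
        ids=keep.sample_ids,
        taxa=keep.otu_ids,
        tree=tree,
        normalized=normalized,
    )
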