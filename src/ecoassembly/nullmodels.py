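"""Null models for assembly-process inference: betaNTI and Raup-Crick (Bray-Curtis).

Two complementary nulls:

* **betaNTI** — the standardized effect size of betaMNTD against a null in
  which taxa are shuffled across the tips of the phylogeny (the tip-to-tip
  distance matrix is relabelled by a random permutation; tree shape and
  abundances are untouched)::

      betaNTI = (betaMNTD_obs - mean(betaMNTD_null)) / sd(betaMNTD_null)

  |betaNTI| >= 2 indicates that selection dominates: positive values mean
  more phylogenetic turnover than expected (heterogeneous selection),
  negative values less (homogeneous selection).

* **RC_bray** — a probabilistic Raup-Crick null on Bray-Curtis
  dissimilarity. Each null community keeps the observed richness and read
  depth of its sample; taxon identities are drawn without replacement with
  probability proportional to metacommunity occupancy, and the remaining
  reads are assigned multinomially with probability proportional to
  metacommunity relative abundance. The observed Bray-Curtis is located in
  the null distribution and rescaled to [-1, +1]::

      RC = 2 * [ #(null < obs) + 0.5 * #(null == obs) ] / n_null - 1

By default one shared null ensemble serves all sample pairs of a run (the
r-th replicate uses the r-th permutation / the r-th per-sample null
community), which cuts compute by the number of pairs while leaving each
pair's marginal null distribution unchanged; fully independent per-pair
nulls are available with ``shared_null=False``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io import OtuTable, ValidationError
from .phylo import _align_table_to_dist, _pair_bmntd

__all__ = [
    "bray_curtis",
    "taxa_shuffle",
    "beta_nti_matrix",
    "rc_bray_matrix",
]

#: columns of the long-format betaNTI result frame
BNTI_COLUMNS = ["sample_a", "sample_b", "bmntd_obs", "null_mean", "null_sd", "bnti", "n_null"]
#: columns of the long-format RC_bray result frame
RC_COLUMNS = ["sample_a", "sample_b", "bc_obs", "rc", "n_null"]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity on counts: sum|x-y| / sum(x+y)."""
    if np.any(table.sample_sums == 0):
        empty = [s for s, n in zip(table.sample_ids, table.sample_sums) if n == 0]
        raise ValidationError(f"Bray-Curtis undefined for empty samples: {empty}")
    d = squareform(pdist(table.counts.T.astype(float), metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


def taxa_shuffle(dist: DistanceMatrix, rng) -> DistanceMatrix:
    """Shuffle taxa across the phylogeny: one random relabelling of the matrix.

    Rows and columns are permuted jointly, so the multiset of off-diagonal
    distances (the tree shape) is preserved exactly.
    """
    rng = _as_rng(rng)
    perm = rng.permutation(dist.shape[0])
    return DistanceMatrix(dist.data[np.ix_(perm, perm)], ids=dist.ids)


# ---------------------------------------------------------------------------
# betaNTI
# ---------------------------------------------------------------------------

def _null_bmntd_shared(d, present, weights, perms, pairs, chunk=48):
    """betaMNTD under shared tip-shuffles, vectorised over permutations.

    For permutation p the relabelled submatrix for pair (A, B) is
    d[p[ia]][:, p[ib]]; its row-wise minima equal colmin_B[p[ia]] where
    colmin_B[i] = min_{j in B} d[i, p[j]] — computed once per sample per
    permutation and reused across all pairs containing that sample.
    """
    n_null = perms.shape[0]
    out = np.empty((n_null, len(pairs)))
    for start in range(0, n_null, chunk):
        P = perms[start:start + chunk]
        m = P.shape[0]
        colmin = []
        for ib in present:
            # (n_taxa, m, k) gather then min over the community's columns
            g = d[:, P[:, ib]]
            colmin.append(g.min(axis=2).T)  # (m, n_taxa)
        for k, (a, b) in enumerate(pairs):
            ga = np.take_along_axis(colmin[b], P[:, present[a]], axis=1)  # (m, kA)
            gb = np.take_along_axis(colmin[a], P[:, present[b]], axis=1)
            out[start:start + m, k] = 0.5 * (ga @ weights[a] + gb @ weights[b])
    return out


def beta_nti_matrix(
    table: OtuTable,
    dist: DistanceMatrix,
    n_null: int = 999,
    rng=None,
    shared_null: bool = True,
    abundance_weighted: bool = True,
) -> pd.DataFrame:
    """betaNTI for every sample pair of a table.

    Returns a long-format frame (one row per unordered pair, a < b in table
    order) with columns ``sample_a, sample_b, bmntd_obs, null_mean, null_sd,
    bnti, n_null``. Degenerate pairs whose null distribution has zero
    standard deviation (e.g. identical samples) get ``bnti = NaN`` — no
    selection signal — and are expected to fall through to the RC step.

    The shuffle pool is every taxon of ``dist`` (the regional pool): taxa
    are randomized across the whole phylogeny supplied, so the caller
    controls the null's species pool by pruning (or not pruning) the tree.
    """
    if n_null < 2:
        raise ValidationError("n_null must be >= 2")
    rng = _as_rng(rng)
    table = table.drop_empty_otus()
    index = {o: i for i, o in enumerate(dist.ids)}
    missing = [o for o in table.otu_ids if o not in index]
    if missing:
        raise ValidationError(f"OTUs absent from the distance matrix: {missing[:5]}")
    to_pool = np.array([index[o] for o in table.otu_ids])
    d = np.ascontiguousarray(dist.data)
    n_pool = d.shape[0]
    n = table.n_samples
    rel = table.relative_abundance()
    present, weights = [], []
    for j in range(n):
        ia = np.flatnonzero(table.counts[:, j] > 0)
        if ia.size == 0:
            raise ValidationError(f"sample {table.sample_ids[j]!r} is empty")
        w = rel[ia, j] if abundance_weighted else np.full(ia.size, 1.0)
        present.append(to_pool[ia])  # pool coordinates
        weights.append(w / w.sum())

    pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    obs = np.array([
        _pair_bmntd(weights[a], weights[b], present[a], present[b], d) for a, b in pairs
    ])

    if shared_null:
        perms = np.array([rng.permutation(n_pool) for _ in range(n_null)])
        null = _null_bmntd_shared(d, present, weights, perms, pairs)
    else:
        null = np.empty((n_null, len(pairs)))
        for k, (a, b) in enumerate(pairs):
            perms = np.array([rng.permutation(n_pool) for _ in range(n_null)])
            null[:, k] = _null_bmntd_shared(
                d, [present[a], present[b]], [weights[a], weights[b]],
                perms, [(0, 1)],
            )[:, 0]

    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = np.where(sd > 0, (obs - mean) / np.where(sd > 0, sd, 1.0), np.nan)
    ids = table.sample_ids
    return pd.DataFrame({
        "sample_a": [ids[a] for a, _ in pairs],
        "sample_b": [ids[b] for _, b in pairs],
        "bmntd_obs": obs,
        "null_mean": mean,
        "null_sd": sd,
        "bnti": bnti,
        "n_null": n_null,
    })


# ---------------------------------------------------------------------------
# RC_bray
# ---------------------------------------------------------------------------

def _null_assemblies(rng, n_null, richness, depth, log_occ, pool_ab) -> np.ndarray:
    """n_null null communities preserving one sample's richness and depth."""
    n_taxa = log_occ.size
    # identities: weighted draw without replacement via Gumbel top-k
    keys = log_occ + rng.gumbel(size=(n_null, n_taxa))
    top = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    sel = np.zeros((n_null, n_taxa), dtype=np.int64)
    np.put_along_axis(sel, top, 1, axis=1)
    # reads: each drawn taxon keeps 1 read, the rest follow regional abundance
    extra = depth - richness
    if extra > 0:
        p = sel * pool_ab
        p = p / p.sum(axis=1, keepdims=True)
        sel += rng.multinomial(extra, p)
    return sel


def rc_bray_matrix(
    table: OtuTable,
    n_null: int = 999,
    rng=None,
    shared_null: bool = True,
) -> pd.DataFrame:
    """Raup-Crick (Bray-Curtis) for every sample pair of a table.

    Metacommunity occupancy and relative-abundance pools are computed from
    ``table`` itself. Returns a long-format frame with columns ``sample_a,
    sample_b, bc_obs, rc, n_null``; rc is in [-1, +1].
    """
    if n_null < 1:
        raise ValidationError("n_null must be >= 1")
    rng = _as_rng(rng)
    table = table.drop_empty_otus()
    counts = table.counts
    n_taxa, n = table.n_otus, table.n_samples
    if n < 2:
        raise ValidationError("need >= 2 samples")
    occ = table.occupancy().astype(float)
    pool_ab = counts.sum(axis=1) / counts.sum()
    with np.errstate(divide="ignore"):
        log_occ = np.log(occ)  # -inf for unoccupied taxa (excluded)
    n_pool = int((occ > 0).sum())
    richness = (counts > 0).sum(axis=0)
    depth = counts.sum(axis=0)
    too_rich = [table.sample_ids[j] for j in range(n) if richness[j] > n_pool]
    if too_rich:
        raise ValidationError(f"sample richness exceeds metacommunity richness: {too_rich}")

    bc_obs_mat = squareform(pdist(counts.T.astype(float), metric="braycurtis"))

    if shared_null:
        nulls = [
            _null_assemblies(rng, n_null, int(richness[j]), int(depth[j]), log_occ, pool_ab)
            for j in range(n)
        ]

    rows = []
    for a in range(n):
        for b in range(a + 1, n):
            if shared_null:
                na, nb = nulls[a], nulls[b]
            else:
                na = _null_assemblies(rng, n_null, int(richness[a]), int(depth[a]), log_occ, pool_ab)
                nb = _null_assemblies(rng, n_null, int(richness[b]), int(depth[b]), log_occ, pool_ab)
            num = np.abs(na - nb).sum(axis=1)
            den = (na + nb).sum(axis=1)
            bc_null = num / den
            obs = bc_obs_mat[a, b]
            less = int((bc_null < obs).sum())
            ties = int((bc_null == obs).sum())
            rc = 2.0 * (less + 0.5 * ties) / n_null - 1.0
            rows.append((table.sample_ids[a], table.sample_ids[b], obs, rc, n_null))
    return pd.DataFrame(rows, columns=RC_COLUMNS)
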