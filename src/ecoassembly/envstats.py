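"""Environmental / geographic distances, Mantel tests, phylogenetic signal,
ordination and PERMANOVA.

Environmental distance follows the usual convention for mixed-unit
variables: each variable is z-standardized (mean 0, variance 1, sample sd)
and sites are compared by Euclidean distance in z-space, so no single
variable's units dominate.

Phylogenetic signal is assessed with a Mantel correlogram: pairwise niche
distances (Euclidean over z-scored abundance-weighted niche optima) are
correlated with membership in equal-width phylogenetic-distance classes; a
positive, significant statistic in the short-distance classes indicates
niche conservatism among close relatives, the prerequisite of the betaNTI
framework.

Mantel, PCoA and PERMANOVA are implemented here directly (they are a few
lines each) so that permutation streams are seeded, R^2 is reported and
negative PCoA eigenvalues are surfaced rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io import OtuTable, SampleMetadata, ValidationError

__all__ = [
    "env_distance",
    "geo_distance",
    "mantel",
    "niche_values",
    "phylo_signal_correlogram",
    "regress_bnti_env",
    "env_correlations",
    "pcoa",
    "permanova",
]

EARTH_RADIUS_KM = 6371.0


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _zscore_columns(x: np.ndarray, names) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    flat = [n for n, s in zip(names, sd) if s == 0 or not np.isfinite(s)]
    if flat:
        raise ValidationError(f"constant environmental variable(s): {flat}")
    return (x - mu) / sd


def env_distance(metadata: SampleMetadata, variables=None) -> DistanceMatrix:
    """Euclidean distance between sites over z-standardized variables."""
    env = metadata.env_matrix(variables)
    if len(env) < 2:
        raise ValidationError("need >= 2 samples")
    z = _zscore_columns(env.to_numpy(dtype=float), env.columns)
    return DistanceMatrix(squareform(pdist(z)), ids=list(env.index))


def geo_distance(metadata: SampleMetadata) -> DistanceMatrix:
    """Great-circle (haversine) distance in km, Earth radius 6371 km."""
    lat = np.radians(metadata.frame["latitude"].to_numpy(dtype=float))
    lon = np.radians(metadata.frame["longitude"].to_numpy(dtype=float))
    if np.any(np.abs(lat) > np.pi / 2) or np.any(np.abs(lon) > 2 * np.pi):
        raise ValidationError("coordinates out of range (decimal degrees expected)")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    h = np.clip(h, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(d, ids=list(metadata.frame.index))


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    rng=None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with permutation p.

    ``alternative='greater'`` (default) tests for positive association;
    'two-sided' uses |r|. p = (1 + exceedances) / (1 + n_perm).
    """
    if list(d1.ids) != list(d2.ids):
        d2 = d2.filter(d1.ids)
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    rng = _as_rng(rng)
    x = squareform(d1.data, checks=False)
    y2 = d2.data
    y = squareform(y2, checks=False)
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("degenerate (constant) distance matrix")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    n = d1.shape[0]
    exceed = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        yp = squareform(y2[np.ix_(p, p)], checks=False)
        r = np.corrcoef(x, yp)[0, 1]
        if alternative == "greater":
            exceed += r >= r_obs
        elif alternative == "less":
            exceed += r <= r_obs
        else:
            exceed += abs(r) >= abs(r_obs)
    return r_obs, (1 + exceed) / (1 + n_perm)


# ---------------------------------------------------------------------------
# phylogenetic signal
# ---------------------------------------------------------------------------

def niche_values(
    table: OtuTable,
    metadata: SampleMetadata,
    variables=None,
    occupancy_min: int = 4,
) -> pd.DataFrame:
    """Abundance-weighted niche optimum per OTU per environmental variable.

    niche(o, v) = sum_s relabund(o,s) * env(s,v) / sum_s relabund(o,s).
    The returned frame carries ``occupancy`` and a boolean ``tested``
    column: only OTUs occupying at least ``occupancy_min`` samples enter
    signal testing (low occupancy biases niche estimation).
    """
    meta = metadata.aligned(table.sample_ids)
    env = meta.env_matrix(variables).to_numpy(dtype=float)
    rel = table.relative_abundance()
    tot = rel.sum(axis=1)
    if np.any(tot == 0):
        empty = [o for o, t in zip(table.otu_ids, tot) if t == 0]
        raise ValidationError(f"OTUs with no reads anywhere: {empty[:5]}")
    niche = (rel @ env) / tot[:, None]
    out = pd.DataFrame(niche, index=table.otu_ids,
                       columns=list(metadata.env_matrix(variables).columns))
    out.insert(0, "occupancy", table.occupancy())
    out["tested"] = out["occupancy"] >= occupancy_min
    return out


@dataclass
class CorrelogramClass:
    """One phylogenetic-distance class of a Mantel correlogram."""

    index: int
    lower: float
    upper: float
    n_pairs: int
    mantel_r: float      # NaN when the class is empty
    p: float
    p_corrected: float
    tested: bool


def _holm_progressive(pvals):
    """Progressive Holm correction: class k is corrected within classes 1..k."""
    out = []
    for k in range(len(pvals)):
        sub = np.asarray(pvals[: k + 1], dtype=float)
        order = np.argsort(sub)
        m = len(sub)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * sub[idx])
            adj[idx] = min(1.0, running)
        out.append(float(adj[k]))
    return out


def phylo_signal_correlogram(
    niches: pd.DataFrame,
    dist: DistanceMatrix,
    n_classes: int | None = None,
    n_perm: int = 999,
    rng=None,
) -> list[CorrelogramClass]:
    """Mantel correlogram of niche distance against phylogenetic distance.

    ``niches`` is the output of :func:`niche_values`; only rows with
    ``tested`` True are used. Classes are equal-width over the observed
    phylogenetic-distance range (Sturges count by default). The class
    statistic is the negated Pearson correlation between the niche-distance
    vector and class membership, so positive values mean ecological
    similarity at that phylogenetic distance (positive signal). p-values
    are two-sided permutation tests with progressive Holm correction.
    """
    rng = _as_rng(rng)
    used = niches[niches["tested"]]
    ids = [o for o in dist.ids if o in set(used.index)]
    if len(ids) < 4:
        raise ValidationError("fewer than 4 OTUs pass the occupancy filter")
    var_cols = [c for c in used.columns if c not in ("occupancy", "tested")]
    z = _zscore_columns(used.loc[ids, var_cols].to_numpy(dtype=float), var_cols)
    niche_vec = pdist(z)
    sub = dist.filter(ids)
    phylo_vec = squareform(sub.data, checks=False)

    n_pairs = niche_vec.size
    if n_classes is None:
        n_classes = int(np.ceil(np.log2(n_pairs)) + 1)  # Sturges
    if n_classes < 2:
        raise ValidationError("need >= 2 distance classes")
    lo, hi = phylo_vec.min(), phylo_vec.max()
    edges = np.linspace(lo, hi, n_classes + 1)
    # assign every pair to exactly one class (last edge inclusive)
    cls = np.clip(np.searchsorted(edges, phylo_vec, side="right") - 1, 0, n_classes - 1)

    n = len(ids)
    centered = niche_vec - niche_vec.mean()
    denom_x = np.sqrt((centered ** 2).sum())

    def class_r(vec, membership_sets):
        rs = []
        c = vec - vec.mean()
        dx = np.sqrt((c ** 2).sum())
        for mem in membership_sets:
            ind = mem.astype(float)
            ic = ind - ind.mean()
            di = np.sqrt((ic ** 2).sum())
            if di == 0 or dx == 0:
                rs.append(np.nan)
            else:
                rs.append(-(c @ ic) / (dx * di))
        return np.array(rs)

    memberships = [cls == k for k in range(n_classes)]
    r_obs = class_r(niche_vec, memberships)

    # permute taxa (rows/cols of the niche-distance matrix) jointly for all classes
    niche_sq = squareform(niche_vec)
    exceed = np.zeros(n_classes)
    for _ in range(n_perm):
        p = rng.permutation(n)
        vec_p = squareform(niche_sq[np.ix_(p, p)], checks=False)
        r_p = class_r(vec_p, memberships)
        exceed += np.abs(r_p) >= np.abs(r_obs)

    results = []
    raw_p = []
    for k in range(n_classes):
        tested = bool(memberships[k].sum() > 0 and np.isfinite(r_obs[k]))
        p = (1 + exceed[k]) / (1 + n_perm) if tested else np.nan
        raw_p.append(p if tested else 1.0)
        results.append((k, edges[k], edges[k + 1], int(memberships[k].sum()),
                        float(r_obs[k]) if tested else np.nan, p, tested))
    corrected = _holm_progressive(raw_p)
    return [
        CorrelogramClass(index=k, lower=lo_, upper=hi_, n_pairs=np_, mantel_r=r,
                         p=p, p_corrected=corrected[k] if t else np.nan, tested=t)
        for (k, lo_, hi_, np_, r, p, t) in results
    ]


# ---------------------------------------------------------------------------
# regression / correlation screens
# ---------------------------------------------------------------------------

@dataclass
class PairRegression:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n_pairs: int
    note: str = ("p-value is descriptive only: pairwise observations share "
                 "samples and are not independent")


def regress_bnti_env(bnti_pairs: pd.DataFrame, envdist: DistanceMatrix,
                     value_col: str = "bnti") -> PairRegression:
    """OLS of pairwise betaNTI (e.g. bootstrap means) on environmental distance."""
    idx = {s: i for i, s in enumerate(envdist.ids)}
    sub = bnti_pairs.dropna(subset=[value_col])
    if len(sub) < 3:
        raise ValidationError("need >= 3 pairs with defined betaNTI")
    x = np.array([envdist.data[idx[a], idx[b]]
                  for a, b in zip(sub["sample_a"], sub["sample_b"])])
    y = sub[value_col].to_numpy(dtype=float)
    res = stats.linregress(x, y)
    return PairRegression(slope=float(res.slope), intercept=float(res.intercept),
                          r_squared=float(res.rvalue ** 2), p=float(res.pvalue),
                          n_pairs=len(sub))


def env_correlations(metadata: SampleMetadata, variables=None) -> pd.DataFrame:
    """Pairwise Pearson correlations among environmental variables.

    Long frame (var_a, var_b, r, p, significant) over unordered pairs,
    two-sided t-test p, alpha 0.05.
    """
    env = metadata.env_matrix(variables)
    if len(env) < 3:
        raise ValidationError("need >= 3 samples")
    _zscore_columns(env.to_numpy(dtype=float), env.columns)  # constant check
    rows = []
    cols = list(env.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r, p = stats.pearsonr(env[a], env[b])
            rows.append((a, b, float(r), float(p), p < 0.05))
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r", "p", "significant"])


# ---------------------------------------------------------------------------
# ordination / PERMANOVA
# ---------------------------------------------------------------------------

def pcoa(d: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical principal-coordinate analysis (Gower's scaling).

    Double-centers -0.5 * d**2, eigendecomposes, and returns coordinates
    for positive eigenvalues (sorted descending) plus the full eigenvalue
    spectrum — negative eigenvalues are reported, their axes dropped.
    """
    a = -0.5 * d.data ** 2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    g = (g + g.T) / 2
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if np.allclose(d.data, 0):
        import warnings

        warnings.warn("all-zero distance matrix: coordinates are all zero")
        return (pd.DataFrame(np.zeros((n, 1)), index=list(d.ids), columns=["PC1"]),
                eigvals)
    pos = eigvals > max(1e-9 * abs(eigvals).max(), 0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=list(d.ids), columns=cols), eigvals


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p: float
    n_perm: int
    n_groups: int


def permanova(d: DistanceMatrix, groups, n_perm: int = 999, rng=None) -> PermanovaResult:
    """Single-factor PERMANOVA on a distance matrix.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums within-group pair terms
    scaled by group size; pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a));
    p by permutation of group labels.
    """
    rng = _as_rng(rng)
    labels = np.asarray(pd.Series(groups).reindex(list(d.ids)).to_numpy()
                        if isinstance(groups, (pd.Series, dict)) else list(groups))
    n = d.shape[0]
    if len(labels) != n:
        raise ValidationError("groups length must match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("need >= 2 groups")
    if np.any(counts < 2):
        singles = uniq[counts < 2].tolist()
        raise ValidationError(f"singleton group(s): {singles}")
    d2 = d.data ** 2
    a = len(uniq)

    def pseudo_f(lab):
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for g in uniq:
            idx = np.flatnonzero(lab == g)
            ss_within += d2[np.ix_(idx, idx)][np.triu_indices(idx.size, 1)].sum() / idx.size
        ss_between = ss_total - ss_within
        return (ss_between / (a - 1)) / (ss_within / (n - a)), ss_between / ss_total

    f_obs, r2 = pseudo_f(labels)
    exceed = 0
    for _ in range(n_perm):
        f_p, _ = pseudo_f(labels[rng.permutation(n)])
        exceed += f_p >= f_obs
    return PermanovaResult(pseudo_f=float(f_obs), r_squared=float(r2),
                           p=(1 + exceed) / (1 + n_perm), n_perm=n_perm, n_groups=a)
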