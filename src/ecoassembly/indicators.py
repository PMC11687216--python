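"""IndVal habitat-preference analysis with permutation testing.

For each OTU and site group g the group-equalized indicator value combines

* specificity  A = mean relative abundance in g / sum of group means, and
* fidelity     B = fraction of g's samples where the OTU occurs,

into stat = sqrt(A * B); the OTU's best group maximises stat. Significance
comes from permuting sample-to-group assignments (group sizes preserved).
Group-equalized means (the "IndVal.g" convention) are the default because
site groups along an estuarine transect are rarely balanced; the classic
unequalized variant is available via ``group_equalize=False``.

OTUs whose relative abundance is below ``min_relabund`` in every sample are
removed before testing — extremely rare taxa make habitat preference
unestimable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .io import OtuTable, ValidationError

__all__ = ["indval", "habitat_preference_counts"]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _indval_stats(rel, pres, group_idx, group_sizes, group_equalize):
    """stat matrix (n_otus x n_groups) from relative abundances and presence."""
    if group_equalize:
        means = np.stack([rel[:, idx].mean(axis=1) for idx in group_idx], axis=1)
    else:
        # classic IndVal: abundance summed over samples, unequalized
        means = np.stack([rel[:, idx].sum(axis=1) for idx in group_idx], axis=1)
    tot = means.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(tot > 0, means / np.where(tot > 0, tot, 1.0), 0.0)
    b = np.stack(
        [pres[:, idx].sum(axis=1) / sz for idx, sz in zip(group_idx, group_sizes)],
        axis=1,
    )
    return a, b, np.sqrt(a * b)


def indval(
    table: OtuTable,
    groups,
    n_perm: int = 999,
    min_relabund: float = 1e-4,
    rng=None,
    group_equalize: bool = True,
) -> pd.DataFrame:
    """Indicator-value analysis of every (sufficiently abundant) OTU.

    Parameters
    ----------
    groups : mapping sample_id -> group label
    min_relabund : float
        Pre-filter: drop OTUs below this relative abundance in all samples
        (default 1e-4, i.e. 0.01 %).

    Returns a frame with columns otu_id, best_group, A, B, stat, p, q
    (Benjamini-Hochberg over tested OTUs).
    """
    rng = _as_rng(rng)
    labels = pd.Series({s: groups[s] for s in table.sample_ids})
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValidationError("need >= 2 groups")
    group_idx = [np.flatnonzero((labels == g).to_numpy()) for g in uniq]
    group_sizes = np.array([idx.size for idx in group_idx])
    if np.any(group_sizes == 0):
        raise ValidationError("every group must contain >= 1 sample")

    rel = table.relative_abundance()
    keep = (rel >= min_relabund).any(axis=1)
    if not keep.any():
        return pd.DataFrame(columns=["otu_id", "best_group", "A", "B", "stat", "p", "q"])
    rel = rel[keep]
    pres = rel > 0
    otu_ids = [o for o, k in zip(table.otu_ids, keep) if k]

    a, b, stat = _indval_stats(rel, pres, group_idx, group_sizes, group_equalize)
    best = stat.argmax(axis=1)
    rows = np.arange(len(otu_ids))
    obs_stat = stat[rows, best]

    n_samples = table.n_samples
    exceed = np.zeros(len(otu_ids))
    for _ in range(n_perm):
        perm = rng.permutation(n_samples)
        gi = [perm[idx] for idx in group_idx]
        _, _, s = _indval_stats(rel, pres, gi, group_sizes, group_equalize)
        exceed += s.max(axis=1) >= obs_stat
    p = (1 + exceed) / (1 + n_perm)
    q = false_discovery_control(p, method="bh")

    return pd.DataFrame({
        "otu_id": otu_ids,
        "best_group": [uniq[i] for i in best],
        "A": a[rows, best],
        "B": b[rows, best],
        "stat": obs_stat,
        "p": p,
        "q": q,
    })


def habitat_preference_counts(records: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Per habitat, the number of OTUs significantly preferring it (raw p < alpha)."""
    out: dict = {}
    sig = records[records["p"] < alpha]
    for g, n in sig["best_group"].value_counts().items():
        out[g] = int(n)
    return out
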