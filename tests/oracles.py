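"""Independent brute-force oracles used to validate the optimised implementations.

Every function here is deliberately naive (explicit loops, per-pair path
walks, per-branch bookkeeping) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def cophenetic_brute(tree):
    """Tip-to-tip distances by explicit root-path walking (LCA subtraction)."""
    tips = list(tree.tips())
    paths = {}
    for tip in tips:
        path = []
        node = tip
        while node.parent is not None:
            path.append(node)
            node = node.parent
        paths[tip.name] = path  # tip -> root, excluding root
    names = [t.name for t in tips]
    n = len(names)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi = paths[names[i]]
            pj = paths[names[j]]
            seti = set(id(x) for x in pi)
            shared = next((x for x in pj if id(x) in seti), None)
            # distance = depth_i + depth_j - 2 * depth(LCA)
            di = sum(x.length for x in pi)
            dj = sum(x.length for x in pj)
            if shared is None:
                dl = 0.0
            else:
                anc = []
                node = shared
                while node.parent is not None:
                    anc.append(node.length)
                    node = node.parent
                dl = sum(anc)
            out[i, j] = out[j, i] = di + dj - 2 * dl
    return names, out


def bmntd_brute(abund_a: dict, abund_b: dict, dist: dict, weighted: bool = True) -> float:
    """Double-loop betaMNTD; ``dist`` maps (otu_i, otu_j) -> distance."""
    a_ids = [o for o, v in abund_a.items() if v > 0]
    b_ids = [o for o, v in abund_b.items() if v > 0]

    def d(i, j):
        return 0.0 if i == j else dist[(i, j)]

    def half(src_ids, src_ab, dst_ids):
        total = sum(src_ab[o] for o in src_ids)
        acc = 0.0
        for o in src_ids:
            nearest = min(d(o, t) for t in dst_ids)
            w = src_ab[o] / total if weighted else 1.0 / len(src_ids)
            acc += w * nearest
        return acc

    return 0.5 * (half(a_ids, abund_a, b_ids) + half(b_ids, abund_b, a_ids))


def bray_curtis_brute(x, y) -> float:
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


def weighted_unifrac_brute(tree, counts: dict, sample_a: str, sample_b: str,
                           normalized: bool) -> float:
    """Explicit per-branch descendant-mass bookkeeping.

    ``counts`` maps sample -> {otu: reads}.
    """
    tot_a = sum(counts[sample_a].values())
    tot_b = sum(counts[sample_b].values())
    num = 0.0
    den = 0.0
    for node in tree.traverse(include_self=False):
        length = node.length or 0.0
        tips_below = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        pa = sum(counts[sample_a].get(o, 0) for o in tips_below) / tot_a
        pb = sum(counts[sample_b].get(o, 0) for o in tips_below) / tot_b
        num += length * abs(pa - pb)
        den += length * (pa + pb)
    if normalized:
        return num / den if den > 0 else 0.0
    return num


def permanova_brute(d: np.ndarray, labels) -> tuple[float, float]:
    """pseudo-F and R^2 by direct evaluation of the sums of squares."""
    labels = np.asarray(labels)
    n = d.shape[0]
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    groups = sorted(set(labels))
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        acc = 0.0
        for ii, i in enumerate(idx):
            for j in idx[ii + 1:]:
                acc += d[i, j] ** 2
        ss_within += acc / len(idx)
    ss_between = ss_total - ss_within
    a = len(groups)
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


def pcoa_distances_brute(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances among ordination points."""
    n = coords.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.sqrt(((coords[i] - coords[j]) ** 2).sum())
    return out


def indval_brute(rel: np.ndarray, pres: np.ndarray, groups) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group-equalized IndVal A, B, stat for one OTU matrix (loops)."""
    labels = sorted(set(groups))
    n_otu = rel.shape[0]
    a = np.zeros((n_otu, len(labels)))
    b = np.zeros((n_otu, len(labels)))
    for gi, g in enumerate(labels):
        idx = [j for j, lab in enumerate(groups) if lab == g]
        for o in range(n_otu):
            a[o, gi] = np.mean([rel[o, j] for j in idx])
            b[o, gi] = np.mean([1.0 if pres[o, j] else 0.0 for j in idx])
    asum = a.sum(axis=1, keepdims=True)
    asum[asum == 0] = 1.0
    a = a / asum
    return a, b, np.sqrt(a * b)
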