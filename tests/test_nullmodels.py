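import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from ecoassembly import (
    OtuTable,
    beta_nti_matrix,
    bray_curtis,
    cophenetic_distances,
    rc_bray_matrix,
    taxa_shuffle,
)
from .conftest import random_table, random_tree
from .oracles import bray_curtis_brute


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "x,y,expected",
        [((5, 5), (5, 5), 0.0), ((10, 0), (0, 10), 1.0), ((6, 2), (2, 2), 4 / 12)],
    )
    def test_hand_evaluated_pairs(self, x, y, expected):
        table = OtuTable(np.array([x, y]).T, ["o1", "o2"], ["A", "B"])
        assert bray_curtis(table)["A", "B"] == pytest.approx(expected)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        table = random_table(rng, 10, 5)
        dm = bray_curtis(table)
        for i, j in itertools.combinations(range(5), 2):
            ref = bray_curtis_brute(table.counts[:, i], table.counts[:, j])
            assert dm[i, j] == pytest.approx(ref, abs=1e-12)


class TestTaxaShuffle:
    def test_preserves_multiset_and_symmetry(self):
        rng = np.random.default_rng(1)
        tree = random_tree(rng, 8)
        dm = cophenetic_distances(tree)
        sh = taxa_shuffle(dm, rng)
        assert sorted(sh.condensed_form()) == pytest.approx(sorted(dm.condensed_form()))
        assert np.all(np.diag(sh.data) == 0)
        assert np.allclose(sh.data, sh.data.T)

    def test_uniform_over_permutations(self):
        # 4 tips -> 24 permutations; with distinct pairwise distances each
        # permutation of the matrix is identifiable by its flattened values
        base = np.array(
            [[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6], [3, 5, 6, 0]], dtype=float
        )
        dm = DistanceMatrix(base, ids=list("abcd"))
        rng = np.random.default_rng(0)
        seen = {}
        n = 2400
        for _ in range(n):
            key = taxa_shuffle(dm, rng).data.tobytes()
            seen[key] = seen.get(key, 0) + 1
        assert len(seen) == 24
        freqs = np.array(list(seen.values())) / n
        assert np.all(np.abs(freqs - 1 / 24) < 0.02)


def _exhaustive_bnti(table, dm):
    """Exact null over all permutations of <= 6 taxa (oracle)."""
    from ecoassembly.phylo import beta_mntd

    ids = list(dm.ids)
    rel = table.relative_abundance()
    comm = [
        {o: rel[i, j] for i, o in enumerate(table.otu_ids)}
        for j in range(table.n_samples)
    ]
    obs = beta_mntd(comm[0], comm[1], dm)
    nulls = []
    for perm in itertools.permutations(range(len(ids))):
        data = dm.data[np.ix_(perm, perm)]
        nulls.append(beta_mntd(comm[0], comm[1], DistanceMatrix(data, ids=ids)))
    nulls = np.array(nulls)
    return (obs - nulls.mean()) / nulls.std(ddof=1)


class TestBetaNti:
    def test_clade_separation_forces_positive_sign(self):
        tree = TreeNode.read(["(((a:.1,b:.1):2,(c:.1,d:.1):2):1,(e:.1,f:.1):3);"])
        dm = cophenetic_distances(tree)
        counts = np.zeros((6, 2), dtype=int)
        ids = list(dm.ids)
        counts[[ids.index("a"), ids.index("b")], 0] = 10
        counts[[ids.index("e"), ids.index("f")], 1] = 10
        table = OtuTable(counts, ids, ["A", "B"])
        exact = _exhaustive_bnti(table, dm)
        assert exact > 0
        res = beta_nti_matrix(table, dm, n_null=999, rng=0)
        assert res.loc[0, "bnti"] > 0
        # Monte-Carlo estimate close to the exhaustive-permutation value
        assert res.loc[0, "bnti"] == pytest.approx(exact, abs=0.6)

    def test_identical_samples_undefined(self, toy_tree):
        counts = np.array([[3, 3], [2, 2], [5, 5]])
        table = OtuTable(counts, ["a", "b", "c"], ["A", "B"])
        res = beta_nti_matrix(table, cophenetic_distances(toy_tree), n_null=99, rng=0)
        assert res.loc[0, "null_sd"] == 0
        assert np.isnan(res.loc[0, "bnti"])

    def test_self_null_calibration(self):
        # data generated by the null: tip labels randomly reassigned before
        # "observation" -> betaNTI should be ~N(0, 1)
        rng = np.random.default_rng(12)
        tree = random_tree(rng, 20)
        dm = cophenetic_distances(tree)
        zs = []
        for _ in range(40):
            table = random_table(rng, 20, 2)
            table = OtuTable(table.counts, list(dm.ids), table.sample_ids)
            shuffled = taxa_shuffle(dm, rng)
            res = beta_nti_matrix(table, shuffled, n_null=299, rng=rng)
            if not np.isnan(res.loc[0, "bnti"]):
                zs.append(res.loc[0, "bnti"])
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.35
        assert 0.7 < zs.std(ddof=1) < 1.3

    def test_reproducible_and_label_invariant(self):
        rng = np.random.default_rng(8)
        tree = random_tree(rng, 10)
        dm = cophenetic_distances(tree)
        table = random_table(rng, 10, 4)
        table = OtuTable(table.counts, list(dm.ids), table.sample_ids)
        r1 = beta_nti_matrix(table, dm, n_null=199, rng=42)
        r2 = beta_nti_matrix(table, dm, n_null=199, rng=42)
        assert r1.equals(r2)
        # consistent renaming of OTUs across table and matrix changes nothing
        renamed = {o: f"x_{o}" for o in dm.ids}
        dm2 = DistanceMatrix(dm.data, ids=[renamed[o] for o in dm.ids])
        table2 = OtuTable(table.counts, [renamed[o] for o in table.otu_ids],
                          table.sample_ids)
        r3 = beta_nti_matrix(table2, dm2, n_null=199, rng=42)
        np.testing.assert_allclose(r1["bnti"], r3["bnti"])

    def test_per_pair_mode_close_to_shared_mode(self):
        rng = np.random.default_rng(21)
        tree = random_tree(rng, 15)
        dm = cophenetic_distances(tree)
        table = random_table(rng, 15, 3)
        table = OtuTable(table.counts, list(dm.ids), table.sample_ids)
        shared = beta_nti_matrix(table, dm, n_null=499, rng=1, shared_null=True)
        perpair = beta_nti_matrix(table, dm, n_null=499, rng=1, shared_null=False)
        np.testing.assert_allclose(shared["bmntd_obs"], perpair["bmntd_obs"])
        np.testing.assert_allclose(shared["null_mean"], perpair["null_mean"], rtol=0.25)


class TestRcBray:
    def test_extreme_bounds(self):
        rng = np.random.default_rng(4)
        # two wildly divergent samples among a pool -> obs BC >= all nulls
        counts = np.zeros((20, 2), dtype=int)
        counts[:10, 0] = 50
        counts[10:, 1] = 50
        table = OtuTable(counts, [f"o{i}" for i in range(20)], ["A", "B"])
        res = rc_bray_matrix(table, n_null=199, rng=rng)
        assert res.loc[0, "rc"] == pytest.approx(1.0)

    def test_identical_pair_near_minus_one(self):
        # obs BC = 0: no null can be smaller; ties (null BC = 0) are rare
        # once the pool is large enough for null fills to differ
        rng = np.random.default_rng(6)
        col = rng.integers(5, 40, size=12)
        counts = np.tile(col[:, None], (1, 2))
        table = OtuTable(counts, [f"o{i}" for i in range(12)], ["A", "B"])
        res = rc_bray_matrix(table, n_null=199, rng=0)
        assert res.loc[0, "rc"] <= -1 + 4 / 199

    def test_bounds_and_determinism(self):
        rng = np.random.default_rng(9)
        table = random_table(rng, 15, 5, depth=100)
        r1 = rc_bray_matrix(table, n_null=199, rng=3)
        r2 = rc_bray_matrix(table, n_null=199, rng=3)
        assert r1.equals(r2)
        assert np.all(r1["rc"].abs() <= 1)

    def test_self_null_calibration(self):
        # pairs generated by the null procedure itself -> RC mean ~ 0
        from ecoassembly.nullmodels import _null_assemblies

        rng = np.random.default_rng(30)
        base = random_table(rng, 25, 8, depth=300)
        occ = base.occupancy().astype(float)
        pool = base.counts.sum(axis=1) / base.counts.sum()
        with np.errstate(divide="ignore"):
            log_occ = np.log(occ)
        rcs = []
        for _ in range(50):
            a = _null_assemblies(rng, 1, 12, 300, log_occ, pool)[0]
            b = _null_assemblies(rng, 1, 12, 300, log_occ, pool)[0]
            counts = base.counts.copy()
            counts[:, 0] = a
            counts[:, 1] = b
            tab = OtuTable(counts, base.otu_ids, base.sample_ids)
            res = rc_bray_matrix(tab, n_null=199, rng=rng)
            rcs.append(res.loc[0, "rc"])
        assert abs(np.mean(rcs)) < 0.25
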