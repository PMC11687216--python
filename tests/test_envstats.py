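import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from ecoassembly import (
    OtuTable,
    SampleMetadata,
    ValidationError,
    cophenetic_distances,
    env_correlations,
    env_distance,
    geo_distance,
    mantel,
    niche_values,
    pcoa,
    permanova,
    phylo_signal_correlogram,
    regress_bnti_env,
    simulate_tree,
    evolve_niche_bm,
    niche_conservatism_transform,
)
from .conftest import random_table, random_tree
from .oracles import pcoa_distances_brute, permanova_brute


def _random_dm(rng, n):
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    return DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])


class TestEnvDistance:
    def test_identical_rows_zero_and_zscore_contract(self, toy_metadata):
        d = env_distance(toy_metadata)
        assert np.all(np.diag(d.data) == 0)
        env = toy_metadata.env_matrix().to_numpy()
        z = (env - env.mean(0)) / env.std(0, ddof=1)
        assert np.allclose(z.mean(0), 0, atol=1e-9)
        assert np.allclose(z.std(0, ddof=1), 1, atol=1e-9)

    def test_two_sites_one_variable(self):
        frame = pd.DataFrame(
            {
                "season": ["summer"] * 2, "layer": ["surface"] * 2,
                "fraction": ["DNA"] * 2, "latitude": [22.0, 22.1],
                "longitude": [113.0] * 2, "salinity": [10.0, 20.0],
            },
            index=pd.Index(["a", "b"], name="sample_id"),
        )
        d = env_distance(SampleMetadata(frame), ["salinity"])
        # z-scores are +-1/sqrt(2)... with ddof=1 sd: z = +-0.7071 -> distance 1.4142
        assert d["a", "b"] == pytest.approx(np.sqrt(2))

    def test_constant_variable_is_named(self, toy_metadata):
        toy_metadata.frame["flat"] = 1.0
        meta = SampleMetadata(toy_metadata.frame)
        with pytest.raises(ValidationError, match="flat"):
            env_distance(meta)


class TestGeoDistance:
    def test_haversine_one_degree_longitude_at_equator(self):
        frame = pd.DataFrame(
            {
                "season": ["s"] * 2, "layer": ["l"] * 2, "fraction": ["DNA"] * 2,
                "latitude": [0.0, 0.0], "longitude": [0.0, 1.0],
                "salinity": [1.0, 2.0],
            },
            index=pd.Index(["a", "b"], name="sample_id"),
        )
        d = geo_distance(SampleMetadata(frame))
        assert d["a", "b"] == pytest.approx(111.19, abs=0.01)

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(
            {
                "season": ["s"] * 3, "layer": ["l"] * 3, "fraction": ["DNA"] * 3,
                "latitude": rng.uniform(-60, 60, 3),
                "longitude": rng.uniform(-170, 170, 3),
                "salinity": [1.0, 2.0, 3.0],
            },
            index=pd.Index(["a", "b", "c"], name="sample_id"),
        )
        d = geo_distance(SampleMetadata(frame)).data
        assert np.allclose(d, d.T)
        assert d[0, 1] + d[1, 2] >= d[0, 2] - 1e-9


class TestMantel:
    def test_self_correlation_and_minimal_p(self):
        rng = np.random.default_rng(0)
        d = _random_dm(rng, 8)
        r, p = mantel(d, d, n_perm=199, rng=rng)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        d = _random_dm(rng, 7)
        d2 = DistanceMatrix(2.5 * d.data + 1 - np.eye(7), ids=d.ids)
        r, _ = mantel(d, d2, n_perm=99, rng=rng)
        assert r == pytest.approx(1.0)

    def test_agrees_with_skbio(self):
        rng = np.random.default_rng(2)
        d1, d2 = _random_dm(rng, 9), _random_dm(rng, 9)
        r, _ = mantel(d1, d2, n_perm=99, rng=rng)
        r_ref, _, _ = skbio_mantel(d1, d2, permutations=0)
        assert r == pytest.approx(r_ref, abs=1e-12)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(60):
            d1, d2 = _random_dm(rng, 8), _random_dm(rng, 8)
            _, p = mantel(d1, d2, n_perm=99, rng=rng)
            ps.append(p)
        # one-sided p under independence: roughly uniform
        assert 0.25 < np.mean(ps) < 0.75


class TestNicheValues:
    def test_weighted_mean_and_occupancy_filter(self, toy_metadata):
        # equal library sizes so relative abundances mirror raw counts
        counts = np.array([[10, 10, 0, 0], [0, 5, 10, 5], [0, 0, 0, 3], [10, 5, 10, 12]])
        table = OtuTable(counts, ["o1", "o2", "o3", "o4"], toy_metadata.sample_ids)
        nv = niche_values(table, toy_metadata, variables=["salinity"], occupancy_min=4)
        # o1 sits evenly in s1+s2 -> mean of their salinities
        assert nv.loc["o1", "salinity"] == pytest.approx((0.2 + 6.0) / 2)
        # o3 in one sample only -> that sample's value, excluded from testing
        assert nv.loc["o3", "salinity"] == pytest.approx(33.0)
        assert not nv.loc["o3", "tested"]
        assert not nv.loc["o2", "tested"]   # occupancy 3 excluded at default
        assert nv.loc["o4", "tested"]       # occupancy 4 retained


class TestCorrelogram:
    @staticmethod
    def _niche_frame(tree, values, occupancy=5):
        ids = [t.name for t in tree.tips()]
        return pd.DataFrame(
            {"occupancy": occupancy, "niche": [values[o] for o in ids], "tested": True},
            index=ids,
        )

    def test_brownian_signal_in_shortest_class(self):
        hits = 0
        for seed in range(4):
            tree = simulate_tree(40, seed)
            conserved = niche_conservatism_transform(tree, 0.2)
            vals = evolve_niche_bm(conserved, 2.0, 0.0, seed)
            niches = self._niche_frame(tree, vals)
            classes = phylo_signal_correlogram(
                niches, cophenetic_distances(tree), n_classes=5, n_perm=199,
                rng=np.random.default_rng(seed),
            )
            first = next(c for c in classes if c.tested)
            if first.mantel_r > 0 and first.p < 0.05:
                hits += 1
        assert hits >= 3

    def test_permuted_niches_rarely_significant(self):
        rng = np.random.default_rng(7)
        false_pos = 0
        reps = 20
        for seed in range(reps):
            tree = simulate_tree(30, seed)
            ids = [t.name for t in tree.tips()]
            vals = dict(zip(ids, rng.permutation(np.linspace(0, 1, len(ids)))))
            niches = self._niche_frame(tree, vals)
            classes = phylo_signal_correlogram(
                niches, cophenetic_distances(tree), n_classes=4, n_perm=199, rng=rng
            )
            if any(c.tested and c.p_corrected < 0.05 for c in classes):
                false_pos += 1
        assert false_pos <= reps * 0.25

    def test_classes_partition_all_pairs(self):
        tree = simulate_tree(25, 3)
        ids = [t.name for t in tree.tips()]
        rng = np.random.default_rng(0)
        vals = dict(zip(ids, rng.normal(size=len(ids))))
        niches = self._niche_frame(tree, vals)
        classes = phylo_signal_correlogram(
            niches, cophenetic_distances(tree), n_classes=6, n_perm=99, rng=rng
        )
        assert sum(c.n_pairs for c in classes) == len(ids) * (len(ids) - 1) // 2
        for c in classes:
            if c.tested:
                assert c.p_corrected >= c.p - 1e-12  # Holm is monotone


class TestRegression:
    def _pairs(self, envd, values):
        ids = list(envd.ids)
        rows = []
        k = 0
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rows.append((ids[i], ids[j], values[k]))
                k += 1
        return pd.DataFrame(rows, columns=["sample_a", "sample_b", "bnti"])

    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(0)
        envd = _random_dm(rng, 6)
        x = envd.condensed_form()
        pairs = self._pairs(envd, 1.5 * x - 0.4)
        reg = regress_bnti_env(pairs, envd)
        assert reg.slope == pytest.approx(1.5)
        assert reg.intercept == pytest.approx(-0.4)
        assert reg.r_squared == pytest.approx(1.0)

    def test_constant_bnti_zero_slope(self):
        rng = np.random.default_rng(1)
        envd = _random_dm(rng, 5)
        reg = regress_bnti_env(self._pairs(envd, np.full(10, 1.3)), envd)
        assert reg.slope == pytest.approx(0.0, abs=1e-12)


class TestEnvCorrelations:
    def test_hand_checked_pearson(self, toy_metadata):
        out = env_correlations(toy_metadata)
        row = out[(out.var_a == "salinity") & (out.var_b == "NO3")].iloc[0]
        x = toy_metadata.frame["salinity"]
        y = toy_metadata.frame["NO3"]
        ref = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert row.r == pytest.approx(ref)
        assert row.r < 0  # nutrients anticorrelate with salinity


class TestPcoa:
    def test_recovers_line_geometry(self):
        d = DistanceMatrix(
            np.abs(np.subtract.outer([0.0, 1.0, 3.0], [0.0, 1.0, 3.0])),
            ids=["a", "b", "c"],
        )
        coords, eigvals = pcoa(d)
        rec = pcoa_distances_brute(coords.to_numpy())
        np.testing.assert_allclose(rec, d.data, atol=1e-9)
        assert eigvals[0] > 0

    def test_gower_property_nonnegative_eigenvalues(self):
        rng = np.random.default_rng(2)
        d = _random_dm(rng, 7)  # Euclidean-embeddable by construction
        _, eigvals = pcoa(d)
        assert np.all(eigvals > -1e-9)

    def test_agrees_with_skbio(self):
        rng = np.random.default_rng(4)
        d = _random_dm(rng, 8)
        coords, _ = pcoa(d)
        ref = skbio_pcoa(d, method="eigh").samples.to_numpy()
        k = min(coords.shape[1], 4)
        for ax in range(k):  # axes defined up to sign
            ours, theirs = coords.to_numpy()[:, ax], ref[:, ax]
            assert min(np.abs(ours - theirs).max(), np.abs(ours + theirs).max()) < 1e-6

    def test_zero_matrix_warns_and_returns_zeros(self):
        d = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        with pytest.warns(UserWarning):
            coords, _ = pcoa(d)
        assert np.allclose(coords.to_numpy(), 0)


class TestPermanova:
    def test_block_structure_matches_enumeration(self):
        d = np.ones((6, 6)) - np.eye(6)
        d[np.ix_([0, 1, 2], [0, 1, 2])] = 0
        d[np.ix_([3, 4, 5], [3, 4, 5])] = 0
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
        groups = ["g1"] * 3 + ["g2"] * 3
        res = permanova(dm, groups, n_perm=199, rng=0)
        f_ref, r2_ref = permanova_brute(d, groups)
        assert res.pseudo_f == pytest.approx(f_ref)
        assert res.r_squared == pytest.approx(r2_ref)
        assert 0 <= res.r_squared <= 1

    def test_agrees_with_skbio_statistic(self):
        rng = np.random.default_rng(6)
        d = _random_dm(rng, 9)
        groups = ["a"] * 4 + ["b"] * 3 + ["c"] * 2
        res = permanova(d, groups, n_perm=99, rng=rng)
        ref = skbio_permanova(d, groups, permutations=9)
        assert res.pseudo_f == pytest.approx(ref["test statistic"], abs=1e-9)

    def test_singleton_group_rejected(self):
        rng = np.random.default_rng(1)
        d = _random_dm(rng, 5)
        with pytest.raises(ValidationError, match="singleton"):
            permanova(d, ["a", "a", "a", "a", "b"], n_perm=99, rng=0)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(60):
            d = _random_dm(rng, 8)
            groups = list(rng.permutation(["a"] * 4 + ["b"] * 4))
            ps.append(permanova(d, groups, n_perm=99, rng=rng).p)
        assert 0.25 < np.mean(ps) < 0.75
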