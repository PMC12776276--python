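import numpy as np
import pytest

from retinotopo.spatial_stats import (
    SpatialStat,
    bh_adjust,
    build_weights,
    cosine_similarity,
    group_anchors,
    is_pattern_similar,
    moran_scan,
    morans_I,
    morans_test,
    pearson_spatial,
    select_anchors,
)
from retinotopo.topo_grid import GeneMap


def gmap(values, gene="g"):
    return GeneMap(gene=gene, values=np.asarray(values, dtype=float))


def brute_force_moran(values, valid, neighborhood="queen"):
    """O(n²) double-loop evaluation of Moran's I on a masked lattice."""
    nr, nc = values.shape
    pts = [(i, j) for i in range(nr) for j in range(nc) if valid[i, j]]
    x = np.array([values[i, j] for i, j in pts])
    z = x - x.mean()
    num = 0.0
    W = 0.0
    for a, (i1, j1) in enumerate(pts):
        for b, (i2, j2) in enumerate(pts):
            if a == b:
                continue
            di, dj = abs(i1 - i2), abs(j1 - j2)
            adj = (max(di, dj) == 1) if neighborhood == "queen" else (di + dj == 1)
            if adj:
                num += z[a] * z[b]
                W += 1
    return len(pts) / W * num / (z @ z)


class TestMoransI:
    def test_checkerboard_rook_is_minus_one(self):
        vals = np.array([[1.0, -1.0], [-1.0, 1.0]])
        w = build_weights(np.ones((2, 2), dtype=bool), neighborhood="rook")
        assert morans_I(gmap(vals), w) == pytest.approx(-1.0)

    def test_matches_brute_force_on_random_masked_fields(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            valid = rng.random((6, 6)) > 0.3
            if valid.sum() < 4:
                continue
            vals = np.where(valid, rng.normal(size=(6, 6)), np.nan)
            w = build_weights(valid)
            if w.W == 0:
                continue
            expected = brute_force_moran(vals, valid)
            assert morans_I(gmap(vals), w) == pytest.approx(expected, abs=1e-12)

    def test_null_expectation_minus_one_over_n_minus_1(self):
        rng = np.random.default_rng(1)
        w = build_weights(np.ones((6, 6), dtype=bool))
        draws = [morans_I(gmap(rng.normal(size=(6, 6))), w) for _ in range(400)]
        assert np.mean(draws) == pytest.approx(-1 / 35, abs=0.01)

    def test_constant_field_is_error_not_zero(self):
        w = build_weights(np.ones((3, 3), dtype=bool))
        with pytest.raises(ValueError, match="zero variance"):
            morans_I(gmap(np.ones((3, 3))), w)


class TestMoransTest:
    def test_negative_autocorrelation_gives_p_one(self):
        vals = np.indices((6, 6)).sum(axis=0) % 2 * 2.0 - 1.0  # checkerboard
        w = build_weights(np.ones((6, 6), dtype=bool), neighborhood="rook")
        st = morans_test(gmap(vals), w, n_perm=99, seed=0)
        assert st.p_value == 1.0

    def test_strong_gradient_hits_minimum_p(self):
        vals = np.tile(np.arange(8, dtype=float), (8, 1))
        w = build_weights(np.ones((8, 8), dtype=bool))
        st = morans_test(gmap(vals), w, n_perm=999, seed=0)
        assert st.p_value == pytest.approx(1 / 1000)

    def test_type_I_calibration_on_exchangeable_null(self):
        """iid values on the lattice are exchangeable: rejections at alpha=0.01
        must fall in the 99% binomial acceptance region over 500 fields."""
        from scipy.stats import binom

        rng = np.random.default_rng(3)
        w = build_weights(np.ones((12, 12), dtype=bool))
        maps = [gmap(rng.normal(size=(12, 12)), gene=f"n{k}") for k in range(500)]
        stats = moran_scan(maps, w, n_perm=199, seed=0)
        rej = sum(s.p_value <= 0.01 for s in stats)
        assert binom.ppf(0.005, 500, 0.01) <= rej <= binom.ppf(0.995, 500, 0.01)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(6, 6))
        w = build_weights(np.ones((6, 6), dtype=bool))
        a = morans_test(gmap(vals), w, n_perm=199, seed=9)
        b = morans_test(gmap(vals), w, n_perm=199, seed=9)
        assert a.p_value == b.p_value


class TestBH:
    def test_all_equal_p_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.03] * 5), 0.03)

    def test_stepup_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestSimilarity:
    def test_identical_maps_cosine_one(self):
        v = np.random.default_rng(0).random((4, 4))
        assert cosine_similarity(gmap(v), gmap(v)) == pytest.approx(1.0)

    def test_disjoint_support_cosine_zero(self):
        a = np.array([[1.0, 0.0], [0.0, 0.0]])
        b = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert cosine_similarity(gmap(a), gmap(b)) == pytest.approx(0.0)

    def test_hand_computed_cosine(self):
        a = np.array([[1.0, 2.0, 2.0]])
        b = np.array([[2.0, 1.0, 2.0]])
        assert cosine_similarity(gmap(a), gmap(b)) == pytest.approx(8 / 9)

    def test_pearson_affine_invariance(self):
        v = np.random.default_rng(1).random((4, 4))
        r, p = pearson_spatial(gmap(v), gmap(2 * v + 1))
        assert r == pytest.approx(1.0)
        r, _ = pearson_spatial(gmap(v), gmap(-v))
        assert r == pytest.approx(-1.0)

    def test_similarity_flag_requires_both_thresholds(self):
        # r just above 0.9 with tiny p → similar; same r with p > 0.001 → not
        assert is_pattern_similar(0.91, 1e-5)
        assert not is_pattern_similar(0.91, 0.005)
        assert not is_pattern_similar(0.85, 1e-9)


def archetype_maps(G=20, noise=0.0, rng=None):
    """Five mutually dissimilar patterns on a fully valid G×G grid."""
    i, j = np.mgrid[0:G, 0:G]
    u = 2 * j / (G - 1) - 1
    v = 2 * i / (G - 1) - 1
    base = {
        "dorsal": (v + 1) / 2,
        "ventral": (1 - v) / 2,
        "nasal": (u + 1) / 2,
        "spot": np.exp(-((u - 0.3) ** 2 + v**2) / (2 * 0.2**2)),
        "stripe": np.exp(-((u * 0.5 + v * 0.866) ** 2) / (2 * 0.2**2)),
    }
    if noise and rng is not None:
        return {k: w + rng.normal(0, noise, w.shape) for k, w in base.items()}
    return base


class TestAnchors:
    def _stats_and_maps(self, fields):
        w = build_weights(np.ones(next(iter(fields.values())).shape, dtype=bool))
        maps = {g: gmap(v, gene=g) for g, v in fields.items()}
        stats = moran_scan(list(maps.values()), w, n_perm=999, seed=0)
        return stats, maps

    def test_single_significant_gene_is_sole_anchor(self):
        fields = {"only": archetype_maps()["dorsal"]}
        stats, maps = self._stats_and_maps(fields)
        aset = select_anchors(stats, maps, A_max=20, tau_redundancy=0.9)
        assert aset.anchors == ["only"]

    def test_three_archetypes_with_duplicates(self):
        rng = np.random.default_rng(0)
        base = archetype_maps()
        fields = {}
        for name in ("dorsal", "ventral", "spot"):
            fields[name] = base[name]
            for d in range(3):
                fields[f"{name}_dup{d}"] = base[name] + rng.normal(0, 0.02, base[name].shape)
        stats, maps = self._stats_and_maps(fields)
        aset = select_anchors(stats, maps, A_max=20, tau_redundancy=0.9)
        assert len(aset.anchors) == 3
        archetype_of = lambda g: g.split("_")[0]
        assert {archetype_of(a) for a in aset.anchors} == {"dorsal", "ventral", "spot"}
        for g, row in aset.assignment.iterrows():
            assert archetype_of(row["anchor"]) == archetype_of(g)

    def test_a_max_caps_anchor_count(self):
        # 30 mutually dissimilar patterns: distinct one-hot blocks
        rng = np.random.default_rng(1)
        fields = {}
        for k in range(30):
            v = rng.normal(0, 0.01, (12, 12))
            v[(k // 6) * 2: (k // 6) * 2 + 2, (k % 6) * 2: (k % 6) * 2 + 2] = 5.0
            fields[f"p{k:02d}"] = v
        stats, maps = self._stats_and_maps(fields)
        aset = select_anchors(stats, maps, A_max=20, tau_redundancy=0.9)
        assert len(aset.anchors) == 20

    def test_anchor_pairwise_similarity_below_tau(self):
        rng = np.random.default_rng(2)
        base = archetype_maps()
        fields = {k: v + rng.normal(0, 0.02, v.shape) for k, v in base.items()}
        stats, maps = self._stats_and_maps(fields)
        aset = select_anchors(stats, maps, A_max=20, tau_redundancy=0.9)
        for a in aset.anchors:
            for b in aset.anchors:
                if a != b:
                    assert cosine_similarity(maps[a], maps[b]) < 0.9

    def test_no_significant_genes_errors(self):
        stats = [SpatialStat(gene="x", I=0.5, n=10, p_value=0.5, significant=False)]
        with pytest.raises(ValueError, match="significant"):
            select_anchors(stats, {}, A_max=5, tau_redundancy=0.9)


class TestGroupAnchors:
    def _benchmark(self, tau=0.97):
        """5 archetypes, two of which (spotA/spotB) are near-duplicates, each
        with noisy duplicate members."""
        G = 20
        i, j = np.mgrid[0:G, 0:G]
        u = 2 * j / (G - 1) - 1
        v = 2 * i / (G - 1) - 1
        spot = lambda cu: np.exp(-((u - cu) ** 2 + v**2) / (2 * 0.25**2))
        # centered gradients so only the two spots are mutual nearest anchors
        base = {
            "dorsal": v,
            "ventral": -v,
            "nasal": u,
            "spotA": spot(0.28),
            "spotB": spot(0.44),
        }
        rng = np.random.default_rng(4)
        fields = {}
        for name, f in base.items():
            fields[name] = f
            for d in range(2):
                fields[f"{name}_dup{d}"] = f + rng.normal(0, 0.005, f.shape)
        w = build_weights(np.ones((G, G), dtype=bool))
        maps = {g: gmap(x, gene=g) for g, x in fields.items()}
        stats = moran_scan(list(maps.values()), w, n_perm=999, seed=0)
        aset = select_anchors(stats, maps, A_max=20, tau_redundancy=tau)
        return aset, maps

    def test_mutual_nn_pair_merges_into_four_groups(self):
        aset, maps = self._benchmark(tau=0.97)
        assert len(aset.anchors) == 5
        aset = group_anchors(aset, maps)
        assert len(aset.anchor_groups) == 4
        merged = [g for g in aset.anchor_groups if len(g) == 2]
        assert len(merged) == 1
        assert {a.split("_")[0][:4] for a in merged[0]} == {"spot"}

    def test_anchor_without_members_forms_no_cluster(self):
        base = archetype_maps()
        fields = {"dorsal": base["dorsal"], "spot": base["spot"]}
        w = build_weights(np.ones((20, 20), dtype=bool))
        maps = {g: gmap(v, gene=g) for g, v in fields.items()}
        stats = moran_scan(list(maps.values()), w, n_perm=999, seed=0)
        aset = select_anchors(stats, maps, A_max=5, tau_redundancy=0.9)
        aset = group_anchors(aset, maps)
        # no members → no cluster-forming anchors → no merges
        assert all(len(g) == 1 for g in aset.anchor_groups)
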