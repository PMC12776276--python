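import itertools

import numpy as np
import pytest
from scipy.cluster import hierarchy

from retinotopo.profile_tools import (
    Profile1D,
    ProfileMatrix,
    axis_profile_from_cells,
    cluster_profiles,
    cross_modal_compare,
    dendrogram_to_newick,
    interpolate_to_common_axis,
    masked_pearson,
    profile_correlation_matrix,
)


def prof(positions, mean, label="p"):
    positions = np.asarray(positions, dtype=float)
    mean = np.asarray(mean, dtype=float)
    return Profile1D(
        positions=positions,
        mean=mean,
        spread=np.zeros_like(mean),
        coverage=np.ones(len(mean), dtype=int),
        label=label,
    )


class TestAxisProfiles:
    def test_default_bin_count_is_50(self, small_bench):
        bundle, scores, _ = small_bench
        p = axis_profile_from_cells(scores, bundle.dataset, "Tbx5", "DV")
        assert len(p.positions) == 50

    def test_constant_gene_gives_flat_profile(self, small_bench):
        bundle, scores, _ = small_bench
        # DECOY genes are flat in space; profile varies only by noise — use
        # a synthetic constant column instead for exactness
        import scipy.sparse as sp
        from conftest import make_toy_dataset
        from retinotopo.io_core import normalize_counts
        from retinotopo.axis_scoring import AxisScores
        import pandas as pd

        ds = make_toy_dataset(np.full((100, 2), 7))
        normalize_counts(ds)
        rng = np.random.default_rng(0)
        dv = rng.random(100)
        table = pd.DataFrame(
            {"dorsal_score": dv, "ventral_score": 0, "nasal_score": dv,
             "temporal_score": 0, "dv_score": dv, "nt_score": dv},
            index=pd.Index(ds.cells, name="cell_id"),
        )
        sc = AxisScores(table=table, rng_seed=0, n_bins=24, n_ctrl=100)
        p = axis_profile_from_cells(sc, ds, "g0", "DV", n_bins=5, min_cells=0)
        vals = p.mean[np.isfinite(p.mean)]
        assert np.allclose(vals, vals[0])

    def test_low_confidence_threshold_is_strictly_more_than(self, small_bench):
        """A bin with exactly min_cells cells is flagged; one more is not."""
        bundle, scores, _ = small_bench
        p = axis_profile_from_cells(scores, bundle.dataset, "Tbx5", "NT", min_cells=50)
        at = p.coverage == 50
        above = p.coverage == 51
        assert np.all(p.low_confidence[at]) if at.any() else True
        assert not np.any(p.low_confidence[above])
        # definitional check independent of data
        np.testing.assert_array_equal(p.low_confidence, p.coverage <= 50)

    def test_unknown_gene_errors(self, small_bench):
        bundle, scores, _ = small_bench
        with pytest.raises(KeyError):
            axis_profile_from_cells(scores, bundle.dataset, "NOPE", "DV")


class TestInterpolation:
    def test_identity_on_common_axis(self):
        a = prof([0, 1, 2], [5, 6, 7], "a")
        b = prof([0, 1, 2], [1, 1, 1], "b")
        pm = interpolate_to_common_axis([a, b], step=1.0)
        np.testing.assert_allclose(pm.row("a"), [5, 6, 7])

    def test_midpoint_of_a_line(self):
        a = prof([0, 2], [0, 10], "a")
        b = prof([0, 2], [0, 0], "b")
        pm = interpolate_to_common_axis([a, b], step=1.0)
        assert pm.row("a")[1] == pytest.approx(5.0)

    def test_no_extrapolation(self):
        a = prof([0, 2], [0, 10], "a")
        b = prof([-1, 3], [1, 1], "b")
        pm = interpolate_to_common_axis([a, b], step=1.0)
        assert np.isnan(pm.row("a")[0])  # position -1 outside a's range
        assert np.isfinite(pm.row("b")[0])


class TestCorrelationMatrix:
    def test_duplicated_row_correlates_one(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=10)
        pm = ProfileMatrix(genes=["a", "b"], positions=np.arange(10.0), values=np.vstack([v, v]))
        corr = profile_correlation_matrix(pm)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_negated_row_correlates_minus_one(self):
        v = np.random.default_rng(1).normal(size=10)
        pm = ProfileMatrix(genes=["a", "b"], positions=np.arange(10.0), values=np.vstack([v, -v]))
        assert profile_correlation_matrix(pm).loc["a", "b"] == pytest.approx(-1.0)

    def test_masked_pearson_over_joint_positions_only(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        b = np.array([2.0, 2.5, 4.0, 5.0, 9.0])
        joint = ~np.isnan(a)
        expected = np.corrcoef(a[joint], b[joint])[0, 1]
        assert masked_pearson(a, b) == pytest.approx(expected)

    def test_fewer_than_three_joint_positions_is_missing(self):
        a = np.array([1.0, 2.0, np.nan, np.nan])
        b = np.array([2.0, np.nan, 1.0, np.nan])
        assert np.isnan(masked_pearson(a, b))

    def test_zero_variance_warns_and_is_missing(self):
        a = np.ones(5)
        b = np.arange(5.0)
        with pytest.warns(UserWarning, match="zero variance"):
            assert np.isnan(masked_pearson(a, b))


def all_tree_orders(Z, n):
    """Every leaf order consistent with the dendrogram (all 2^(n-1) flips)."""
    def orders(node):
        if node < n:
            return [[node]]
        left = int(Z[node - n, 0])
        right = int(Z[node - n, 1])
        out = []
        for lo in orders(left):
            for ro in orders(right):
                out.append(lo + ro)
                out.append(ro + lo)
        return out

    return orders(2 * n - 2)


class TestClustering:
    def test_identical_pair_merges_first_at_zero(self):
        corr = np.array([[1.0, 1.0, -0.9], [1.0, 1.0, -0.9], [-0.9, -0.9, 1.0]])
        import pandas as pd

        Z, order = cluster_profiles(pd.DataFrame(corr, index=list("abc"), columns=list("abc")))
        assert Z[0, 2] == pytest.approx(0.0)  # first merge height
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_average_linkage_heights_match_hand_agglomeration(self):
        # 3-leaf case is hand-checkable: first merge min distance, then average
        import pandas as pd

        d_ab, d_ac, d_bc = 0.1, 0.5, 0.7
        corr = 1 - np.array([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0.0]])
        np.fill_diagonal(corr, 1.0)
        Z, _ = cluster_profiles(pd.DataFrame(corr, index=list("abc"), columns=list("abc")))
        assert Z[0, 2] == pytest.approx(d_ab)
        assert Z[1, 2] == pytest.approx((d_ac + d_bc) / 2)

    @pytest.mark.parametrize("n,seed", [(6, 0), (7, 1), (8, 2)])
    def test_leaf_order_is_globally_optimal(self, n, seed):
        """Exact optimal leaf ordering equals exhaustive search over all
        orders consistent with the tree."""
        import pandas as pd

        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        corr = np.corrcoef(pts)
        labels = [f"g{k}" for k in range(n)]
        Z, order = cluster_profiles(pd.DataFrame(corr, index=labels, columns=labels))
        dist = 1 - corr

        def adjacent_sum(idx_order):
            return sum(dist[a, b] for a, b in zip(idx_order, idx_order[1:]))

        got = adjacent_sum([labels.index(g) for g in order])
        best = min(adjacent_sum(o) for o in all_tree_orders(Z, n))
        assert got == pytest.approx(best)

    def test_missing_correlations_imputed_with_warning(self):
        import pandas as pd

        corr = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        corr.iloc[0, 1] = corr.iloc[1, 0] = np.nan
        with pytest.warns(UserWarning, match="imputed"):
            Z, order = cluster_profiles(corr)
        assert len(order) == 3

    def test_newick_export_contains_all_leaves(self):
        import pandas as pd

        corr = pd.DataFrame(np.eye(3) * 0.5 + 0.5, index=list("abc"), columns=list("abc"))
        corr.iloc[0, 1] = corr.iloc[1, 0] = 0.9
        Z, _ = cluster_profiles(corr)
        nwk = dendrogram_to_newick(Z, list("abc"))
        assert nwk.endswith(";") and all(leaf in nwk for leaf in "abc")


class TestCrossModal:
    def test_identical_profiles_give_r_one(self):
        x = np.linspace(0, 1, 20)
        v = np.sin(x * 3) + 1
        fish = ProfileMatrix(genes=["G"], positions=x * 100, values=v[None, :])
        scrna = ProfileMatrix(genes=["G"], positions=x, values=(2 * v + 3)[None, :])
        out = cross_modal_compare(fish, scrna)
        assert out["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_constant_profile_is_missing_with_warning(self):
        x = np.linspace(0, 1, 10)
        fish = ProfileMatrix(genes=["G"], positions=x, values=np.ones((1, 10)))
        scrna = ProfileMatrix(genes=["G"], positions=x, values=np.arange(10.0)[None, :])
        with pytest.warns(UserWarning, match="constant"):
            out = cross_modal_compare(fish, scrna)
        assert np.isnan(out["pearson_r"].iloc[0])

    def test_no_shared_genes_errors(self):
        x = np.linspace(0, 1, 5)
        a = ProfileMatrix(genes=["A"], positions=x, values=np.ones((1, 5)))
        b = ProfileMatrix(genes=["B"], positions=x, values=np.ones((1, 5)))
        with pytest.raises(ValueError, match="shared"):
            cross_modal_compare(a, b)
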