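"""Spatial statistics: Mantel, Moran's I, D_G, aggregation, transects."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from standscape import spatial
from standscape.spatial import DistanceClassSpec

from oracles import morans_i_direct


class TestMantel:
    def test_identical_matrices_give_perfect_correlation(self):
        rng = np.random.default_rng(0)
        pts = rng.random((10, 2))
        d = squareform(pdist(pts))
        res = spatial.mantel_test(d, d.copy(), n_perms=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_constant_matrix_rejected(self):
        d = squareform(pdist(np.random.default_rng(0).random((6, 2))))
        with pytest.raises(ValueError, match="zero-variance"):
            spatial.mantel_test(np.zeros_like(d), d, n_perms=9)

    def test_agrees_with_skbio_on_statistic(self):
        skbio_mantel = pytest.importorskip("skbio.stats.distance").mantel
        from skbio import DistanceMatrix

        rng = np.random.default_rng(3)
        a = squareform(pdist(rng.random((12, 2))))
        b = squareform(pdist(rng.random((12, 2))))
        ours = spatial.mantel_test(a, b, n_perms=999, seed=0)
        r_ref, p_ref, _ = skbio_mantel(
            DistanceMatrix(a), DistanceMatrix(b), method="pearson",
            permutations=999, alternative="greater",
        )
        assert ours.r == pytest.approx(float(r_ref), abs=1e-12)
        assert ours.p_value == pytest.approx(float(p_ref), abs=0.05)


class TestDistanceClasses:
    def test_classes_partition_all_pairs_in_range(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 5000, size=(20, 2))
        spec = DistanceClassSpec(10, 1.0)  # covers up to 10 km > max possible
        groups = spatial._pair_classes(coords, spec)
        assert sum(g[0].size for g in groups) == 20 * 19 // 2


class TestMoransI:
    def test_matches_direct_definition_per_class(self):
        rng = np.random.default_rng(2)
        n = 15
        coords = rng.uniform(0, 3000, size=(n, 2))
        calls = rng.integers(0, 3, size=(n, 4)).astype(np.int8)
        spec = DistanceClassSpec(4, 1.0)
        res = spatial.morans_i_correlogram(calls, coords, spec, n_perms=5, seed=0)
        d_km = squareform(pdist(coords)) / 1000.0
        for c in range(4):
            w = ((d_km >= c * 1.0) & (d_km < (c + 1) * 1.0)).astype(float)
            np.fill_diagonal(w, 0.0)
            if w.sum() == 0:
                assert np.isnan(res.values[c])
                continue
            per_marker = []
            for j in range(4):
                y = calls[:, j] / 2.0
                if np.ptp(y) > 0:
                    per_marker.append(morans_i_direct(y, w))
            assert res.values[c] == pytest.approx(np.mean(per_marker), abs=1e-10)

    def test_two_cluster_construction_positive_short_negative_long(self):
        rng = np.random.default_rng(4)
        n_half = 15
        coords = np.vstack(
            [rng.normal(0, 50, (n_half, 2)), rng.normal(10_000, 50, (n_half, 2))]
        )
        calls = np.vstack(
            [np.zeros((n_half, 20)), np.full((n_half, 20), 2)]
        ).astype(np.int8)
        spec = DistanceClassSpec(30, 0.5)
        res = spatial.morans_i_correlogram(calls, coords, spec, n_perms=99, seed=0)
        assert res.values[0] > res.env_high[0]  # short class above envelope
        last = np.max(np.flatnonzero(~np.isnan(res.values)))
        assert res.values[last] < 0

    def test_monomorphic_panel_rejected(self):
        coords = np.random.default_rng(0).random((5, 2)) * 1000
        with pytest.raises(ValueError, match="polymorphic"):
            spatial.morans_i_correlogram(
                np.zeros((5, 3), dtype=np.int8), coords, DistanceClassSpec(3, 1.0)
            )

    def test_permutation_null_mean_matches_analytic(self):
        # E[I] under the randomization null is -1/(n-1) per class
        rng = np.random.default_rng(5)
        n = 40
        coords = rng.uniform(0, 2000, size=(n, 2))
        calls = rng.integers(0, 3, size=(n, 10)).astype(np.int8)
        spec = DistanceClassSpec(3, 1.0)
        res = spatial.morans_i_correlogram(calls, coords, spec, n_perms=400, seed=0)
        for c in range(3):
            if res.n_pairs[c] > 20:
                assert res.perm_mean[c] == pytest.approx(-1 / (n - 1), abs=0.02)


class TestDG:
    def test_hand_values(self):
        y = spatial._scores(np.array([[0, 0, 0], [2, 1, 0]], dtype=np.int8))
        d = spatial.gregorius_distance_matrix(np.array([[0], [2]], dtype=np.int8))
        assert d[0, 1] == pytest.approx(1.0)
        d2 = spatial.gregorius_distance_matrix(np.array([[0], [1]], dtype=np.int8))
        assert d2[0, 1] == pytest.approx(0.5)
        d3 = spatial.gregorius_distance_matrix(
            np.array([[0, 1, 2], [0, 1, 2]], dtype=np.int8)
        )
        assert d3[0, 1] == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_metric_properties_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, size=(3, 12)).astype(np.int8)
        d = spatial.gregorius_distance_matrix(g)
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)
        for i, j, k in [(0, 1, 2), (1, 2, 0), (2, 0, 1)]:
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_distogram_detects_structure(self):
        rng = np.random.default_rng(6)
        coords = np.vstack(
            [rng.normal(0, 30, (10, 2)), rng.normal(5000, 30, (10, 2))]
        )
        calls = np.vstack([np.zeros((10, 10)), np.full((10, 10), 2)]).astype(np.int8)
        res = spatial.dg_distogram(calls, coords, DistanceClassSpec(12, 0.5),
                                   n_perms=99, seed=0)
        assert res.values[0] < res.env_low[0]  # near pairs more similar


class TestAggregation:
    def test_coincident_points_give_zero(self):
        res = spatial.aggregation_index(np.zeros((5, 2)), area=100.0, n_sims=19, seed=0)
        assert res.r == 0.0

    def test_uniform_random_points_near_one(self):
        rng = np.random.default_rng(7)
        rs = []
        for s in range(20):
            pts = rng.uniform(0, 100, size=(400, 2))
            rs.append(spatial.aggregation_index(pts, 100.0**2, n_sims=1, seed=s).r)
        assert abs(np.mean(rs) - 1.0) < 0.05

    def test_square_grid_exceeds_one(self):
        xx, yy = np.meshgrid(np.arange(20), np.arange(20))
        pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        res = spatial.aggregation_index(pts, 400.0, n_sims=9, seed=0)
        # closed form: every NN distance is the grid spacing (1), CSR
        # expectation is 0.5/sqrt(400/400) = 0.5, so R = 2
        assert res.r == pytest.approx(2.0)


class TestTransects:
    def test_enumerated_example(self):
        res = spatial.transect_clustering(list("AAABB"))
        assert res.c2 == pytest.approx(1.0)
        assert res.c3 == pytest.approx(1 / 3)

    def test_alternating_sequence_has_no_clustering(self):
        res = spatial.transect_clustering(list("ABABA"))
        assert res.c2 == 0.0 and res.c3 == 0.0

    def test_monotypic_transect_is_fully_clustered(self):
        res = spatial.transect_clustering(["X"] * 6)
        assert res.c2 == 1.0 and res.c3 == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("ABC"), min_size=3, max_size=12))
    def test_c3_never_exceeds_c2(self, seq):
        res = spatial.transect_clustering(seq)
        assert 0 <= res.c3 <= res.c2 <= 1
        if res.c2 == res.c3 == 1:
            assert len(set(seq)) == 1

    def test_too_short_transect_rejected(self):
        with pytest.raises(ValueError):
            spatial.transect_clustering(["A", "B"])


class TestRegression:
    def test_collinear_inputs_give_r2_one(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        res = spatial.cluster_vs_fis_regression(x, 0.5 + 2 * x)
        assert res["r2"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)

    def test_two_stands_insufficient(self):
        with pytest.raises(ValueError):
            spatial.cluster_vs_fis_regression([0.1, 0.2], [0.5, 0.6])

    def test_constant_predictor_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            spatial.cluster_vs_fis_regression([0.5] * 4, [0.1, 0.2, 0.3, 0.4])
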