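"""Enrichment-kinetics analytics: slopes, reference regression, paired test,
gap-statistic clustering and classical MDS."""

import numpy as np
import pandas as pd
import pytest

from chloroflux.kinetics import (DegenerateTestError, LabelSeries,
                                 cluster_and_order, enrichment_slope,
                                 gap_select_k, mds_embed, paired_slope_test,
                                 regress_on_reference)
from chloroflux.simulate import simulate_labeling


def series(name, times, values, **kw):
    return LabelSeries(name, np.asarray(times, float),
                       np.asarray(values, float), **kw)


class TestEnrichmentSlope:
    def test_exact_linear(self):
        t = np.array([5.0, 10.0, 20.0, 40.0])
        s = series("x", t, 0.01 * t)
        slope, intercept, r = enrichment_slope(s)
        assert slope == pytest.approx(0.01)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r == pytest.approx(1.0)

    def test_constant_series_has_zero_slope(self):
        s = series("x", [5, 10, 20], [0.3, 0.3, 0.3])
        slope, _, _ = enrichment_slope(s, include_origin=False)
        assert slope == pytest.approx(0.0, abs=1e-15)

    def test_origin_included_by_default(self):
        # without (0, 0) these two points could not be fit at all
        s = series("x", [10, 20], [0.1, 0.2])
        slope, _, _ = enrichment_slope(s)
        assert slope == pytest.approx(0.01, rel=0.05)

    def test_noisy_linear_recovery_within_two_se(self):
        # ~95% of seeded replicates must land within 2 s.e. of the truth
        t = np.linspace(4, 40, 10)
        true = 0.005
        se = 0.005 / np.sqrt(((t - t.mean()) ** 2).sum())
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = np.clip(true * t + rng.normal(0, 0.005, t.size), 0, 1)
            slope, _, _ = enrichment_slope(series("x", t, vals),
                                           include_origin=False)
            hits += abs(slope - true) < 2 * se
        assert hits >= 17

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            enrichment_slope(series("x", [10.0], [0.1]),
                             include_origin=True, window=(0, 5))


class TestRegressOnReference:
    def test_identity_gives_unit_slope_and_r(self):
        t = [5, 10, 20, 40]
        ref = series("DHAP", t, [0.05, 0.1, 0.2, 0.35])
        slope, r = regress_on_reference(ref, ref)
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_proportional_series(self):
        t = [5, 10, 20, 40]
        ref = series("DHAP", t, [0.05, 0.1, 0.2, 0.35])
        half = series("S7P", t, [0.025, 0.05, 0.1, 0.175])
        slope, r = regress_on_reference(half, ref)
        assert slope == pytest.approx(0.5)
        assert r == pytest.approx(1.0)

    def test_downstream_pool_has_subunit_slope(self, two_pool):
        # slow turnovers keep both pools in the rising (pre-plateau) regime
        # over the fit window, where the downstream pool must lag
        slow = two_pool.with_parameters(pools={"A": 5.0, "B": 10.0})
        sim = simulate_labeling(slow, [5.0, 10.0, 20.0, 40.0])
        up = series("A", sim.times, sim.enrichment("A"))
        down = series("B", sim.times, sim.enrichment("B"))
        slope, r = regress_on_reference(down, up)
        assert slope < 1.0
        assert r > 0.95

    def test_zero_variance_reference_rejected(self):
        t = [5, 10, 20]
        with pytest.raises(ValueError, match="variance"):
            regress_on_reference(series("x", t, [0.1, 0.2, 0.3]),
                                 series("ref", t, [0.2, 0.2, 0.2]))


class TestPairedSlopeTest:
    def test_hand_computed_example(self):
        # diffs (0.5, 0.6, 0.4, 0.5): mean 0.5, sd 0.0816497,
        # t = 0.5 / (0.0816497/2) = 12.2474, df = 3
        t, p = paired_slope_test([1, 2, 3, 4], [0.5, 1.4, 2.6, 3.5])
        assert t == pytest.approx(12.247449, abs=1e-5)
        assert p == pytest.approx(0.0011722, abs=1e-6)

    def test_identical_sets_degenerate(self):
        with pytest.raises(DegenerateTestError):
            paired_slope_test([1, 2, 3], [1, 2, 3])

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.raises(DegenerateTestError, match="constant"):
            paired_slope_test([1, 2, 3], [0.5, 1.5, 2.5])


class TestClustering:
    def planted(self, rng, k=4, per=6, sep=10.0, d=6):
        centers = rng.uniform(0, 100, size=(k, d))
        centers = centers - centers.mean(0) + sep * np.arange(k)[:, None]
        rows = np.concatenate([c + rng.normal(0, 1.0, size=(per, d))
                               for c in centers])
        return rows, np.repeat(np.arange(k), per)

    def test_gap_recovers_planted_k(self, rng):
        X, _ = self.planted(rng, k=4, sep=12.0)
        res = gap_select_k(X, kmin=2, kmax=8, B=30, seed=5, n_init=20)
        assert res.k == 4

    @pytest.mark.parametrize("k_true", [2, 3, 5])
    def test_gap_recovers_varied_k(self, k_true):
        rng = np.random.default_rng(1000 + k_true)
        X, _ = self.planted(rng, k=k_true, per=8, sep=15.0)
        res = gap_select_k(X, kmin=2, kmax=8, B=30, seed=5, n_init=20)
        assert res.k == k_true

    def test_missing_values_rejected(self):
        X = np.full((25, 4), np.nan)
        with pytest.raises(ValueError, match="missing"):
            gap_select_k(X, kmax=8)

    def test_fast_curve_lands_in_cluster_one(self):
        mat = pd.DataFrame(
            np.vstack([np.full((3, 5), 90.0) + np.eye(3, 5),
                       np.full((3, 5), 10.0) - np.eye(3, 5)]),
            index=[f"r{i}" for i in range(6)])
        res = cluster_and_order(mat, k=2, seed=0, n_init=10)
        assert (res.labels.iloc[:3] == 1).all()
        assert (res.labels.iloc[3:] == 2).all()

    def test_duplicate_rows_share_cluster(self, rng):
        X, _ = self.planted(rng, k=3, per=5, sep=12.0)
        X[1] = X[0]
        res = cluster_and_order(X, k=3, seed=0, n_init=10)
        assert res.labels.iloc[0] == res.labels.iloc[1]

    def test_membership_stable_under_row_permutation(self, rng):
        X, _ = self.planted(rng, k=3, per=5, sep=12.0)
        perm = rng.permutation(X.shape[0])
        a = cluster_and_order(X, k=3, seed=0, n_init=10).labels.to_numpy()
        b = cluster_and_order(X[perm], k=3, seed=0,
                              n_init=10).labels.to_numpy()
        assert np.array_equal(a[perm], b)

    def test_gap_reproducible_under_seed(self, rng):
        X, _ = self.planted(rng, k=3, per=7, sep=12.0)
        r1 = gap_select_k(X, kmax=6, B=10, seed=9, n_init=10)
        r2 = gap_select_k(X, kmax=6, B=10, seed=9, n_init=10)
        assert r1.k == r2.k
        pd.testing.assert_frame_equal(r1.gap_curve, r2.gap_curve)

    def test_k_larger_than_rows_rejected(self):
        with pytest.raises(ValueError):
            cluster_and_order(np.zeros((3, 2)), k=5, seed=0)


class TestMDS:
    def test_collinear_points_embed_collinear(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        coords = mds_embed(X)
        assert np.abs(coords["dim2"]).max() < 1e-6

    def test_distances_reproduced_for_2d_data(self, rng):
        X = rng.normal(size=(12, 2)) @ rng.normal(size=(2, 7))
        coords = mds_embed(X).to_numpy()
        orig = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        emb = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.abs(orig - emb).max() < 1e-8

    def test_projection_never_expands_distances(self, rng):
        X = rng.normal(size=(15, 6))
        coords = mds_embed(X).to_numpy()
        orig = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        emb = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.all(emb <= orig + 1e-8)

    def test_identical_rows_map_together(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [4.0, 0.0], [0.0, 4.0]])
        coords = mds_embed(X).to_numpy()
        assert np.allclose(coords[0], coords[1])

    def test_matches_pcoa_reference(self, rng):
        # independent reference: scikit-bio principal coordinates analysis
        skbio = pytest.importorskip("skbio")
        from scipy.spatial.distance import pdist, squareform
        X = rng.normal(size=(10, 4))
        coords = mds_embed(X).to_numpy()
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(squareform(pdist(X)))).samples.iloc[:, :2] \
            .to_numpy()
        for j in range(2):
            assert (np.allclose(coords[:, j], ref[:, j], atol=1e-6)
                    or np.allclose(coords[:, j], -ref[:, j], atol=1e-6))

    def test_rank_zero_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            mds_embed(np.ones((4, 3)))
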