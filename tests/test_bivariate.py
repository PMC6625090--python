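"""Bivariate K estimators, the 95% envelope, LBI, and ranking significance."""
import numpy as np
import pytest

from nanoclust import (
    BivariatePattern,
    InsufficientPointsError,
    PointPattern,
    PointPatternError,
    RadiusGrid,
    StudyRegion,
    biv_null_envelope,
    bivariate_k,
    edge_correction_weight,
    lbi,
    lbi_significance,
    lbi_test,
    simulate_csr,
    standardize_bivariate,
)
from nanoclust.bivariate import LBIResult
from nanoclust.univariate import Envelope, standardize_curve, KCurve


def brute_force_cross_k(big, small, region, radii):
    """Literal double sums of the two directed cross estimators."""
    n_b, n_s = len(big), len(small)
    k_bs = np.zeros(len(radii))
    k_sb = np.zeros(len(radii))
    for a, r in enumerate(radii):
        s_bs = s_sb = 0.0
        for i in range(n_b):
            for j in range(n_s):
                d = float(np.hypot(*(big[i] - small[j])))
                if d <= r:
                    s_bs += edge_correction_weight(big[i], d, region)
                    s_sb += edge_correction_weight(small[j], d, region)
        k_bs[a] = s_bs
        k_sb[a] = s_sb
    scale = region.area / (n_b * n_s)
    return scale * k_bs, scale * k_sb


def _pair(region, big_pts, small_pts):
    return BivariatePattern(
        PointPattern(big_pts, region, "big"), PointPattern(small_pts, region, "small")
    )


class TestBivariateK:
    def test_single_cross_pair_hand_example(self, region, grid):
        pair = _pair(region, [[500, 500]], [[500, 510]])
        curve = bivariate_k(pair, grid)
        at = lambda r: np.flatnonzero(grid.radii == r)[0]
        # distance exactly 10 nm: inclusive indicator fires at r = 10
        assert curve.k_bs[at(10)] == pytest.approx(1.0e6)
        assert curve.k_sb[at(10)] == pytest.approx(1.0e6)
        assert curve.k_biv[at(10)] == pytest.approx(1.0e6)
        assert curve.l_biv_minus_r[at(10)] == pytest.approx(
            np.sqrt(1.0e6 / np.pi) - 10
        )
        assert curve.l_biv_minus_r[at(10)] == pytest.approx(554.19, abs=0.01)
        assert curve.k_biv[at(5)] == 0.0
        assert curve.l_biv_minus_r[at(5)] == pytest.approx(-5.0)

    def test_channel_exchangeability(self, region, grid):
        """K_biv is symmetric under channel relabeling (interior points)."""
        rng = np.random.default_rng(23)
        for _ in range(10):
            big = rng.uniform(300, 700, (rng.integers(2, 20), 2))
            small = rng.uniform(300, 700, (rng.integers(2, 20), 2))
            pair = _pair(region, big, small)
            k1 = bivariate_k(pair, grid).k_biv
            k2 = bivariate_k(pair.swapped(), grid).k_biv
            np.testing.assert_allclose(k1, k2, rtol=1e-12)

    def test_matches_brute_force(self, region, coarse_grid):
        rng = np.random.default_rng(29)
        for _ in range(6):
            big = rng.uniform(0, 1000, (rng.integers(1, 40), 2))
            small = rng.uniform(0, 1000, (rng.integers(1, 40), 2))
            curve = bivariate_k(_pair(region, big, small), coarse_grid)
            k_bs, k_sb = brute_force_cross_k(big, small, region, coarse_grid.radii)
            np.testing.assert_allclose(curve.k_bs, k_bs, rtol=1e-9, atol=1e-9)
            np.testing.assert_allclose(curve.k_sb, k_sb, rtol=1e-9, atol=1e-9)

    def test_nondecreasing(self, region, grid):
        rng = np.random.default_rng(31)
        pair = _pair(region, rng.uniform(0, 1000, (30, 2)), rng.uniform(0, 1000, (40, 2)))
        curve = bivariate_k(pair, grid)
        for k in (curve.k_bs, curve.k_sb, curve.k_biv):
            assert np.all(np.diff(k) >= -1e-12)

    def test_empty_channel_rejected(self, region, grid):
        pair = _pair(region, np.empty((0, 2)), [[1.0, 1.0]])
        with pytest.raises(InsufficientPointsError):
            bivariate_k(pair, grid)


class TestNullEnvelope:
    @pytest.fixture(scope="class")
    def pair(self, region):
        return BivariatePattern(
            simulate_csr(100, region, 1, "big"), simulate_csr(100, region, 2, "small")
        )

    def test_deterministic(self, pair, grid):
        a = biv_null_envelope(pair, grid, n_sims=100, seed=5)
        b = biv_null_envelope(pair, grid, n_sims=100, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_level_monotonicity(self, pair, grid):
        lo = biv_null_envelope(pair, grid, level=0.95, n_sims=150, seed=5)
        hi = biv_null_envelope(pair, grid, level=0.99, n_sims=150, seed=5)
        assert np.all(lo.values <= hi.values)

    def test_positive_at_50(self, pair, grid):
        env = biv_null_envelope(pair, grid, n_sims=300, seed=6)
        assert env.values[grid.radii == 50][0] > 0

    def test_toroidal_null_available(self, pair, grid):
        env = biv_null_envelope(pair, grid, n_sims=100, seed=7, null="toroidal")
        assert np.isfinite(env.values).all()
        with pytest.raises(PointPatternError):
            biv_null_envelope(pair, grid, n_sims=100, seed=7, null="nope")


class TestLBI:
    @staticmethod
    def _std_from_constant(grid, value):
        env = Envelope(grid, np.ones(len(grid)), 0.95, 100, 0)
        raw = np.full(len(grid), float(value))
        return standardize_curve(KCurve(grid, np.zeros(len(grid)), raw), env)

    def test_envelope_level_curve_integrates_to_100(self, grid):
        std = self._std_from_constant(grid, 1.0)
        assert lbi(std).lbi == 100.0

    @pytest.mark.parametrize("value,expected", [(0.0, 0.0), (2.0, 200.0)])
    def test_constant_curves(self, grid, value, expected):
        assert lbi(self._std_from_constant(grid, value)).lbi == pytest.approx(expected)

    def test_undefined_radius_inside_band_raises(self, grid):
        values = np.ones(len(grid))
        values[grid.radii == 60] = -1.0
        env = Envelope(grid, values, 0.95, 100, 0)
        std = standardize_curve(
            KCurve(grid, np.zeros(len(grid)), np.ones(len(grid))), env
        )
        with pytest.raises(PointPatternError, match="60"):
            lbi(std)

    def test_band_outside_grid_raises(self):
        g = RadiusGrid(np.array([200.0, 220.0]))
        env = Envelope(g, np.ones(2), 0.95, 100, 0)
        std = standardize_curve(KCurve(g, np.zeros(2), np.ones(2)), env)
        with pytest.raises(PointPatternError):
            lbi(std)

    def test_lbi_range_validation(self):
        with pytest.raises(PointPatternError):
            LBIResult(1.0, r_lo=110.0, r_hi=10.0)


class TestSignificance:
    def test_extreme_rank(self):
        null = np.arange(1000.0)
        assert lbi_significance(LBIResult(2000.0), null) == pytest.approx(1 / 1001)

    def test_median_rank(self):
        null = np.arange(999.0)
        p = lbi_significance(LBIResult(499.0), null)
        assert p == pytest.approx(0.5, abs=0.01)

    def test_needs_enough_null_values(self):
        with pytest.raises(PointPatternError):
            lbi_significance(LBIResult(1.0), np.arange(10.0))

    def test_lbi_test_detects_coclustering(self, region, grid):
        from nanoclust import ClusterProcessParams, simulate_bivariate

        params = ClusterProcessParams()
        hits = 0
        reps = 20
        for s in range(reps):
            pair = simulate_bivariate("colocalized", params, 100, 100, region, seed=(3, s))
            result, _, _ = lbi_test(pair, grid, n_sims=150, seed=(4, s))
            assert result.lbi > 100.0
            hits += result.p_value <= 0.05
        assert hits >= 0.9 * reps
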