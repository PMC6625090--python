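"""Univariate K/L estimators, envelopes, standardization, bootstrap."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nanoclust import (
    GroupedPatterns,
    InsufficientPointsError,
    KCurve,
    PointPattern,
    PointPatternError,
    RadiusGrid,
    StudyRegion,
    csr_envelope,
    edge_correction_weight,
    k_function,
    l_curve,
    lmax,
    raw_lmax,
    simulate_csr,
    standardize_curve,
)
from nanoclust.univariate import Envelope, EnvelopeCache, permutation_pvalue


def brute_force_k(points: np.ndarray, region: StudyRegion, radii: np.ndarray) -> np.ndarray:
    """Literal O(n^2) double loop over ordered pairs."""
    n = len(points)
    dist, weight = [], []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = float(np.hypot(*(points[i] - points[j])))
            if d <= radii[-1]:
                dist.append(d)
                weight.append(edge_correction_weight(points[i], d, region))
    dist, weight = np.asarray(dist), np.asarray(weight)
    out = np.empty(len(radii))
    for a, r in enumerate(radii):
        out[a] = weight[dist <= r].sum() if len(dist) else 0.0
    return region.area / n**2 * out


class TestKFunction:
    def test_two_point_hand_example(self, region, grid):
        pat = PointPattern([[500, 490], [500, 510]], region)
        curve = k_function(pat, grid)
        # interior pair 20 nm apart: both ordered pairs count with w = 1
        assert curve.k_values[grid.radii == 25][0] == pytest.approx(5.0e5)
        assert curve.k_values[grid.radii == 10][0] == 0.0

    def test_requires_two_points(self, region, grid):
        with pytest.raises(InsufficientPointsError):
            k_function(PointPattern([[1.0, 1.0]], region), grid)

    def test_nondecreasing_in_r(self, region, grid):
        rng = np.random.default_rng(5)
        for _ in range(10):
            pat = simulate_csr(rng.integers(2, 80), region, rng)
            k = k_function(pat, grid).k_values
            assert np.all(np.diff(k) >= 0)

    def test_matches_brute_force(self, region, coarse_grid):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(2, 51))
            pat = simulate_csr(n, region, rng)
            fast = k_function(pat, coarse_grid).k_values
            slow = brute_force_k(pat.points, region, coarse_grid.radii)
            np.testing.assert_allclose(fast, slow, rtol=1e-9, atol=1e-9)


class TestLTransform:
    def test_reference_values(self, grid):
        radii = grid.radii
        k = np.zeros_like(radii)
        curve = l_curve(KCurve(grid, k))
        assert curve.l_minus_r[radii == 10][0] == pytest.approx(-10.0)
        csr = l_curve(KCurve(grid, np.pi * radii**2))
        np.testing.assert_allclose(csr.l_minus_r, 0.0, atol=1e-9)

    def test_hand_value(self, grid):
        k = np.pi * grid.radii**2
        k[grid.radii == 25] = 5.0e5
        curve = l_curve(KCurve(grid, k))
        expected = np.sqrt(5.0e5 / np.pi) - 25
        assert curve.l_minus_r[grid.radii == 25][0] == pytest.approx(expected)
        assert expected == pytest.approx(373.94, abs=0.01)

    def test_negative_k_rejected(self, grid):
        with pytest.raises(PointPatternError):
            KCurve(grid, -np.ones(len(grid)))


class TestEnvelope:
    def test_deterministic_under_seed(self, region, grid):
        a = csr_envelope(50, region, grid, n_sims=100, seed=9)
        b = csr_envelope(50, region, grid, n_sims=100, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_quantile_monotone_in_level(self, region, grid):
        hi = csr_envelope(50, region, grid, level=0.99, n_sims=200, seed=4)
        lo = csr_envelope(50, region, grid, level=0.95, n_sims=200, seed=4)
        assert np.all(hi.values >= lo.values)

    def test_positive_at_intermediate_radius(self, region, grid):
        env = csr_envelope(100, region, grid, n_sims=1000, seed=2)
        assert env.values[grid.radii == 50][0] > 0

    def test_validation(self, region, grid):
        with pytest.raises(PointPatternError):
            csr_envelope(100, region, grid, level=1.5, n_sims=200)
        with pytest.raises(PointPatternError):
            csr_envelope(100, region, grid, n_sims=50)
        with pytest.raises(InsufficientPointsError):
            csr_envelope(1, region, grid, n_sims=200)


class TestStandardization:
    @pytest.fixture(scope="class")
    def envelope(self, region, grid):
        return csr_envelope(100, region, grid, n_sims=200, seed=21)

    def test_self_normalization(self, grid, envelope):
        curve = KCurve(grid, np.zeros(len(grid)), envelope.values.copy())
        std = standardize_curve(curve, envelope)
        assert np.all(std.std_values[std.defined_mask] == 1.0)
        assert lmax(std) == (1.0, float(grid.radii[std.defined_mask][0]))

    def test_zero_curve(self, grid, envelope):
        std = standardize_curve(KCurve(grid, np.zeros(len(grid)), np.zeros(len(grid))), envelope)
        value, _ = lmax(std)
        assert value == 0.0

    def test_double_envelope_at_one_radius(self, grid, envelope):
        raw = np.full(len(grid), -1.0)
        idx = np.flatnonzero(grid.radii == 50)[0]
        assert envelope.values[idx] > 0
        raw[idx] = 2.0 * envelope.values[idx]
        std = standardize_curve(KCurve(grid, np.zeros(len(grid)), raw), envelope)
        value, radius = lmax(std)
        assert value == pytest.approx(2.0)
        assert radius == 50.0

    def test_grid_mismatch(self, envelope):
        short = RadiusGrid(np.arange(1.0, 101.0))
        with pytest.raises(PointPatternError):
            standardize_curve(KCurve(short, np.zeros(100), np.zeros(100)), envelope)

    def test_undefined_radii_excluded(self, grid):
        values = np.full(len(grid), -5.0)
        values[grid.radii >= 100] = 3.0
        env = Envelope(grid, values, 0.99, 100, 0)
        raw = np.full(len(grid), 6.0)
        std = standardize_curve(KCurve(grid, np.zeros(len(grid)), raw), env)
        assert not std.defined_mask[grid.radii == 50][0]
        assert np.isnan(std.std_values[grid.radii == 50][0])
        assert lmax(std)[0] == pytest.approx(2.0)

    def test_lmax_tie_breaks_to_smaller_radius(self):
        g = RadiusGrid(np.array([10.0, 20.0, 30.0, 40.0]))
        env = Envelope(g, np.ones(4), 0.99, 100, 0)
        raw = np.array([0.5, 1.8, 1.8, 0.2])
        std = standardize_curve(KCurve(g, np.zeros(4), raw), env)
        assert lmax(std) == (1.8, 20.0)
        assert raw_lmax(std) == (1.8, 20.0)

    def test_all_undefined_raises(self):
        g = RadiusGrid(np.array([10.0, 20.0]))
        env = Envelope(g, np.array([-1.0, 0.0]), 0.99, 100, 0)
        std = standardize_curve(KCurve(g, np.zeros(2), np.ones(2)), env)
        with pytest.raises(PointPatternError):
            lmax(std)


class TestBootstrap:
    def test_identical_groups_give_p_one(self, region, grid):
        from nanoclust import bootstrap_group_test

        rng = np.random.default_rng(31)
        patterns = [simulate_csr(40, region, rng) for _ in range(3)]
        cache = EnvelopeCache(region, grid, n_sims=100, base_seed=1)
        res = bootstrap_group_test(
            GroupedPatterns("a", patterns),
            GroupedPatterns("b", list(patterns)),
            n_boot=200,
            seed=5,
            cache=cache,
        )
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_requires_two_patterns_per_group(self, region, grid):
        from nanoclust import bootstrap_group_test

        one = GroupedPatterns("a", [simulate_csr(10, region, 0)])
        two = GroupedPatterns("b", [simulate_csr(10, region, 1), simulate_csr(10, region, 2)])
        with pytest.raises(InsufficientPointsError):
            bootstrap_group_test(one, two)

    def test_permutation_p_in_unit_interval_and_detects_shift(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 12)
        b = rng.normal(5, 1, 12)
        res = permutation_pvalue(a, b, n_boot=500, seed=3)
        assert 0 < res.p_value <= 1
        assert res.p_value == pytest.approx(1 / 501)

    def test_curve_statistic_variant(self, region, grid):
        from nanoclust import bootstrap_group_test
        from nanoclust.synthetic import ClusterProcessParams, simulate_thomas

        params = ClusterProcessParams()
        ga = GroupedPatterns("csr", [simulate_csr(250, region, (1, i)) for i in range(3)])
        gb = GroupedPatterns(
            "thomas", [simulate_thomas(params, region, (2, i)) for i in range(3)]
        )
        cache = EnvelopeCache(region, grid, n_sims=100, base_seed=2)
        res = bootstrap_group_test(
            ga, gb, n_boot=100, seed=7, cache=cache, statistic="curve_integral"
        )
        assert res.statistic_kind == "curve_integral"
        assert 0 < res.p_value <= 1


@given(st.integers(0, 2**31 - 1))
def test_envelope_cache_is_order_independent(seed):
    """Cache lookups hit seeds derived from (base_seed, n) only."""
    region = StudyRegion.from_size(300.0)
    grid = RadiusGrid(np.array([10.0, 20.0]))
    a = EnvelopeCache(region, grid, n_sims=100, base_seed=seed % 1000)
    b = EnvelopeCache(region, grid, n_sims=100, base_seed=seed % 1000)
    np.testing.assert_array_equal(a.get(7).values, b.get(7).values)
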