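"""Unit tests for the fast fluctuation-function core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mfmsdfa import core
from mfmsdfa.core import (block_moment, block_scheme, build_prefix_store,
                          cumulative_profile, default_scale_grid,
                          default_thresholds, fit_block_poly,
                          fluctuation_function, fq_surface,
                          local_block_moments, normalize_series, power_sum,
                          range_power_sum, residual_variance_fast)


# ---------------------------------------------------------------------------
# normalization and profile

class TestNormalize:
    def test_three_point_series(self):
        s = normalize_series(np.r_[[1.0, 2.0, 3.0], np.tile([1, 2, 3], 5)])
        # population SD of a repeated 1,2,3 pattern is sqrt(2/3)
        assert s.sigma == pytest.approx(np.sqrt(2 / 3))
        np.testing.assert_allclose(
            s.values[:3], [-1.22474487, 0.0, 1.22474487], atol=1e-8)

    def test_already_standard(self, rng):
        x = rng.normal(size=256)
        x = (x - x.mean()) / x.std()
        s = normalize_series(x)
        np.testing.assert_allclose(s.values, x, atol=1e-12)
        assert s.mu == pytest.approx(0.0, abs=1e-12)
        assert s.sigma == pytest.approx(1.0)

    def test_zero_mean_unit_sd_invariant(self, white_series):
        s = normalize_series(white_series * 7.3 - 2.0)
        assert abs(s.values.mean()) < 1e-12
        assert abs(s.values.std() - 1.0) < 1e-12

    @given(a=st.floats(0.01, 100), b=st.floats(-50, 50))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        x = np.sin(np.arange(64) * 0.7) + np.cos(np.arange(64) * 0.13)
        np.testing.assert_allclose(normalize_series(a * x + b).values,
                                   normalize_series(x).values, atol=1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_series(np.full(100, 3.14))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            normalize_series(np.arange(8.0))


class TestProfile:
    def test_cumulative_sum_and_inverse(self, white_series):
        s = normalize_series(white_series)
        y = cumulative_profile(s).y
        assert y[0] == s.values[0]
        np.testing.assert_array_equal(np.diff(y), s.values[1:] + y[:-1]
                                      - y[:-1])
        np.testing.assert_allclose(np.diff(y), s.values[1:], atol=0)


# ---------------------------------------------------------------------------
# block scheme

class TestBlockScheme:
    def test_maximal_overlap(self):
        sch = block_scheme(100, 10, 9)
        assert sch.M == 91 == 100 - 10 + 1
        np.testing.assert_array_equal(sch.starts, np.arange(1, 92))
        assert sch.excluded_tail == 0

    def test_no_overlap(self):
        sch = block_scheme(100, 10, 0)
        assert sch.M == 10
        np.testing.assert_array_equal(sch.starts, np.arange(1, 100, 10))

    def test_partial_overlap_with_tail(self):
        sch = block_scheme(103, 10, 5)
        assert sch.M == 19
        assert sch.excluded_tail == 3

    @pytest.mark.parametrize("n", [4, 7, 16, 63, 500])
    def test_maximal_overlap_count_property(self, n):
        assert block_scheme(1000, n, n - 1).M == 1000 - n + 1

    @pytest.mark.parametrize("N,n,L", [(100, 101, 0), (100, 10, 10),
                                       (100, 3, 0), (100, 10, -1)])
    def test_invalid_rejected(self, N, n, L):
        with pytest.raises(ValueError):
            block_scheme(N, n, L)


# ---------------------------------------------------------------------------
# power sums

class TestPowerSums:
    @pytest.mark.parametrize("V", [1, 2, 3, 4])
    @pytest.mark.parametrize("n", [1, 2, 5, 10, 137, 1000])
    def test_matches_brute_force(self, V, n):
        assert power_sum(V, n) == sum(i ** V for i in range(1, n + 1))

    def test_known_values(self):
        assert power_sum(1, 10) == 55
        assert power_sum(3, 4) == 100
        assert power_sum(4, 10) == 25333

    def test_out_of_range_power_rejected(self):
        with pytest.raises(ValueError):
            power_sum(5, 10)
        with pytest.raises(ValueError):
            power_sum(0, 10)

    def test_range_sums(self):
        assert range_power_sum(1, 5, 5) == 5 + 6 + 7 + 8 + 9
        assert range_power_sum(2, 1, 10) == power_sum(2, 10)
        assert range_power_sum(4, 3, 2) == 81 + 256

    @pytest.mark.parametrize("V", [1, 2, 3, 4])
    def test_range_matches_brute_force(self, V):
        for start, n in [(1, 1), (7, 13), (990, 11)]:
            assert range_power_sum(V, start, n) == \
                sum(i ** V for i in range(start, start + n))


# ---------------------------------------------------------------------------
# prefix store and block moments

class TestPrefixStore:
    def test_a01_is_plain_prefix_sum(self, white_series):
        prof = cumulative_profile(normalize_series(white_series))
        store = build_prefix_store(prof)
        idx = np.arange(0, prof.N + 1)
        np.testing.assert_allclose(
            store.prefix(0, 1, idx),
            np.concatenate(([0.0], np.cumsum(prof.y))), rtol=1e-12,
            atol=1e-12)

    def test_single_segment_equals_running_sum(self, white_series):
        prof = cumulative_profile(normalize_series(white_series))
        store = build_prefix_store(prof)
        i = np.arange(1, 129, dtype=float)
        running = np.cumsum(i * prof.y[:128])
        np.testing.assert_allclose(store.prefix(1, 1, np.arange(1, 129)),
                                   running, rtol=1e-12)

    def test_reconstruction_matches_direct_sum_at_1e4(self, rng):
        prof = cumulative_profile(normalize_series(rng.normal(size=10_000)))
        store = build_prefix_store(prof)
        i = np.arange(1, prof.N + 1, dtype=float)
        for V, W in core.MOMENT_PAIRS:
            terms = (i ** V) * (prof.y ** W)
            direct = np.cumsum(terms)
            rec = store.prefix(V, W, np.arange(1, prof.N + 1))
            # relative to the accumulated term magnitude, the only scale a
            # running float sum can be accurate against
            scale = np.maximum(np.cumsum(np.abs(terms)), 1.0)
            assert np.max(np.abs(rec - direct) / scale) < 1e-12

    def test_block_moment_matches_direct(self, rng):
        prof = cumulative_profile(normalize_series(rng.normal(size=10_000)))
        store = build_prefix_store(prof)
        i = np.arange(1, prof.N + 1, dtype=float)
        for V, W in core.MOMENT_PAIRS:
            t = (i ** V) * (prof.y ** W)
            for start, n in [(1, 50), (123, 977), (9000, 1000), (5000, 4)]:
                direct = t[start - 1:start + n - 1].sum()
                got = block_moment(store, V, W, start, n)
                assert got == pytest.approx(direct, rel=1e-10, abs=1e-10)

    def test_first_block_equals_prefix(self, white_series):
        prof = cumulative_profile(normalize_series(white_series))
        store = build_prefix_store(prof)
        assert block_moment(store, 1, 1, 1, 200) == \
            pytest.approx(store.prefix(1, 1, 200), rel=1e-14)

    def test_out_of_range_block_rejected(self, white_series):
        prof = cumulative_profile(normalize_series(white_series))
        store = build_prefix_store(prof)
        with pytest.raises(IndexError):
            block_moment(store, 0, 1, prof.N - 5, 10)
        with pytest.raises(IndexError):
            block_moment(store, 0, 1, 0, 10)


# ---------------------------------------------------------------------------
# polynomial fits and residual variances

def _moments_for(y_block, start=1):
    """Local-index moments of one explicit block, computed directly."""
    n = y_block.size
    j = np.arange(1, n + 1, dtype=float)
    return core.BlockMoments(
        n=n, starts=np.array([start]),
        s0=np.array([y_block.sum()]),
        s1=np.array([(j * y_block).sum()]),
        s2=np.array([(j * j * y_block).sum()]),
        sy2=np.array([(y_block * y_block).sum()]))


class TestBlockFit:
    def test_exact_line(self):
        j = np.arange(1, 21, dtype=float)
        a1, b1 = fit_block_poly(_moments_for(2 * j + 3), 1)
        assert b1[0] == pytest.approx(2.0, rel=1e-12)
        assert a1[0] == pytest.approx(3.0, rel=1e-12)

    def test_exact_parabola(self):
        j = np.arange(1, 31, dtype=float)
        a2, b2, c2 = fit_block_poly(_moments_for(j ** 2), 2)
        assert c2[0] == pytest.approx(1.0, rel=1e-10)
        assert b2[0] == pytest.approx(0.0, abs=1e-8)
        assert a2[0] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("order", [1, 2])
    def test_matches_generic_least_squares(self, order, rng):
        y = rng.normal(size=57).cumsum()
        coeffs = np.column_stack(fit_block_poly(_moments_for(y), order))[0]
        j = np.arange(1, 58, dtype=float)
        expected = np.polynomial.polynomial.polyfit(j, y, order)
        np.testing.assert_allclose(coeffs, expected, rtol=1e-9, atol=1e-9)

    def test_degenerate_block_rejected(self):
        with pytest.raises(ValueError):
            fit_block_poly(_moments_for(np.arange(3.0)), 2)


class TestResidualVariance:
    def _variance(self, y_block, order):
        mom = _moments_for(y_block)
        coeffs = fit_block_poly(mom, order)
        prof = core.Profile(y_block)
        th = core.Thresholds(th1=0.0, th2=0.0)  # no recompute
        return residual_variance_fast(coeffs, mom, order, th, prof)[0]

    def test_exact_line_zero(self):
        j = np.arange(1, 41, dtype=float)
        assert self._variance(-0.5 * j + 11.0, 1) == pytest.approx(0, abs=1e-10)

    def test_exact_parabola_zero(self):
        j = np.arange(1, 41, dtype=float)
        assert self._variance(0.3 * j ** 2 - j + 2, 2) == \
            pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("order", [1, 2])
    def test_matches_direct_summation(self, order, rng):
        y = rng.normal(size=500).cumsum()
        var = self._variance(y, order)
        j = np.arange(1, 501, dtype=float)
        res = y - np.polynomial.polynomial.polyval(
            j, np.polynomial.polynomial.polyfit(j, y, order))
        assert var == pytest.approx(np.mean(res ** 2), rel=1e-8)

    def test_threshold_triggers_direct_recompute(self, rng):
        # near-linear block: analytic value is below Th1, the direct path
        # must agree with explicit summation
        j = np.arange(1, 101, dtype=float)
        y = 2.0 * j + 1e-6 * rng.normal(size=100)
        mom = _moments_for(y)
        coeffs = fit_block_poly(mom, 1)
        th = core.Thresholds(th1=1.0, th2=1.0)
        var = residual_variance_fast(coeffs, mom, 1, th, core.Profile(y))[0]
        res = y - np.polynomial.polynomial.polyval(
            j, np.polynomial.polynomial.polyfit(j, y, 1))
        assert var == pytest.approx(np.mean(res ** 2), rel=1e-6)


class TestThresholdDefaults:
    @pytest.mark.parametrize("N,th1,th2", [
        (10 ** 4, 1e-3, 1.0),
        (10 ** 6, 1e-2, 100.0),
        (10 ** 2, 1e-3, 1e-2),
        (10 ** 5, 1e-3, 10.0),
    ])
    def test_length_dependence(self, N, th1, th2):
        th = default_thresholds(N)
        assert th.th1 == pytest.approx(th1)
        assert th.th2 == pytest.approx(th2)
        assert th.eps == 0.0


# ---------------------------------------------------------------------------
# fluctuation function

class TestFluctuationFunction:
    @pytest.mark.parametrize("q", [-5.0, -1.0, 0.0, 1.0, 2.0, 5.0])
    def test_constant_variances(self, q):
        F, m = fluctuation_function(np.full(10, 2.25), q)
        assert F == pytest.approx(1.5, rel=1e-12)
        assert m == 10

    def test_two_variance_example_q2(self):
        F, m = fluctuation_function(np.array([1.0, 4.0]), 2.0)
        # power mean: ((1^1 + 4^1)/2)^(1/2)
        assert F == pytest.approx(np.sqrt(2.5), rel=1e-12)
        assert m == 2

    def test_two_variance_example_q0(self):
        F, _ = fluctuation_function(np.array([1.0, 4.0]), 0.0)
        assert F == pytest.approx(np.sqrt(2.0), rel=1e-12)

    def test_zero_variances_excluded_at_nonpositive_q(self):
        v = np.array([0.0, 1.0, 4.0])
        for q in (-2.0, 0.0):
            F, m = fluctuation_function(v, q)
            assert m == 2
        F, m = fluctuation_function(v, 2.0)
        assert m == 3  # zeros legitimately contribute nothing at q > 0

    def test_eps_discards_uniformly(self):
        v = np.array([1e-9, 1.0, 4.0])
        for q in (-2.0, 0.0, 2.0):
            _, m = fluctuation_function(v, q, eps=1e-4)
            assert m == 2

    def test_all_excluded_reports_missing(self):
        F, m = fluctuation_function(np.zeros(5), -1.0)
        assert np.isnan(F) and m == 0

    def test_negative_q_avoids_overflow(self):
        v = np.array([1e-300, 1e-280])
        F, m = fluctuation_function(v, -5.0)
        assert np.isfinite(F) and F > 0 and m == 2


# ---------------------------------------------------------------------------
# full surface

class TestFqSurface:
    def test_affine_invariance(self, white_series):
        base = fq_surface(white_series, n_grid=[8, 32, 128], orders=(1, 2))
        scaled = fq_surface(3.0 * white_series + 7.0,
                            n_grid=[8, 32, 128], orders=(1, 2))
        for o in (1, 2):
            # normalization undoes the affine map up to rounding in (x-mu)/s
            np.testing.assert_allclose(scaled[o].F, base[o].F, rtol=1e-6)

    def test_power_mean_monotonic_in_q(self, white_series):
        surf = fq_surface(white_series, orders=(1,))[1]
        dF = np.diff(surf.F, axis=0)
        assert np.all(dF[np.isfinite(dF)] >= -1e-12)

    def test_exact_polynomial_profile_annihilated(self):
        # a linear series has an exactly quadratic profile, so order-2
        # detrending leaves zero residuals in every block: F = 0 at q > 0
        # and the q <= 0 cells are reported missing
        lin = np.linspace(-1.0, 1.0, 64)
        surf = fq_surface(lin, n_grid=[8, 16], orders=(2,))[2]
        jq_pos = surf.q_grid > 0
        assert np.all(np.abs(surf.F[jq_pos, :]) < 1e-10)
        # at q <= 0 the cells are either reported missing (exact zeros
        # excluded) or carry only float dust from the residual evaluation
        jq_neg = surf.q_grid <= 0
        dust = surf.F[jq_neg, :]
        assert np.all(~np.isfinite(dust) | (np.abs(dust) < 1e-10))

    def test_deterministic(self, white_series):
        a = fq_surface(white_series, orders=(1,))[1]
        b = fq_surface(white_series, orders=(1,))[1]
        np.testing.assert_array_equal(a.F, b.F)

    def test_shared_grid_and_counts(self, white_series):
        surf = fq_surface(white_series, orders=(1, 2))
        np.testing.assert_array_equal(surf[1].n_grid, surf[2].n_grid)
        N = white_series.size
        # at maximal overlap every retained count is M = N - n + 1
        for o in (1, 2):
            expected = N - surf[o].n_grid + 1
            assert np.all(surf[o].retained == expected[None, :])

    def test_default_scale_grid_shape(self):
        grid = default_scale_grid(100_000)
        assert grid[0] == 8 and grid[-1] == 25_000
        assert np.all(np.diff(grid) > 0)

    def test_invalid_orders_rejected(self, white_series):
        with pytest.raises(ValueError):
            fq_surface(white_series, orders=(3,))

    def test_to_frame_columns(self, white_series):
        frame = fq_surface(white_series, n_grid=[8, 16],
                           orders=(1,))[1].to_frame()
        assert list(frame.columns) == [
            "order", "q", "n", "tau", "F_normalized", "F_original_units",
            "retained_blocks"]
        assert len(frame) == 11 * 2
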