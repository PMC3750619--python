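"""Trimmed means, central bands and scale curves derived from the MBD ordering."""

import math

import numpy as np
import pytest

from mbdtools import band_area, central_band, central_partition, mbd, scale_curve, tmean

from conftest import random_matrix


class TestTrimmedMean:
    def test_alpha_zero_is_ordinary_mean(self, rng):
        x = random_matrix(rng, 11, 7)
        res = tmean(x, alpha=0.0)
        np.testing.assert_array_equal(np.sort(res.retained), np.arange(11))
        np.testing.assert_allclose(res.tm, x.mean(axis=0), atol=1e-15)

    @pytest.mark.parametrize("n,alpha,kept", [(25, 0.25, 19), (25, 0.0, 25), (10, 0.5, 5), (7, 0.9, 1)])
    def test_retention_count(self, rng, n, alpha, kept):
        res = tmean(random_matrix(rng, n, 4), alpha=alpha)
        assert len(res.retained) == kept == math.ceil((1 - alpha) * n)

    def test_identical_rows_give_common_row(self):
        x = np.tile([3.0, -1.0, 2.0], (6, 1))
        for a in (0.0, 0.3, 0.8):
            np.testing.assert_allclose(tmean(x, a).tm, [3.0, -1.0, 2.0])

    def test_retained_are_the_deepest(self, rng):
        x = random_matrix(rng, 15, 6)
        res = tmean(x, alpha=0.4)
        np.testing.assert_array_equal(res.retained, mbd(x).ordering[: len(res.retained)])

    def test_invalid_alpha(self, rng):
        x = random_matrix(rng, 5, 3)
        for a in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError, match="invalid trimming proportion"):
                tmean(x, alpha=a)

    def test_robust_to_gross_outliers(self, rng):
        clean = rng.standard_normal((20, 30))
        outliers = rng.standard_normal((2, 30)) + 50.0
        x = np.vstack([clean, outliers])
        target = np.zeros(30)  # clean-population mean
        robust = tmean(x, alpha=0.2).tm
        naive = x.mean(axis=0)
        assert np.linalg.norm(robust - target) < np.linalg.norm(naive - target)


class TestCentralBand:
    def test_p_one_is_full_envelope(self, rng):
        x = random_matrix(rng, 9, 5)
        env = central_band(x, 1.0)
        np.testing.assert_array_equal(env.lower, x.min(axis=0))
        np.testing.assert_array_equal(env.upper, x.max(axis=0))

    def test_tiny_p_selects_only_deepest(self, rng):
        x = random_matrix(rng, 9, 5)
        env = central_band(x, 0.05)  # ceil(0.45) = 1 sample
        deepest = mbd(x).deepest
        np.testing.assert_array_equal(env.lower, x[deepest])
        np.testing.assert_array_equal(env.upper, x[deepest])

    def test_quarter_of_25_keeps_seven(self, rng):
        env = central_band(random_matrix(rng, 25, 4), 0.25)
        assert len(env.members) == 7

    def test_invalid_p(self, rng):
        x = random_matrix(rng, 5, 3)
        for p in (0.0, -0.2, 1.01):
            with pytest.raises(ValueError, match="invalid proportion"):
                central_band(x, p)

    def test_partition_is_nested(self, rng):
        x = random_matrix(rng, 14, 10, ties=True)
        envs = central_partition(x, [0.25, 0.5, 0.75, 1.0])
        assert len(envs) == 4
        for inner, outer in zip(envs, envs[1:]):
            assert np.all(inner.lower >= outer.lower)
            assert np.all(inner.upper <= outer.upper)

    def test_partition_rejects_non_increasing(self, rng):
        with pytest.raises(ValueError, match="invalid band limits"):
            central_partition(random_matrix(rng, 5, 3), [0.5, 0.5, 1.0])


class TestScaleCurve:
    def test_area_nondecreasing_in_p(self, rng):
        for _ in range(10):
            x = random_matrix(rng, int(rng.integers(3, 20)), int(rng.integers(2, 15)), ties=True)
            sc = scale_curve(x)
            assert np.all(np.diff(sc.area) >= -1e-12)

    def test_single_central_sample_has_zero_area(self, rng):
        x = random_matrix(rng, 10, 6)
        sc = scale_curve(x, p_grid=[0.1])  # ceil(1) = 1 sample
        assert sc.area[0] == 0.0

    def test_one_variable_always_zero_area(self, rng):
        sc = scale_curve(random_matrix(rng, 8, 1))
        np.testing.assert_array_equal(sc.area, 0.0)

    def test_translation_invariance_and_scale_equivariance(self, rng):
        x = random_matrix(rng, 12, 9)
        shift = rng.standard_normal(9)
        base = scale_curve(x).area
        np.testing.assert_allclose(scale_curve(x + shift).area, base, atol=1e-9)
        np.testing.assert_allclose(scale_curve(3.0 * x).area, 3.0 * base, rtol=1e-12)

    def test_scaled_population_dominates(self, rng):
        center = rng.standard_normal(20)
        a = center + rng.standard_normal((25, 20))
        b = center + 3.0 * rng.standard_normal((25, 20))
        sa, sb = scale_curve(a), scale_curve(b)
        # compare at p >= 2/n where bands are non-degenerate
        assert np.all(sb.area[2:] > sa.area[2:])

    def test_band_area_is_trapezoidal(self):
        env = central_band(np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 1.0]]), 1.0)
        assert band_area(env) == pytest.approx(np.trapezoid([1.0, 2.0, 1.0]))
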