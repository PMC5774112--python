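"""Normalization conventions and the low-intensity filter."""

import numpy as np
import pandas as pd
import pytest

from radioshift.preprocess import (FilterConfig, estimate_error_coefficient,
                                   filter_low_intensity, normalize_to_control_median,
                                   normalize_to_percentile)

from conftest import make_matrix


class TestPercentileNormalization:
    def test_constant_array_becomes_one(self):
        m = make_matrix(np.full((5, 2), 7.0), ["g", "g"], ["18w", "18w"])
        out = normalize_to_percentile(m, 50)
        assert (out.values.to_numpy() == 1.0).all()
        assert out.scale == "chip_normalized"

    def test_median_uses_linear_interpolation(self):
        # 50th percentile of (1,2,3,4) under linear interpolation is 2.5
        m = make_matrix(np.array([[1.0], [2.0], [3.0], [4.0]]), ["g"], ["18w"])
        out = normalize_to_percentile(m, 50)
        np.testing.assert_allclose(out.values.iloc[:, 0], [0.4, 0.8, 1.2, 1.6])

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(3, 1, size=(30, 2))
        m1 = make_matrix(vals, ["g", "g"], ["18w", "18w"])
        scaled = vals.copy()
        scaled[:, 1] *= 10
        m2 = make_matrix(scaled, ["g", "g"], ["18w", "18w"])
        pd.testing.assert_frame_equal(normalize_to_percentile(m1).values,
                                      normalize_to_percentile(m2).values)

    def test_rejects_non_raw_scale(self):
        m = make_matrix(np.ones((3, 1)), ["g"], ["18w"], scale="chip_normalized")
        with pytest.raises(ValueError, match="raw"):
            normalize_to_percentile(m)


class TestControlMedianNormalization:
    def _chipnorm(self, vals, groups, tps):
        return make_matrix(np.asarray(vals, float), groups, tps, scale="chip_normalized")

    def test_equal_control_values_become_one(self):
        m = self._chipnorm([[2.0, 2.0, 6.0]], ["ctrl", "ctrl", "trt"], ["18w"] * 3)
        out = normalize_to_control_median(m, "ctrl")
        np.testing.assert_allclose(out.values.iloc[0], [1.0, 1.0, 3.0])

    def test_even_control_count_uses_central_mean(self):
        # control values (2, 4) -> median 3; treated 6 -> ratio 2
        m = self._chipnorm([[2.0, 4.0, 6.0]], ["ctrl", "ctrl", "trt"], ["18w"] * 3)
        out = normalize_to_control_median(m, "ctrl")
        assert out.values.iloc[0, 2] == pytest.approx(2.0)

    def test_contemporaneous_isolation(self):
        """30-week ratios are untouched by changes to 18-week controls."""
        vals = np.array([[2.0, 8.0, 5.0, 10.0]])
        groups = ["ctrl", "trt", "ctrl", "trt"]
        tps = ["18w", "18w", "30w", "30w"]
        out1 = normalize_to_control_median(self._chipnorm(vals, groups, tps), "ctrl")
        vals2 = vals.copy()
        vals2[0, 0] = 400.0  # perturb the 18w control only
        out2 = normalize_to_control_median(self._chipnorm(vals2, groups, tps), "ctrl")
        cols_30 = [c for c, tp in zip(out1.values.columns, tps) if tp == "30w"]
        pd.testing.assert_frame_equal(out1.values[cols_30], out2.values[cols_30])

    def test_zero_control_median_becomes_nan(self):
        m = self._chipnorm([[0.0, 0.0, 6.0]], ["ctrl", "ctrl", "trt"], ["18w"] * 3)
        out = normalize_to_control_median(m, "ctrl")
        assert out.values.iloc[0].isna().all()

    def test_control_ratio_median_is_one_per_timepoint(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(0, 1, size=(50, 6))
        groups = ["ctrl", "ctrl", "trt", "ctrl", "ctrl", "trt"]
        tps = ["18w"] * 3 + ["30w"] * 3
        out = normalize_to_control_median(self._chipnorm(vals, groups, tps), "ctrl")
        for tp in ("18w", "30w"):
            ctrl = out.arrays_where(group="ctrl", timepoint=tp)
            np.testing.assert_allclose(out.values[ctrl].median(axis=1), 1.0, rtol=1e-12)

    def test_missing_controls_at_timepoint_errors(self):
        m = self._chipnorm([[1.0, 2.0]], ["trt", "trt"], ["18w", "18w"])
        with pytest.raises(ValueError, match="18w"):
            normalize_to_control_median(m, "ctrl")


class TestErrorCoefficient:
    def test_constant_low_block_gives_zero(self):
        vals = np.concatenate([np.full(10, 2.0), np.full(90, 100.0)])
        m = make_matrix(vals[:, None], ["g"], ["18w"])
        assert estimate_error_coefficient(m).iloc[0] == 0.0

    def test_recovers_known_background_sd(self):
        rng = np.random.default_rng(42)
        n = 40000
        bg = rng.normal(50, 5, n // 10)
        sig = rng.normal(5000, 300, n - n // 10)
        m = make_matrix(np.concatenate([bg, sig])[:, None], ["g"], ["18w"])
        est = estimate_error_coefficient(m).iloc[0]
        assert est == pytest.approx(5.0, rel=0.2)

    def test_invariant_to_probe_order(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(2, 1, 200)
        m1 = make_matrix(vals[:, None], ["g"], ["18w"])
        m2 = make_matrix(vals[::-1][:, None], ["g"], ["18w"])
        assert estimate_error_coefficient(m1).iloc[0] == \
            estimate_error_coefficient(m2).iloc[0]

    def test_too_few_probes_errors(self):
        m = make_matrix(np.ones((5, 1)), ["g"], ["18w"])
        with pytest.raises(ValueError, match="10"):
            estimate_error_coefficient(m)


def _background_matrix(seed=0, n_signal=900, n_background=100, n_arrays=28):
    """Signal probes far above background, plus planted all-background probes.

    Background probes are exactly the lowest decile of every array, bounded,
    and with spread large relative to their range (arcsine-shaped), so their
    maximum always lies below 3x the robust scale of that decile.
    """
    rng = np.random.default_rng(seed)
    sig = rng.lognormal(np.log(1000), 0.3, size=(n_signal, n_arrays))
    bg = rng.beta(0.5, 0.5, size=(n_background, n_arrays))
    vals = np.vstack([sig, bg])
    groups = ["g"] * n_arrays
    tps = ["18w"] * n_arrays
    m = make_matrix(vals, groups, tps)
    background_probes = [f"p{i}" for i in range(n_signal, n_signal + n_background)]
    return m, background_probes


class TestLowIntensityFilter:
    def test_planted_background_probes_all_removed(self):
        m, bg_probes = _background_matrix()
        retained = filter_low_intensity(m, FilterConfig())
        assert not set(bg_probes) & set(retained)
        # expressed probes kept
        assert len(retained) == 900

    def test_boundary_on_failing_array_count(self):
        n_arrays = 5
        vals = np.full((3, n_arrays), 100.0)
        # probe p1 fails on exactly 2 arrays, p2 on exactly 3
        vals = np.vstack([vals, np.array([[0.0, 0.0, 100, 100, 100]]),
                          np.array([[0.0, 0.0, 0.0, 100, 100]])])
        # add low-intensity noise block so the coefficient is positive
        rng = np.random.default_rng(0)
        vals = np.vstack([vals, np.abs(rng.normal(0, 1, size=(45, n_arrays)))])
        m = make_matrix(vals, ["g"] * n_arrays, ["18w"] * n_arrays)
        cfg = FilterConfig(min_failing_arrays=3)
        retained = filter_low_intensity(m, cfg)
        assert "p3" in retained      # 2 failures < 3
        assert "p4" not in retained  # 3 failures

    def test_min_failing_exceeding_arrays_errors(self):
        m, _ = _background_matrix(n_arrays=5)
        with pytest.raises(ValueError, match="min_failing_arrays"):
            filter_low_intensity(m, FilterConfig(min_failing_arrays=6))

    @pytest.mark.parametrize("mult_pair", [(1.0, 3.0), (3.0, 10.0)])
    def test_multiplier_monotonicity(self, mult_pair):
        m, _ = _background_matrix(seed=1)
        lo, hi = mult_pair
        kept_lo = filter_low_intensity(m, FilterConfig(error_coefficient_multiplier=lo))
        kept_hi = filter_low_intensity(m, FilterConfig(error_coefficient_multiplier=hi))
        assert set(kept_hi) <= set(kept_lo)

    def test_min_failing_monotonicity(self):
        m, _ = _background_matrix(seed=2)
        kept_strict = filter_low_intensity(m, FilterConfig(min_failing_arrays=5))
        kept_lax = filter_low_intensity(m, FilterConfig(min_failing_arrays=28))
        assert set(kept_strict) <= set(kept_lax)
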