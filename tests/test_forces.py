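import numpy as np
import pytest

from mechunfold.forces import (SmoothedTrace, combine, count_peaks, rupture_force,
                               smooth, smooth_trace)
from mechunfold.io import ForceTrace
from mechunfold.synthetic import TraceSpec, gen_force_trace


def trace(f1, f2, dt=0.05, v_pull=1.0):
    n = len(f1)
    return ForceTrace(time=np.arange(n) * dt, f1=np.asarray(f1, float),
                      f2=np.asarray(f2, float), v_pull=v_pull, k_spring=830.0)


def triangle_profile(peaks, width=5.0, dx=0.05):
    """Symmetric triangles of given (x_center, height) on a flat baseline."""
    x = np.arange(0.0, max(p[0] for p in peaks) + 2 * width, dx)
    f = np.zeros_like(x)
    for xc, h in peaks:
        f += np.clip(h * (1 - np.abs(x - xc) / (width / 2)), 0.0, None)
    return x, f


class TestCombine:
    @pytest.mark.parametrize("f1,f2,expected", [(100.0, -100.0, 100.0),
                                                (100.0, -90.0, 95.0),
                                                (0.0, 0.0, 0.0)])
    def test_half_difference(self, f1, f2, expected):
        tr = trace([f1] * 2, [f2] * 2)
        np.testing.assert_allclose(combine(tr), expected)


class TestSmooth:
    def test_constant_stays_constant_everywhere(self):
        st = smooth(np.full(200, 7.0), np.arange(200) * 0.05, v_pull=1.0)
        np.testing.assert_allclose(st.force, 7.0, atol=1e-12)

    def test_sigma_time_scales_inversely_with_velocity(self):
        st = smooth(np.zeros(100), np.arange(100) * 0.05, v_pull=0.01,
                    elong_width=0.1)
        assert st.sigma_time == pytest.approx(10.0)
        assert st.sigma_elong == pytest.approx(0.1)

    def test_unit_impulse_becomes_normalized_gaussian(self):
        n = 401
        f = np.zeros(n)
        f[200] = 1.0
        st = smooth(f, np.arange(n) * 0.05, v_pull=1.0, elong_width=0.5)
        assert st.force.sum() == pytest.approx(1.0, rel=1e-9)
        assert np.argmax(st.force) == 200
        np.testing.assert_allclose(st.force, st.force[::-1], atol=1e-12)

    def test_non_uniform_sampling_rejected(self):
        t = np.array([0.0, 0.05, 0.2, 0.25])
        with pytest.raises(ValueError, match="resampl"):
            smooth(np.zeros(4), t, v_pull=1.0)

    def test_linear_and_shift_invariant(self):
        rng = np.random.default_rng(7)
        f = rng.normal(size=300)
        g = rng.normal(size=300)
        t = np.arange(300) * 0.05
        s = lambda y: smooth(y, t, 1.0).force
        np.testing.assert_allclose(s(2 * f + 3 * g), 2 * s(f) + 3 * s(g),
                                   atol=1e-9)
        np.testing.assert_allclose(s(f + 5.0), s(f) + 5.0, atol=1e-9)

    def test_smoothed_max_bounded_by_raw_max(self):
        rng = np.random.default_rng(11)
        f = rng.normal(200, 50, size=500)
        st = smooth(f, np.arange(500) * 0.05, 1.0)
        assert st.force.max() <= f.max() + 1e-9


class TestRuptureForce:
    def test_window_excludes_later_higher_peak(self):
        x, f = triangle_profile([(12.0, 600.0), (30.0, 800.0)])
        st = SmoothedTrace(elongation=x, force=f, sigma_time=0.1, sigma_elong=0.1)
        rec = rupture_force(st)
        assert rec.f_r == pytest.approx(600.0)
        assert rec.peak_x == pytest.approx(12.0)

    def test_monotone_ramp_peaks_at_window_edge(self):
        x = np.arange(0.0, 20.05, 0.05)
        st = SmoothedTrace(elongation=x, force=10 * x, sigma_time=0.1,
                           sigma_elong=0.1)
        rec = rupture_force(st)
        assert rec.peak_x == pytest.approx(20.0)

    def test_short_trace_flagged_truncated(self):
        x = np.arange(0.0, 5.0, 0.05)
        st = SmoothedTrace(elongation=x, force=np.ones_like(x), sigma_time=0.1,
                           sigma_elong=0.1)
        assert rupture_force(st).truncated

    def test_monotone_in_window_width(self):
        x, f = triangle_profile([(12.0, 600.0), (30.0, 800.0)])
        st = SmoothedTrace(elongation=x, force=f, sigma_time=0.1, sigma_elong=0.1)
        f_narrow = rupture_force(st, first_peak_window=15.0).f_r
        f_wide = rupture_force(st, first_peak_window=35.0).f_r
        assert f_narrow <= f_wide

    def test_planted_sawtooth_peak_matches_closed_form_smoothing(self):
        # noiseless Bell-loading trace: ramp at 50 pN/nm with a full drop at
        # x0 = 10 nm, i.e. f(x) = k·x − F·H(x−x0).  Its Gaussian smoothing is
        # g(x) = k·x − F·Phi((x−x0)/sigma), maximized at x0 − u·sigma with
        # u = sqrt(2·ln(F/(k·sigma·sqrt(2·pi)))).
        from scipy.stats import norm
        spec = TraceSpec(v_pull=0.1, k_eff=50.0, events=((10.0, 1.0),),
                         noise_sd=0.0, duration=150.0)
        st = smooth_trace(gen_force_trace(spec, seed=0), elong_width=0.1)
        rec = rupture_force(st)
        k, F, sigma, x0 = spec.k_eff, 500.0, st.sigma_elong, 10.0
        u = np.sqrt(2 * np.log(F / (k * sigma * np.sqrt(2 * np.pi))))
        x_star = x0 - u * sigma
        g_star = k * x_star - F * norm.cdf(-u)
        assert rec.f_r == pytest.approx(g_star, abs=0.5)
        assert rec.peak_x == pytest.approx(x_star, abs=0.05)


class TestCountPeaks:
    def test_three_planted_triangles(self):
        x, f = triangle_profile([(10.0, 500.0), (25.0, 500.0), (40.0, 500.0)])
        st = SmoothedTrace(elongation=x, force=f, sigma_time=0.1, sigma_elong=0.1)
        n, px = count_peaks(st, prominence=100.0, min_separation=5.0)
        assert n == 3
        np.testing.assert_allclose(px, [10.0, 25.0, 40.0], atol=0.05)

    def test_low_middle_peak_not_counted(self):
        x, f = triangle_profile([(10.0, 500.0), (25.0, 80.0), (40.0, 500.0)])
        st = SmoothedTrace(elongation=x, force=f, sigma_time=0.1, sigma_elong=0.1)
        assert count_peaks(st, prominence=100.0, min_separation=5.0)[0] == 2

    def test_flat_trace_has_no_peaks(self):
        st = SmoothedTrace(elongation=np.arange(100.0), force=np.zeros(100),
                           sigma_time=0.1, sigma_elong=0.1)
        assert count_peaks(st, prominence=100.0, min_separation=5.0)[0] == 0

    def test_peak_ordering_consistent_across_smoothing_widths(self):
        # well-separated peaks of distinct heights keep their height order
        spec = TraceSpec(v_pull=0.1, k_eff=50.0, noise_sd=15.0, duration=600.0,
                         events=((8.0, 1.0), (24.0, 1.0), (45.0, 1.0)))
        tr = gen_force_trace(spec, seed=3)
        orders = []
        for width in (0.1, 1.0):
            st = smooth_trace(tr, elong_width=width)
            _, px = count_peaks(st, prominence=100.0, min_separation=5.0)
            heights = [st.force[np.argmin(np.abs(st.elongation - x))] for x in px]
            orders.append(np.argsort(heights).tolist())
        assert orders[0] == orders[1]
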