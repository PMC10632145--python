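"""Calcium preprocessing chain: interpolation, bleach, outliers, smoothing,
response windows, second derivative."""

import numpy as np
import pytest

from sigprop.traces import (RawTraceSet, correct_photobleach,
                            interpolate_missing, preprocess, remove_outliers,
                            response_window, second_derivative, smooth_causal)


def make_traces(F, dt=0.5, mask=None):
    F = np.atleast_2d(np.asarray(F, float)).T if np.asarray(F).ndim == 1 else np.asarray(F, float)
    if mask is None:
        mask = np.zeros_like(F, dtype=bool)
    return RawTraceSet(F=F, mask=mask, dt=dt)


class TestInterpolation:
    def test_no_missing_is_identity(self, rng):
        tr = make_traces(rng.standard_normal(100))
        out = interpolate_missing(tr)
        np.testing.assert_array_equal(out.F, tr.F)

    def test_linear_midpoint(self):
        F = np.array([1.0, 99.0, 3.0])
        mask = np.array([[False], [True], [False]])
        out = interpolate_missing(make_traces(F, mask=mask))
        assert out.F[1, 0] == pytest.approx(2.0)

    def test_sinusoid_reconstruction_within_curvature_bound(self, rng):
        dt = 0.5
        t = np.arange(0, 100, dt)
        omega = 0.3
        F = np.sin(omega * t) + 2.0
        mask = (rng.random(t.size) < 0.1)
        mask[0] = mask[-1] = False
        # isolated gaps only: the analytic bound applies to single-sample gaps
        mask[1:] &= ~mask[:-1]
        out = interpolate_missing(make_traces(F, mask=mask[:, None]))
        err = np.max(np.abs(out.F[:, 0] - F))
        bound = (2 * dt) ** 2 * omega**2 / 8.0
        assert err <= bound * 1.01

    def test_too_few_samples_raises(self):
        mask = np.array([[True], [True], [False]])
        with pytest.raises(ValueError, match="present samples"):
            interpolate_missing(make_traces([1.0, 2.0, 3.0], mask=mask))

    def test_edge_gap_held_at_nearest(self):
        F = np.array([9.0, 5.0, 6.0, 9.0])
        mask = np.array([[True], [False], [False], [True]])
        out = interpolate_missing(make_traces(F, mask=mask))
        assert out.F[0, 0] == 5.0 and out.F[3, 0] == 6.0


class TestBleachCorrection:
    def test_constant_trace_unchanged(self):
        tr = make_traces(np.full(400, 50.0))
        out = correct_photobleach(tr)
        np.testing.assert_allclose(out.F, tr.F, rtol=1e-3)

    def test_pure_double_exponential_flattened(self):
        t = np.arange(0, 600, 0.5)
        F = 30.0 * np.exp(-t / 400.0) + 70.0 * np.exp(-t / 2000.0)
        out = correct_photobleach(make_traces(F))
        rel_dev = np.abs(out.F[:, 0] - F[0]) / F[0]
        assert rel_dev.max() < 0.01

    def test_transient_amplitudes_preserved(self):
        t = np.arange(0, 600, 0.5)
        base = 40.0 * np.exp(-t / 300.0) + 60.0 * np.exp(-t / 3000.0)
        transient = np.zeros_like(t)
        for t0 in (100, 300, 500):
            transient += 20.0 * np.exp(-np.clip(t - t0, 0, None) / 5.0) * (t >= t0)
        out = correct_photobleach(make_traces(base + transient))
        corrected = out.F[:, 0]
        for t0 in (100, 300, 500):
            i = int(t0 / 0.5)
            true_amp = 20.0 / base[i] * base[0]
            got_amp = corrected[i] - corrected[i - 5]
            assert got_amp == pytest.approx(true_amp, rel=0.05)


class TestOutlierRemoval:
    def test_clean_gaussian_unchanged(self, rng):
        F = rng.standard_normal(500)
        F = F[np.abs(F - F.mean()) < 4.9 * F.std()]
        tr = make_traces(F)
        out = remove_outliers(tr)
        np.testing.assert_array_equal(out.F, tr.F)

    def test_single_spike_removed(self, rng):
        F = rng.standard_normal(500)
        F = F[np.abs(F - F.mean()) < 4 * F.std()]
        spiked = F.copy()
        spiked[100] = F.mean() + 10 * F.std()
        out = remove_outliers(make_traces(spiked))
        assert abs(out.F[100, 0] - spiked[100]) > 5 * F.std()
        np.testing.assert_array_equal(out.F[102:, 0], spiked[102:])

    def test_constant_trace_no_division_error(self):
        tr = make_traces(np.full(50, 3.0))
        out = remove_outliers(tr)
        np.testing.assert_array_equal(out.F, tr.F)


class TestCausalSmoothing:
    def test_constant_unchanged(self):
        tr = make_traces(np.full(50, 2.5))
        np.testing.assert_allclose(smooth_causal(tr).F, tr.F, atol=1e-10)

    def test_linear_ramp_reproduced_exactly(self):
        F = 0.7 * np.arange(60) + 3.0
        out = smooth_causal(make_traces(F))
        np.testing.assert_allclose(out.F[:, 0], F, atol=1e-9)

    def test_causality_impulse(self):
        F = np.zeros(60)
        F[30] = 1.0
        out = smooth_causal(make_traces(F))
        assert np.all(out.F[:30, 0] == 0)
        assert np.any(out.F[30:, 0] != 0)

    def test_short_trace_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            smooth_causal(make_traces(np.ones(5)))


class TestResponseWindow:
    def _tr(self, F):
        return make_traces(F)

    def test_constant_gives_zero(self):
        tr = self._tr(np.full(200, 80.0))
        w = response_window(tr, stim_time=40.0, neuron=0)
        assert np.all(w.values == 0)
        assert w.F0 == 80.0

    def test_doubling_gives_one(self):
        F = np.full(240, 50.0)
        F[120:] = 100.0
        w = response_window(self._tr(F), stim_time=60.0, neuron=0)
        assert np.all(w.post_values == pytest.approx(1.0))

    def test_exponential_decay_mean_closed_form(self):
        dt, a, tau, T = 0.5, 0.8, 6.0, 30.0
        F0 = 100.0
        F = np.full(240, F0)
        i0 = 120
        t_post = np.arange(0, T, dt)
        F[i0:i0 + t_post.size] = F0 * (1 + a * np.exp(-t_post / tau))
        w = response_window(self._tr(F), stim_time=i0 * dt, neuron=0)
        expected = a * tau * (1 - np.exp(-T / tau)) / T
        # left-endpoint sampling biases the discrete mean by ~dt/(2 tau)
        assert w.post_values.mean() == pytest.approx(expected, rel=dt / tau)

    def test_scale_invariance(self, rng):
        F = 100.0 + 5 * rng.standard_normal(240).cumsum() * 0.01 + np.linspace(0, 1, 240)
        w1 = response_window(self._tr(F), 60.0, 0)
        w2 = response_window(self._tr(3.7 * F), 60.0, 0)
        np.testing.assert_allclose(w1.values, w2.values, rtol=1e-10, atol=1e-12)

    def test_negative_baseline_rejected(self):
        F = np.full(240, -5.0)
        with pytest.raises(ValueError, match="baseline"):
            response_window(self._tr(F), 60.0, 0)


class TestSecondDerivative:
    def _window(self, values, dt=0.5):
        from sigprop.traces import ResponseWindow
        t = np.arange(values.size) * dt - 30.0
        return ResponseWindow(values=values, F0=1.0, dt=dt, t=t,
                              pre_mask=t < 0, post_mask=t >= 0)

    def test_linear_is_zero(self):
        w = self._window(0.3 * np.arange(120.0))
        assert np.max(np.abs(second_derivative(w)[13:])) < 1e-9

    def test_quadratic_gives_constant(self):
        dt = 0.5
        t = np.arange(120) * dt
        a = 0.02
        w = self._window(a * t**2, dt)
        np.testing.assert_allclose(second_derivative(w)[13:], 2 * a, rtol=1e-6)

    def test_sine_amplitude_transfer(self):
        # d2/dt2 sin(wt) = -w^2 sin(wt); the causal filter attenuates, so the
        # measured amplitude ratio must lie between ~half and the exact w^2
        dt = 0.5
        t = np.arange(400) * dt
        omega = 0.2
        w = self._window(np.sin(omega * t), dt)
        d2 = second_derivative(w)[50:]
        ratio = d2.std() / np.sin(omega * t)[50:].std()
        assert 0.4 * omega**2 < ratio <= omega**2 * 1.05


class TestPipeline:
    def test_stage_idempotence(self, rng):
        # smoothing is exactly idempotent on signals it reproduces (order <= 1)
        ramp = make_traces(2.0 + 0.3 * np.arange(100.0))
        sm = smooth_causal(ramp)
        np.testing.assert_allclose(smooth_causal(sm).F, sm.F, atol=1e-9)
        F = 100 + rng.standard_normal(300)
        tr = make_traces(F)
        it = interpolate_missing(tr)
        np.testing.assert_array_equal(interpolate_missing(it).F, it.F)
        ro = remove_outliers(tr)
        np.testing.assert_array_equal(remove_outliers(ro).F, ro.F)

    def test_full_chain_runs(self, rng):
        F = (100 * np.exp(-np.arange(300) * 0.5 / 500.0))[:, None] + rng.standard_normal((300, 1))
        mask = rng.random((300, 1)) < 0.05
        out = preprocess(RawTraceSet(F=F, mask=mask, dt=0.5))
        assert out.F.shape == F.shape
        assert not out.mask.any()
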