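"""Symbolic exponential-convolution algebra, fitting, rise time, stereotypy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sigprop.kernels import (CanonicalTerm, ExpChainTerm, Kernel, apply_kernel,
                             convolve_exp, desaturate, eval_kernel, fit_kernel,
                             random_kernel, rise_time, stereotypy, to_canonical)
from conftest import numeric_kernel_eval


class TestConvolutionRules:
    def test_equal_rate_exponential_gives_linear_term(self):
        # e^{-gt} (*) g e^{-gt} = g t e^{-gt}
        out = convolve_exp(CanonicalTerm(1.0, 0, 0.7), 0.7)
        assert out == [CanonicalTerm(0.7, 1, 0.7)]

    def test_distinct_rate_exponential_splits_into_two(self):
        out = convolve_exp(CanonicalTerm(1.0, 0, 1.0), 2.0)
        assert sorted((t.a, t.n, t.gamma) for t in out) == [(-2.0, 0, 2.0), (2.0, 0, 1.0)]

    @pytest.mark.parametrize("term,gn", [
        (CanonicalTerm(1.0, 0, 1.0), 2.0),
        (CanonicalTerm(0.5, 2, 0.4), 0.4),
        (CanonicalTerm(-1.3, 3, 0.9), 0.35),
        (CanonicalTerm(2.0, 1, 1.5), 0.2),
    ])
    def test_rules_match_numerical_convolution(self, term, gn):
        dt, tmax = 0.002, 40.0
        t = np.arange(0.0, tmax, dt)
        f = term.a * t**term.n * np.exp(-term.gamma * t)
        g = gn * np.exp(-gn * t)
        num = np.convolve(f, g)[: t.size] * dt - 0.5 * dt * (f[0] * g + g[0] * f)
        out = Kernel([])
        out._canonical = convolve_exp(term, gn)
        sym = eval_kernel(out, t)
        assert np.max(np.abs(sym - num)) < 1e-4 * max(np.max(np.abs(num)), 1e-12)

    def test_output_is_causal(self):
        out = convolve_exp(CanonicalTerm(1.0, 1, 0.5), 0.9)
        k = Kernel([])
        k._canonical = out
        assert np.all(eval_kernel(k, np.array([-5.0, -0.1])) == 0.0)


class TestCanonicalExpansion:
    def test_single_chain_is_identity(self):
        terms = to_canonical(Kernel([ExpChainTerm(2.5, (0.3,))]))
        assert terms == [CanonicalTerm(2.5, 0, 0.3)]

    def test_triple_equal_rate_chain(self):
        # (theta e^{-gt})^{*3} = t^2/2 e^{-gt}; integral 1/g^3
        g = 0.5
        k = Kernel([ExpChainTerm(1.0, (g, g, g))])
        terms = k.canonical
        assert len(terms) == 1
        assert terms[0].n == 2 and terms[0].gamma == g
        assert terms[0].a == pytest.approx(0.5)
        assert k.integral() == pytest.approx(1.0 / g**3)

    def test_integral_identity(self, rng):
        # sum over chains of c_m * prod(1/gamma) equals the canonical integral
        for _ in range(20):
            k = random_kernel(rng)
            canon_integral = sum(t.integral() for t in k.canonical)
            assert canon_integral == pytest.approx(k.integral(), rel=1e-9)

    def test_convolution_is_commutative(self):
        a = Kernel([ExpChainTerm(1.0, (0.2, 1.1))])
        b = Kernel([ExpChainTerm(1.0, (1.1, 0.2))])
        t = np.linspace(0, 50, 500)
        np.testing.assert_allclose(eval_kernel(a, t), eval_kernel(b, t), rtol=1e-10)

    def test_symbolic_equals_numeric_on_random_kernels(self, rng):
        worst = 0.0
        for _ in range(25):
            k = random_kernel(rng)
            num = numeric_kernel_eval(k, 60.0, 0.01)
            sym = eval_kernel(k, np.arange(0.0, 60.0, 0.01))
            err = np.max(np.abs(sym - num)) / np.max(np.abs(num))
            worst = max(worst, err)
        assert worst < 1e-6


class TestEvalAndApply:
    def test_empty_kernel_evaluates_to_zero(self):
        assert np.all(eval_kernel(Kernel(), np.linspace(-5, 5, 11)) == 0)

    def test_unit_exponential_at_zero(self):
        assert eval_kernel(Kernel([ExpChainTerm(1.0, (1.0,))]), np.array([0.0]))[0] == 1.0

    def test_two_rate_chain_closed_form(self):
        k = Kernel([ExpChainTerm(1.0, (1.0, 2.0))])
        t = np.array([0.3, 1.0, 2.5])
        np.testing.assert_allclose(eval_kernel(k, t), np.exp(-t) - np.exp(-2 * t),
                                   rtol=1e-12)

    def test_apply_zero_kernel(self):
        u = np.sin(np.linspace(0, 5, 40))
        assert np.all(apply_kernel(Kernel(), u, 0.5) == 0)

    def test_step_response_closed_form(self):
        # a e^{-gt} * step -> a (1 - e^{-gt}) / g
        a, g, dt = 0.7, 0.4, 0.002
        u = np.ones(int(40 / dt))
        out = apply_kernel(Kernel([ExpChainTerm(a, (g,))]), u, dt)
        t = np.arange(u.size) * dt
        expected = a * (1 - np.exp(-g * t)) / g
        assert np.max(np.abs(out - expected)) < a * dt * 2

    @given(alpha=st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=20, deadline=None)
    def test_linearity(self, alpha):
        k = Kernel([ExpChainTerm(0.5, (0.3, 0.8))])
        u = np.cos(np.linspace(0, 6, 50))
        np.testing.assert_allclose(apply_kernel(k, alpha * u, 0.5),
                                   alpha * apply_kernel(k, u, 0.5), atol=1e-12)


class TestFitting:
    dt = 0.5

    def _auto(self):
        t = np.arange(0, 30, self.dt)
        return np.exp(-t / 8.0) - np.exp(-t / 1.5)

    def test_zero_downstream_gives_zero_kernel(self):
        u = self._auto()
        assert fit_kernel(u, np.zeros_like(u), self.dt).is_zero()

    def test_noiseless_single_chain_recovery(self):
        u = self._auto()
        true = Kernel([ExpChainTerm(0.4, (0.25,))])
        d = apply_kernel(true, u, self.dt)
        fit = fit_kernel(u, d, self.dt)
        pred = apply_kernel(fit, u, self.dt)
        r2 = 1 - np.sum((pred - d) ** 2) / np.sum((d - d.mean()) ** 2)
        assert r2 > 0.99

    def test_saturating_two_chain_recovery_under_noise(self, rng):
        u = self._auto()
        true = Kernel([ExpChainTerm(0.6, (0.4,)), ExpChainTerm(-0.25, (1.2,))])
        d = apply_kernel(true, u, self.dt)
        noisy = d + 0.1 * np.max(np.abs(d)) * rng.standard_normal(d.size)
        fit = fit_kernel(u, noisy, self.dt)
        pred = apply_kernel(fit, u, self.dt)
        r2 = 1 - np.sum((pred - d) ** 2) / np.sum((d - d.mean()) ** 2)
        assert r2 > 0.95

    def test_longer_chains_cannot_fit_worse(self):
        # adding convolution factors enriches the model family; the selected
        # fit must be at least as good as the best single-exponential fit
        u = self._auto()
        d = apply_kernel(Kernel([ExpChainTerm(0.5, (0.3, 0.3))]), u, self.dt)
        fit1 = fit_kernel(u, d, self.dt, models=((1,),))
        fit_all = fit_kernel(u, d, self.dt)
        rss = lambda k: np.sum((apply_kernel(k, u, self.dt) - d) ** 2)
        assert rss(fit_all) <= rss(fit1) * (1 + 1e-6)


class TestSerialization:
    def test_dict_roundtrip_preserves_kernel(self, rng):
        k = random_kernel(rng)
        back = Kernel.from_dict(k.to_dict())
        t = np.linspace(0, 40, 200)
        np.testing.assert_array_equal(eval_kernel(back, t), eval_kernel(k, t))


class TestRiseTime:
    def test_single_exponential_is_instantaneous(self):
        assert rise_time(Kernel([ExpChainTerm(1.0, (0.5,))])) == 0.0

    def test_linear_times_exponential_matches_grid_oracle(self):
        g = 0.8
        k = Kernel([ExpChainTerm(1.0, (g, g))])
        t = np.arange(0, 60, 1e-4)
        v = np.abs(eval_kernel(k, t))
        ipk = np.argmax(v)
        oracle = t[ipk] - t[np.nonzero(v[: ipk + 1] >= v[ipk] / np.e)[0][0]]
        assert rise_time(k) == pytest.approx(oracle, abs=0.25)

    def test_saturating_kernel_desaturates_to_zero_rise(self):
        # fast instantaneous transfer masked by a slower opposite-sign term
        k = Kernel([ExpChainTerm(1.0, (0.3,)), ExpChainTerm(-0.8, (1.5,))])
        raw_peak_t = np.argmax(np.abs(eval_kernel(k, np.arange(0, 60, 0.01))))
        assert raw_peak_t > 0  # raw shape peaks late
        assert rise_time(k) == 0.0

    def test_zero_kernel_rejected(self):
        with pytest.raises(ValueError):
            rise_time(Kernel())

    def test_desaturate_keeps_dominant_sign(self):
        k = Kernel([ExpChainTerm(1.0, (0.5,)), ExpChainTerm(-0.3, (1.0,))])
        kept = desaturate(k)
        assert all(ch.c > 0 for ch in kept.chains)


class TestStereotypy:
    def _stims(self):
        t = np.arange(0, 30, 0.5)
        return [np.exp(-t / 5.0) - np.exp(-t / 1.0), np.exp(-t / 8.0)]

    def test_identical_kernels_score_one(self):
        k = Kernel([ExpChainTerm(0.5, (0.3,))])
        assert stereotypy([k, k, k], self._stims(), 0.5) == pytest.approx(1.0)

    def test_sign_flip_scores_minus_one(self):
        k = Kernel([ExpChainTerm(0.5, (0.3,))])
        neg = Kernel([ExpChainTerm(-0.5, (0.3,))])
        assert stereotypy([k, neg], self._stims(), 0.5) == pytest.approx(-1.0)

    def test_matches_brute_force_round_robin(self, rng):
        kernels = [random_kernel(rng) for _ in range(4)]
        stims = self._stims()
        outs = {(i, s): apply_kernel(k, stims[s], 0.5)
                for i, k in enumerate(kernels) for s in range(len(stims))}
        cors = []
        for s in range(len(stims)):
            for i in range(4):
                for j in range(i + 1, 4):
                    cors.append(np.corrcoef(outs[(i, s)], outs[(j, s)])[0, 1])
        assert stereotypy(kernels, stims, 0.5) == pytest.approx(np.mean(cors))

    def test_requires_two_kernels(self):
        with pytest.raises(ValueError):
            stereotypy([Kernel([ExpChainTerm(1.0, (0.5,))])], self._stims(), 0.5)
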