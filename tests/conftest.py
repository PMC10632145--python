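import logging

import numpy as np
import pytest

from sigprop.kernels import ExpChainTerm, Kernel
from sigprop.synth import GroundTruthNetwork, SimConfig, gen_ground_truth

logging.getLogger("sigprop").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def single_edge_net():
    """Two neurons, one known excitatory kernel 0 -> 1."""
    k = Kernel([ExpChainTerm(0.4, (0.3,))])
    return GroundTruthNetwork(
        n_neurons=2, edges={(0, 1): k},
        inhibitory_flags={(0, 1): False}, extrasynaptic_flags={(0, 1): False})


@pytest.fixture()
def quiet_cfg():
    """Noise-free, bleach-free, gap-free configuration."""
    return SimConfig(duration=120.0, noise_sd=0.0, missing_fraction=0.0,
                     response_probability=1.0, seed=7)


@pytest.fixture(scope="session")
def small_net():
    return gen_ground_truth(8, 0.2, frac_inhibitory=0.1, seed=11)


def trapezoid_convolve(f, g, dt):
    """Composite-trapezoid causal convolution of two sampled causal signals."""
    n = f.size
    c = np.convolve(f, g)[:n] * dt
    return c - 0.5 * dt * (f[0] * g + g[0] * f)


def numeric_kernel_eval(k: Kernel, t_max: float, dt: float) -> np.ndarray:
    """Independent numerical evaluation: trapezoid convolution of the chain
    factors on a dt grid, Richardson-refined with the dt/2 grid."""
    def on_grid(step):
        t = np.arange(0.0, t_max, step)
        total = np.zeros_like(t)
        for ch in k.chains:
            f = None
            for gam in ch.rates:
                e = np.exp(-gam * t)
                f = e if f is None else trapezoid_convolve(f, e, step)
            total += ch.c * f
        return total
    coarse = on_grid(dt)
    fine = on_grid(dt / 2)[::2]
    return (4.0 * fine - coarse) / 3.0
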