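import numpy as np
import pytest

from girfopt import EddyModel, EpiSequenceSpec, build_epi
from girfopt.waveform import GradientWaveform, RasterGrid

DT = 10e-6


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def eddy_model():
    """The scanner-typical single eddy term used throughout the benchmarks."""
    return EddyModel(terms=[(5e-6, 50e-6)])


@pytest.fixture(scope="session")
def small_spec():
    """Fast EPI spec for unit tests (seconds, not minutes)."""
    return EpiSequenceSpec(matrix=32, R=1, partial_fourier="25/32", echo_spacing=0.6e-3)


@pytest.fixture(scope="session")
def small_epi(small_spec):
    return build_epi(small_spec)


@pytest.fixture(scope="session")
def bench_spec():
    """The full-scale R=1 benchmark used by the acceptance tests."""
    return EpiSequenceSpec(matrix=64, R=1, partial_fourier="49/64", echo_spacing=1.07e-3)


@pytest.fixture(scope="session")
def bench_epi(bench_spec):
    return build_epi(bench_spec)


@pytest.fixture(scope="session")
def bench_optimized(bench_epi, eddy_model):
    """Optimized R=1 benchmark, shared across acceptance tests (slow)."""
    from girfopt.optimize import OptimizationProblem, optimize

    w, adc = bench_epi
    problem = OptimizationProblem(
        initial=w, adc=adc, model=eddy_model, n_iters=30000, seed=1
    )
    return optimize(problem)


def random_waveform(rng, n, scale=5.0, dt=DT, axes=(0, 1, 2)):
    g = np.zeros((3, n))
    for ax in axes:
        g[ax, 1:-1] = rng.normal(0, scale, n - 2)
    return GradientWaveform(RasterGrid(dt=dt, n=n), g)


def smooth_waveform(n, freq=100.0, amp=20.0, dt=DT):
    """Narrow-band (hanning-windowed sine) waveform, zero at the ends."""
    t = np.arange(n) * dt
    g = np.zeros((3, n))
    g[0] = amp * np.sin(2 * np.pi * freq * t) * np.hanning(n)
    g[1] = 0.5 * amp * np.sin(2 * np.pi * 0.7 * freq * t) * np.hanning(n)
    g[:, 0] = 0.0
    g[:, -1] = 0.0
    return GradientWaveform(RasterGrid(dt=dt, n=n), g)
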