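"""k-space loss, hinge penalties, analytic gradients, and optimization."""

import numpy as np
import pytest

from girfopt import (
    EddyModel,
    HardwareLimits,
    OptimizationProblem,
    k_rmse,
    kspace_loss,
    optimize,
)
from girfopt.distortion import as_operator
from girfopt.epi import AdcSampling
from girfopt.optimize import _loss_and_grad, constraint_penalty
from girfopt.waveform import GradientWaveform, RasterGrid

from conftest import DT, random_waveform


def test_kspace_loss_zero_for_identity_model(small_epi):
    w, adc = small_epi
    assert kspace_loss(w, adc, EddyModel(terms=[])) == pytest.approx(0.0, abs=1e-18)


def test_kspace_loss_uniform_shift_closed_form(small_epi):
    """Shifting nominal targets by delta in k_x gives loss = N_k * delta^2."""
    w, adc = small_epi
    delta = 0.37
    shifted = AdcSampling(times=adc.times, nominal_k=adc.nominal_k + [delta, 0.0])
    loss = kspace_loss(w, shifted, EddyModel(terms=[]))
    assert loss == pytest.approx(adc.n_samples * delta**2, rel=1e-10)


def test_kspace_loss_matches_bruteforce(rng, eddy_model):
    """Independent cumulative-sum recomputation of the realized trajectory."""
    from girfopt.distortion import eddy_forward

    n = 200
    w = random_waveform(rng, n)
    times = np.sort(rng.uniform(0, n * DT, 17))
    k0 = rng.normal(0, 30, (17, 2))
    adc = AdcSampling(times=times, nominal_k=k0)
    loss = kspace_loss(w, adc, eddy_model)
    # brute force: trapezoid-free direct sum per sample time
    G = eddy_forward(w, eddy_model).samples
    from girfopt.waveform import GAMMA_BAR_MT

    acc = 0.0
    for i, t in enumerate(times):
        mfull = int(np.floor(t / DT))
        for col, ax in enumerate([0, 1]):
            k = GAMMA_BAR_MT * (np.sum(G[ax, :mfull]) * DT + G[ax, mfull] * (t - mfull * DT))
            acc += (k - k0[i, col]) ** 2
    assert loss == pytest.approx(acc, rel=1e-10)


def test_penalty_zero_within_limits(small_epi):
    w, _ = small_epi
    assert constraint_penalty(w, HardwareLimits(g_max=72.0, s_max=180.0), 1.0, 1.0) == 0.0


def test_penalty_single_amplitude_hinge():
    g = np.zeros((3, 6))
    g[0, 3] = 73.0  # one sample 1 mT/m over the limit
    g[2, 2] = -10.0
    w = GradientWaveform(RasterGrid(dt=DT, n=6), g)
    lim = HardwareLimits(g_max=72.0, s_max=1e9)
    assert constraint_penalty(w, lim, w_g=1.0, w_s=0.0) == pytest.approx(1.0)


def test_nominal_benchmark_penalty_free(bench_epi):
    w, _ = bench_epi
    assert constraint_penalty(w, HardwareLimits(g_max=72.0, s_max=180.0), 1e3, 1e3) == 0.0


def test_gradient_matches_finite_differences(rng, eddy_model):
    """Analytic adjoint gradient vs central differences on a 30-sample toy,
    with both hinge penalties active."""
    n = 30
    g = np.zeros((3, n))
    g[:2, 1:-1] = rng.normal(0, 20, (2, n - 2))
    w = GradientWaveform(RasterGrid(dt=DT, n=n), g)
    times = np.sort(rng.uniform(2 * DT, (n - 2) * DT, 9))
    adc = AdcSampling(times=times, nominal_k=rng.normal(0, 50, (9, 2)))
    op = as_operator(eddy_model, n, DT)
    lim = HardwareLimits(g_max=30.0, s_max=400.0)
    total, _, l_amp, l_slew, grad = _loss_and_grad(g, w, adc, op, lim, 7.0, 3.0, times)
    assert l_amp > 0 and l_slew > 0
    fd = np.zeros_like(g)
    h = 1e-4
    for ax in range(3):
        for i in range(n):
            gp = g.copy()
            gp[ax, i] += h
            gm = g.copy()
            gm[ax, i] -= h
            fd[ax, i] = (
                _loss_and_grad(gp, w, adc, op, lim, 7.0, 3.0, times)[0]
                - _loss_and_grad(gm, w, adc, op, lim, 7.0, 3.0, times)[0]
            ) / (2 * h)
    assert np.linalg.norm(grad - fd) / np.linalg.norm(fd) < 1e-5


def test_gradient_matches_finite_differences_tf(rng):
    """Same check through the transfer-function operator with cross-terms."""
    from girfopt import make_synthetic_tf
    from girfopt.distortion import fft_length

    n = 30
    g = np.zeros((3, n))
    g[:2, 1:-1] = rng.normal(0, 10, (2, n - 2))
    w = GradientWaveform(RasterGrid(dt=DT, n=n), g)
    times = np.sort(rng.uniform(2 * DT, (n - 2) * DT, 7))
    adc = AdcSampling(times=times, nominal_k=rng.normal(0, 40, (7, 2)))
    grid = np.sort(np.fft.fftfreq(fft_length(n), d=DT))
    tf = make_synthetic_tf(
        eddy=EddyModel(terms=[(5e-6, 50e-6)]), delay=3e-6, cross_scale=0.05,
        grid=grid, dt=DT,
    )
    op = as_operator(tf, n, DT)
    lim = HardwareLimits(g_max=1e9, s_max=1e9)
    _, _, _, _, grad = _loss_and_grad(g, w, adc, op, lim, 0.0, 0.0, times)
    fd = np.zeros_like(g)
    h = 1e-4
    for ax in range(3):
        for i in range(n):
            gp = g.copy()
            gp[ax, i] += h
            gm = g.copy()
            gm[ax, i] -= h
            fd[ax, i] = (
                _loss_and_grad(gp, w, adc, op, lim, 0.0, 0.0, times)[0]
                - _loss_and_grad(gm, w, adc, op, lim, 0.0, 0.0, times)[0]
            ) / (2 * h)
    assert np.linalg.norm(grad - fd) / np.linalg.norm(fd) < 1e-5


def test_identity_model_is_noop(small_epi):
    w, adc = small_epi
    problem = OptimizationProblem(
        initial=w, adc=adc, model=EddyModel(terms=[]), n_iters=5
    )
    res = optimize(problem)
    assert res.loss_history[0, 0] == pytest.approx(0.0, abs=1e-18)
    assert res.best_iteration == 0
    np.testing.assert_array_equal(res.waveform.samples, w.samples)


def test_best_loss_non_increasing(small_epi, eddy_model):
    w, adc = small_epi
    res = optimize(
        OptimizationProblem(initial=w, adc=adc, model=eddy_model, n_iters=300)
    )
    running = np.minimum.accumulate(res.loss_history[:, 0])
    assert np.all(np.diff(running) <= 0)
    assert res.loss_history.shape == (300, 4)


def test_endpoints_pinned(small_epi, eddy_model):
    w, adc = small_epi
    res = optimize(
        OptimizationProblem(initial=w, adc=adc, model=eddy_model, n_iters=200)
    )
    assert res.waveform.has_zero_ends()
    np.testing.assert_array_equal(res.waveform.samples[2], w.samples[2])  # z untouched


def test_optimization_reduces_k_error(small_epi, eddy_model):
    """Short run on the small sequence: order-of-magnitude k-rmse drop
    while respecting the hardware limits."""
    w, adc = small_epi
    unc = k_rmse(w, adc, eddy_model)
    res = optimize(
        OptimizationProblem(initial=w, adc=adc, model=eddy_model, n_iters=6000, seed=3)
    )
    assert res.final_k_rmse <= 0.10 * unc
    assert res.peak_slew <= 180.0
    assert res.peak_g <= 72.0


def test_unpenalized_at_least_as_good_in_k(small_epi, eddy_model):
    """Dropping the penalties is a relaxation: its k-loss cannot be worse
    (at matched budgets, up to small optimization noise)."""
    w, adc = small_epi
    kwargs = dict(initial=w, adc=adc, model=eddy_model, n_iters=3000)
    pen = optimize(OptimizationProblem(**kwargs))
    rel = optimize(OptimizationProblem(w_g=0.0, w_s=0.0, **kwargs))
    k_pen = np.min(pen.loss_history[:, 1])
    k_rel = np.min(rel.loss_history[:, 1])
    assert k_rel <= k_pen * 1.05


def test_lowered_slew_limit_forces_tradeoff(small_epi, eddy_model):
    """With s_max below the nominal peak slew the optimizer must slow the
    ramps down: peak slew drops below the new limit (plus tolerance) while
    the k error degrades gracefully (stays below uncorrected)."""
    w, adc = small_epi
    tight = HardwareLimits(g_max=72.0, s_max=0.8 * w.peak_slew())
    res = optimize(
        OptimizationProblem(
            initial=w, adc=adc, model=eddy_model, limits=tight, n_iters=6000
        )
    )
    assert res.peak_slew <= tight.s_max * 1.02
    assert res.final_k_rmse < k_rmse(w, adc, eddy_model)


def test_determinism(small_epi, eddy_model):
    w, adc = small_epi
    r1 = optimize(OptimizationProblem(initial=w, adc=adc, model=eddy_model, n_iters=100, seed=5))
    r2 = optimize(OptimizationProblem(initial=w, adc=adc, model=eddy_model, n_iters=100, seed=5))
    np.testing.assert_array_equal(r1.waveform.samples, r2.waveform.samples)
    np.testing.assert_array_equal(r1.loss_history, r2.loss_history)
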