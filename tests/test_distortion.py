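"""Eddy-current and transfer-function forward models."""

import numpy as np
import pytest

from girfopt import EddyModel, eddy_forward, girf_forward, make_synthetic_tf
from girfopt.distortion import TransferFunction, fft_length
from girfopt.waveform import GradientWaveform, RasterGrid

from conftest import DT, random_waveform


def fft_grid(n, dt=DT):
    """Sorted FFT frequency grid of the padded transform (exact tf grid)."""
    return np.sort(np.fft.fftfreq(fft_length(n), d=dt))


# ---------------------------------------------------------------------------
# exponential eddy model


def test_empty_terms_is_identity(rng):
    w = random_waveform(rng, 100)
    out = eddy_forward(w, EddyModel(terms=[]))
    np.testing.assert_array_equal(out.samples, w.samples)


def test_eddy_matches_bruteforce_convolution(rng):
    """FFT convolution path vs an O(n^2) direct sum over kernel samples."""
    n = 120
    w = random_waveform(rng, n)
    alpha, tau = 3e-6, 40e-6
    out = eddy_forward(w, EddyModel(terms=[(alpha, tau)])).samples
    gdot = np.diff(np.concatenate([w.samples, np.zeros((3, 1))], axis=1), axis=1) / DT
    expected = w.samples.copy()
    for ax in range(3):
        for i in range(n):
            acc = 0.0
            for j in range(i + 1):
                acc += gdot[ax, i - j] * alpha * np.exp(-j * DT / tau)
            expected[ax, i] -= acc
    np.testing.assert_allclose(out, expected, rtol=1e-10, atol=1e-12)


def test_eddy_flattop_closed_form():
    """During the flat-top the perturbation is a geometric-sum transient.

    With slew samples occupying indices [0, r) at constant rate sdot, the
    perturbation at flat sample i >= r is
    sdot * alpha * q^{i-r+1} (1 - q^r) / (1 - q),  q = e^{-dt/tau}.
    """
    r, f, a = 10, 60, 18.0
    alpha, tau = 5e-6, 50e-6
    n = 1 + r + f + r + 1
    g = np.zeros((3, n))
    g[0, 1 : 1 + r] = a * np.arange(1, r + 1) / r
    g[0, 1 + r : 1 + r + f] = a
    g[0, 1 + r + f : 1 + 2 * r + f] = a * np.arange(r - 1, -1, -1) / r
    w = GradientWaveform(RasterGrid(dt=DT, n=n), g)
    out = eddy_forward(w, EddyModel(terms=[(alpha, tau)])).samples
    sdot = a / (r * DT)
    q = np.exp(-DT / tau)
    # skip the final flat sample: the forward-difference slew already sees
    # the down-ramp there
    for i in range(1 + r + 5, r + f):
        transient = sdot * alpha * q ** (i - r + 1) * (1 - q**r) / (1 - q)
        assert out[0, i] == pytest.approx(a - transient, rel=1e-9)


def test_eddy_causality(rng):
    """Perturbing future samples never changes earlier realized samples."""
    w = random_waveform(rng, 200)
    m = EddyModel(terms=[(5e-6, 50e-6), (1e-6, 300e-6)])
    base = eddy_forward(w, m).samples
    g2 = w.samples.copy()
    g2[:, 150:-1] += rng.normal(0, 5, (3, 49))
    out = eddy_forward(GradientWaveform(w.grid, g2), m).samples
    # one-sample lookahead from the forward-difference slew: sample 149 may
    # move; everything earlier must be unchanged (to FFT roundoff)
    np.testing.assert_allclose(out[:, :149], base[:, :149], rtol=0, atol=1e-12)
    assert not np.allclose(out[:, 150:], base[:, 150:])


def test_eddy_dc_fidelity_on_plateau():
    """Realized value converges to the demanded plateau as transients decay."""
    n = 3000
    g = np.zeros((3, n))
    g[0, 1:200] = np.linspace(0, 30, 199)
    g[0, 200:-1] = 30.0
    w = GradientWaveform(RasterGrid(dt=DT, n=n), g)
    out = eddy_forward(w, EddyModel(terms=[(5e-6, 50e-6)])).samples
    # deep into the plateau (clear of the ramp transient and of the final
    # step back to zero) the realized value equals the demand
    assert abs(out[0, n - 10] - 30.0) < 1e-9


def test_eddy_benchmark_displaces_most_adc_samples(bench_epi, eddy_model):
    from girfopt.waveform import waveform_kspace

    w, adc = bench_epi
    realized = eddy_forward(w, eddy_model)
    traj = waveform_kspace(realized, adc.times, axes=(0, 1))
    disp = np.abs(traj.k - adc.nominal_k).max(axis=1)
    assert np.mean(disp > 1e-9) >= 0.90


# ---------------------------------------------------------------------------
# transfer-function operator


def test_identity_tf_is_identity(rng):
    n = 256
    w = random_waveform(rng, n)
    tf = TransferFunction.identity(fft_grid(n))
    out = girf_forward(w, tf).samples
    np.testing.assert_allclose(out, w.samples, rtol=0, atol=1e-12 * np.abs(w.samples).max())


def test_girf_linearity(rng):
    n = 300
    w1 = random_waveform(rng, n)
    w2 = random_waveform(rng, n)
    tf = make_synthetic_tf(
        eddy=EddyModel(terms=[(5e-6, 50e-6)]),
        delay=2e-6,
        resonances=[(1200.0, 0.05, 0.02)],
        cross_scale=0.01,
        grid=fft_grid(n),
        dt=DT,
    )
    a, b = 1.7, -0.6
    combo = GradientWaveform(w1.grid, a * w1.samples + b * w2.samples)
    lhs = girf_forward(combo, tf).samples
    rhs = a * girf_forward(w1, tf).samples + b * girf_forward(w2, tf).samples
    np.testing.assert_allclose(lhs, rhs, rtol=0, atol=1e-10 * np.abs(lhs).max())


def test_girf_hermitian_returns_real(rng):
    """A Hermitian response always produces a real waveform (no raise)."""
    n = 200
    w = random_waveform(rng, n)
    tf = make_synthetic_tf(
        eddy=EddyModel(terms=[(1e-5, 80e-6)]), delay=5e-6, cross_scale=0.05,
        grid=fft_grid(n), dt=DT,
    )
    out = girf_forward(w, tf)
    assert np.isrealobj(out.samples)


def test_synthetic_tf_matches_eddy_forward(rng):
    """Cross-model oracle: raster-discretized tf == exponential model."""
    n = 2000
    w = random_waveform(rng, n)
    m = EddyModel(terms=[(5e-6, 50e-6)])
    tf = make_synthetic_tf(eddy=m, grid=fft_grid(n), dt=DT, discretization="raster")
    a = eddy_forward(w, m).samples
    b = girf_forward(w, tf).samples
    rel = np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(a**2))
    assert rel < 1e-6


def test_tf_range_too_narrow_raises(rng):
    w = random_waveform(rng, 100)
    tf = TransferFunction.identity(np.linspace(-10e3, 10e3, 101))
    with pytest.raises(ValueError, match="tabulated range"):
        girf_forward(w, tf)


def test_tf_selfterm_csv_loader(tmp_path):
    freq = np.linspace(-50e3, 50e3, 11)
    h = 1.0 / (1.0 + 1j * freq / 30e3)
    path = tmp_path / "tf.csv"
    rows = ["freq_hz,H_real,H_imag"] + [
        f"{f},{v.real},{v.imag}" for f, v in zip(freq, h)
    ]
    path.write_text("\n".join(rows))
    tf = TransferFunction.load_selfterm_csv(path)
    for i in range(3):
        np.testing.assert_allclose(tf.H[i, i], h)
    np.testing.assert_allclose(tf.freq, freq)


def test_tf_h5_roundtrip(tmp_path):
    tf = make_synthetic_tf(
        eddy=EddyModel(terms=[(5e-6, 50e-6)]), delay=1e-6, cross_scale=0.02, dt=DT
    )
    path = tmp_path / "tf.h5"
    tf.save_h5(path)
    back = TransferFunction.load_h5(path)
    np.testing.assert_array_equal(back.freq, tf.freq)
    np.testing.assert_array_equal(back.H, tf.H)


# ---------------------------------------------------------------------------
# synthetic-tf generator


def test_synthetic_tf_no_terms_is_identity():
    tf = make_synthetic_tf(eddy=EddyModel(terms=[]), dt=DT)
    for i in range(3):
        np.testing.assert_allclose(tf.H[i, i], 1.0)
        for j in range(3):
            if i != j:
                np.testing.assert_array_equal(tf.H[i, j], 0.0)


def test_pure_delay_phase_slope():
    delay = 7e-6
    grid = np.linspace(-50e3, 50e3, 501)
    tf = make_synthetic_tf(delay=delay, grid=grid, dt=DT)
    phase = np.unwrap(np.angle(tf.H[0, 0]))
    slopes = np.diff(phase) / np.diff(2 * np.pi * grid)
    np.testing.assert_allclose(slopes, -delay, rtol=1e-9)


def test_eddy_selfterm_magnitude_dip():
    """|H(0)| = 1 and |H| dips below 1 at intermediate frequency.

    Direct-evaluation oracle for the continuous flavour:
    H = 1 - i w (alpha/dt) tau / (1 + i w tau).
    """
    alpha, tau = 5e-6, 50e-6
    grid = np.linspace(-50e3, 50e3, 1001)
    tf = make_synthetic_tf(
        eddy=EddyModel(terms=[(alpha, tau)]), grid=grid, dt=DT, discretization="continuous"
    )
    h = tf.H[0, 0]
    mid = grid.size // 2
    assert abs(h[mid]) == pytest.approx(1.0, abs=1e-12)
    w = 2 * np.pi * grid
    expected = 1.0 - 1j * w * (alpha / DT) * tau / (1.0 +1j * w * tau)
    np.testing.assert_allclose(h, expected, rtol=1e-12)
    assert np.abs(h[mid + 100]) < 1.0
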