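"""Forward models mapping demanded to realized gradient waveforms.

Two model families are supported:

* an analytic exponential eddy-current model: each step in the demanded
  waveform excites decaying perturbations, realized as a causal convolution
  of the discrete slew with exponential kernels;
* a tabulated linear-time-invariant gradient system transfer function
  (GSTF) with cross-terms, applied by frequency-domain multiplication.

Discretization convention for the eddy model
--------------------------------------------
The model is defined on the gradient raster: with discrete slew
``gdot[i] = (g[i+1] - g[i]) / dt`` (units mT/m/s, trailing zero sample), the
realized waveform is

    G[i] = g[i] - sum_j gdot[i - j] * sum_n alpha_n * exp(-j * dt / tau_n)

i.e. kernel *samples* ``alpha_n * exp(-j dt / tau_n)`` (j >= 0) are summed
against the slew without a dt weight.  Equivalently the continuous kernel is
``(alpha_n / dt) * exp(-t / tau_n)``: the amplitude ``alpha_n`` is specified
per raster interval, which is how scanner eddy-current amplitude settings
are conventionally quoted.  With the typical raster of 10 us, an amplitude
of a few 1e-6 already produces percent-level waveform perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.fft import next_fast_len
from scipy.signal import fftconvolve

from .waveform import GradientWaveform


@dataclass
class EddyModel:
    """List of exponential eddy-current terms (alpha_n, tau_n).

    ``alpha_n`` is the dimensionless per-raster amplitude (see module
    docstring); ``tau_n`` is the decay time constant in seconds.  An empty
    list is the identity model.
    """

    terms: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, tau in self.terms:
            if not tau > 0:
                raise ValueError(f"eddy time constant must be positive, got {tau}")

    def kernel(self, n: int, dt: float) -> np.ndarray:
        """Summed kernel samples ``sum_n alpha_n exp(-j dt / tau_n)``, j < n."""
        j = np.arange(n)
        out = np.zeros(n)
        for a, tau in self.terms:
            out += a * np.exp(-j * dt / tau)
        return out


def _forward_diff(samples: np.ndarray, dt: float) -> np.ndarray:
    """Discrete slew in mT/m/s with trailing zero sample, shape preserved."""
    padded = np.concatenate([samples[:, 1:], np.zeros((samples.shape[0], 1))], axis=1)
    return (padded - samples) / dt


def eddy_forward(w: GradientWaveform, m: EddyModel) -> GradientWaveform:
    """Realized waveform under the exponential eddy-current model.

    Acts independently per axis (no cross-terms); causal by construction.
    """
    if not m.terms:
        return w.copy()
    n = w.n
    ker = m.kernel(n, w.dt)
    gdot = _forward_diff(w.samples, w.dt)
    pert = fftconvolve(gdot, ker[None, :], axes=1)[:, :n]
    return GradientWaveform(w.grid, w.samples - pert)


@dataclass
class TransferFunction:
    """Tabulated first-order GSTF: complex 3x3 response on a frequency grid.

    ``H[out_axis, in_axis, :]`` maps demanded input axes to realized output
    axes.  The grid must be monotonically increasing and, for real realized
    waveforms, the response must satisfy Hermitian symmetry
    ``H(-f) = conj(H(f))`` (enforced approximately by the constructors,
    checked when applied).
    """

    freq: np.ndarray  # Hz, increasing, spanning negative and positive
    H: np.ndarray  # complex, shape (3, 3, n_freq)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.H = np.asarray(self.H, dtype=complex)
        if self.H.shape != (3, 3, self.freq.size):
            raise ValueError(f"H must have shape (3, 3, n_freq), got {self.H.shape}")
        if self.freq.size > 1 and not np.all(np.diff(self.freq) > 0):
            raise ValueError("frequency grid must be strictly increasing")

    @classmethod
    def identity(cls, freq: np.ndarray) -> "TransferFunction":
        freq = np.asarray(freq, dtype=float)
        H = np.zeros((3, 3, freq.size), dtype=complex)
        for i in range(3):
            H[i, i] = 1.0
        return cls(freq, H)

    def interpolate(self, f: np.ndarray) -> np.ndarray:
        """H resampled at frequencies ``f`` (3, 3, f.size).

        Real and imaginary parts are interpolated linearly and separately.
        Frequencies beyond the tabulated grid raise: the tabulated range is
        the model's domain of validity and silent extrapolation would invent
        high-frequency response where measurements are unreliable.
        """
        f = np.asarray(f, dtype=float)
        if f.size and (f.min() < self.freq[0] - 1e-9 or f.max() > self.freq[-1] + 1e-9):
            raise ValueError(
                f"requested frequencies [{f.min():.3g}, {f.max():.3g}] Hz exceed "
                f"the tabulated range [{self.freq[0]:.3g}, {self.freq[-1]:.3g}] Hz"
            )
        out = np.empty((3, 3, f.size), dtype=complex)
        for o in range(3):
            for i in range(3):
                out[o, i] = np.interp(f, self.freq, self.H[o, i].real) + 1j * np.interp(
                    f, self.freq, self.H[o, i].imag
                )
        return out

    # -- I/O ---------------------------------------------------------------

    def save_h5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("freq", data=self.freq)
            fh.create_dataset("H_real", data=self.H.real)
            fh.create_dataset("H_imag", data=self.H.imag)

    @classmethod
    def load_h5(cls, path: str | Path) -> "TransferFunction":
        with h5py.File(path, "r") as fh:
            freq = np.asarray(fh["freq"])
            H = np.asarray(fh["H_real"]) + 1j * np.asarray(fh["H_imag"])
        return cls(freq, H)

    @classmethod
    def load_selfterm_csv(cls, path: str | Path) -> "TransferFunction":
        """Single-axis self-term CSV (columns: freq_hz, H_real, H_imag),
        replicated onto all three diagonal entries."""
        data = np.atleast_2d(np.loadtxt(path, delimiter=",", skiprows=1))
        tf = cls.identity(data[:, 0])
        for i in range(3):
            tf.H[i, i] = data[:, 1] + 1j * data[:, 2]
        return tf


def fft_length(n: int) -> int:
    """Padded FFT length used by the frequency-domain operators (>= 2n)."""
    return next_fast_len(2 * n)


def girf_forward(w: GradientWaveform, tf: TransferFunction) -> GradientWaveform:
    """Realized waveform under a tabulated GSTF, including cross-terms.

    The waveform is zero-padded to at least twice its duration (wraparound
    guard), transformed, multiplied by the interpolated response, and
    inverse-transformed; the result is asserted real and truncated to the
    original support.
    """
    n = w.n
    L = fft_length(n)
    f = np.fft.fftfreq(L, d=w.dt)
    Hf = tf.interpolate(f)
    if L % 2 == 0:
        # the unpaired Nyquist bin represents +/-f_nyq jointly and must be real
        Hf[:, :, L // 2] = Hf[:, :, L // 2].real
    X = np.fft.fft(w.samples, n=L, axis=1)
    Y = np.einsum("oif,if->of", Hf, X)
    y = np.fft.ifft(Y, axis=1)
    scale = np.max(np.abs(y)) or 1.0
    resid = np.max(np.abs(y.imag)) / scale
    if resid > 1e-9:
        raise ValueError(
            f"realized waveform has imaginary residue {resid:.2e} (relative); "
            "transfer function violates Hermitian symmetry"
        )
    out = y.real[:, :n].copy()
    return GradientWaveform(w.grid, out)


def make_synthetic_tf(
    eddy: EddyModel | None = None,
    delay: float = 0.0,
    resonances: list[tuple[float, float, float]] | None = None,
    cross_scale: float = 0.0,
    grid: np.ndarray | None = None,
    dt: float = 10e-6,
    discretization: str = "raster",
) -> TransferFunction:
    """Synthetic first-order GSTF emulating a measured gradient chain.

    Self-terms combine an eddy-current factor, a pure delay ``exp(-i w
    delay)``, and damped mechanical resonance factors
    ``1 + amp * (i w / w0) / (1 - (w / w0)^2 + 2 i zeta w / w0)`` for each
    ``(f0, damping, amplitude)`` triple.  Cross-terms, far smaller than
    self-terms on real systems, are smooth odd perturbations scaled by
    ``cross_scale`` (default 0).

    ``discretization='raster'`` uses the exact discrete-time transfer
    function of :func:`eddy_forward` on raster ``dt`` (forward-difference
    slew, kernel samples at j*dt), so that ``girf_forward`` with this tf
    reproduces ``eddy_forward`` to numerical precision when the grid matches
    the FFT frequencies.  ``'continuous'`` uses the continuous-time kernel
    ``(alpha/dt) exp(-t/tau)`` instead.
    """
    if grid is None:
        grid = np.linspace(-1.0 / (2 * dt), 1.0 / (2 * dt), 2049)
    grid = np.asarray(grid, dtype=float)
    if not (grid[0] < 0.0 < grid[-1]):
        raise ValueError("frequency grid must span negative and positive frequencies")
    w = 2 * np.pi * grid
    self_term = np.ones(grid.size, dtype=complex)
    if eddy is not None and eddy.terms:
        if discretization == "raster":
            D = (np.exp(1j * w * dt) - 1.0) / dt
            K = np.zeros(grid.size, dtype=complex)
            for a, tau in eddy.terms:
                K += a / (1.0 - np.exp(-dt / tau) * np.exp(-1j * w * dt))
            self_term = self_term - D * K
        elif discretization == "continuous":
            K = np.zeros(grid.size, dtype=complex)
            for a, tau in eddy.terms:
                K += (a / dt) * tau / (1.0 + 1j * w * tau)
            self_term = self_term - 1j * w * K
        else:
            raise ValueError(f"unknown discretization {discretization!r}")
    self_term = self_term * np.exp(-1j * w * delay)
    for f0, zeta, amp in resonances or []:
        u = grid / f0
        self_term = self_term * (1.0 + amp * (1j * u) / (1.0 - u**2 + 2j * zeta * u))

    H = np.zeros((3, 3, grid.size), dtype=complex)
    for i in range(3):
        H[i, i] = self_term
    if cross_scale:
        # smooth, Hermitian-symmetric cross coupling (odd imaginary lobe)
        f_n = grid / max(abs(grid[-1]), 1.0)
        lobe = 1j * f_n * np.exp(-(f_n * 3) ** 2)
        for o in range(3):
            for i in range(3):
                if o != i:
                    H[o, i] = cross_scale * (1.0 + 0.3 * (o - i)) * lobe
    # every factor above is Hermitian (H(-f) = conj(H(f))) by construction
    return TransferFunction(grid, H)


# ---------------------------------------------------------------------------
# linear-operator view used by the optimizer


class DistortionOperator:
    """Demanded -> realized linear map with an adjoint, fixed to a grid.

    The optimizer needs repeated applications of the model and of its
    adjoint (for analytic gradients); precomputing kernels/responses for a
    fixed waveform length keeps the inner loop cheap.
    """

    def apply(self, samples: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def adjoint(self, samples: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class EddyOperator(DistortionOperator):
    def __init__(self, model: EddyModel, n: int, dt: float):
        self.n = n
        self.dt = dt
        self.kernel = model.kernel(n, dt)
        self.active = bool(model.terms)

    def apply(self, samples: np.ndarray) -> np.ndarray:
        if not self.active:
            return samples.copy()
        gdot = _forward_diff(samples, self.dt)
        pert = fftconvolve(gdot, self.kernel[None, :], axes=1)[:, : self.n]
        return samples - pert

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        if not self.active:
            return y.copy()
        # adjoint of conv-with-kernel is correlation; adjoint of the
        # forward difference is a negated backward difference
        corr = fftconvolve(y, self.kernel[None, ::-1], axes=1)[:, self.n - 1 :]
        dcorr = np.empty_like(corr)
        dcorr[:, 0] = -corr[:, 0]
        dcorr[:, 1:] = corr[:, :-1] - corr[:, 1:]
        return y - dcorr / self.dt


class TransferFunctionOperator(DistortionOperator):
    def __init__(self, tf: TransferFunction, n: int, dt: float):
        self.n = n
        self.L = fft_length(n)
        f = np.fft.fftfreq(self.L, d=dt)
        self.Hf = tf.interpolate(f)
        if self.L % 2 == 0:
            self.Hf[:, :, self.L // 2] = self.Hf[:, :, self.L // 2].real

    def apply(self, samples: np.ndarray) -> np.ndarray:
        X = np.fft.fft(samples, n=self.L, axis=1)
        Y = np.einsum("oif,if->of", self.Hf, X)
        return np.fft.ifft(Y, axis=1).real[:, : self.n]

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        X = np.fft.fft(y, n=self.L, axis=1)
        Y = np.einsum("oif,of->if", np.conj(self.Hf), X)
        return np.fft.ifft(Y, axis=1).real[:, : self.n]


def as_operator(model, n: int, dt: float) -> DistortionOperator:
    if isinstance(model, EddyModel):
        return EddyOperator(model, n, dt)
    if isinstance(model, TransferFunction):
        return TransferFunctionOperator(model, n, dt)
    if isinstance(model, DistortionOperator):
        return model
    raise TypeError(f"unsupported distortion model type {type(model)!r}")


def apply_model(w: GradientWaveform, model) -> GradientWaveform:
    """Dispatch demanded -> realized for either model family."""
    if isinstance(model, EddyModel):
        return eddy_forward(w, model)
    if isinstance(model, TransferFunction):
        return girf_forward(w, model)
    raise TypeError(f"unsupported distortion model type {type(model)!r}")
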