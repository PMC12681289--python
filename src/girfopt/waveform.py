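"""Gradient waveforms on a fixed raster and their k-space trajectories.

Conventions used throughout the package:

* gradient amplitude is stored in mT/m, time in seconds;
* a waveform sample ``g[i]`` is held constant over ``[i*dt, (i+1)*dt)``
  (zero-order hold), so time integrals are exact piecewise-constant sums;
* slew rate is the forward difference ``(g[i+1] - g[i]) / dt`` with an
  implicit trailing zero sample, reported in mT/m/ms;
* k-space coordinates are in cycles/m, ``k(t) = gamma_bar * int_0^t G dt'``
  with ``gamma_bar = gamma / 2 pi = 42.577478 MHz/T``.  This choice makes the
  Cartesian line spacing of an imaging sequence exactly ``1 / FOV``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

#: gamma / 2 pi for protons in Hz/T.
GAMMA_BAR_HZ_PER_T = 42.577478e6

#: k-space accrual per (mT/m * s): gamma_bar * 1e-3, in 1/m.
GAMMA_BAR_MT = GAMMA_BAR_HZ_PER_T * 1e-3

#: default gradient raster time in seconds.
DEFAULT_RASTER = 10e-6

AXES = ("x", "y", "z")


@dataclass(frozen=True)
class RasterGrid:
    """Uniform time raster: ``n`` samples of duration ``dt`` each."""

    dt: float = DEFAULT_RASTER
    n: int = 0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"raster time must be positive, got dt={self.dt}")
        if self.n < 0:
            raise ValueError(f"sample count must be non-negative, got n={self.n}")

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        """Left edges of the hold intervals."""
        return np.arange(self.n) * self.dt


@dataclass
class GradientWaveform:
    """Three-axis gradient waveform (mT/m) on a :class:`RasterGrid`.

    Axes are ordered (x = readout, y = phase encode, z = slice).  Demanded
    waveforms built by the sequence generator start and end at exactly zero
    on every axis (checked via :meth:`has_zero_ends`; realized model outputs
    may carry residual transients and are exempt).
    """

    grid: RasterGrid
    samples: np.ndarray  # shape (3, n)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != 3:
            raise ValueError(f"samples must have shape (3, n), got {self.samples.shape}")
        if self.samples.shape[1] != self.grid.n:
            raise ValueError(
                f"sample count {self.samples.shape[1]} does not match grid n={self.grid.n}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    def has_zero_ends(self) -> bool:
        """True when every axis starts and ends at exactly 0."""
        if not self.grid.n:
            return True
        return bool(np.all(self.samples[:, 0] == 0.0) and np.all(self.samples[:, -1] == 0.0))

    @classmethod
    def zeros(cls, n: int, dt: float = DEFAULT_RASTER) -> "GradientWaveform":
        return cls(RasterGrid(dt=dt, n=n), np.zeros((3, n)))

    @property
    def n(self) -> int:
        return self.grid.n

    @property
    def dt(self) -> float:
        return self.grid.dt

    def copy(self) -> "GradientWaveform":
        return GradientWaveform(self.grid, self.samples.copy())

    def slew(self) -> np.ndarray:
        """Forward-difference slew rate in mT/m/ms, shape (3, n).

        The sample after the waveform end is taken as zero, so the final
        entry is the ramp back to idle (zero for a compliant waveform).
        """
        return slew_rate(self.samples, self.grid.dt)

    def peak_amplitude(self) -> float:
        return float(np.max(np.abs(self.samples))) if self.n else 0.0

    def peak_slew(self) -> float:
        return float(np.max(np.abs(self.slew()))) if self.n else 0.0


def slew_rate(samples: np.ndarray, dt: float) -> np.ndarray:
    """Forward-difference slew (mT/m/ms) of per-axis samples with trailing 0."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    padded = np.concatenate([samples[:, 1:], np.zeros((samples.shape[0], 1))], axis=1)
    return (padded - samples) / (dt * 1e3)


@dataclass
class KSpaceTrajectory:
    """k-space coordinates (1/m) at a set of sample times."""

    times: np.ndarray
    k: np.ndarray  # shape (n_samples, n_axes)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if self.k.shape[0] != self.times.shape[0]:
            raise ValueError("times and k must have matching leading dimension")


def cumulative_k(w: GradientWaveform) -> np.ndarray:
    """k at the raster edges ``t = 0, dt, ..., n*dt``; shape (3, n+1), 1/m."""
    inc = GAMMA_BAR_MT * w.samples * w.dt
    out = np.zeros((3, w.n + 1))
    np.cumsum(inc, axis=1, out=out[:, 1:])
    return out


def waveform_kspace(
    w: GradientWaveform, times: np.ndarray, axes: tuple[int, ...] = (0, 1, 2)
) -> KSpaceTrajectory:
    """Exact k-space locations of ``w`` at arbitrary ``times`` within support.

    The integral of the zero-order-hold waveform is piecewise linear in t:
    full raster intervals contribute ``g[i] * dt`` and the partial final
    interval contributes ``g[m] * (t - m*dt)``.
    """
    times = np.asarray(times, dtype=float)
    if times.size and (times.min() < 0.0 or times.max() > w.grid.duration * (1 + 1e-12)):
        raise ValueError(
            f"requested time outside waveform support [0, {w.grid.duration:.6g}] s"
        )
    edges = cumulative_k(w)
    m = np.minimum(np.floor(times / w.dt).astype(int), w.n - 1) if w.n else np.zeros(0, int)
    frac = times - m * w.dt
    k = edges[:, m] + GAMMA_BAR_MT * w.samples[:, m] * frac
    return KSpaceTrajectory(times=times, k=k[list(axes), :].T)


def sample_k_adjoint(
    w: GradientWaveform, times: np.ndarray, kbar: np.ndarray, axes: tuple[int, ...] = (0, 1)
) -> np.ndarray:
    """Adjoint of the linear map ``samples -> waveform_kspace(...).k``.

    Given cotangents ``kbar`` (n_samples, len(axes)) on the trajectory,
    returns the gradient with respect to the waveform samples, shape (3, n).
    Used by the optimizer; kept next to the forward map so the two stay in
    lock-step.
    """
    times = np.asarray(times, dtype=float)
    kbar = np.asarray(kbar, dtype=float)
    n = w.n
    m = np.minimum(np.floor(times / w.dt).astype(int), n - 1)
    frac = times - m * w.dt
    out = np.zeros((3, n))
    for col, ax in enumerate(axes):
        r = kbar[:, col]
        # full-interval term: sample j receives dt * sum of r_i over m_i > j
        acc = np.zeros(n + 1)
        np.add.at(acc, m, r)
        tail = np.cumsum(acc[::-1])[::-1]  # tail[j] = sum over m_i >= j
        full = np.zeros(n)
        full[: n - 1] = tail[1:n]
        out[ax] += GAMMA_BAR_MT * w.dt * full
        # partial-interval term at the straddled sample
        part = np.zeros(n)
        np.add.at(part, m, frac * r)
        out[ax] += GAMMA_BAR_MT * part
    return out


# ---------------------------------------------------------------------------
# I/O


def save_waveform_h5(path: str | Path, w: GradientWaveform) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("dt", data=w.dt)
        f.create_dataset("samples", data=w.samples)


def load_waveform_h5(path: str | Path) -> GradientWaveform:
    with h5py.File(path, "r") as f:
        dt = float(f["dt"][()])
        samples = np.asarray(f["samples"])
    return GradientWaveform(RasterGrid(dt=dt, n=samples.shape[1]), samples)


def save_waveform_csv(path: str | Path, w: GradientWaveform) -> None:
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["t", "gx", "gy", "gz"])
        for i in range(w.n):
            writer.writerow([repr(i * w.dt)] + [repr(float(v)) for v in w.samples[:, i]])


def load_waveform_csv(path: str | Path) -> GradientWaveform:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    data = np.atleast_2d(data)
    t = data[:, 0]
    dt = float(t[1] - t[0]) if t.size > 1 else DEFAULT_RASTER
    return GradientWaveform(RasterGrid(dt=dt, n=data.shape[0]), data[:, 1:4].T)
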