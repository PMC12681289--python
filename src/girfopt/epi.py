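"""Nominal EPI gradient waveform and ADC construction.

Builds single- and multi-shot 2-D EPI readout trains: x/y prephasers, a
bipolar trapezoidal readout train with phase-encode blips in the turnaround
gaps, and ADC sampling confined to the readout flat-tops.  Acquired lines
honour the acceleration factor R (every R-th line) and partial Fourier
(asymmetric omission of the early, pre-echo lines).  The nominal k-space
trajectory at the ADC times lies exactly on the Cartesian grid with spacing
1/FOV.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import yaml

from .waveform import (
    DEFAULT_RASTER,
    GAMMA_BAR_MT,
    GradientWaveform,
    RasterGrid,
    cumulative_k,
)


class InfeasibleTimingError(ValueError):
    """Raised when the requested timing cannot be met within hardware limits."""


@dataclass
class EpiSequenceSpec:
    """Geometry and timing of a 2-D EPI acquisition.

    Parameters
    ----------
    fov:
        Field of view in metres (isotropic in-plane).
    matrix:
        Image matrix size (readout samples per line = phase-encode lines).
    R:
        Acceleration factor; every R-th phase-encode line is acquired.
    partial_fourier:
        Acquired-lines / total-lines fraction; the early (most negative
        k_y, pre-echo) lines are omitted, shortening the echo time.
    n_shots:
        Number of interleaved shots; shot s acquires lines s, s+n_shots, ...
        of the R-decimated set.
    echo_spacing:
        Time between echo centres in seconds; must be an integer multiple
        of the raster time.
    adc_dwell:
        ADC sample period in seconds (defaults to the raster time).
    g_max, s_max:
        Hardware amplitude (mT/m) and slew (mT/m/ms) limits used for the
        nominal design.
    design_slew_fraction:
        Nominal ramps are designed at this fraction of s_max so the nominal
        waveform sits strictly below the limit, leaving headroom for
        corrections.
    """

    fov: float = 0.25
    matrix: int = 64
    R: int = 1
    partial_fourier: Fraction = Fraction(1, 1)
    n_shots: int = 1
    echo_spacing: float = 0.8e-3
    adc_dwell: float | None = None
    dt: float = DEFAULT_RASTER
    g_max: float = 72.0
    s_max: float = 180.0
    design_slew_fraction: float = 0.9
    te: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.partial_fourier, str):
            self.partial_fourier = Fraction(self.partial_fourier)
        self.partial_fourier = Fraction(self.partial_fourier).limit_denominator(4096)
        if not self.fov > 0:
            raise ValueError("fov must be positive")
        if self.matrix < 8:
            raise ValueError("matrix must be at least 8")
        if self.R < 1:
            raise ValueError("R must be a positive integer")
        if not (Fraction(1, 2) < self.partial_fourier <= 1):
            raise ValueError("partial_fourier must lie in (1/2, 1]")
        n_esp = self.echo_spacing / self.dt
        if abs(n_esp - round(n_esp)) > 1e-6:
            raise ValueError("echo_spacing must be an integer multiple of the raster time")
        if self.adc_dwell is None:
            self.adc_dwell = self.dt

    # -- derived geometry ---------------------------------------------------

    @property
    def delta_k(self) -> float:
        """Cartesian k-space spacing, 1/m."""
        return 1.0 / self.fov

    @property
    def n_pf_lines(self) -> int:
        """Number of lines retained after partial Fourier (before R)."""
        n = int(round(self.partial_fourier * self.matrix))
        if n > self.matrix:
            raise ValueError("partial fourier fraction exceeds 1")
        return n

    def acquired_lines(self, shot: int = 0) -> np.ndarray:
        """Phase-encode line indices acquired by ``shot`` (0-based, ascending).

        Line j sits at k_y = (j - matrix//2) * delta_k.  Partial Fourier
        omits the first (most negative k_y) lines; R keeps every R-th of
        the remainder; shots interleave the R-decimated set.
        """
        if not 0 <= shot < self.n_shots:
            raise ValueError(f"shot must be in [0, {self.n_shots})")
        first = self.matrix - self.n_pf_lines
        decimated = np.arange(first, self.matrix, self.R)
        return decimated[shot :: self.n_shots]

    @property
    def n_lines_total(self) -> int:
        return sum(self.acquired_lines(s).size for s in range(self.n_shots))

    @property
    def flat_readout_amplitude(self) -> float:
        """Readout flat-top amplitude (mT/m) fixed by dwell and resolution."""
        return self.delta_k / (GAMMA_BAR_MT * self.adc_dwell)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "fov": self.fov,
            "matrix": self.matrix,
            "R": self.R,
            "partial_fourier": str(self.partial_fourier),
            "n_shots": self.n_shots,
            "echo_spacing": self.echo_spacing,
            "adc_dwell": self.adc_dwell,
            "dt": self.dt,
            "g_max": self.g_max,
            "s_max": self.s_max,
            "design_slew_fraction": self.design_slew_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EpiSequenceSpec":
        return cls(**d)

    def save_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load_yaml(cls, path: str | Path) -> "EpiSequenceSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class AdcSampling:
    """ADC sample times and the nominal (target) k-space they should see."""

    times: np.ndarray  # (N_k,), seconds from waveform start
    nominal_k: np.ndarray  # (N_k, 2) target (k_x, k_y) in 1/m

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.nominal_k = np.asarray(self.nominal_k, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("ADC times must be strictly increasing")
        if self.nominal_k.shape != (self.times.size, 2):
            raise ValueError("nominal_k must have shape (N_k, 2)")

    @property
    def n_samples(self) -> int:
        return self.times.size


# ---------------------------------------------------------------------------
# trapezoid primitives (all on the raster, discrete areas exact)


def _trapezoid(a: float, n_ramp: int, n_flat: int) -> np.ndarray:
    """Trapezoid samples with linear ramps; discrete area = a * dt * (n_flat + n_ramp)."""
    up = a * np.arange(1, n_ramp + 1) / n_ramp
    down = a * np.arange(n_ramp - 1, -1, -1) / n_ramp
    return np.concatenate([up, np.full(n_flat, a), down])


def _shortest_trapezoid_for_area(
    area: float, dt: float, g_lim: float, s_lim: float
) -> np.ndarray:
    """Shortest raster trapezoid of given signed area under amplitude/slew limits.

    ``s_lim`` is in mT/m/ms; the discrete area of the returned lobe equals
    ``area`` exactly (in mT/m * s).
    """
    if area == 0.0:
        return np.zeros(0)
    mag = abs(area)
    s_si = s_lim * 1e3  # mT/m/s
    # triangular candidate: area = a * dt * n_ramp, a = s_si * n_ramp * dt
    n_ramp = max(1, int(np.ceil(np.sqrt(mag / (s_si * dt * dt)))))
    a = mag / (dt * n_ramp)
    n_flat = 0
    if a > g_lim:
        # amplitude-limited: flat top at <= g_lim
        n_ramp = max(1, int(np.ceil(g_lim / (s_si * dt))))
        n_flat = int(np.ceil(mag / (g_lim * dt) - n_ramp))
        if n_flat < 0:
            n_flat = 0
        a = mag / (dt * (n_flat + n_ramp))
    return np.sign(area) * _trapezoid(a, n_ramp, n_flat)


def build_epi(spec: EpiSequenceSpec, shot: int = 0) -> tuple[GradientWaveform, AdcSampling]:
    """Construct the nominal waveform and ADC sampling for one shot.

    The ADC samples sit on readout flat-tops only (no ramp sampling), with
    dwell equal to ``spec.adc_dwell``; the cumulative integral of the
    returned waveform at every ADC time equals the nominal Cartesian grid
    coordinate exactly (up to float rounding).
    """
    dt = spec.dt
    dk = spec.delta_k
    n = spec.matrix
    s_design = spec.design_slew_fraction * spec.s_max
    lines = spec.acquired_lines(shot)
    if lines.size == 0:
        raise InfeasibleTimingError("no lines acquired; check R/partial_fourier/n_shots")

    a_read = spec.flat_readout_amplitude
    if a_read > spec.g_max:
        raise InfeasibleTimingError(
            f"flat readout amplitude {a_read:.2f} mT/m exceeds g_max={spec.g_max}; "
            "limiting parameter: adc_dwell (increase dwell or fov)"
        )
    n_esp = int(round(spec.echo_spacing / dt))
    n_ramp = max(1, int(np.ceil(a_read / (s_design * 1e3 * dt))))
    n_flat = n_esp - 2 * n_ramp
    # Settle time before the first ADC sample of each flat-top.  This value
    # makes the integrated k_x land on the grid for forward *and* reversed
    # readouts: the accrual between the last sample of one line and the
    # first sample of the next must vanish, which requires the ADC window
    # to sit time-symmetrically within the zero-order-hold trapezoid.
    t_settle = 0.5 * (dt * (n_flat - 1) - (n - 1) * spec.adc_dwell)
    if n_flat < 1 or t_settle < 0:
        raise InfeasibleTimingError(
            f"echo spacing {spec.echo_spacing * 1e3:.3f} ms too short: flat-top "
            f"({max(n_flat, 0)} samples) cannot host {n} ADC samples at dwell "
            f"{spec.adc_dwell * 1e6:.1f} us with ramps at s_max={spec.s_max} "
            "mT/m/ms; limiting parameter: echo_spacing"
        )

    # phase-encode blips: one line step between consecutive echoes
    line_step = spec.R * spec.n_shots
    blip_area = line_step * dk / GAMMA_BAR_MT
    n_half = 1
    while (blip_area / (dt * n_half)) / (n_half * dt * 1e3) > s_design:
        n_half += 1
    if n_half > n_ramp:
        raise InfeasibleTimingError(
            "phase-encode blip infeasible within the readout turnaround; "
            "limiting parameter: echo_spacing (ramp too short for blip area)"
        )
    b_amp = blip_area / (dt * n_half)
    if b_amp > spec.g_max:
        raise InfeasibleTimingError(
            "phase-encode blip amplitude exceeds g_max; limiting parameter: g_max"
        )

    n_lines = lines.size
    # assemble readout train: alternating trapezoids back-to-back, triangular
    # blips centred on the boundary between consecutive readouts
    train_len = n_lines * n_esp
    gx_train = np.zeros(train_len)
    gy_train = np.zeros(train_len)
    trap = _trapezoid(a_read, n_ramp, n_flat)
    for j in range(n_lines):
        gx_train[j * n_esp : j * n_esp + trap.size] = ((-1) ** j) * trap
    blip = _trapezoid(b_amp, n_half, 0)
    for j in range(n_lines - 1):
        centre = (j + 1) * n_esp
        gy_train[centre - n_half : centre + n_half] = blip

    adc_offsets = np.arange(n) * spec.adc_dwell
    t_adc0 = n_ramp * dt + t_settle

    # nominal k targets (grid, in acquisition order)
    kx_grid = (np.arange(n) - n // 2) * dk
    times = np.empty(n_lines * n)
    k0 = np.empty((n_lines * n, 2))
    for j, line in enumerate(lines):
        sl = slice(j * n, (j + 1) * n)
        times[sl] = j * n_esp * dt + t_adc0 + adc_offsets
        kx = kx_grid if j % 2 == 0 else kx_grid[::-1]
        k0[sl, 0] = kx
        k0[sl, 1] = (line - n // 2) * dk

    # prephasers: bring k to the first ADC sample's target exactly.
    # k accrued by the train up to the first ADC time (discrete integral):
    m0 = int(np.floor(t_adc0 / dt))
    frac0 = t_adc0 - m0 * dt
    kx_train0 = GAMMA_BAR_MT * (np.sum(gx_train[:m0]) * dt + gx_train[m0] * frac0)
    pre_area_x = (k0[0, 0] - kx_train0) / GAMMA_BAR_MT
    pre_area_y = k0[0, 1] / GAMMA_BAR_MT
    pre_x = _shortest_trapezoid_for_area(pre_area_x, dt, spec.g_max, s_design)
    pre_y = _shortest_trapezoid_for_area(pre_area_y, dt, spec.g_max, s_design)
    n_pre = max(pre_x.size, pre_y.size)

    pad0 = 1  # idle sample so the waveform starts at exactly 0
    total = pad0 + n_pre + train_len + 1
    g = np.zeros((3, total))
    g[0, pad0 + n_pre - pre_x.size : pad0 + n_pre] = pre_x
    g[1, pad0 + n_pre - pre_y.size : pad0 + n_pre] = pre_y
    g[0, pad0 + n_pre : pad0 + n_pre + train_len] = gx_train
    g[1, pad0 + n_pre : pad0 + n_pre + train_len] = gy_train

    w = GradientWaveform(RasterGrid(dt=dt, n=total), g)
    t_shift = (pad0 + n_pre) * dt
    adc = AdcSampling(times=times + t_shift, nominal_k=k0)

    if w.peak_amplitude() > spec.g_max or w.peak_slew() > spec.s_max:
        raise InfeasibleTimingError(
            "nominal waveform exceeds hardware limits; limiting parameter: "
            + ("g_max" if w.peak_amplitude() > spec.g_max else "s_max")
        )
    return w, adc


def build_epi_all(spec: EpiSequenceSpec) -> list[tuple[GradientWaveform, AdcSampling]]:
    """All shots of a (possibly multishot) EPI acquisition."""
    return [build_epi(spec, shot=s) for s in range(spec.n_shots)]


def nominal_k_check(w: GradientWaveform, adc: AdcSampling) -> float:
    """Max relative deviation of the integrated trajectory from nominal_k."""
    from .waveform import waveform_kspace

    traj = waveform_kspace(w, adc.times, axes=(0, 1))
    scale = np.max(np.abs(adc.nominal_k)) or 1.0
    return float(np.max(np.abs(traj.k - adc.nominal_k)) / scale)


# ---------------------------------------------------------------------------
# best-effort Pulseq text export (out of acceptance scope)


def export_pulseq_text(path: str | Path, w: GradientWaveform, adc: AdcSampling) -> None:
    """Write a minimal Pulseq-style .seq text file (shapes + ADC event).

    Best-effort interchange format: one arbitrary-gradient event per axis
    holding the full waveform as an uncompressed shape, and a single ADC
    block.  Not bit-exact against vendor interpreters.
    """
    lines = ["# Pulseq sequence file (minimal export)", "[VERSION]", "major 1", "minor 4",
             "revision 0", "", "[DEFINITIONS]", f"GradientRasterTime {w.dt}", ""]
    lines.append("[SHAPES]")
    for i in range(3):
        lines.append(f"shape_id {i + 1}")
        lines.append(f"num_samples {w.n}")
        scale = np.max(np.abs(w.samples[i])) or 1.0
        lines.extend(repr(v) for v in (w.samples[i] / scale))
        lines.append("")
    lines.append("[ADC]")
    dwell = adc.times[1] - adc.times[0] if adc.n_samples > 1 else w.dt
    lines.append(f"1 {adc.n_samples} {dwell * 1e9:.0f} {adc.times[0] * 1e6:.3f} 0 0")
    Path(path).write_text("\n".join(lines) + "\n")
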