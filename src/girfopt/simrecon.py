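"""EPI signal simulation at off-grid k-locations, nominal-grid
reconstruction, and image-error / ghost metrics.

The signal model is a direct discrete Fourier summation over phantom
pixels, ``s(k) = sum_r rho(r) exp(-i 2 pi k . r)``: exact at arbitrary
(displaced) k-locations, linear in intensity, with no relaxation,
off-resonance, coil sensitivity or noise.  Reconstruction places each
acquired sample at its *nominal* Cartesian position and inverse-Fourier
transforms — this mismatch is precisely the mechanism by which trajectory
errors become Nyquist ghosts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epi import AdcSampling, EpiSequenceSpec
from .waveform import KSpaceTrajectory


@dataclass
class Phantom2D:
    """Non-negative intensity image on a square FOV with a support mask."""

    image: np.ndarray
    fov: float
    support_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2 or self.image.shape[0] != self.image.shape[1]:
            raise ValueError("phantom image must be square")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("phantom image must be finite")
        if self.support_mask is None:
            self.support_mask = self.image > 0
        self.support_mask = np.asarray(self.support_mask, dtype=bool)

    @property
    def n(self) -> int:
        return self.image.shape[0]


def ellipse_phantom(n: int, fov: float = 0.25) -> Phantom2D:
    """Built-in multi-ellipse phantom (head-like composite).

    A large bright ellipse with a darker interior rim, two low-intensity
    "ventricles", and three small high-contrast inserts; structure chosen
    to produce broadband k-space content so trajectory errors are visible.
    Coordinates are in units of the half-FOV; the support stays well inside
    the FOV so edge strips are artifact-only regions.
    """
    c = n // 2
    y, x = np.mgrid[0:n, 0:n]
    u = (x - c) / (n / 2)  # [-1, 1)
    v = (y - c) / (n / 2)

    def ell(cx, cy, ax_, ay, angle=0.0):
        ca, sa = np.cos(angle), np.sin(angle)
        ur = (u - cx) * ca + (v - cy) * sa
        vr = -(u - cx) * sa + (v - cy) * ca
        return (ur / ax_) ** 2 + (vr / ay) ** 2 <= 1.0

    img = np.zeros((n, n))
    img[ell(0.0, 0.0, 0.62, 0.55)] = 1.0
    img[ell(0.0, 0.0, 0.55, 0.48)] = 0.8
    img[ell(-0.16, -0.05, 0.11, 0.22, 0.25)] = 0.35
    img[ell(0.16, -0.05, 0.11, 0.22, -0.25)] = 0.35
    img[ell(0.0, 0.28, 0.08, 0.08)] = 1.2
    img[ell(-0.22, 0.25, 0.05, 0.05)] = 0.1
    img[ell(0.25, 0.22, 0.045, 0.045)] = 1.1
    return Phantom2D(image=img, fov=fov, support_mask=ell(0.0, 0.0, 0.62, 0.55))


def pixel_coords(n: int, fov: float) -> np.ndarray:
    """Pixel centre coordinates along one axis, metres, centred on 0."""
    return (np.arange(n) - n // 2) * (fov / n)


def simulate_signal(ph: Phantom2D, traj: KSpaceTrajectory) -> np.ndarray:
    """Discrete Fourier summation of the phantom at arbitrary k-locations.

    ``traj.k`` is (N_k, 2) with columns (k_x, k_y); pixel (iy, ix) sits at
    (x[ix], y[iy]).  Returns complex samples of length N_k.
    """
    k = np.asarray(traj.k, dtype=float)
    if not np.all(np.isfinite(k)):
        raise ValueError("trajectory contains non-finite k values")
    n = ph.n
    r = pixel_coords(n, ph.fov)
    ex = np.exp(-2j * np.pi * np.outer(k[:, 0], r))  # (N_k, n) over x
    ey = np.exp(-2j * np.pi * np.outer(k[:, 1], r))  # (N_k, n) over y
    # s_i = sum_{iy,ix} rho[iy,ix] ey[i,iy] ex[i,ix]
    return np.einsum("iy,yx,ix->i", ey, ph.image, ex, optimize=True)


def smoothstep_pf_filter(spec: EpiSequenceSpec) -> np.ndarray:
    """Per-line k_y apodization reducing partial-Fourier Gibbs ringing.

    Cubic smoothstep (3u^2 - 2u^3) rising from 0 at the asymmetric
    (unacquired-band) edge over the width of the band's mirror; unity
    elsewhere.  Returns weights for all ``matrix`` lines.
    """
    n = spec.matrix
    wts = np.ones(n)
    n_miss = n - spec.n_pf_lines
    if n_miss > 0:
        first = n_miss  # first acquired line index
        width = n_miss
        idx = np.arange(first, min(first + width, n))
        u = (idx - first + 1) / (width + 1)
        wts[:first] = 0.0
        wts[idx] = 3 * u**2 - 2 * u**3
    return wts


def reconstruct(
    samples: np.ndarray,
    spec: EpiSequenceSpec,
    adc: AdcSampling | list[AdcSampling],
    apply_pf_filter: bool = True,
) -> np.ndarray:
    """Nominal-grid inverse-Fourier reconstruction.

    Each acquired sample is placed at its nominal Cartesian position (this
    applies the readout reversal of even echoes implicitly), unacquired
    lines are zero-filled, the partial-Fourier smooth-step apodization is
    applied across the asymmetric edge, and a centred 2-D inverse FFT
    returns the complex image.
    """
    adcs = adc if isinstance(adc, list) else [adc]
    k_all = np.concatenate([a.nominal_k for a in adcs], axis=0)
    samples = np.asarray(samples)
    if samples.shape[0] != k_all.shape[0]:
        raise ValueError(
            f"sample count {samples.shape[0]} does not match ADC metadata {k_all.shape[0]}"
        )
    n = spec.matrix
    c = n // 2
    ix = np.rint(k_all[:, 0] * spec.fov).astype(int) + c
    iy = np.rint(k_all[:, 1] * spec.fov).astype(int) + c
    if ix.min() < 0 or ix.max() >= n or iy.min() < 0 or iy.max() >= n:
        raise ValueError("nominal k-locations fall outside the reconstruction grid")
    ksp = np.zeros((n, n), dtype=complex)
    ksp[iy, ix] = samples
    if apply_pf_filter:
        ksp *= smoothstep_pf_filter(spec)[:, None]
    img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(ksp)))
    return img


def nrmse(image: np.ndarray, target: np.ndarray) -> float:
    """Percent RMS magnitude error of ``image`` relative to ``target``."""
    image = np.asarray(image)
    target = np.asarray(target)
    if image.shape != target.shape:
        raise ValueError("image and target must have the same shape")
    denom = np.sqrt(np.mean(np.abs(target) ** 2))
    if denom == 0:
        raise ValueError("target image is identically zero")
    return float(100.0 * np.sqrt(np.mean((np.abs(image) - np.abs(target)) ** 2)) / denom)


def default_ghost_boxes(
    n: int, object_radius_frac: float = 0.35, strip_frac: float = 0.1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fe_box, pe_box, object_box) boolean masks for the ghost metric.

    Object: central disc of radius ``object_radius_frac * FOV``.  The
    phase-encode box is a pair of full-width strips at the top/bottom image
    edges (ghosts replicate along PE); the frequency-encode box is the
    left/right strips with the PE rows excluded so the boxes are disjoint.
    """
    c = n // 2
    y, x = np.mgrid[0:n, 0:n]
    rr = np.sqrt((x - c) ** 2 + (y - c) ** 2)
    object_box = rr <= object_radius_frac * n
    wstrip = max(1, int(round(strip_frac * n)))
    pe_box = np.zeros((n, n), dtype=bool)
    pe_box[:wstrip, :] = True
    pe_box[-wstrip:, :] = True
    fe_box = np.zeros((n, n), dtype=bool)
    fe_box[:, :wstrip] = True
    fe_box[:, -wstrip:] = True
    fe_box &= ~pe_box
    pe_box &= ~object_box
    fe_box &= ~object_box
    return fe_box, pe_box, object_box


def ghost_metric(
    image: np.ndarray,
    fe_box: np.ndarray | None = None,
    pe_box: np.ndarray | None = None,
    object_box: np.ndarray | None = None,
) -> float:
    """Nyquist-ghost score: (RMS in PE strips - RMS in FE strips) / object RMS.

    EPI ghosts replicate the object along the phase-encode direction only,
    so the difference isolates ghost energy from any isotropic background.
    """
    mag = np.abs(np.asarray(image))
    n = mag.shape[0]
    if fe_box is None or pe_box is None or object_box is None:
        fe_box, pe_box, object_box = default_ghost_boxes(n)
    for name, box in (("fe", fe_box), ("pe", pe_box), ("object", object_box)):
        if not np.any(box):
            raise ValueError(f"{name} box is empty")
    if np.any(fe_box & pe_box):
        raise ValueError("fe and pe boxes must be disjoint")
    rms = lambda m: np.sqrt(np.mean(mag[m] ** 2))
    return float((rms(pe_box) - rms(fe_box)) / rms(object_box))
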