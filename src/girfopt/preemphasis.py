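"""Classic pre-emphasis baselines: exponential-model first-order correction
and GSTF inversion by filtered frequency-domain division.

These are the corrections the k-space optimizer is compared against.  Both
modify the *demanded* waveform so that the realized waveform approximates
the original demand; neither can respect hardware limits, which is the
motivation for the optimization approach.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import fftconvolve

from .distortion import EddyModel, TransferFunction, eddy_forward, fft_length, _forward_diff
from .waveform import GradientWaveform


@dataclass
class PreemphasisParams:
    """First-order pre-emphasis terms (alpha_tilde_n, tau_tilde_n).

    Same kernel convention as :class:`~girfopt.distortion.EddyModel`; the
    correction is *added* rather than subtracted.
    """

    terms: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for _, tau in self.terms:
            if not tau > 0:
                raise ValueError(f"pre-emphasis time constant must be positive, got {tau}")


def exp_preemphasis(w: GradientWaveform, p: PreemphasisParams) -> GradientWaveform:
    """g_PRE = g + gdot (*) sum_n alpha~_n exp(-t / tau~_n).

    Identical discretization to :func:`~girfopt.distortion.eddy_forward`
    with the sign of the convolution term flipped.
    """
    if not p.terms:
        return w.copy()
    mirror = EddyModel(terms=list(p.terms))
    ker = mirror.kernel(w.n, w.dt)
    gdot = _forward_diff(w.samples, w.dt)
    pert = fftconvolve(gdot, ker[None, :], axes=1)[:, : w.n]
    return GradientWaveform(w.grid, w.samples + pert)


def analytic_inverse(alpha: float, tau: float) -> tuple[float, float]:
    """Continuous-domain first-order inverse of a single eddy term.

    In the Laplace domain the exact inverse of ``1 - s a tau/(1 + s tau)``
    is ``1 + s a' tau'/(1 + s tau')`` with ``a' = a/(1-a)``,
    ``tau' = tau (1-a)``.  On the discrete raster this is accurate for
    smooth (band-limited) waveforms; broadband content picks up
    second-order error, which is why fitted parameters deviate.
    """
    return alpha / (1.0 - alpha), tau * (1.0 - alpha)


def fit_preemphasis(
    w: GradientWaveform,
    m: EddyModel,
    tau_bounds: tuple[float, float] = (1e-6, 1e-3),
    n_grid: int = 60,
) -> tuple[PreemphasisParams, float]:
    """Numerically fit a single-term pre-emphasis to invert ``m`` on ``w``.

    Minimizes RMS of ``eddy_forward(exp_preemphasis(w)) - w`` over
    (alpha~, tau~).  Because both operators are linear in the waveform and
    the correction is linear in alpha~, the optimal alpha~ for fixed tau~
    is a closed-form least-squares projection; tau~ is found by log-spaced
    grid search refined with bounded scalar minimization.

    Returns the fitted parameters and the achieved RMS residual.
    """
    gdot = _forward_diff(w.samples, w.dt)
    if not np.any(gdot):
        raise ValueError("waveform has zero slew everywhere; pre-emphasis fit is degenerate")
    base = eddy_forward(w, m).samples - w.samples  # residual at alpha~ = 0
    if not m.terms:
        return PreemphasisParams(terms=[]), 0.0
    n = w.n

    def residual_for_tau(tau_t: float) -> tuple[float, float]:
        unit = EddyModel(terms=[(1.0, tau_t)]).kernel(n, w.dt)
        corr = fftconvolve(gdot, unit[None, :], axes=1)[:, :n]
        # realized change per unit alpha~: eddy model applied to correction
        col = EddyOperatorApply(m, corr, w)
        # least squares: minimize ||base + a * col||
        denom = np.vdot(col, col).real
        a_opt = 0.0 if denom == 0 else float(-np.vdot(col, base).real / denom)
        a_opt = max(a_opt, 0.0)
        res = float(np.sqrt(np.mean((base + a_opt * col) ** 2)))
        return a_opt, res

    taus = np.geomspace(tau_bounds[0], tau_bounds[1], n_grid)
    results = [residual_for_tau(t) for t in taus]
    best_i = int(np.argmin([r for _, r in results]))
    lo = taus[max(best_i - 1, 0)]
    hi = taus[min(best_i + 1, n_grid - 1)]
    opt = minimize_scalar(
        lambda lt: residual_for_tau(np.exp(lt))[1],
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    tau_fit = float(np.exp(opt.x))
    a_fit, res = residual_for_tau(tau_fit)
    if results[best_i][1] < res:  # guard against a flat refine landing worse
        a_fit, res = results[best_i]
        tau_fit = float(taus[best_i])
    return PreemphasisParams(terms=[(a_fit, tau_fit)]), res


def EddyOperatorApply(m: EddyModel, samples: np.ndarray, w: GradientWaveform) -> np.ndarray:
    """Apply the eddy forward model to raw samples on w's grid (linear)."""
    ker = m.kernel(samples.shape[1], w.dt)
    gdot = _forward_diff(samples, w.dt)
    return samples - fftconvolve(gdot, ker[None, :], axes=1)[:, : samples.shape[1]]


@dataclass
class TukeySpec:
    """Tukey low-pass used to regularize GSTF inversion.

    Unity up to ``cutoff * (1 - transition_width)``, cosine taper down to
    zero at ``cutoff`` (applied on |f|).
    """

    cutoff: float = 45e3
    transition_width: float = 0.3

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")
        if not 0 <= self.transition_width <= 1:
            raise ValueError("transition_width must lie in [0, 1]")

    def window(self, f: np.ndarray) -> np.ndarray:
        af = np.abs(np.asarray(f, dtype=float))
        f0 = self.cutoff * (1.0 - self.transition_width)
        out = np.ones_like(af)
        taper = (af > f0) & (af < self.cutoff)
        if self.transition_width > 0:
            u = (af[taper] - f0) / (self.cutoff - f0)
            out[taper] = 0.5 * (1.0 + np.cos(np.pi * u))
        out[af >= self.cutoff] = 0.0
        return out


def gstf_preemphasis(
    w: GradientWaveform, tf: TransferFunction, filt: TukeySpec | None = None
) -> GradientWaveform:
    """Pre-emphasis by frequency-domain division by the GSTF self-terms.

    Per axis: ``g~_PRE(f) = T(f) g~(f) / H_ii(f)`` with T the Tukey window
    (T = 1 when ``filt`` is None).  Cross-terms are deliberately ignored;
    inverting the full matrix would couple axes and is not what scanner
    pre-emphasis implementations do.
    """
    n = w.n
    L = fft_length(n)
    f = np.fft.fftfreq(L, d=w.dt)
    Hf = tf.interpolate(f)
    if L % 2 == 0:
        Hf[:, :, L // 2] = Hf[:, :, L // 2].real  # unpaired Nyquist bin
    T = filt.window(f) if filt is not None else np.ones(L)
    out = np.empty_like(w.samples)
    for ax in range(3):
        h = Hf[ax, ax]
        passband = T > 0
        if np.any(np.abs(h[passband]) < 1e-3):
            raise ValueError(
                f"self-term H_{'xyz'[ax]}{'xyz'[ax]} has near-zero magnitude in the "
                "filter passband; frequency-domain inversion would diverge"
            )
        X = np.fft.fft(w.samples[ax], n=L)
        Y = np.zeros(L, dtype=complex)
        Y[passband] = T[passband] * X[passband] / h[passband]
        out[ax] = np.fft.ifft(Y).real[:n]
    return GradientWaveform(w.grid, out)
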