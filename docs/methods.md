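# Methods

## Problem setting

An MRI gradient chain maps demanded waveforms `g(t)` (mT/m, per axis) to
realized waveforms `G(t)`. For Cartesian EPI the quantity of interest is not
`G` itself but the k-space locations sampled at the ADC times,
`kᵢ = γ̄ ∫₀^{tᵢ} G dt′` (cycles/m, `γ̄ = 42.577478 MHz/T`); any systematic
displacement from the nominal grid — in particular displacements that
alternate between odd and even echoes — aliases object energy into N/2
ghosts. `girfopt` designs the demanded waveform by minimizing the summed
squared displacement of the realized ADC samples, with linear hinge
penalties on demanded amplitude and slew so hardware limits are respected
by the *demanded* waveform the scanner would be asked to play.

## Distortion models

**Exponential eddy-current model.** Defined on the gradient raster
(Δt = 10 µs by default): with discrete slew `ġᵢ = (gᵢ₊₁ − gᵢ)/Δt` (1/s, a
trailing zero sample closes the waveform),

    Gᵢ = gᵢ − Σⱼ ġᵢ₋ⱼ · Σₙ αₙ e^{−j Δt/τₙ} .

The kernel samples are *not* Δt-weighted: `αₙ` is an amplitude per raster
interval, equivalent to a continuous kernel `(αₙ/Δt) e^{−t/τₙ}`. This
convention matters: at α = 5e-6 and τ = 50 µs the operator attenuates
high-frequency content by tens of percent, which is what makes the
benchmark distortion "significant" and what forces the classic first-order
inverse to use a shortened time constant (see below). An α interpreted as a
plain dimensionless step-response amplitude would produce perturbations of
order α·Δg ≈ 10⁻⁴ mT/m — five orders of magnitude too small to ghost an
image. Causality holds up to the one-sample lookahead inherent in the
forward difference.

**Tabulated GSTF.** A complex 3×3 response `H(f)` on a stored frequency
grid, applied by FFT with zero padding to at least twice the waveform
length (wraparound guard), linear interpolation of real and imaginary parts
onto the FFT grid, and a hard error if the waveform's Nyquist range exceeds
the tabulated grid — extrapolating a measured response into frequencies
where it was never characterized is exactly the failure mode Tukey
filtering exists to prevent. The unpaired −Nyquist FFT bin is forced real
(it represents ±f_nyq jointly in a real transform). Hermitian symmetry of
the stored response is asserted at apply time via the imaginary residue of
the inverse transform (tolerance 1e-9 relative).

**Synthetic GSTF generator.** Self-terms combine (i) the eddy factor —
by default the exact discrete-time transfer function of the raster
convolution above (`discretization="raster"`), so the two model families
agree to machine precision on matched grids; a `"continuous"` flavour with
kernel `(α/Δt)e^{−t/τ}` is available — (ii) a pure delay `e^{−iωΔ}` and
(iii) damped resonance factors per `(f₀, ζ, amplitude)` triple. Cross-terms
are smooth odd-imaginary lobes scaled by `cross_scale` (default 0), far
smaller than self-terms as on real systems. All factors are Hermitian by
construction.

## Pre-emphasis baselines

**Exponential pre-emphasis** adds the mirrored convolution term
(`g_PRE = g + ġ ⊗ Σ α̃ₙ e^{−t/τ̃ₙ}`, same discretization). The
continuous-limit single-term inverse is `α̃ = α/(1−α)`, `τ̃ = τ(1−α)`, but
on the raster the inverse of `1 − D(z)K(z)` is a two-pole response, so the
best *single*-term parameters shift substantially: numerically fitting
(log-spaced τ̃ grid with closed-form least-squares α̃ per candidate, then
bounded scalar refinement — the residual is linear in α̃ because both
operators are linear) on the matrix-64 EPI benchmark yields
α̃ ≈ 8.4e-6, τ̃ ≈ 26 µs for the (5e-6, 50 µs) forward term, i.e. roughly
doubled amplitude and halved time constant. The continuous-limit identity
is recovered on narrow-band waveforms (residual < 1e-3 of waveform RMS at
100 Hz content), which is how the property test exercises it.

**GSTF inversion** divides per axis by the self-term on the padded FFT
grid, `g̃_PRE = T(f) g̃ / H_ii(f)`, with `T` a Tukey window: unity up to
`cutoff·(1 − transition_width)`, cosine taper to zero at `cutoff` (defaults
45 kHz and 0.3, applied on |f|). Division errors out if |H_ii| < 1e-3
anywhere in the passband. Cross-terms are deliberately not inverted.
Unfiltered division is the exact algebraic inverse of the forward operator
provided the inverse-response tail fits inside the waveform support (the
round-trip test keeps a quiet tail margin for this reason); with the
default filter the inversion is inexact but still reduces per-line k-space
endpoint errors by well over an order of magnitude on the eddy benchmark.

Both baselines roughly double the demanded peak slew on trapezoid trains:
the correction term jumps by ≈ α̃/Δt · Δġ at every ramp corner, which for
α̃ ≈ 1e-5 and Δt = 10 µs matches the nominal slew itself. This is the
quantitative content of the baseline-contrast check: fitted pre-emphasis of
the benchmark demands ≈ 339 mT/m/ms against a 180 mT/m/ms limit.

## Optimizer

The total loss is the k-space term plus linear hinges
`w_g Σ max(0, |g| − g_max) + w_ġ Σ max(0, |ġ| − s_max)` (weights default
1e3; hinges act on magnitudes since the hardware bounds are magnitude
limits; the subgradient at the kink is taken as 0). All three pieces are
compositions of fixed linear maps (distortion operator, cumulative-integral
sampling) with pointwise nonlinearities, so the gradient is computed by
hand-written adjoints: correlation with the reversed kernel / conjugated
response, reverse cumulative sums for the sampling map, negated backward
differences for the slew. A dedicated test pins the analytic gradient to
central finite differences (< 1e-5 relative on a 30-sample toy with both
hinges active, for both model families).

Updates are Adam on the free samples (both in-plane axes, endpoints pinned
at exactly zero; z untouched). Package defaults: learning rate 0.05 mT/m
(the natural step for corrections of ~1 mT/m; equivalently 5e-5 in T/m
units) decaying exponentially to 1e-8 over the run, and
β₁ = β₂ = 0.99. The heavy momentum is deliberate: the residual after the
fast initial phase consists of per-line coherent k-offsets whose gradients
are spread thinly over thousands of samples, and raising β₁ from 0.9 to
0.99 reduced the stalled residual by a factor ≈ 30 at equal iteration
count in our calibration runs. The best-loss iterate (not the last) is
returned, so the reported loss sequence is non-increasing by construction;
a post-hoc hard check flags any >0.5% limit violation on the returned
waveform. The optimization is fully deterministic; the seed is stored for
forward compatibility only.

Convergence interacts with sequence timing in a way worth knowing: with
ADC dwell equal to the raster time, every raster sample inside the ADC
window is individually pinned by the grid targets, so corrections must be
expressed in the readout turnarounds. The echo spacing therefore needs
enough flat-top slack beyond the ADC window — the standing benchmark uses
1.07 ms (≈ 15 spare samples per side at matrix 64), while the short-TE
variant at 0.8 ms (2 spare samples) is intentionally tight and converges
to a constraint-riding solution with peak slew at 180 mT/m/ms.

## EPI generator

Trapezoidal bipolar readout train with triangular phase-encode blips
centred on the readout boundaries; x/y prephasers (shortest trapezoid for
the required area) bring k to the first sample's target exactly. Discrete
areas are exact by construction (`area = a·Δt·(n_flat + n_ramp)` for the
ramp sample convention used), and the ADC settle time
`t_settle = (Δt(n_flat − 1) − (n−1)·dwell)/2` places the ADC window
time-symmetrically in the zero-order-hold trapezoid — the condition under
which forward and reversed readouts both land on the grid; the builders
verify ≤ 1e-9 relative deviation. ADC samples sit on flat-tops only (no
ramp sampling), dwell defaults to the raster time and may be smaller
(matrix 96 at 1.07 ms echo spacing needs 9 µs). Partial Fourier omits the
early (pre-echo) lines; acceleration keeps every R-th remaining line;
multishot interleaves the decimated set (shot s takes lines s, s+n_shots,
…). Nominal designs use 90% of the slew limit so the nominal waveform sits
strictly inside the constraint box. Slice gradients and RF are not modeled
— the package optimizes in-plane encoding only. A minimal Pulseq-style
text export is provided for interchange; it is best-effort and untested
against vendor interpreters.

## Simulation and reconstruction testbench

Signal is the exact discrete Fourier sum `s(k) = Σ_r ρ(r) e^{−i2πk·r}`
over phantom pixels, evaluated at the (generally off-grid) realized
k-locations — linear in intensity, no relaxation, off-resonance, coil
sensitivity or noise, so the images isolate trajectory effects.
Reconstruction places every sample at its *nominal* grid position (which
implicitly applies even-echo readout reversal), zero-fills unacquired
lines, applies a cubic smoothstep (3u² − 2u³) ramp across the asymmetric
partial-Fourier edge over the width of the unacquired band's mirror, and
inverse-FFTs. Placing distorted data at nominal positions is the mechanism
that converts trajectory errors into ghosts. On-grid full sampling inverts
exactly (round-trip < 1e-10); undersampled (R > 1) variants are evaluated
on k-space displacement and constraint satisfaction only — zero-filled
reconstructions of undersampled data alias by construction and parallel
imaging is out of scope.

The built-in phantom is a parametric multi-ellipse composite (bright shell,
darker interior, two low-intensity lobes, three small inserts) whose
support stays within a 0.31·FOV radius, leaving the edge strips artifact-
only. Metrics: `NRMSE = 100·RMS(|I| − |I_ref|)/RMS(|I_ref|)` against the
distortion-free reconstruction through the identical pipeline (so
partial-Fourier and filter effects cancel), and a ghost score
`(RMS(PE strips) − RMS(FE strips)) / RMS(object disc)` with default
geometry: central disc of radius 0.35·FOV, 0.1·FOV-wide strips at the
image edges, corners assigned to the PE pair and all boxes disjoint. The
difference of the two strip directions cancels isotropic background, since
EPI ghosts replicate along phase encode only.

What the synthetic testbench does not emulate: measured-GSTF uncertainty
and noise, B₀/off-resonance and receive-field shading, relaxation decay
along the echo train, and concomitant/higher-order fields. Passing tests
therefore demonstrate correctness of the trajectory-to-image mechanism and
of the optimization under a *known* model, not robustness to model error
on a real scanner.

## Benchmark conditions (desk scale)

All variants: 250 mm FOV, 10 µs raster, limits 72 mT/m and 180 mT/m/ms,
eddy term α = 5e-6, τ = 50 µs. Variants: R=1 (matrix 64, partial Fourier
49/64), R=2 (matrix 64, 51/64), R=3 (matrix 66 — chosen divisible by 3 so
the acceleration tiles the line grid, the scaled analogue of an odd
129-line convention), 4-shot interleave (matrix 64), and the short-TE
R=1 variant at 0.8 ms echo spacing. Iteration budgets: 30k for the
benchmark NRMSE figure (≈ 1 minute), 8–12k for the constraint checks.
These sizes keep the full pipeline at minutes on one CPU while leaving the
optimizer's asymptotics clearly visible (k-rmse ≈ 0.3% of uncorrected at
30k iterations).

## Numerical choices and edge cases

* Zero-order-hold integration is exact (piecewise-linear k); sample times
  exactly on raster edges take the zero-length fractional branch, and both
  branches agree by continuity.
* `fft_length(n) = next_fast_len(2n)` is shared by every frequency-domain
  code path so tests can construct transfer-function grids that coincide
  with the FFT frequencies (no interpolation error in oracles).
* Degenerate inputs raise informative errors: infeasible echo spacing
  (naming the limiting parameter), transfer-function range narrower than
  the waveform bandwidth, near-zero self-terms in the inversion passband,
  zero-slew waveforms in the pre-emphasis fit, non-finite losses in the
  optimizer (naming the first offending component).
* Realized waveforms are allowed nonzero first/last samples (the eddy
  transient does not vanish at the boundaries); the zero-end invariant is
  enforced on built sequences and on optimizer output via endpoint
  pinning.

## Known limitations

* The optimizer is first-order; on very tight timing it rides the slew
  constraint and converges slowly rather than provably reaching the
  constrained optimum.
* Single-term pre-emphasis fitting only (matching its intended use as a
  baseline); multi-term fits would need a different parameterization.
* GSTF cross-terms are modeled in the forward map and the optimizer but
  never inverted by the pre-emphasis baseline (by design).
* The Pulseq export is schematic; sequences intended for hardware should
  be re-validated in a vendor toolchain.
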