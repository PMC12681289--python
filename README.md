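# girfopt

Hardware-aware MRI gradient waveform design for non-ideal gradient chains.

Real gradient systems do not play out the waveforms they are asked to play:
eddy currents, group delays and mechanical resonances smooth and shift the
realized gradients, so the k-space locations actually sampled by an EPI
readout drift off the Cartesian grid and the reconstruction ghosts. The
classic fix — pre-emphasis, i.e. predistorting the demanded waveform so the
realized one matches the demand — cannot respect amplitude or slew-rate
limits: it systematically *overdrives* the ramps, which is why scanner
specifications have to be down-rated to leave headroom.

`girfopt` instead treats precompensation as a constrained optimization of
the thing that actually matters for imaging, the k-space sample locations:

```
g_op = argmin  Σᵢ ‖kᵢ(G) − k₀,ᵢ‖²
             + w_g Σₜ max(0, |g(t)| − g_max)
             + w_ġ Σₜ max(0, |ġ(t)| − s_max)
```

where `g` is the demanded waveform (free variables), `G = f{g}` the realized
waveform under a fixed linear distortion model, `kᵢ = γ̄ ∫₀^{tᵢ} G dt′` the
realized k-space location at ADC time `tᵢ`, and the hinge terms are active
only when the amplitude or slew limits are violated. The distortion model is
either an analytic exponential eddy-current model,

```
G(t) = g(t) − ġ(t) ⊗ θ(t) Σₙ αₙ e^{−t/τₙ}
```

or a tabulated gradient system transfer function (GSTF) `H(ω)` with
cross-terms. Minimization uses Adam with analytic adjoint gradients — the
model is a constant linear operator, so no autodiff framework is needed.

The package is aimed at pulse-sequence and gradient-system researchers who
want to study acquisition-side trajectory correction without scanner access:
it bundles the two baselines (exponential pre-emphasis with numerically
fitted parameters, and Tukey-filtered GSTF inversion), an EPI sequence
generator, a synthetic-GSTF generator, and a simulation/reconstruction
testbench that turns trajectory errors into images and Nyquist-ghost scores.

## Worked example

Compare no correction, classic fitted pre-emphasis, and k-space
optimization on the single-shot EPI benchmark (250 mm FOV, matrix 64,
partial Fourier 49/64, echo spacing 1.07 ms) under a scanner-typical eddy
term (α = 5e-6, τ = 50 µs) with limits 72 mT/m and 180 mT/m/ms:

```python
from fractions import Fraction
from girfopt import EddyModel, EpiSequenceSpec
from girfopt.experiment import ExperimentConfig, compare_methods

spec = EpiSequenceSpec(matrix=64, R=1, partial_fourier=Fraction(49, 64),
                       echo_spacing=1.07e-3)
model = EddyModel(terms=[(5e-6, 50e-6)])
cfgs = [ExperimentConfig(sequence=spec, model=model, method=m, n_iters=30000,
                         quiet=True)
        for m in ("none", "exp_preemphasis", "optimize")]
print(compare_methods(cfgs).to_string(index=False))
```

```
         method  nrmse_percent  ghost_metric    k_rmse    peak_g  peak_slew  constraints_satisfied
           none      77.524792      0.732232 11.009293 26.618141 159.708849                   True
exp_preemphasis      14.995941      0.167972  1.590161 28.985434 339.166380                  False
       optimize       0.116152      0.010869  0.028396 26.148216 159.711242                   True
```

Reading the table: uncorrected, the eddy currents displace the ADC samples
by an RMS of 11 m⁻¹ (2.8 line spacings) and the image is dominated by N/2
ghosting (ghost score 0.73, NRMSE 78% against the distortion-free
reconstruction). Pre-emphasis restores most of the trajectory but demands a
peak slew of 339 mT/m/ms — nearly twice the hardware limit, so the waveform
could not actually be played out. The optimizer reaches a 0.12% image error
with the demanded waveform still inside both limits.

A CLI wraps the same pipeline (`girfopt build-seq / make-tf / correct /
optimize / simulate / report`); every run writes waveform HDF5, a metrics
YAML and a loss-history CSV into a run directory.

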