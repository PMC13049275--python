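# ivimflow

Encoding-time-dependent intravoxel incoherent motion (IVIM) modeling for
flow-compensated / non-flow-compensated double diffusion encoding (FC/NC
DDE) MRI.

## The problem

IVIM imaging separates the diffusion-weighted MR signal into a tissue
water compartment and a microvascular blood compartment,

    S / S0 = (1 − f) exp(−b D) + f F_P exp(−b D_b),

where `f` is the perfusion fraction, `D` the tissue diffusion
coefficient, `D_b` the blood diffusion coefficient, and `F_P` the extra
attenuation of the blood signal caused by incoherent capillary flow.
How `F_P` behaves depends on how far the blood travels along its
capillary segments during the diffusion encoding. At short encoding
times `T` the flow is *ballistic* (straight segments, fully rephased by
flow-compensated gradients); at long `T` it mimics diffusion
(*pseudodiffusion*, insensitive to flow compensation); clinical
encoding times often land in between.

`ivimflow` models the full transition. Blood velocity is treated as an
Ornstein–Uhlenbeck (Langevin) process with mean squared speed `v²` and
correlation time `τ` — the average time the flow keeps its direction —
giving an exponential velocity autocorrelation
`⟨v(t)v(t′)⟩ = (v²/d) exp(−|t−t′|/τ)` for isotropic `d`-dimensional
flow. Under the Gaussian phase approximation, `F_P = exp(−⟨φ²⟩/2)` with
`⟨φ²⟩ = ∫∫ q(t)q(t′)⟨v(t)v(t′)⟩ dt dt′`, and for a DDE waveform
(two bipolar pairs of lobe duration `δ`, separation `Δ`; the second
pair inverted for flow compensation) the phase variance has the closed
form

    F_P = exp(−γ²G² (v²/d) [τ⁴(Ψ + Ω) − 4δτ³ + 2δ²(Δ − δ/3)τ])

    Ψ = 2 e^{−(Δ+δ)/τ} (e^{δ/τ} − 1)(2e^{Δ/τ} + e^{δ/τ} − 1)
    Ω = m e^{−T/τ} (e^{Δ/τ} − 1)² (e^{δ/τ} − 1)²,   m = +1 (NC), −1 (FC)

which reduces to the pseudodiffusion model `exp(−b D*)`, `D* = v²τ/d`,
as `τ → 0`, and to the ballistic model `exp(−c²v²/2d)` (NC) or 1 (FC)
as `τ → ∞`, with `b = ∫q²dt` and `c = −∫q dt` the diffusion- and
flow-weighting factors. Fitting FC/NC data acquired at several encoding
times therefore disentangles the blood speed `v` from the correlation
time `τ`.

## What is in the package

- `ivimflow.waveforms` — piecewise-constant effective gradient
  waveforms, the DDE constructor, dephasing factor q(t), b- and
  c-values.
- `ivimflow.model` — the closed-form `F_P` (overflow-free for any τ),
  its diffusive/ballistic limits, and the two-compartment signal.
- `ivimflow.derivation` — the phase-variance engine: exact numeric
  double quadrature for any piecewise-linear q(t) and VACF, and a
  sympy implementation of the cell-splitting algorithm that derives
  closed forms for arbitrary piecewise-constant waveforms (the DDE
  result above is re-derived and verified symbolically in the tests).
- `ivimflow.langevin` — Monte-Carlo simulation of the Langevin velocity
  process, per-walker phase accrual and the ensemble signal.
- `ivimflow.synthetic` — synthetic FC/NC multi-T datasets emulating a
  brain protocol (b = 0–200 s/mm², T = 50–100 ms, δ = 8.6 ms,
  Δ = 10 ms, six-direction geometric averaging, Rician noise).
- `ivimflow.inference` — voxel-wise Bayesian estimation of
  (D, f, v, τ, S0) by an affine-invariant ensemble MCMC sampler with
  uniform priors, plus bootstrap confidence intervals and map fitting.
- `ivimflow.experiments` — reproducible desk-scale studies (regime
  convergence, analytic-vs-simulated curves, SNR robustness sweep).
- `ivimflow.cli` — the `ivimflow` command (`predict`, `derive`,
  `simulate`, `fit`, `experiment ...`).

## Worked example

```python
import numpy as np
from ivimflow import (make_dde, bvalue, cvalue, strength_for_b, IVIMParams,
                      fp_closed_form, simulate_phases, ensemble_signal)

G = strength_for_b(100.0, 8.6, 10.0)          # gradient for b = 100 s/mm^2
nc = make_dde(G, delta=8.6, Delta=10.0, T=50.0, flow_compensated=False)
fc = make_dde(G, delta=8.6, Delta=10.0, T=50.0, flow_compensated=True)
print(f"G = {G:.2f} mT/m   b(NC) = {bvalue(nc):.1f} s/mm^2   "
      f"c(NC) = {cvalue(nc):.3f} s/mm   c(FC) = {abs(cvalue(fc)):.2e} s/mm")

p = IVIMParams(f=1.0, D=0.0, v=1.5 * np.sqrt(3), tau=200.0)  # sigma_v = 1.5 mm/s
for label, w, m in (("NC", nc, +1), ("FC", fc, -1)):
    fp_a = float(fp_closed_form(p, G, 8.6, 10.0, 50.0, m))
    fp_s, se = ensemble_signal(simulate_phases(w, tau=200.0, sigma_v=1.5, seed=1))
    print(f"{label}: analytic F_P = {fp_a:.4f}   simulated = {fp_s:.4f} +- {se:.4f}")
```

prints

```
G = 36.39 mT/m   b(NC) = 100.0 s/mm^2   c(NC) = 1.674 s/mm   c(FC) = 1.36e-15 s/mm
NC: analytic F_P = 0.0555   simulated = 0.0566 +- 0.0053
FC: analytic F_P = 0.8229   simulated = 0.8247 +- 0.0019
```

The NC measurement is strongly attenuated by the incoherent flow, the
FC measurement recovers most of the signal (T/τ = 0.25 is an
intermediate-to-ballistic regime), and 20 000 Langevin walkers land
within statistical error of the closed form. The same model fits data:
`fit_voxel(signals, default_protocol())` returns posterior medians,
95% intervals and split-R̂ diagnostics for (D, f, v, τ, S0).

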