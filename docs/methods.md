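# Methods

## Flow model

Capillary blood velocity (the component along the encoding direction)
is modeled as an Ornstein–Uhlenbeck process,

    dv = −(v/τ) dt + sqrt(2 σ_v²/τ) dξ,

whose stationary distribution is N(0, σ_v²) and whose autocorrelation
decays exponentially with correlation time τ. For isotropic flow in d
dimensions the mean squared speed is v̄² = d σ_v²; the package reports
the speed parameter `v = sqrt(v̄²)` and uses `d = 3` by default. The
per-component σ_v used by the simulator and the `v` of the analytic
model are therefore related by `σ_v = v/√3`; both conventions appear in
the API where each is natural (simulator: σ_v; model/fitting: v). The
ratio T/τ of encoding time to correlation time indexes the flow regime:
diffusive (T ≫ τ), intermediate (T ≈ τ), ballistic (T ≪ τ).

The choice of an exponential velocity autocorrelation (rather than the
linear one implied by equal-length straight capillary segments) is what
makes the phase distribution exactly Gaussian — the accumulated phase
φ = −∫ q v dt is a linear functional of a Gaussian process — so the
Gaussian phase approximation F_P = exp(−⟨φ²⟩/2) is exact under this
model, not an approximation on top of one.

## Waveforms and closed form

Waveforms are ideal rectangles (zero rise time) stored as effective
gradients: the refocusing pulse's sign flip is absorbed so ∫G dt = 0
holds directly and q(t) = γ∫G dt′ is a plain integral. The DDE layout
puts the first bipolar pair on [0, Δ+δ], the second ending at T, and
any slack between the pairs, symmetric about the refocusing pulse. The
overall sign is chosen so the flow-weighting factor c = −∫q dt is
nonnegative for NC (only c² is physical). `T ≥ 2(Δ+δ)` is enforced;
`δ = Δ` (no plateau) and `T = 2(Δ+δ)` (no gap) are valid edge cases.

The closed form for the DDE phase variance was derived with the
package's own symbolic engine (`ivimflow.derivation`), which implements
the cell-splitting algorithm: partition [0, TE]² by the waveform
breakpoints, split diagonal cells at t = t′ so exp(−|t−t′|/τ) is smooth
per sub-cell, integrate exactly, and sum. The engine handles any
piecewise-constant gradient waveform with the exponential or constant
(ballistic) VACF; the linear VACF is supported numerically only. The
derived DDE expression is frozen into `ivimflow.model` as Ψ and Ω and
re-verified in the test suite both symbolically (simplify-to-zero) and
against adaptive double quadrature (relative error < 1e−6 over a
τ, δ, Δ, T, polarity grid; typical agreement ~1e−10).

Two structural checks fall out of the derivation: with the
polarity-odd cross term Ω removed (equivalently, averaging the FC and
NC expressions), the DDE phase variance is exactly twice that of a
single bipolar pair; and a constant VACF reproduces ⟨φ²⟩ = c²v̄²/d.

## Numerical evaluation

Ψ and Ω as typeset contain growing exponentials (e^{Δ/τ} etc.) that
overflow for τ ≪ δ. They are evaluated in an algebraically identical
form containing only decaying exponentials, valid because δ ≤ Δ and
T ≥ 2(Δ+δ):

    Ψ = 4 − 4e^{−δ/τ} − 4e^{−Δ/τ} + 2e^{−(Δ−δ)/τ} + 2e^{−(Δ+δ)/τ}
    Ω = m (1−e^{−Δ/τ})²(1−e^{−δ/τ})² e^{−(T−2Δ−2δ)/τ}

At large τ the bracket τ⁴(Ψ+Ω) − 4δτ³ + 2δ²(Δ−δ/3)τ loses all
precision to cancellation (the τ⁴…τ¹ orders cancel analytically), so
for τ > 2T it is evaluated by its series in 1/τ starting at the
surviving fourth order. The two branches agree to ~1e−10 at the switch
point. The series is summed to a fixed order (40): for the FC waveform
the leading fourth-order coefficient cancels exactly, so any
"first-term negligible" early exit would be wrong.

Limits: the diffusive reduction F_P → exp(−bD*) requires τ small
compared with the gradient timing (δ, Δ), not merely T; with δ = 8.6 ms
it is accurate to 1% only for τ ≲ 0.4 ms. The ballistic reduction
converges slowly in T/τ at high b (still ~2% off for NC at T/τ = 0.01,
b = 200 s/mm²) and is tested deep in the asymptote (τ = 10⁶ ms for NC;
T/τ = 10⁻⁴ for the FC → 1 contract).

## Monte-Carlo simulator

Euler–Maruyama updates v(t+Δt) = v(1−Δt/τ) + sqrt(2σ_v²Δt/τ)ξ with
initial velocities drawn from the stationary distribution (no burn-in).
Default Δt = 0.1 ms; Δt is auto-refined (with a warning) to τ/20 when
the requested step is too coarse for the requested τ. The per-step
phase increment uses the exact integral of the piecewise-linear q(t)
over the step against the walker's start-of-step velocity, so the
discretization error sits only in the velocity process (O(Δt/τ));
halving Δt moves F_P by less than one Monte-Carlo SE at the defaults.
The ensemble signal is the modulus of the complex mean (magnitude MRI);
its SE comes from a 20-fold delete-one-group jackknife over walkers.
Only the encoding-direction velocity component is simulated — linear
encoding projects out everything else.

## Synthetic data

The generator emulates a multi-encoding-time brain acquisition:
b = 0, 5, 10, 20, 30, 100, 200 s/mm² at T = 50, 60, 85, 100 ms for
both FC and NC (56 points per voxel), δ = 8.6 ms, Δ = 10 ms, six
encoding directions combined by geometric averaging. Tissue defaults
are brain-like medians (f = 4.75 %, D = 0.91 μm²/ms, v = 1.51 mm/s,
S0 = 1) with the correlation time selecting the regime: 10 ms
(diffusive), 130 ms (intermediate), 800 ms (ballistic). Rician noise is
applied after direction averaging at the stated SNR (σ = S0/SNR), which
matches SNR bookkeeping that already folds in the averaging; a
noise-per-direction slow path exists for checking that equivalence.
Realistic brain SNR on the averaged data is taken as ≈30–70.

What the generator does *not* emulate: EPI artifacts, motion or drift,
partial-volume mixing, spatial heterogeneity of parameters (voxels are
i.i.d. draws at one parameter set), or hematocrit-dependent D_b.
Passing recovery tests on these data therefore demonstrate estimator
behavior under the model's own assumptions, not robustness to real
acquisition confounds.

## Bayesian inference

Voxels are fitted independently with uniform priors D ∈ [0, 3] μm²/ms,
f ∈ [0, 1], v ∈ [0, 5] mm/s, τ ∈ [1, 1000] ms, S0 ∈ [0, 2·Smax], and
D_b fixed at 1.75 μm²/ms. The likelihood is Gaussian on magnitude
signals with the per-voxel noise SD integrated out under a Jeffreys
prior (log L = −n/2 · log RSS), appropriate for SNR ≳ 20; a Rician
likelihood at known σ is an option. τ is sampled on a log scale with
the Jacobian correction keeping its prior uniform.

Sampler: a vectorized affine-invariant ensemble ("stretch move", 16
walkers per voxel, a = 2), advancing the ensembles of all voxels in
lockstep as array operations. A plain adaptive random-walk Metropolis
chain was implemented first and abandoned: the posterior at realistic
SNR is a long curved ridge in (f, v, τ) along which isotropic proposals
mix so slowly that single chains pass within-chain R̂ checks while
stuck on one section of the ridge (medians from an independent emcee
run disagreed grossly; the test suite keeps emcee as the independent
cross-check of the implemented sampler). Walkers start overdispersed
across the prior; convergence is monitored by split-R̂ across walkers
with a warning above 1.05. Defaults: 1000 post-burn-in sweeps (16 000
draws), equal burn-in. Point estimates are posterior medians with
2.5/97.5 percentile intervals; cohort uncertainties use a percentile
bootstrap of the median.

## Recovery behavior and known limitations

At high SNR (2000) the fit recovers all five parameters essentially
exactly in the intermediate regime (e.g. median f̂ bias ≈ −0.001 pp,
τ̂ = 127 ms at truth 130 ms in a 50-voxel run). At realistic brain SNR
(50) the single-voxel data contain little information about the
microvascular parameters: the Fisher information at the brain-like
truth gives Cramér–Rao SDs of ≈8 percentage points for f, ≈1.2 mm/s
for v and ≈420 ms for τ (the FC−NC signal separation never exceeds
~1.1σ per point pair). The flat-prior posterior median is then
prior-dominated: f̂ is biased up by several percentage points (~+9 to
+13 pp across seeds), v̂ is pulled toward the prior interior
(underestimated by ~0.9 mm/s), and τ̂ moves toward the prior's center —
up in the diffusive and intermediate regimes, down in the ballistic
regime. D̂ remains nearly unbiased. These are properties of voxel-wise
Bayesian estimation under weak likelihoods, not implementation error
(the independent emcee route reproduces them); estimators that share
information across voxels (spatial priors, hierarchical models) shrink
these biases dramatically but are outside this package's scope, which
deliberately fits voxels independently. Reported τ values at realistic
SNR should accordingly be read as upper-bounded by prior influence, and
f as optimistic.

## Study parameter choices

Desk-scale defaults: recovery studies use 100 voxels per condition,
SNR levels {20, 50, 200, 2000}, and 2000-sweep ensembles — enough for
medians of posterior medians to stabilize to ~1 pp in f while keeping a
full sweep to minutes per condition. The regime-convergence scan uses
σ_v = 1.5 mm/s, b = 200 s/mm², fixed τ = 200 ms with varying T (the
DDE's point: T changes while b, c, δ, Δ stay fixed), and a 5% relative
FC−NC difference as the configurable "converged" threshold; under it
the pseudodiffusive regime begins at T/τ = 5.0 (grid step 0.05), i.e.
not before 4 average direction changes. The Monte-Carlo agreement study
runs 20 000 walkers at Δt = 0.1 ms, matching the analytic curves within
3 SE everywhere it is evaluated.
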