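# Methods

## Model

Two identical Wilson–Cowan populations, each an excitatory group *x_i*
and an inhibitory group *y_i*, coupled through links that originate from
the excitatory groups only (the `alpha_i` links target the other
population's excitatory group, the `beta_i` links its inhibitory group).
Every rate equation has the form `-decay * activity + S(input)`, where
the input is a linear combination of activities plus a constant external
stimulus.  Zero activity is the resting background, so negative values
express depression below rest; the refractory saturation term of the
original Wilson–Cowan formulation is omitted (negligible refractory
period).  The activation is `S(z) = z / sqrt(1 + z^2)`: odd, strictly
increasing, unit slope at the origin, |S| < 1.  Three activation regimes
are exposed:

* `NONLINEAR` — the model proper, used for all simulation defaults;
* `LINEAR` — `S(z) = z`, valid where |z| ≪ 1, the basis of the entire
  closed-form analysis (and genuinely unstable in several regimes, hence
  the integrator's blow-up guard);
* `SATURATING` — `S(z) = sign(z)`, the |z| → ∞ limit used only to
  discuss the strong-excitation regime; it has no derivative and is
  rejected by every Jacobian-based routine.

Both populations share one set of intrinsic parameters (a, b, c, d, e,
w); asymmetry enters only through couplings and stimuli.  This
identicality assumption is what makes the closed forms below tractable.

## Linear analysis

With `S(z) ≈ z` the system is affine, `ds/dt = A s + u`,
`u = (I1, J1, I2, J2)`.  The unique equilibrium is computed by a dense
linear solve of `A s = -u`; the closed form
`x1* = (M·Q1 + P1·Q2)/(M² − P1·P2)` (notation in the README) is kept as
a documentation form and as an internal cross-check, because the solve
is unambiguous where typeset sign conventions are not.  The denominator
`M² − P1·P2` equals `det A = γ₄`; configurations within 1e−12 (relative)
of singular raise rather than return a meaningless point.

The characteristic polynomial coefficients are evaluated from their
closed forms (γ₁ = 2(E−W), …, γ₄ = M² + bE(α₁β₂+α₂β₁) − b²β₁β₂ −
E²α₁α₂) and are property-tested against the numerically computed
characteristic polynomial of the Jacobian on random configurations
(1e−8 relative).  Eigenvalues always come from the dense eigensolver,
never from quartic root formulas.  The Routh–Hurwitz quotients
δ₁ = (γ₁γ₂−γ₃)/γ₁ and δ₂ = (δ₁γ₃−γ₁γ₄)/δ₁ decide stability; any
quantity within 1e−9 of zero sets a `marginal` flag instead of silently
taking a side, because Hopf boundaries are measure-zero sets where a
strict verdict would be noise.

Critical values: `w_c = a+d+e`, `e_c = w−(a+d)`, and for symmetric
coupling `alpha_c = a+d+e−w` (δ₂ = 0 ⇔ ε₁ = 0 there).  `beta_c` is
found by scipy's bisection on β ↦ δ₂(β) to 1e−6, requiring a
sign-changing bracket.  The Hopf period of the newborn cycle is
`2π/√ε₂`, defined only when ε₂ > 0.

## Integration

Classical fixed-step RK4, default step 0.01 from the origin — the
deliberately plain scheme keeps runs bit-reproducible and the contract
faithful to a fixed-step protocol; no adaptive or stiff machinery is
offered.  Default horizon 2000 time units with the second half used as
the measurement window: every benchmark case settles visibly well
within this budget and the cost is negligible.  The inner loop is
JIT-compiled (numba) and mirrors the pure-numpy `rhs`/`jacobian`
definitions; tests pin the two routes together and verify
fourth-order convergence and agreement with the matrix-exponential
solution of the linear model.  A trajectory leaving |state| ≤ 1e6
aborts with the divergence time: the linear activation genuinely
diverges in several regimes and silent inf propagation is unacceptable.

Steady states are reported as the tail mean when every coordinate's
peak-to-peak range over the window is below tolerance (default 1e−3 for
case reports).  Periods are the mean spacing of upward zero crossings
of the mean-removed tail, linearly interpolated between samples, with at
least 3 crossings required; an FFT-peak estimate is provided as a
cross-check utility only — zero crossings are more precise than a
spectral bin at these run lengths.

## Lyapunov spectra and classification

Tangent-space Benettin method: four perturbation vectors (initially the
identity frame) are co-evolved under the analytic Jacobian using the
same RK4 stages as the state, re-orthonormalized by modified
Gram–Schmidt every 0.5 time units, accumulating log stretch factors.
Defaults: 500 time units of transient discarded, 4000 of averaging
window.  At this budget the exponents of all nine benchmark cases are
stable to two decimal places and each case runs in well under a minute
on one CPU.  A classical finite-perturbation two-trajectory scheme would
estimate the same spectrum but needs a perturbation size tuned per case;
the tangent-space route has no such knob and is exactly deterministic.
Two consistency oracles are built in and tested: for a stable linear
system the spectrum equals the eigenvalue real parts, and on any run the
exponent sum must match the time-averaged Jacobian trace (volume
contraction rate), which the kernel accumulates alongside.

Classification treats |L| < 0.01 as zero: all negative → equilibrium;
(0,−,−,−) → limit cycle; (0,0,−,−) → 2-torus; (+,0,−,−) → chaotic;
anything else → unclassified.  Reported spectra are never rounded — the
tolerance lives only in the class decision.

**Isolated configurations** (all couplings zero) are a special case: the
4-D flow is then a product of two independent planar flows, and the
product spectrum conflates the factors — two independent limit cycles
contribute two zero exponents and would masquerade as a torus.  Since a
planar autonomous flow admits only equilibria and limit cycles
(Poincaré–Bendixson), `run_case` classifies isolated configs from the
two-exponent spectrum of population 1's planar subsystem, computed with
a dedicated 2-D tangent-space kernel.  The full 4-D spectrum remains
available for such configs; only the class decision routes through the
planar view.

## Benchmark suite

Nine labelled cases (a–i) share the baseline a = d = 0.01, b = 20,
c = 10, e = 10, I1 = 2, I2 = 1, J1 = J2 = 0 and vary w, alpha, beta.
Two scans accompany them: the chaotic window in w at alpha = 3 (chaos
strictly inside w ∈ {13, 14}, none strictly outside at {12, 17} — the
window edges near 12.5 and 16.5 are fuzzy and deliberately excluded
from strict assertions), and class/δ₂-sign transitions along alpha,
beta or w grids.  Grids are explicit inputs and never auto-refined, so
a scan is reproducible from its config alone.

Two deliberate measurement choices deserve emphasis:

* **Developed-cycle period.** The Hopf formula 2π/√ε₂ ≈ 0.629 describes
  the newborn cycle at the symmetric threshold alpha_c = 2.02, and the
  measured period just above threshold (alpha = 2.05) is 0.633.  The
  fully developed cycle of case (d) (alpha = 3), however, has period
  0.7708 — confirmed independently by an adaptive RK45 integration at
  rtol = 1e−10 and by three estimators (zero-crossing, FFT peak, peak
  spacing).  The commonly quoted 0.63 for that case is the linear
  estimate, not the nonlinear cycle's period; one acceptance-level test
  records this discrepancy as a deliberate failure.
* **Saturation reading.** For w = 20, alpha = 3 every sigmoid input is
  driven deep into |S| ≈ 1, so activities relax toward the decay bounds
  (|x| → 1/a = 100).  The flow's exact fixed point is ≈ (99.9995,
  99.209); the benchmark values (x ≈ 99.3, y ≈ 98.5) correspond to
  reading the state after five excitatory decay time constants
  (t = 500), which `experiments.saturation_run` adopts as its
  observation horizon.  Both numbers — the horizon reading and the true
  asymptote — are what the code computes; nothing is fitted.

## Determinism

There is no randomness anywhere: initial conditions, tangent frames and
grids are fixed inputs, so identical invocations produce bit-identical
CSV/JSON outputs, and a run manifest suffices to reproduce any artifact
exactly.  Property tests draw random parameter sets from a seeded
generator confined to the test suite.

## Limitations

* The closed-form analysis is exact only for the linear activation; for
  the nonlinear model it is trustworthy where |z| ≪ 1 at the operating
  point (slow decay a = d ≪ 1 keeps the benchmark equilibria in this
  regime, which is why the linear equilibria match the nonlinear tails
  to three decimals).
* Hopf transversality is observed numerically (eigenvalue pair crossing
  at δ₂ = 0), not proven symbolically.
* No continuation or Floquet machinery: bifurcations are bracketed by
  grid scans only.
* Spectrum estimation needs the analytic Jacobian; exponents from scalar
  time series (embedding methods) are out of scope.
* Heterogeneous populations (different intrinsic parameters per
  population), time-varying stimuli and the refractory term are not
  representable by design.
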