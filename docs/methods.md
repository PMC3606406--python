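# Methods

## Model

Each of the N neurons carries a phase-like membrane potential `u ∈ [0, 1]`
with dynamics `du/dt = F(u) + g E(t)`; crossing `u = 1` emits a spike and
resets the neuron to `u = 0`.  The velocity field `F` is assumed positive
on [0, 1] (supra-threshold: every isolated neuron fires repetitively) and
at least four times differentiable in the interior; a jump between the
one-sided limits `F(0⁺)` and `F(1⁻)` is allowed and is the decisive
quantity for splay-state stability.  Time is measured in membrane time
constants, so the LIF field is `F(u) = a − u`, `a > 1`.

Spikes drive the common field through a critically damped second-order
filter, `Ë + 2αĖ + α²E = (α²/N) Σ_n δ(t − t_n)`: each spike adds an
α-pulse `α² t e^{−αt}/N` with rise/decay time `1/α`.  The 1/N
normalisation makes the time-averaged field equal the population firing
rate (E → 1/T in the splay state), independent of N.

### Event-driven map

With `P := αE + Ė` the field between spikes is `E(t) = (E₀ + tP₀)e^{−αt}`,
so integrating from one spike to the next gives the exact update

    E' = (E + τP) e^{−ατ},      P' = P e^{−ατ} + α²/N,

the kick being applied at the end of the interval (the new spike).  The
membrane update over τ is exact for LIF (variation of constants,
`u' = e^{−τ}u + χ(τ, E, P)`) and numerically integrated for generic
fields (DOP853, rtol 1e−11 / atol 1e−13 — tight because the stability
analysis finite-differences through this map and needs at least four clean
digits after differencing).  The interspike time is the first root of the
threshold condition for the leading neuron: safeguarded bracketing +
Brent for LIF (|residual| < 1e−13), integrator event detection otherwise.
After each spike the indices shift by one (comoving frame) and the firing
neuron re-enters at the bottom with `u = 0` exactly.

Simultaneous crossings (avalanches) are not supported: the splay regime
keeps potentials separated by O(1/N), so an ordering violation is treated
as an error, not a state to resolve.  `α = 1` is excluded from the LIF
closed form (removable singularity); the generic path covers it.

A fourth-order series version of the membrane update (defect O(τ⁵)) is
kept solely as a validation path and as the basis of the truncated
tangent map below.

## Splay states

In the comoving frame the splay state is a fixed point: constant interval
`τ = T/N`, a τ-periodic field pair

    P̃ = (α²/N)/(1 − e^{−ατ}),    Ẽ = τ P̃ e^{−ατ}/(1 − e^{−ατ}),

(expm1-based evaluation, safe for large ατ) and a decreasing ladder of
potentials from `ũ_0 = 1` down to `ũ_N = 0`.

* **Thermodynamic limit.**  The period T0 is the unique positive root of
  `∫₀¹ du/(g + T F(u)) = 1` (for LIF, equivalently
  `(a + g/T)(1 − e^{−T}) = 1`).  The root is bracketed and polished with
  Brent; existence requires `g < 1` because the one-period potential gain
  tends to g as T → 0 and grows without bound with T.  The profile
  `U(x)`, `x = j/N`, solves `1 − x = ∫₀^U dv/(g + T0 F(v))`, and the slope
  integral `H(x) = ∫₀ˣ F′(U(y))dy` is evaluated after the change of
  variables `y → U`, avoiding any profile interpolation.  The combination
  `C(x) = e^{T0 H(x)} (F(U(x)) + g/T0)` is conserved along the profile
  and is used as a correctness invariant (constant to 1e−9 on a 101-point
  grid).

* **Finite N.**  Generic fields: shooting on τ — set the field pair to its
  τ-periodic value, march the one-interval update N times from `u = 0` and
  root-find the terminal condition `u = 1` (|residual| < 1e−12).  LIF: the
  linear recursion sums to `ũ_j = χ (1 − e^{(j−N)τ})/(1 − e^{−τ})`, so a
  single scalar root-find in τ (xtol 1e−14, needed because the 1/N⁴ period
  corrections at N = 64 are ~3e−8) gives the exact state.

* **Finite-size period correction (LIF).**  Expanding the exact interval
  gain χ(τ) with the periodic field values substituted yields

      χ = (a + g/T)[τ − τ²/2 + τ³/6 − τ⁴/24] + a τ⁵/120 + (g/T) K(α) τ⁵/720 + …

  with the pulse-shape constant `K(α) = 6 − α² − 2α³`.  This constant is
  never trusted as transcribed: a symbolic Taylor oracle (sympy) re-derives
  it at build/test time for α ∈ {3, 9, 30}.  Propagating the τ⁵ defect
  through the period condition gives `T(N) = T0 + T4/N⁴` with

      T4 = −ζ/ξ,   ζ(T) = g T³ (1 − e^{−T})(K(α) − 6)/720,
                   ξ(T) = (a + g/T) e^{−T} − (g/T²)(1 − e^{−T}),

  ξ being the T-derivative of the period condition.  The corrections of
  order 1/N, 1/N², 1/N³ vanish identically; numerically,
  `N⁴(T(N) − T0)/T4 → 1` (within 2% by N = 64, within 0.02% by N = 128).

## Floquet analysis

The state vector of the return map is `(u_1, …, u_{N−1}, E, P)` — the
reset potential is pinned at 0 — so there are N+1 multipliers: two field
modes near `e^{−ατ}` and N−1 membrane modes hugging the unit circle.
Multipliers are converted to exponents through
`μ_k = e^{iφ_k} e^{(λ_k + iω_k)τ}`: the two deepest-in-the-disk
multipliers are assigned to the field branch, the rest are assigned mode
numbers by nearest phase `2πk/N` (a collision raises an error — it signals
an unconverged state or too small N), and the residual phase, wrapped to
(−π, π], gives ω.  One direction of the full variational problem (and the
trivial zero exponent removed by the Poincaré section) is not represented
in this reduced map; it is documented, not reconstructed.

Three Jacobian routes:

1. **Exact (LIF, preferred).**  Closed-form differentiation of
   `u'_{j−1} = e^{−τ}u_j + χ` and the field map, with dτ eliminated via
   the threshold identity; the common divisor is the velocity of the
   firing neuron at threshold.  All LIF results in the acceptance studies
   use this route.
2. **Finite differences (generic).**  Centred differences (h = 1e−6,
   scaled per coordinate, optional Richardson combination of h and h/2)
   of the full event-driven step, re-solving the interspike time at every
   perturbed evaluation.  Agrees with route 1 entrywise to 1e−6 on the
   LIF closed-form step.
3. **Truncated tangent map (cross-check).**  Analytic differentiation of
   the fourth-order series update, truncated at τ³ in the coefficients,
   with exact elimination of dτ through the pinned image of the firing
   neuron (algebraically equivalent, at this truncation order, to
   substituting the expanded field variations).  Its spectrum converges to
   the exact one as N grows; the measured relative defect at φ = π shrinks
   roughly like 1/N (the truncation enters the δu-coefficients at absolute
   order τ⁴ while the target eigenvalue deviation is O(1/N³)).

The analytic SW spectrum uses the *effective* drive `ℱ(v) = F(v) + g/T0`
in the denominator, `λ_k ∝ (F(1) − F(0))/(ℱ(1)ℱ(0))`.  This reading is
forced by the LIF identity `1/(ℱ(1)ℱ(0)) = e^{T0} + e^{−T0} − 2` (a
direct consequence of the period condition), which the implementation
verifies to 1e−12; a `denominator="bare"` switch preserves the literal
alternative.  The crossover form `λ_k = gα²/(4π²k²) · (F(1)−F(0))/(ℱℱ)`
is the small-phase limit, N-independent, valid for 1 ≪ k ≪ N.

**Scope of the sign rule.**  `stability_verdict` (stable iff
`g(F(1) − F(0)) < 0`) covers the SW branch only.  At the canonical
parameters (a = 1.3, g = 0.4, α = 9) the k = 1 long-wavelength pair is
genuinely unstable with an N-independent rate ≈ 0.0165 — the precursor of
partial synchronisation in excitatory networks with fast pulses — while
the whole SW branch is stable.  Numeric verdicts in the spectrum
comparison are therefore computed over the SW window `k/N ∈ [0.1, 0.9]`.
At α = 3 every mode is stable, which is why the nonlinear
perturbation-growth validation runs there.

## Parameters that matter

| parameter | meaning | units | default | why |
|---|---|---|---|---|
| `a` | LIF bias | potential / time constant | 1.3 | moderately supra-threshold; free period ln(a/(a−1)) ≈ 1.47 |
| `g` | coupling strength | potential | 0.4 | well inside the existence range (g < 1), clearly non-perturbative |
| `α` | inverse pulse width | 1/time constant | 9 | pulse much faster than the period but far from the δ-pulse limit |
| `N` | network size | — | study-dependent | spectra over {50…400}; period scaling over {8…64} |

The canonical triple (1.3, 0.4, 9) is an implementation default for tests
and docs, chosen to sit in the generic excitatory regime; every study
states its parameters explicitly.

## Synthetic initial states

`io.make_initial_state` generates the exact splay state, a jittered splay
state (uniform noise of given amplitude on all but the reset neuron,
re-sorted), or a fully random ordered state, all seeded.  These emulate
the idealised homogeneous network only: no heterogeneity in `a` or `g`,
no synaptic delays, no noise during the dynamics, identical pulse shapes.
Passing tests therefore demonstrate correctness of the deterministic
homogeneous model, not robustness of splay states in biologically
heterogeneous networks.

## Numerical choices

* Root-finding is bracketed Brent everywhere (interspike times, periods,
  shooting); residual tolerances 1e−12–1e−13, τ-tolerance 1e−14 for the
  scaling studies.
* Quadratures use adaptive Gauss–Kronrod (`scipy.integrate.quad`); the
  endpoint behaviour for discontinuous F is benign because F > 0.
* The existence scan samples the shooting residual on a 256-point
  geometric τ-grid in (0, 50/N] and bisects the coupling on the presence
  of a sign change (default resolution 0.005).
* Degenerate inputs: g ≥ 1 raises an existence error; α = 1 is rejected by
  the LIF closed form; log-log fits refuse fewer than 3 points and
  magnitudes at solver tolerance (|ΔT| < 100 eps, |λ| < 1e−9 for all N).
* The perturbation-growth fit skips the first third of the run (the gap
  between the leading exponent and the next modes is small) and truncates
  at distance 1e−2 (nonlinear regime) and 1e−13 (noise floor); distance to
  the splay orbit is minimised over cyclic relabelings.
* Problem sizes: spectra to N = 400 (401×401 eigenproblems), period
  scaling to N = 64 with the closed-form solver, nonlinear runs of a few
  thousand periods at N = 8 — everything completes in well under a minute
  on one CPU.

## Known limitations

* Long-wavelength (k = O(1)) modes are computed numerically but have no
  analytic counterpart here; mean-field treatment of that branch and the
  partial-synchronisation Hopf bifurcation are out of scope.
* δ-pulse synapses are excluded: the α → ∞ and N → ∞ limits do not
  commute, so results here do not extrapolate to zero-width pulses.
* The fourth-order period coefficient is LIF-specific; for generic fields
  only the vanishing of the corrections through 1/N³ is exercised.
* Avalanches, heterogeneous parameters, delays and noise are not
  supported.
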