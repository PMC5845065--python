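# Methods

`viscopulse` models the attenuation of a pressure pulse travelling
along a straight, fluid-filled, thin-walled tube whose wall is a linear
viscoelastic solid — the setting of a vascular graft meant to damp
arterial pulses. This note records the models, the numerical choices,
and the limits of what the synthetic experiments can show.

## Constitutive models

Two differential models describe the wall material:

- **Maxwell**: spring `E1` and dashpot `eta` in series, relaxation time
  `tau = eta/E1`. Stress obeys `dσ/dt = E1 dε/dt − σ/τ`. The model
  relaxes fully (fluid-like at long times) and shows permanent
  deformation.
- **Zener** (standard linear solid): a Maxwell branch in parallel with
  a spring `E0`. Stress obeys
  `dσ/dt + σ/τ = (E0+E1) dε/dt + (E0/τ) ε`. Instantaneous modulus
  `E0+E1`, equilibrium modulus `E0`. Setting `E0 = 0` recovers the
  Maxwell model exactly.

Parameters are SI internally (`Pa`, `s`); card files may carry
`_MPa`/`_mm` suffixed keys, converted on ingest.

**Stress-response integration.** For tabulated strain the record is
taken as exactly piecewise linear, which makes both ODEs linear with
piecewise-linear forcing; each segment then has a closed-form
exponential update, and the response is propagated segment-by-segment
*exactly* (for that strain model) in O(n). This was chosen over
stepping an adaptive Runge–Kutta pair across the interpolant's slope
discontinuities, which is both slower by three orders of magnitude and
less accurate near the kinks; it matters because the parameter fitter
evaluates hundreds of responses. When an analytic strain-rate callback
is supplied (e.g. an exact sinusoid), the response is integrated with
adaptive RK45 at `rtol 1e-8`, `atol 1e-12`.

## Wave propagation

With thin-wall equilibrium `p·r = σ·e`, mass continuity and momentum
balance (convective and frictional terms neglected — low-velocity,
laminar regime), the pressure obeys:

- Maxwell wall: the damped wave equation
  `p_tt + p_t/τ = c² p_xx`, `c² = e·E1/(2ρr)` (a Moens–Korteweg-type
  speed);
- Zener wall: the third-order Moore–Gibson–Thompson-type equation
  `c² p_txx + (c0²/τ) p_xx = p_ttt + p_tt/τ`, with branch speeds
  `c0² = e·E0/(2ρr)`, `c1² = e·E1/(2ρr)` and pulse speed
  `c² = c0² + c1²`.

### Modal spectra

On `x ∈ [0, L]` with pinned ends, modes `sin(nπx/L)` have eigenvalues
`λ_n = (nπ/L)²` and per-mode temporal characteristic roots:

- **Maxwell**: discriminant `Δ_n = 1/(4τ²) − λ_n c²`; rates
  `μ_{1n,2n} = −1/(2τ) ± √Δ_n`. Modes with `Δ_n < 0` are underdamped
  (all decay at exactly `1/(2τ)`); low modes with `Δ_n > 0` are
  overdamped, the slowest being `μ_11`. (The sign in front of `1/(2τ)`
  is negative — decaying solutions; the magnitude of `μ_11` for
  `τ = 0.2 s`, `c = 5 m/s`, `L = 10 m` is 0.555 s⁻¹.) The count of
  overdamped modes is `k = floor(L/(2cπτ))`.
- **Zener**: each mode's three roots `1/τ_{n,k}` solve
  `x³ − x²/τ + λ_n(c0²+c1²)x − λ_n c0²/τ = 0`. Roots are evaluated in
  closed form (Cardano; trigonometric three-real-root form when
  `R²+Q³ < 0`, where the literal surds cancel catastrophically) and
  cross-checked on every call against a companion-matrix eigenvalue
  solve; disagreement beyond 1e-9 relative raises. The mode's decay
  time is `τ_n = 1/min Re(1/τ_{n,k})`.

As `n → ∞` the Zener decay rate tends to the **essential spectrum**
`1/τ_∞ = min((1/τ)·E0/(E0+E1), (1/(2τ))·E1/(E0+E1))` — the rate at
which sharp pulses (dominated by high modes) decay.

### Envelope summary and attenuation

When `τ²c² ≥ 1 m²` a single exponential describes the spatial envelope
of a travelling pulse, `p ∝ exp(−x/(c·τ_eq))`, with

- Maxwell: `τ_eq = 2τ` (all modes underdamped), else `−1/μ_11`;
- Zener: `τ_eq = max(τ(E0+E1)/E0, 2τ(E0+E1)/E1)`, identically `τ_∞`.

Note the Zener `τ_eq` always satisfies `τ_eq ≥ 3τ`, with equality at
the branch boundary `E1 = 2E0` (the sometimes-quoted `(2τ, 3τ)` window
for the `E1 < 2E0` branch is an algebra slip: that branch equals
`2τ(1 + E0/E1) > 3τ`).

Attenuation over length `L` is `a = 1 − exp(−L/(c·τ_eq))`; inverting
gives the design length `L = c·τ_eq·ln(1/(1−a))`.

The threshold `τ²c² ≥ 1 m²` is applied as a hard feasibility gate with
the computed value always reported, so callers can impose stricter
margins; see "Limitations" for why they often should.

## Method-of-lines simulator

Space is discretized with second-order centered differences on `N`
interior nodes (`h = L/(N+1)`, default `N = 512`); time integration is
adaptive Dormand–Prince 4(5) (`rtol 1e-8`). The inlet carries one
raised-cosine heartbeat pulse `f(t) = (p_max/2)(1 − cos 2πt/T)` for
`t ≤ T`; the outlet is pinned to zero. The Maxwell system integrates
`(p_i, r_i = dp_i/dt)`; the third-order Zener system additionally
carries `s_i = d²p_i/dt²`, with inlet `r_0 = f'(t)` (analytic) and the
mirrored outlet condition `r_{N+1} = r_{N−1}`. The governing equations
also admit a corner condition `∂²p/∂t∂x(L, 0) = 0` whose discrete role
is ambiguous; the implementation follows the discrete boundary set
above and the quiescent initial state, under which the corner condition
holds trivially at `t = 0`.

Default time horizon is `0.9·L/c`, keeping the pulse inside the tube so
outlet reflections never contaminate decay measurements.

**Decay measurement.** Per snapshot (default cadence 0.15 s), the pulse
amplitude and position are the interior global maximum (excluding
`x ≤ 2h`), refined by a parabola through the peak cell to remove grid
quantization. Snapshots enter the fit once the pulse has fully entered
(`t ≥ T`) and while the peak is away from the outlet. `log(amplitude)`
is regressed on position: slope gives the decay length `d`
(`p ∝ exp(−x/d)`), and `τ_fit = d/c`. Both slope and intercept are
fitted (the envelope's normalization is not assumed). `R² < 0.9` sets a
low-confidence flag, signalling that no single exponential describes
the decay.

## Parameter fitting

The misfit between an experimental record and a simulated stress
response is the mean orthogonal (point-to-polyline) distance in the
stress–strain plane, each axis z-scored by the experimental mean and
standard deviation — a scale-free way to make Pa and dimensionless
strain commensurable (the alternative, raw units, would let stress
dominate entirely). Minimization is Nelder–Mead over log-transformed
parameters (positivity without constraints), `fatol 1e-8`, up to 2000
iterations, default 5 restarts jittered by seeded uniform factors in
[0.5, 1.5]; results are deterministic given the seed.

## Synthetic test data

The generator emulates a gripped uniaxial cyclic tensile test on a soft
silicone: strain `ε(t) = offset + amplitude·sin(2πft)` with defaults
`f = 1 Hz`, `amplitude = offset = 0.035` (a 0→7% cycle), 6 s at 100 Hz,
stress from the exact constitutive response, plus optional seeded
Gaussian noise expressed as a fraction of the noiseless stress standard
deviation.

The nonzero mean strain is deliberate, twice over. Physically, a
gripped tensile specimen cycled "up to 7%" cannot pass into
compression, so the cycle runs 0→7%, not ±7%. Statistically, it is what
makes the inverse problem well-posed: a *zero-mean* sinusoid at a
single frequency exposes only the storage and loss moduli — two numbers
for three Zener parameters — leaving a one-parameter family of
materials indistinguishable up to the brief start-up transient. With
2% stress noise the fitted optimum wanders along that family (errors of
100–300% were observed); with the 0→7% cycle the mean stress pins `E0`
directly and all three parameters recover to ~1% under the same noise.

What the generator does **not** emulate: instrument drift, grip
slippage, the ±3% thick-wall stress bias of a flattened-tube specimen,
multi-frequency content, or amplitude-dependent (nonlinear)
viscoelasticity. Passing recovery tests therefore shows the estimator
is correct and well-conditioned for this protocol — not that every real
single-frequency test identifies a Zener solid.

The canonical silicone (PDMS) card used throughout —
`E0 = 2.114 MPa`, `E1 = 0.9365 MPa`, `τ = 0.2611 s` — is treated as a
fixed material definition (the original instrument records are not
available), giving `c = 13.808 m/s` in a 4 mm-radius, 0.5 mm-wall,
water-filled conduit and ~4% predicted attenuation per meter.

## Inverse design

For each modulus pair `(E0, E1)` on a grid (default 100×100,
log-spaced over 0.01–10 MPa) there is exactly one `τ` meeting a target
attenuation `a` over a device length `L`:
`τ = L/(c·κ·ln(1/(1−a)))` with `κ = τ_eq/τ` fixed by the moduli ratio
(`2(E0+E1)/E1` if `E1 < 2E0`, else `(E0+E1)/E0`; continuous at the
boundary, though the `τ` surface is non-smooth there — accepted, it
matches the formulae). A pair is feasible only if the resulting
`τ²c² ≥ 1 m²`.

A useful closed-form consequence: `τ·c = L/(κ·ln(1/(1−a)))` does not
depend on the moduli magnitudes at all, only on their ratio through
`κ ≥ 3`. The validity product over a design map is therefore bounded by
`(L/(3·ln(1/(1−a))))²` — about 10.9 m² for 2% over 200 mm and only
1.7 m² for 5% over 200 mm.

## Numerical choices

- Integrator tolerances: stress responses `rtol 1e-8 / atol 1e-12`;
  field simulations `rtol 1e-8 / atol 1e-9·p_max`. Overridable.
- Critical damping is classified within `|Δ_n| < 1e-12·(1/4τ²)` and
  treated as a repeated-root overdamped mode.
- Mode-count default for spectrum exports: 200.
- Degenerate inputs: non-monotone time grids, non-positive parameters,
  thickness-to-diameter ratios above 0.25 and empty records raise
  `ValueError`; ratios in (0.2, 0.25] warn. Closed-form/numerical root
  disagreement raises `ArithmeticError`.
- Tie-break in the Zener decay constant: the minimum *real part* over
  the three roots defines `τ_n`; complex pairs contribute their common
  real part.

## Problem sizes used in the shipped tests

Simulator checks run the 10 m reference tube at `N = 512`
(Maxwell/Zener envelope and bracket checks), `N = 1024` for the
Maxwell convergence pair, and `N = 1024/2048` for the Zener convergence
pair. The Zener case needs the finer baseline: its reference pulse
loses only ~16% of its amplitude across the tube, so the fitted decay
length amplifies small dispersion errors (the 512→1024 change is
~1.5%, 1024→2048 is ~0.15%). Fitting checks use the full 6 s protocol;
the 20-replicate noisy-recovery check uses single restarts per
replicate.

## Limitations

- The single-exponential envelope (`τ_eq`) is quantitatively reliable
  only well above the validity threshold. At `τ²c² = 100` the simulator
  agrees with `τ_eq` to a few percent; at `τ²c² ≈ 1–10` — which is the
  *entire* reachable range inside the attenuation design maps, by the
  bound above — measured attenuation deviates from the target by
  ±25–70%, because the travelling sharp pulse mixes modal rates and
  often tracks the oscillatory-branch rate `(1/(2τ))·E1/(E0+E1)` rather
  than the essential-spectrum minimum. Feasibility maps should be read
  as order-of-magnitude design guidance; the shipped tests verify that
  simulated attenuation at feasible points falls within the bracket set
  by the slowest mode and the fast essential branch, and within a
  factor of two of the target.
- In the strongly mixed regime (`τ²c² ≪ 1`) no single decay constant
  fits; the measured constant lands between `τ_∞` and `τ_1` but matches
  neither, and even the `R²` of the log-linear fit can remain
  deceptively high (≈0.94 for the reference case), so the 0.9
  low-confidence threshold does not always trip there.
- Reflections, bifurcations, fluid viscosity, convective acceleration,
  nonlinear/large-strain and fractional-order wall models are out of
  scope, as is reconstruction of full series solutions from arbitrary
  initial data (the simulator supplies complete fields instead).
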