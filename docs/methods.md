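# Methods

## Hill stage

The afterloaded force–velocity relation of a fully activated strip is
fitted with the rectangular hyperbola

    (V + b)(iT + a) = b (TT + a),

with residuals in velocity (afterload is the controlled variable) and TT
fixed at the independently measured isometric tension.  Starting values
come from the linearized transform `(TT − iT)/V` regressed on `iT`; the
optimizer works in `log(a), log(b)` so positivity is structural.  The
reported `Vmax = b·TT/a` is the fitted zero-load velocity, and
`G = Vmax/b = TT/a` holds to machine precision by construction.  The
zero-load clamp point enters as an ordinary point at load 0.  On
noise-free hyperbolic data the fit is exact (relative rss < 1e-18,
property-tested over a broad (a, b, TT) sweep).

## Crossbridge model

Two-state sliding-filament kinetics with strain-dependent rates:
attachment `f(x) = f1·x/h` and detachment `g(x) = g1·x/h` on the working
stroke `0 ≤ x ≤ h`, no attachment beyond `h`, constant fast detachment
`g2` for `x < 0`.  At steady shortening velocity v the attached fraction
solves `−v·dn/dx = f(1−n) − g·n`, giving the closed forms

    n(x) = F1 (1 − exp((f1+g1)(x² − h²)/(2hv))),   0 ≤ x ≤ h
    n(x) = n(0) exp(g2 x / v),                      x < 0
    n = F1 on (0, h] at v = 0,                      F1 = f1/(f1+g1).

Force is the spring moment `∫ n(x)·k_cb·x dx`; normalized by its
isometric value it depends on the rates only through the shape ratio
`r = (f1+g1)/g2` and the reduced velocity `u = v/φ`, `φ = (f1+g1)h/2`:

    P/P0 = 1 − u(1 − e^{−1/u})(1 + r²u/2).

The closed form is verified against a stiff-safe numerical integration
of the transport ODE (≤ 1e-6 absolute over 50 random rate sets) and
against a 10⁶-slab Riemann sum of the force integral (≤ 1e-5).

Derived molecular quantities:

- `kcat = [f1·g1/(2(f1+g1))]·(h/ell)` — the isometric attachment flux
  per actin site (one ATP per cycle);
- `po = F1·k_cb·h/2` — mean spring force of the isometric attached
  population;
- `ts = h / v_cb_max` with `v_cb_max` the root of `P(v) = 0`;
- `atpase = kcat·MC` exactly;
- efficiency `= P(v)·v / (e_ATP · cycling rate)`, maximized over v; it
  vanishes at both ends and peaks at an interior velocity.

### Inversion: mechanics → rates

Three constraints identify the rates from a measured curve:

1. **shape** — `r` is chosen so the model curve matches the data;
2. **scale** — `φ` makes the model's unloaded velocity equal
   `Vmax·L_ref` (nm/s);
3. **partition** — `f1/(f1+g1)` is *not* determined by the normalized
   curve (any partition yields the same shape), so it is supplied as a
   configuration constant (default 0.7, consistent with the term-cohort
   mean rates).  It affects `po`, `kcat` and efficiency but not `G`,
   `v_cb_max` or `ts`.  A direct consequence: the pipeline's recovered
   `po` is constant across samples, and recovered `f1 : g1` is a
   convention, while their sum and `g2` are measured.

Two shape-matching routes are provided.  `invert_from_hill` solves
`G_model(r) = G_sample`, where `G_model(r)` is the Hill curvature fitted
to the model curve sampled at the same relative-load grid as the
measurement protocol (this grid consistency removes discretization
bias).  That route is only well-posed while the model curve is
Hill-like: for `r` beyond ≈ 1.3 the model curve's best positive-G Hill
fit collapses to G ≈ 0 and carries no information about r (the curve
bulges above the straight line, a shape outside the positive-G Hill
family).  The pipeline therefore uses `fit_rates`, which matches the
model curve to the measured points by least squares over `r` with the
velocity scale concentrated out analytically — well-posed for every
`r ∈ [1e-3, 1e3]` and identical to the curvature match on Hill-like
data.  Monotonicity of `G_model(r)` is asserted (and tested) only on
the Hill-like range r ∈ [0.1, 1.2].

### Physical constants

| constant | default | units | rationale |
|---|---|---|---|
| h | 11 | nm | optical-tweezer stroke of smooth/skeletal myosin |
| ell | 36 | nm | actin helical repeat (one site per repeat) |
| k_cb | 0.5 | pN/nm | crossbridge stiffness; puts po at 1–2 pN |
| e_atp | 6.0e-20 | J | free energy per ATP (≈ 60 pN·nm) |
| L_ref | 4500 | nm/Lo | crossbridge sliding per unit-Lo shortening; smooth-muscle contractile-unit scale |
| partition | 0.7 | – | f1/(f1+g1), term-cohort-mean-consistent |

L_ref deserves a caveat.  With `ts = h/(Vmax·L_ref)` no single L_ref can
place both cohorts' mean stroke times inside the reported ranges
(0.13 ± 0.07 s term, 0.06 ± 0.04 s non-pregnant): the reported ts
ordering is inverted relative to the reported Vmax ordering under any
such relation.  L_ref = 4500 nm/Lo puts the term cohort's
mean-rate-curve ts (0.072 s) in range and treats ts elsewhere as a
property-level quantity (positive, scale-covariant: doubling all rates
halves ts), not a numeric target.

## Thermodynamics

- **Force** `Eo/T` with `Eo = 4.24·MC²` (MC in nmol/g, T in kelvin;
  29 °C bath = 302.15 K).  Taken literally; note that at the cohort
  mean contents this gives forces an order of magnitude above the
  reported cohort "thermo force" row under any display-scaling reading —
  the pipeline therefore asserts only orderings and signs, never
  absolute thermodynamic magnitudes.
- **Flow** `v0 = g1`.  The cohort flow statistics coincide numerically
  with the g1 row in both groups (means and sd), so the slow detachment
  constant is used as the detachment-limited cycling flow, in s⁻¹.
- **EPR** `y = force·v0`, exactly, per sample.
- **EEP**, two estimators, both reported:
  1. *trend derivative*: the cohort's (ts, y) cloud is fitted — power
     law `A·ts^β` (log-log least squares) for far-from-equilibrium
     groups, quadratic polynomial for near-equilibrium groups (a
     quadratic lets the derivative itself rise linearly with ts, which a
     straight line cannot) — and `y′_i` is the fitted derivative at each
     sample's ts.  The stability flag (`EEP > 0`) uses this estimator.
  2. *deviation product*: `(1/T)(Eo − Eo*)(v0 − v0*)` about the group
     stationary means; its group mean equals `(1/T)·cov(Eo, v0)`
     (population convention), tested against an explicit double loop.
- **Regime**: ordinary least squares of v0 on force versus a
  two-parameter power law, compared by an F-type ratio of log-scale
  residual variances with (n−2, n−2) degrees of freedom.  A straight
  line fitted in raw space to a genuinely curved (decade-spanning)
  relation leaves systematically inflated log residuals, driving the
  p-value below alpha (default 0.05) → far-from-equilibrium.  Linear
  predictions ≤ 0 are clamped to a tiny positive value, correctly
  penalizing the linear model.  This operationalization labels
  *structured nonlinearity*; a patternless scatter (no force–flow
  relationship at all) is not flagged.

## Phase equation and bifurcation

The regression is fitted exactly as stated — y on y′, quadratic — and
rearranged: `y = c0 + c1 y′ + c2 y′²` gives `a_lin = −1/c1`,
`y_inf = c0`, `b_quad = c2/c1`.  The parameter ψ is taken to be the
curvature G itself, entering through the fitted power law
`y′² = A_pow·G^beta`, so the one-parameter equation is
`y′ = a_lin(y_inf − y) − k_comb·G^beta` with `k_comb = b_quad·A_pow`.

The phase diagram is the parabola `b_quad·y′² + y′ = a_lin(y_inf − y)`;
its two branches merge at the vertex
`y_v = y_inf + 1/(4·a_lin·b_quad)`, `y′_v = −1/(2·b_quad)`.  Fixed-point
stability is decided purely by the sign pattern of the phase map at
`y* ± ε` (relative ε, default 1e-6): (+, −) attracting, (−, +)
repelling, equal signs half-stable; λ is the central-difference slope.
Probing past the vertex on a named branch is an error (the branch is
undefined there); at the vertex itself the analytic continuation of the
real part (−1/(2·b_quad)) is used on the rootless side, which is what
makes the vertex half-stable — the saddle-node structure of the
one-parameter family.  On the reconstructed model the upper-branch
fixed point at `y_inf` is attracting with λ = −a_lin; a strictly zero
λ occurs nowhere on the parabola, so the half-stable behaviour is
attributed to the vertex, and both reports are emitted.

The bifurcation diagram tabulates `y*(G) = y_inf − (k_comb/a_lin)·G^beta`
on G ∈ [0.3, 3.5] (step 0.01); the knee is the grid argmax of the
curvature of y*(G) — the least arbitrary formalization of a visually
identified bend — and lands at G ≈ 0.75 for the reference coefficients,
inside the expected [0.5, 1.5] window around G = 1.

## Synthetic cohorts

Marginals: every parameter (f1, g1, g2, TT, MC) is lognormal,
moment-matched to its target mean ± sd.  Lognormals are forced by the
data themselves — several rate constants have sd ≈ mean, which a normal
would push negative.  Dependence is a Gaussian copula on the log scale
(marginals, and hence the moment matching, are exactly preserved).

The default calibration encodes the qualitative structure the two
cohorts are documented to have, chosen once from a reliability
calculation (per-cohort sign probability ≥ 0.98) and frozen:

- both groups share a *kinetic tempo* factor: pairwise log-correlation
  `rate_corr` among f1, g1, g2 (0.45 term, 0.7 non-pregnant) — faster
  myosin attaches and detaches faster at every strain;
- term cohort: myosin content anti-correlates with the tempo rates f1
  and g2 (`mc_rate_corr = −0.72`), the hypertrophied slow-myosin state;
  content and the flow rate g1 are uncoupled, so the force–flow cloud
  stays unstructured (near-equilibrium).  High-content (high-EPR)
  samples are slow (long ts): EPR rises with ts and the trend-EEP is
  positive.
- non-pregnant cohort: content couples to the flow rate
  (`flow_mc_corr = 0.8`, with the tempo-consistent `mc_rate_corr =
  0.56` to f1/g2), so dissipation concentrates in fast, short-stroke
  samples: EPR falls steeply with ts and the trend-EEP is negative.

All correlation matrices are checked for positive definiteness at
construction.  RNG contract: one root seed; per-sample generators are
derived from `SeedSequence((seed, group code, sample index, stream))`,
so enlarging a cohort never reshuffles earlier samples, and parameter
draws (stream 0) are independent of measurement noise (stream 1).

The protocol emulation samples each strip's forward model curve at
relative loads {0, 0.1, …, 0.7, 1} of TT — zero-load clamp, 6–8
afterloads, isometric point — converts to muscle units through L_ref,
and applies multiplicative Gaussian velocity noise (cv 5 % by default).
Strips fail to contract spontaneously with probability 0.1 and are
flagged (never dropped) as excluded.

What a green synthetic test does establish: the pipeline recovers the
generating kinetics from protocol-sampled mechanics (≤ 2 % noise-free
with the true partition supplied), and the cohort-level thermodynamic
signature — EEP positive at term, negative outside pregnancy; EPR
higher outside pregnancy — is reproduced in ≥ 95 % of seeded cohorts.
What it does not establish: real-tissue covariances (the copula is a
stated construction, not an estimate); absolute agreement of emergent
rows that were never calibration targets.  Two known emergent
divergences: the non-pregnant cohort's fitted Hill curvature comes out
near 0 rather than the reported 0.85 (the canonical model places the
reported mean rates, r = 2.5, outside the Hill-like regime), and stroke
times exceed the reported ranges (see L_ref above).

## Numerical choices

- Root finding (unloaded velocity, load→velocity inversion, shape-ratio
  solve) uses bracketing + Brent iterations to 1e-12 relative or
  tighter; the shape-ratio solve brackets through a cached 241-point
  monotone table of `G_model(r)` over log r ∈ [−3, 3].
- The full-curve rate fit scans 25 grid points in log r and polishes
  with bounded scalar minimization (xatol 1e-10); the velocity scale is
  concentrated out in closed form at every step.
- Quartiles are type-7 (linear interpolation); outliers use the
  1.5·IQR rule; two-group comparisons use the standard one-way ANOVA
  (F = t² identity tested to 1e-10).
- Degenerate inputs fail loudly: G ≤ 0 or Vmax ≤ 0 at inversion,
  all-zero velocities, vertical parabola in the phase rearrangement,
  non-positive inputs to any log-scale fit.  Within a cohort run, a
  strip whose noisy points defeat the Hill/rate fit is recorded under
  `failures` and set aside, mirroring the discarding of unusable strips.

## Limitations

- Single-cycle, steady-state model: no multi-state chemistry, no
  filament compliance, no transient (twitch) dynamics.
- The attachment partition, and hence po, kcat and efficiency levels,
  rest on a convention the mechanics cannot test.
- Thermodynamic magnitudes inherit the literal quadratic force law; only
  signs, orderings and fitted exponents are scientifically load-bearing.
- The regime test needs structured nonlinearity over a substantial force
  range; with ~20 samples it has limited power against mild curvature.
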