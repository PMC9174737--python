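# Methods

## Model

The package models a one-sex (female-driven) age-structured population in
which the birth history of each woman matters through a single state
variable: the age `tau` of her youngest child.  Females are split by
parity into

* `f0(t, a)` — childless females, per year of age, and
* `f(t, a, tau)` — mothers, per year² of (age × time-since-last-birth),
  defined on the triangle `tau <= a`.

Both cohorts die at the female hazard `mu_f(a)`.  Childless women give
birth at the first-birth hazard `beta0(a)`; mothers give birth at
`beta(a, tau)`.  The governing equations are transport equations with
mortality and birth hazards as sinks,

    (∂t + ∂a) f0           = -(mu_f + beta0) f0
    (∂t + ∂a + ∂tau) f     = -(mu_f + beta(a, tau)) f,

closed by two renewal boundaries: newborn girls

    f0(t, 0) = eta [ ∫ beta0 f0 da + ∫∫ beta f da dtau ],

where `eta` is the fraction of births that are female, and new mothers

    f(t, a, 0) = beta0(a) f0(t, a) + ∫ beta(a, tau) f(t, a, tau) dtau.

The total female density `f_tot = f0 + ∫ f dtau` obeys plain
McKendrick–von Foerster transport with mortality only — an identity used
as an internal consistency check.

A birth-spacing policy is the truncation
`beta(a, tau) = beta0(a) · 1{tau > delta}`: no births until the youngest
child is `delta` years old.  `delta = 2` represents the natural interbirth
refractory period (gestation plus lactational recovery) and is the
no-policy baseline; `delta = inf` is the strict one-child limit, in which
every woman bears at most one child.  A minimum childbearing age clamps
`beta0` and `beta` to zero outside the fertile window `[a_min, a_max]`.

### Observed versus first-birth rates

Birth registries measure the *effective* rate `beta_eff(a)` — births per
woman-year among all age-`a` women, regardless of parity.  In the
stationary population the two schedules are linked by

    beta0(a) = beta_eff(a) / (1 - ∫_{a-delta}^{a} beta_eff(s) ds),

with `beta_eff = 0` at negative ages.  `reconstruct_beta0` evaluates this
directly; `forward_beta_eff` solves the same relation for `beta_eff` by
marching forward in age (the trailing integral only involves younger
ages).  The marching handles the current node implicitly, so the two maps
are exact algebraic inverses on the grid.  For `delta = inf` the closed
form `beta_eff = beta0 · exp(-∫ beta0)` (first births only) replaces the
march; its quadrature inverse then agrees only to discretization accuracy
(~3e-4 at the default step), which the tests acknowledge.

### Stationary analysis

At long times `n(t) ~ e^{lambda t}` and the normalized densities converge
to stationary shapes `h0`, `h(a, tau)`, `h_tot = h0 + ∫ h dtau`.  The
growth rate is the unique root of the Euler–Lotka-type condition

    z(lambda) = eta ∫ beta_eff(a) exp(-a lambda - ∫_0^a mu_f) da = 1,

with `z` strictly decreasing.  Given `lambda`:

    h_tot(a) ∝ exp(-a lambda - ∫_0^a mu_f)              (normalized to 1)
    h0(a)    = h_tot(0) exp(-a lambda - ∫_0^a (mu_f + beta0))
    h(a,tau) = h_tot(a-tau) beta_eff(a-tau)
               · exp(-tau lambda - ∫ (mu_f + beta) along the characteristic).

For a birth surface that is *not* the plain truncation (the behavioural
response below), the `beta0 -> beta_eff` relation above does not apply.
The package then solves the two-component eigenproblem directly: for a
trial `lambda` the new-mother boundary density `b(a) = h(a, 0)` satisfies
a Volterra equation marched forward in age, and the age-0 boundary
condition supplies a generalized `z(lambda)`.  When the surface *is* the
plain truncation this route agrees with the marching route (tested to
2e-5 in `lambda`, 1e-4 in `beta_eff`), which is also the package's
numerical verification of the delay relation against the stationary
construction.

### Two-sex summaries

Males are driven by the same birth stream with weight `1 - eta` and their
own mortality `mu_m`; both sexes grow at the female `lambda`.  The
stationary female fraction is `F / (F + M)` with
`F ∝ eta ∫ exp(-a lambda - ∫ mu_f)` and
`M ∝ (1-eta) ∫ exp(-a lambda - ∫ mu_m)`.  The senior fraction is
`∫_{65} h_tot` (threshold configurable, 65 by default).

### Behavioural response

Two multiplicative responses to an imposed delay `delta >= 2`:

* catch-up: mothers whose refractory period just ended give birth at
  `c1 · beta0(a)` for exactly one year, `tau ∈ (delta, delta + 1]`, with
  `c1 = 1 + 0.1 · min(delta - 2, 10)`;
* earlier first births: childless women with `a + delta <= 40` use
  `c2 · beta0(a)`, with `c2 = 1 + 0.05 · min(delta - 2, 10)`.

The one-year window is measured in `tau` and the age condition at the
woman's current age; both readings were open and are fixed here.  Below
`delta = 2` the formulas do not apply and both factors are 1 (with a
warning).

## Numerics

* **Grid.** One uniform grid for age and `tau`: `[0, 110]` years at
  `Δ = 0.1` by default.  Rates are piecewise linear between nodes and zero
  beyond the grid; all integrals are trapezoid sums, cumulative hazards
  are cumulative trapezoids computed once per schedule.  `delta`, `a_min`
  and `a_max` are snapped to the nearest node (logged in run manifests) so
  the refractory cut lies exactly on the lattice.
* **Jump-aware quadrature.** The truncated surface is discontinuous in
  `tau` at `delta` (and at `delta + 1` with the behavioural window).  Each
  `BirthSurface` therefore carries, besides its nodal values (zero at the
  cut, per the strict indicator), the limits *from above* at each node;
  segment-wise quadrature pairs the upper limit at the left endpoint with
  the nodal value at the right endpoint.  This keeps second-order accuracy
  across the cut both in flux integrals and in hazards integrated along
  characteristics.
* **Root finding.** `z(lambda) = 1` is solved by bracket expansion from
  `[-1, 1]` /yr (doubling, capped at ±64) and bisection to
  `|z - 1| < 1e-10`; bisection tolerates the infinities `z` can reach on
  long grids at very negative `lambda`.
* **Forward integrator.** A single characteristic lattice with
  `Δt = Δa = Δtau = Δ` advances both components: one step multiplies each
  density by the exact integrating factor of the trapezoid-averaged hazard
  along its characteristic (all factors precomputed once, so a step is a
  few BLAS-level array operations), then fills the two renewal boundaries
  at the new time.  The block-recursive construction in
  `gamma = min(a_min, delta)` slabs that the same characteristics admit is
  mathematically identical; the uniform lattice was chosen for simpler
  bookkeeping.  Survivors reaching the top of the age grid are removed and
  counted as deaths (mortality data end there; the affected mass is
  negligible over the horizons used).  Trajectories are sampled annually
  regardless of `Δ`.
* **Mass audit.** Each step logs the female mass change, the measured
  boundary inflow ("births") and interior loss ("deaths", including ageing
  out), which balance to rounding by construction and are checked at
  1e-8·n.  Separately, the inflow of new mothers is compared with the
  first/repeat-birth outflow attributed from the hazards; this
  parity-transfer residual is a genuine discretization diagnostic — it
  does not vanish, and the tests assert that it shrinks under grid
  refinement.
* **Problem sizes.** Default analyses use the 1101-node grid; closed-form
  comparisons use a `[0, 2000]`-year grid so truncation is negligible;
  projections run 50–110 years; the refinement check compares `Δ = 0.1`
  against `Δ = 0.05` at a 100-year horizon.  At these sizes the full test
  suite and the acceptance script each run in minutes on one core.

## Synthetic data

`synthetic` generates the inputs the model needs with the structure real
schedules have:

* a unimodal fertility bump on the fertile window (truncated Gaussian,
  exactly rescaled to a prescribed total fertility);
* Gompertz–Makeham mortality with an optional infant-mortality term;
* an age pyramid `∝ exp(-g a - ∫ mu)` (young-heavy for `g > 0`).

The `china_like_preset` bundle (total fertility 2.6, peak age 25, window
(12, 50), `eta = 0.48`, male mortality excess, 490 million females on a
young-heavy pyramid) is a deterministic synthetic calibration evoking
early-1980s China.  It is **not** census data: real schedules have
plateaued fertility shapes, cohort irregularities (famine notches, war
echoes) and non-parametric mortality that the generator does not emulate.
Passing tests demonstrate the correctness of the machinery — conversion
identities, eigenvalue/simulation agreement, conservation, monotone and
non-monotone policy responses — not agreement with any measured
population; analyses of real data should load their own rate CSVs.
Generation is deterministic; a seeded log-normal noise decorator exists
for robustness experiments and is never used in defaults.

## Known limitations

* Rates are time-invariant: no `mu(t, a)`, `beta0(t, a)` or `delta(t)`
  scheduling, and no migration, mating or family structure.
* Parity is binary (childless versus at least one child); birth-order
  effects beyond the youngest child's age are out of scope.
* The behavioural-response accuracy is slightly below the plain model's
  because the catch-up window adds a second hazard discontinuity handled
  by the same jump-aware rule.
* `delta < 2` is accepted by the policy object (the truncation is well
  defined) but the behavioural formulas are not; a policy cannot shorten
  the biological refractory period.
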