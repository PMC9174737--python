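# birthdelay

Age-structured population modelling with an imposed refractory period
between births — a "continuous" family of birth-control policies of which
the strict one-child policy is the limiting case.

Instead of capping the number of children, a policy may require a minimum
delay `δ` between consecutive births, or a minimum childbearing age
`a_min`.  To model this the female population is split by parity:
`f0(t, a)` counts childless women by age, and `f(t, a, τ)` counts mothers
by age and by the age `τ` of their youngest child.  Both obey
McKendrick–von Foerster transport with mortality `μ_f(a)` and birth
hazards `β0(a)` (first births) and `β(a, τ) = β0(a)·1{τ > δ}` (later
births), coupled through renewal boundaries for newborn girls (a fraction
`η` of births) and for women who just gave birth.

The package is for demographers and modellers who want to ask: *for a
given fertility/mortality regime, what does an interbirth-delay or
minimum-age policy do to the long-run growth rate, the age pyramid, the
senior share, the sex composition — and how fast does the transient play
out from a real starting pyramid?*

Two quantities tie everything together:

* the **effective birth rate** `β_eff(a)` — what birth registries
  measure — related to the first-birth hazard by
  `β0(a) = β_eff(a) / (1 − ∫_{a−δ}^{a} β_eff)`;
* the **asymptotic growth rate** `λ`, the unique root of the
  Euler–Lotka-type renewal condition
  `z(λ) = η ∫ β_eff(a) exp(−aλ − ∫_0^a μ_f) da = 1`,
  with the stationary age density `h_tot(a) ∝ exp(−aλ − ∫_0^a μ_f)`.

See `docs/methods.md` for the full model, discretization and limitations.

## Worked example

No external data is needed: the `synthetic` module generates schedules
with realistic structure (a unimodal fertility bump, Gompertz–Makeham
mortality, a young-heavy pyramid).  The bundled preset evokes early-1980s
China (total fertility 2.6, `η = 0.48`) but is synthetic, not census data.

```python
import birthdelay as bd

preset = bd.china_like_preset()
beta0 = bd.reconstruct_beta0(preset.beta_eff, preset.natural_delta)

for delta in (2.0, 4.0, 8.0):
    lam, beta_eff = bd.solve_policy_growth_rate(
        beta0, bd.PolicyConfig(delta=delta), preset.mu_f
    )
    print(f"delta={delta:g}: lambda={lam:+.6f}/yr, effective TFR={beta_eff.integral():.3f}")
```

prints

```
delta=2: lambda=+0.003997/yr, effective TFR=2.600
delta=4: lambda=-0.005824/yr, effective TFR=2.037
delta=8: lambda=-0.019103/yr, effective TFR=1.479
```

With the natural two-year spacing the population grows ~0.4 %/yr; a
four-year imposed delay already makes the stationary growth rate negative
(each woman averages ~2.04 births), and at eight years the population
shrinks ~1.9 %/yr.  Every script in `examples/` is a similar small
narrative: stationary age structure and senior share, forward projection
of a pyramid (with a per-step mass audit), the non-monotone effect of the
minimum childbearing age under a strict one-child limit, and the
behavioural-response model in which mothers "catch up" after the
refractory period.

A thin CLI wraps the same pipelines for shell use, e.g.

```
birthdelay synth --out-dir rates/
birthdelay stationary --beta-eff rates/beta_eff.csv --mu-f rates/mu_f.csv \
    --delta 4 --out summary.csv
birthdelay scan-delta --beta-eff rates/beta_eff.csv --mu-f rates/mu_f.csv \
    --from 2 --to 10 --step 1 --out scan.csv
birthdelay evolve --beta-eff rates/beta_eff.csv --mu-f rates/mu_f.csv \
    --initial rates/pyramid.csv --delta 4 --horizon 100 --out-trajectory traj.csv
```

Rate tables are plain `age,rate` CSVs interpolated onto the model grid;
every output gets a JSON manifest (parameters, grid, how `δ` was snapped)
sufficient to regenerate it, and reruns are byte-identical.

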