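# Methods

## Model

The population state is `(n, m)`: `n` public-good producers and `m`
cheaters in a well-mixed patch, evolving as a continuous-time Markov
chain with four reaction channels (one birth and one death per strain).
Autoinducer and public-good concentrations are not modeled explicitly:
both are assumed to equilibrate much faster than births and deaths, so
their effects collapse into state-dependent rates. The public-good
benefit enters the per-capita birth rate through a saturating Hill
function `B(n)` of the producer count; QS activation enters as a second
Hill factor `A(x)` of the signaling count `x` (`n`, or `n + m` when
cheaters also emit autoinducer). Producers pay the production cost `c`
times the activation level; cheaters never pay it. The per-capita death
rate `μ₀·(n+m)` rises linearly with total density (toxic byproducts,
crowding), which guarantees eventual extinction at `(0,0)` and makes the
process almost surely absorbed.

The producer birth rate carries a clamp `max(·, 0)`: with high cost and
low benefit the bracketed per-capita rate can go negative, which is not a
rate. The clamp is applied to the whole bracket times `n`. The cheater
birth rate is a sum of non-negative terms and needs no clamp.

There is no mutation or migration, so a strain that reaches zero count
never returns: the first contact with either axis decides the
evolutionary outcome ("fixation"), even though the population keeps
evolving afterwards until extinction.

## Parameters

| name | meaning | default | units |
|------|---------|---------|-------|
| `g` | maximal public-good birth benefit | 1 (the rate unit) | time⁻¹ |
| `lambda0` | constitutive growth from alternative nutrients | 0.2 | time⁻¹ |
| `c` | maximal production cost, `0 ≤ c ≤ 1` | 0.15 | time⁻¹ |
| `a` | producer advantage added to `g` for producers only | 0 | time⁻¹ |
| `mu0` | density-dependent death constant | 0.01 | time⁻¹·indiv⁻¹ |
| `Kg`, `hg` | benefit half-max count and exponent | 15, 2 | indiv, — |
| `Ka`, `ha` | activation half-max count and exponent | 15, 2 | indiv, — |
| `N` | lattice truncation bound | 100 | indiv |

All rates are in units of `g`. The defaults are a representative
operating point: `Ka = 15` places quorum at moderate density, `mu0 =
0.01` puts the saturated producer equilibrium `n* = round((λ₀+g−c)/μ₀)`
at order 100, the scale at which demographic noise is strong but
populations are not trivially ephemeral. Hill exponents are accepted as
any positive reals, not only integers: the formulas are well defined for
reals and integer sweeps are a special case. The AO and NP strategies are
implemented as exact algebraic substitutions (`A ≡ 1`, `A ≡ 0`), never as
extreme floating `Ka`, so the QS limits `Ka = "zero"` / `"infinity"`
reproduce AO / NP bit-for-bit and `(n/Ka)^h` can never overflow.

`equilibrium_producers` rounds half-up (0.5 away from zero) rather than
using banker's rounding. Note `n*` assumes a saturated benefit `B ≈ 1`;
when `Kg` is comparable to `n*` the actual zero-growth crossing sits
lower (the `zero_net_growth_contour` scan reports the true crossing).

## Solvers

All quantities are solutions of stationary boundary-value problems for
the generator `Q` on the square lattice `{0..N}²` with linear index
`k = n(N+1) + m`. Truncation is reflecting: birth transitions out of
`n = N` or `m = N` get rate zero, deaths are untouched.
`truncation_adequacy` reports the minimal `−net_growth` over the boundary
rows and flags (as a warning, not an error) when it is below `5·μ₀·N`, a
configurable heuristic for when the finite matrix distorts the infinite
chain. Comparisons near the boundary should be treated with caution —
e.g. the exact `Ka`-invariance of invasion fixation probabilities at
`c = 0` (a neutral-martingale identity on the unbounded lattice) only
emerges numerically once the grid leaves ample headroom above `n*`
(relative spread 5·10⁻¹³ at `N = 200` vs 12% at `N = n* + 5`).

Fixation probabilities impose the axis values exactly (1 on the winning
axis, 0 on the other) and solve the interior by sparse LU factorization.
The conditional fixation time solves the same operator with right-hand
side `−π` and zero on both axes, then `τ = θ/π` where `π > 0`; states
with `π = 0` get an explicit NaN (the conditioning event is null there),
serialized as JSON null. The extinction time solves `QT = −1` with
`T(0,0) = 0`.

**Instability detection.** For long-persistence regimes `T` reaches
magnitudes like 10²⁵ and the direct solve, though it factorizes fine,
returns values wrong by orders of magnitude. The residual is therefore
scaled by `‖b‖` alone (not by `‖A‖·‖x‖`): a backward-error scale would
stay tiny precisely when the forward error explodes. A solution with
negative or non-finite entries, or residual above 10⁻⁶, is flagged, and
the automatic path falls back to the decomposition estimator:
`T(n,m) = Σᵢ π^{i,0}(n,m)·T(i,0) + Σⱼ π^{0,j}(n,m)·T(0,j)`, where the
axis-hitting distribution comes from one multi-right-hand-side solve
(all `2N` targets share one factorization) and the axis times from the
1-D closed form. The closed form is a nested sum of positive terms
(no cancellation), accumulated with running products and a log-space
fallback on overflow; it is validated against an exact rational
(Fraction-based) tridiagonal elimination, which keeps full accuracy at
any conditioning.

The decomposition assumes fixation is fast relative to the pure-strain
persistence that follows. Where that separation holds (e.g. `μ₀ = 0.04,
λ₀ = 0.2, c = 0.15`) the median disagreement with the stable direct
solve is ~5%; with `λ₀ = 0` (short extinction times, no separation) it
reaches ~25%. On the axes the decomposition is exact by construction.
Because strict `T_QS > T_AO` comparisons flip for states where the two
strategies are near-tied, classification of a regime as destructive /
constructive is only solver-independent for states with a clear margin;
the tolerance-`δ` variant of the phase diagram exists for exactly this
reason, and the test suite asserts cross-solver stability of the verdict
for states with `|log(T_QS/T_AO)| > log 1.3`.

## Simulation

The simulator is a direct-method SSA (two uniforms per event) on the
*unbounded* lattice — the quadratic death rate needs no truncation — with
per-state rate memoization (trajectories revisit few states). Fixation is
recorded at first axis contact; runs always continue to `(0,0)` or to an
event cap, which raises an error carrying the partial record.
`estimate` spawns per-replicate seeds deterministically from one base
seed and reports the cheater-fixation fraction with an exact
(Clopper–Pearson) 99% CI, and conditional-fixation/extinction time means
with standard errors. Solver/simulator agreement is checked at five
parameter sets spanning QS/AO/NP and both signaling modes.

What simulation-based checks do *not* show: the model itself abstracts
real populations heavily (no spatial structure, no explicit molecule
dynamics, identical rates within a strain, no mutation/migration), so
agreement between the two routes validates the implementation of this
chain, not the biology.

## Scenario drivers and reporting conventions

Comparative maps report on the strictly mixed set `n ≥ 1, m ≥ 1,
n + m ≤ N_report` (axis states make QS/AO ratios degenerate). The phase
diagram computes, per `(λ₀, c)` cell, the fraction of reporting states
with `log(T_QS/T_AO) > δ` (`δ = 0` is the plain strict comparison; ties
count as "not greater"); fraction 0 classifies the cell destructive,
1 constructive, otherwise mixed; cells where solvers fail are marked
missing, never silently zero. Default grids are `λ₀ ∈ {0, 0.05, …, 0.5}`
and `c ∈ {0, 0.025, …, 0.25}`, fully configurable. The Hill-parameter
sweep uses the 5×5×5×5 design `Kg, Ka ∈ {10..30}`, `hg, ha ∈ {1..5}`
(625 rows); AO solves are cached across `(Ka, ha)` since AO ignores
activation parameters. Invasion scenarios start at `(n*, 1)` and refuse
to run when `n* < 1` or `n* > N`; colonization scenarios start at
`(1, 0)` and use the 1-D closed form directly.

Directional regime claims (e.g. "QS is constructive at `λ₀ = 0.2,
c = 0.15`", "cheater signaling shortens extinction times") are
regime-dependent: they hold under some `(μ₀, N)` operating points and
not others. The drivers therefore *log* directional deviations as
warnings and assert only the parameter-robust facts: QS lowers the
invading cheater's fixation probability whenever `c > 0`, and `Ka` has
no effect on invasion fixation at `c = 0` (neutrality). Under the
package defaults at `μ₀ = 0.01`, cheater signaling raises fixation
probability and lowers both fixation and extinction times on the entire
reporting set, while at `μ₀ = 0.04` the extinction-time effect is nearly
neutral — an illustration of why these are reported, not hard-coded.

## Problem sizes

Default test and acceptance runs use `N ≤ 100` for 2-D solves (10 201
states; a solve takes tens of milliseconds), `N = 200` for the
neutrality check, 1000 replicates for simulator validation, and dense
oracles on `N ≤ 4` grids over 20 random parameter draws. These sizes
give sub-minute full runs while keeping every comparison's discriminating
power (oracle agreement is asserted at 10⁻⁹, closed forms at 10⁻⁸
relative).

## Known limitations

* The truncated square grid distorts quantities for start states near the
  boundary; choose `N` with headroom above both `n*` and the zero-growth
  contour (the adequacy report helps).
* The decomposition estimator has no internal error bound; its validity
  rests on the timescale-separation assumption above.
* `τ` is undefined (NaN) where cheater fixation is impossible; downstream
  ratio maps propagate NaN rather than inventing values.
* No quasi-stationary analysis or WKB asymptotics for the extinction
  time; no spatial or multi-patch structure; no mutation or migration.
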