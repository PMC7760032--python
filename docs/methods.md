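# Methods

## Model

`bipbe` solves pure binary aggregation of a bicomponent population. Each
particle carries a property vector (u, v) — in the granulation reading,
solid mass and binder mass, in dimensionless units. Coalescence of two
particles produces one particle with the componentwise sum of properties at
rate a(x, x′); the kernels shipped are the size-independent constant kernel
a = 1 and the additive sum kernel a = θ(x) + θ(x′), θ = u + v. Both are
symmetric, nonnegative and time- and composition-independent. No breakage,
growth or nucleation terms are included.

The initial population is a product of gamma densities,
n(u,v,0) = N₀ g(u; p₁, m₁₀) g(v; p₂, m₂₀) with
g(x; p, m) = ((p+1)/m)^(p+1) xᵖ e^(−(p+1)x/m) / Γ(p+1); each factor has unit
integral and mean m. Defaults are the benchmark values N₀ = 1, p₁ = p₂ = 1,
m₁₀ = m₂₀ = 0.04, which keep the population far inside the truncated
domains used below. The parametric family is implemented in full; nothing
is hard-coded to the defaults.

## Discretization

**Grid.** The infinite domain is truncated at u_max per axis and divided
into geometric cells: boundaries [0, u_min, u_min·q, …, u_max] with
q = (u_max/u_min)^(1/(I−1)); the first cell [0, u_min] absorbs the origin.
Representatives (pivots) are cell midpoints. The benchmark grids use
u_min = 6·10⁻⁵ with u_max = 21 (constant kernel) or 30 (sum kernel) and
I = 20 or 25 cells per axis, giving q ≈ 1.7–2. Only "non-uniform" is
specified for the published grids; geometric spacing is the standard choice
in the sectional literature and the computed q ≈ 2 matches a doubling grid.

**Cell populations.** N_ij is the integral of n over cell (i, j). The
initial condition is discretized by exact cell integration (regularized
incomplete gamma differences), and the analytical reference populations by
5-point Gauss–Legendre quadrature per cell. A midpoint rule (density at the
pivot times cell area) is available as an option and is the convention used
for flat-representation plots, but it is a poor default on q ≈ 2 grids: at
the benchmark horizons it misstates the reference tail cells enough to
dominate the error diagnostics, and it biases the discrete initial mass by
−7%, which directly distorts the sum-kernel decay rate (see Limitations).

**CAT.** For every unordered cell pair (j ≤ k lexicographically) the event
rate (1 − ½δ_jk)·a(x_j, x_k)·N_j·N_k is accumulated into the cell containing
x_j + x_k under the *left-closed* convention, together with the property
flux (x_j + x_k) times the rate. Per receiving cell the mean birth property
ū = V/B is formed and the birth is split over the 2×2 pivots bracketing ū
with tensor-product linear fractions — the unique product-form weights that
are nonnegative, sum to one, and reproduce ū in both components, so number
and both masses are preserved. At the domain edge the missing neighbor
collapses onto the host pivot (a small local bias, traded for positivity).
Aggregates beyond u_max in either component cannot be represented. Under
the default "conservative" truncation such overflow events are removed
entirely (no birth, no death), mirroring the FVS convention, and the
semi-discrete system conserves mass to ~1e-9 relative over the benchmark
horizons (the residual is the edge-clamp bias). The literal "printed"
variant keeps the death sum over all partner cells while still dropping
the overflow births; it reproduces the truncated continuous equation's
physical mass leak (~1e-5 relative over the constant-kernel horizon) and
remains selectable for sensitivity analysis.

**FVS.** Aggregates are assigned under the *right-closed* convention to a
cell l and the full birth is placed at its pivot with weight
φᵇ = θ_sum / (2θ_l − θ_sum); deaths carry φᵈ = θ_l / (2θ_l − θ_sum). Both
vanish jointly when the aggregate exceeds the domain. Per event these
weights satisfy φᵇ − 2φᵈ = −1 (exactly one net particle lost) and
φᵇθ_l = φᵈθ_sum (exact mass conservation, asserted on every RHS call at
1e-10 relative). The two identities uniquely fix the algebraic form of the
weights, and they are unit tests.

*Degenerate corner events.* With the first boundary pinned at 0, the
self-pair of the corner cell aggregates exactly onto that cell's far corner
under the right-closed convention, which zeroes the weight denominator
(θ_lo = 0, θ_sum = θ_hi). Such exactly-on-boundary events are retargeted to
the left-closed cell (one cell up), restoring a positive denominator; both
per-event identities continue to hold. This is the package's own tie-break
for a case the printed convention leaves singular.

**Time integration.** Both semi-discrete systems are advanced by scipy's
embedded adaptive RK45 with rel_tol 1e-8 and abs_tol 1e-12 — tight enough
that time-stepping error is negligible against the spatial discretization
error, which is the object of study. The systems are quadratic and
non-stiff at the benchmark scales.

## Analytical references

Exact series solutions under the gamma-product initial condition are
evaluated in log space (log-gamma) with a running relative cutoff
(term_tol 1e-14) and a cap of k_max = 2000 terms. The peak term index grows
like √(uv)/m, so a few hundred terms are genuinely needed at the largest
benchmark pivots; a convergence guard refuses to declare convergence while
the term magnitudes are still growing in log space (early terms can
underflow to zero at far-tail points). Term k of either series is the
contribution of aggregates of k+1 primary particles.

The sum-kernel solution uses s = u+v, s₀ = m₁₀+m₂₀, φ = N₀(m₁₀+m₂₀) (the
total mass) and τ = 1 − e^(−φt). Two sign conventions found in print were
resolved against hard constraints: τ must lie in [0, 1) with
μ₀₀ = N₀(1−τ) decaying, and the series variable must be **positive**
(s·τ/s₀)ᵏ — the negative variant produces a negative density and moments
that contradict the closure below, while the positive form reduces
term-by-term to the classic 1-D additive-kernel solution's Poisson-type
j-mer weights.

Moments up to third order satisfy closed ODE systems obtained by expanding
(u+u′)ᵃ(v+v′)ᵇ under the aggregation operator. For a = 1 these integrate
to explicit polynomials (μ₀₀ = N₀/(1 + N₀t/2), first moments invariant);
for the sum kernel the closed 10-moment system is integrated with DOP853 at
rtol 1e-12. Quadrature moments of the series match the closures to ~1e-8
at the benchmark end times — a single test that validates the series
transcription and the closure derivation simultaneously.

## Mixing statistic

χ² = η²μ₂₀ − 2η(1−η)μ₁₁ + (1−η)²μ₀₂ with η = 0.5 measures the variance of
excess binder. Its final term is sometimes typeset with μ₂₀ repeated; the
μ₀₂ form is the statistically meaningful variance and coincides with the
printed one for the symmetric benchmark (m₁₀ = m₂₀), so both variants are
selectable with μ₀₂ the default. Under the closures, dχ²/dt ∝ (μ₁₀ − μ₀₁)
(constant kernel) and ∝ (μ₁₀−μ₀₁)(μ₂₀−μ₀₂) (sum kernel): χ² is exactly
invariant for symmetric initial conditions, which the tests assert to 1e-6
relative drift over the benchmark horizons.

## Stochastic oracle

An exact direct (Gillespie) simulation of the coalescence master equation:
n sampled particles in virtual volume V = n/N₀ coalesce pairwise at rate
a/V, so the ensemble's mean-field limit is the continuous equation. Pair
selection is O(1) per event for the constant kernel and uses a
mixture-with-rejection draw proportional to θ_i + θ_j for the sum kernel.
Mass is conserved exactly per event. Cost is quadratic in n; n = 10⁴ runs
in seconds. The oracle is the decisive independent check of the sum-kernel
moment closure and of both deterministic solvers.

**What the oracle comparison shows.** Solver and oracle are compared in the
same sectional lens: oracle particles are binned onto the grid and pivot
moments of both are compared. This isolates the schemes' *dynamic* error
from the (grid-dependent, several-percent) error of representing any
distribution by midpoint pivots, which both sides share. The equivalence
test runs both schemes on a 56×56 geometric grid over [0, 4]²
(u_min = 4·10⁻³, q ≈ 1.15) to t = 5 — resolution chosen so the
deterministic-vs-analytic moment error (≤ 0.3%) is subdominant to the
3-standard-error Monte Carlo band of 50 replicates of 10⁴ particles.

## Benchmark comparison and its limits

The synthetic study conditions are the published ones: 20×20 (and 25×25)
geometric grids, constant kernel on [0,21]² to t = 60 and sum kernel on
[0,30]² to t = 20. At these horizons the degree of aggregation reaches
0.97 (constant; exact 30/31) and 0.82 numerically for the sum kernel
(analytic 1 − e^(−1.6) ≈ 0.80).

Two caveats bound what agreement with the published tables can mean:

- The discrete number balance of both schemes is exact, so for the sum
  kernel μ₀₀ decays at exactly the *discrete* mass: I_agg(20) = 1 −
  e^(−20·M_h). Any published value materially above the analytic 0.80
  implies a discrete initial mass well above 0.08; no defensible
  discretization of the stated initial condition on the stated grid
  produces that, and this package reports the faithful value.
- Distribution-level L1 errors (Δᵢⱼ) at strong aggregation are residuals of
  two large, partially cancelling representation effects and are sensitive
  to exactly how the non-uniform grid aligns with the evolved distribution.
  On this package's geometric grids they reproduce the published pattern
  and magnitude (FVS ahead of CAT on moment-weighted errors; errors
  shrinking with refinement for CAT) but not every printed digit, and the
  refinement trend of the FVS L1 error is non-monotone between 20 and 25
  cells. Convergence was verified separately: moment errors fall to ~1% by
  80×80 cells.

## Known limitations

- Pure aggregation only; kernels must be composition-independent for the
  χ² invariance to hold (the solvers themselves accept any symmetric
  kernel through the generic hook).
- The synthetic benchmark exercises smooth, separable gamma initial data
  and two analytically tractable kernels; passing tests demonstrate
  correctness of the discretizations and diagnostics under these
  conditions, not predictive accuracy for real granulators with physical,
  composition-dependent kernels.
- The stochastic oracle supports the two named kernels only.
- Edge-cell redistribution in CAT clamps to the host pivot, so CAT mass
  conservation is exact only up to the edge-clamp bias (~1e-9 relative over
  the benchmark horizons under the default truncation); FVS conservation
  is exact by construction for all states.
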