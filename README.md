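# bipbe — bicomponent aggregation population balance solvers

Wet-granulation processes (twin-screw, high-shear, fluidized-bed) build
granules by aggregation of particles that carry **two** conserved properties:
solid mass *u* and binder mass *v*. Predicting not just the granule size
distribution but how well the binder is **mixed** across granules requires
solving the bivariate Smoluchowski aggregation equation

```
∂n(u,v,t)/∂t = ½ ∬ a(u−u′, v−v′; u′, v′) n(u−u′, v−v′) n(u′, v′) du′dv′
             −  ∬ a(u, v; u′, v′) n(u, v) n(u′, v′) du′dv′
```

for the number density n(u,v,t), with a symmetric, nonnegative aggregation
kernel a. `bipbe` implements and compares the two standard sectional
discretizations on non-uniform (geometric) grids:

- the **cell average technique (CAT)** — births binned by aggregate size,
  averaged per cell, and redistributed to the bracketing pivots with
  bilinear weights so that number and both component masses are preserved;
- the **conservative finite volume scheme (FVS)** — each birth placed at the
  pivot of the receiving cell with algebraic correction weights φᵇ, φᵈ
  chosen so that each event loses exactly one particle and conserves mass
  exactly.

Alongside the solvers the package provides:

- analytical series solutions for the constant kernel (a = 1) and the sum
  kernel (a = u+v+u′+v′) under the gamma-product initial condition
  n(u,v,0) = N₀ g(u; p₁, m₁₀) g(v; p₂, m₂₀), plus the closed moment ODE
  systems for all moments up to third order;
- diagnostics: moments μᵢⱼ, degree of aggregation I_agg = 1 − μ₀₀(t)/μ₀₀(0),
  weighted sectional errors Δᵢⱼ, average sizes, the excess-binder mixing
  statistic χ² = η²μ₂₀ − 2η(1−η)μ₁₁ + (1−η)²μ₀₂ (η = 0.5), and the flat
  1-D representation of the 2-D cell populations;
- an exact event-driven stochastic simulation (direct Gillespie) of the
  same dynamics, used as an independent oracle;
- a benchmark runner (`bipbe benchmark`) emitting CSV/JSON report bundles.

## Worked example

```python
import bipbe as bp

cfg = bp.BenchmarkConfig(kernel="constant", scheme="both")  # 20x20, t = 60
result = bp.run_benchmark(cfg)
print(result.moment_series["fvs"][["t", "mu00", "Iagg", "chi2"]].iloc[-1])
print(result.errors.round(4))
```

prints (abridged)

```
t       60.000000
mu00     0.032258
Iagg     0.967742
chi2     0.003105
```

i.e. by t = 60 aggregation has consumed 96.8% of the initial particles
(the exact constant-kernel law gives μ₀₀(60) = 1/31, I_agg = 30/31 ≈ 0.97),
while the mixing statistic has drifted from its exact invariant value
4·10⁻⁴ to 3.1·10⁻³ — the discretization, not the physics, moves χ², and
refining the grid pulls it back (1.99·10⁻³ at 30×30). The error table

```
         CAT     FVS
Δ0,0  0.1068  0.1378
Δ1,0  0.2058  0.1917
Δ2,0  0.3261  0.2675
Δ1,1  0.3078  0.2544
Δ3,0  0.4495  0.3408
Δ2,1  0.4096  0.3146
```

gives the L1 discrepancy between numerical and analytical cell populations
weighted by the pivot monomials uⁱvʲ: FVS resolves the higher moments
better, CAT the raw number distribution — the trade-off at the heart of
scheme selection for granulation models. The same runs are available from
the shell:

```
bipbe -v benchmark --kernel constant --scheme both --out report/
```

Short narrative scripts, one per capability, live in `examples/`.

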