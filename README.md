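# lnakit

Intrinsic-noise analysis of biochemical reaction networks by the **linear
noise approximation (LNA)**, coupled in a closed loop to parameter scans
and global optimisers, and validated against exact Gillespie simulation.

## Who this is for

Modellers of signalling and metabolic networks who want to know how large
the random fluctuations in molecular copy numbers are, and — when
parameters such as phosphatase activities are poorly characterised —
*where in parameter space* those fluctuations are largest, smallest, or
most correlated.  Stochastic simulation answers these questions one
parameter point at a time at enormous cost; the LNA answers them in
milliseconds per point, which makes systematic scanning and global
optimisation of noise statistics practical.

## The method

A single-compartment network of K̂ species and M irreversible reactions
with stoichiometric changes ν<sub>iμ</sub> and macroscopic rate laws
f<sub>μ</sub>(x) (x = n/Ω, number densities; Ω the system size converting
densities to particle numbers) obeys the chemical master equation.
Expanding it to next-to-leading order in Ω<sup>−1/2</sup> about a stable
fixed point x\* of the deterministic system dx/dt = Σ<sub>μ</sub>
ν<sub>μ</sub> f<sub>μ</sub>(x) gives Gaussian fluctuations whose
stationary particle-number covariance C solves the Lyapunov equation

```
A C + C Aᵀ + Ω B = 0,
A_ij = Σ_μ ν_iμ ∂f_μ/∂x_j |_{x*},      B_ij = Σ_μ ν_iμ ν_jμ f_μ(x*).
```

Conserved moieties (left null vectors of the stoichiometry matrix) make
the unreduced A singular, so the pipeline is: detect conservation
relations exactly (rational arithmetic) → reduce to K = K̂ − Λ
independent species → find a stable steady state (damped Newton with an
ODE-integration fallback) → solve the Lyapunov equation by the
Bartels–Stewart (Schur) method → recover the full K̂ × K̂ covariance
through the link matrix, C = L C<sup>red</sup> Lᵀ.

On top of the single evaluation, the package closes the loop
{set parameters → steady state → LNA → statistic} inside

* regular **grid scans** (1–n parameters),
* **particle swarm** and **evolutionary programming** optimisers over
  objectives built from `var`, `cov`, `corr`, `cv`, `fano` and `mean`,
  with steady-state particle-number constraints (absolute or relative,
  e.g. "within 50%–200% of the original value"),

and validates LNA covariances against the **Gillespie Direct Method**
(time-weighted ergodic moments with batch-means errors).

Bundled fixtures: the open Michaelis–Menten mechanism, birth–death and
linear-chain networks (exact Poisson oracles), a closed cycle, the
Kholodenko ERK MAPK cascade (K_I = 45, V_cell = 10⁻¹⁴ l, so a stable
steady state exists at reference parameters), and a synthetic two-branch
cascade with a p38-like topology.

## Worked example

```python
from lnakit import erk_cascade, lna, scan, optimise, ParameterRange, ObjectiveSpec

erk = erk_cascade()                 # concentrations in nM, Ω ≈ 6.022 particles/nM
res = lna(erk)
print(res.variance("MKKK"), res.mean("MKKK"))
# 405.5 135.7   — var in particles², mean in particles, at reference V2 = 0.25

# How does MKKK noise depend on the phosphatase activity V2?
sc = scan(erk, "var(MKKK)", [ParameterRange("V2", 0.22, 0.41)], 39)
point, value = sc.argbest("maximise")
print(point, value)
# {'V2': 0.32} 987.5 — an interior local noise maximum

# Where is the MKKK / phospho-MKK covariance largest?
opt = optimise(erk, ObjectiveSpec("cov(MKKK, MKK_P)", "maximise"),
               [ParameterRange("V2", 0.22, 0.41), ParameterRange("k4", 0.015, 0.035)],
               algorithm="pso", seed=1, swarm_size=50, max_iter=40)
print(opt.best_value, opt.best_parameters)
# 4037.1 {'V2': 0.3217, 'k4': 0.0164}
```

The same tasks are available from the shell:

```console
$ lnakit lna michaelis-menten
        S       SE      P       E
S       22.4911 1.9802  0.186616        -1.9802
SE      1.9802  98.0198 -0.0933078      -98.0198
P       0.186616        -0.0933078      99.9067 0.0933078
E       -1.9802 -98.0198        0.0933078       98.0198
means   22.2222 100     100     900
```

Note the conservation structure: var(E) = var(SE) and the conserved
enzyme total E + SE does not fluctuate at all.  Subcommands:
`steady-state`, `lna`, `scan`, `optimise`, `ssa`, `validate`,
`fixtures`.

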