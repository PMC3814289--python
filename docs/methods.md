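# Methods

## Model class and conventions

`lnakit` analyses single-compartment networks of K̂ species and M
strictly irreversible reactions.  Reversible reactions must be split
first; `split_reversible` does this automatically when the rate law is a
syntactic difference `forward − backward` and refuses (with an
instruction to split manually) otherwise, because a net-rate expression
that is not separable does not determine the two propensities that the
stochastic description needs.

Densities and particle numbers are linked by a single scalar system size
Ω: n = Ω·x.  For models in molar units Ω = N_A · V · (unit factor); the
ERK cascade fixture (nM, V = 10⁻¹⁴ l) uses Ω = 10⁻⁹ · N_A · 10⁻¹⁴ ≈
6.022 particles per nM.  Propensities follow the density form
T_μ(n) = Ω f_μ(n/Ω) with no combinatorial n(n−1) correction for
bimolecular mass action; the discrepancy is O(1/Ω), below the accuracy
of the LNA itself, and keeps the deterministic and stochastic
descriptions exactly consistent at leading order.

Rate laws are restricted expression trees (numbers, species, parameters,
`+ − × ÷ ^`).  The restriction is deliberate: it makes every law exactly
differentiable (the drift Jacobian is computed symbolically, not by
finite differences, avoiding step-size pathologies near bifurcations)
and lets hot paths compile each law once into a plain function.  A
finite-difference cross-check of the analytic Jacobian is part of the
test suite.

## Conservation analysis

Conserved moieties are left null vectors of the stoichiometry matrix N.
They are found by greedy exact row reduction over rationals
(`fractions.Fraction`): species are scanned in declared order and
retained as independent while their row of N increases the rank; each
later (dependent) species j yields an exact relation
x_j = c_j + Σ_k α_jk x_k with rational α and integer null vector g
satisfying gᵀN = 0 in integer arithmetic.  Exactness matters: a relation
that held only to rounding error would leave a near-zero eigenvalue in
the reduced drift matrix and poison the Lyapunov solve.  The constants
c_j are evaluated from the model's initial densities and recomputed
whenever those change — they are state-derived totals (the β of the
enzyme moiety), not rate parameters.

The choice of dependent species is not unique; any valid choice yields
the same full covariance, which the suite asserts by permuting the
species declaration order.

## Steady state

The reduced deterministic system is solved by damped Newton from the
initial densities: steps are halved until all reconstructed densities
stay ≥ −10⁻¹² and the residual norm does not increase.  On failure the
ODEs are integrated (LSODA) over horizons 10², 10⁴, 10⁶ time units with
Newton restarted from each endpoint.  Convergence requires the maximum
drift component below 10⁻⁹ relative to the characteristic flux
magnitude.  A clean `SteadyStateError` is raised otherwise; inside the
closed loop this becomes an infeasible evaluation, never a crash.

Stability is classified from the eigenvalues of the reduced drift
Jacobian (stable ⇔ max Re λ < 0).  `find_instability_point` bisects a
parameter interval on the sign of max Re λ (default tolerance 10⁻⁴,
warm-starting each steady-state solve from the previous one) and the
caller can inspect the leading eigenvalue pair to distinguish a Hopf
(complex pair) from a real crossing.  Note the LNA covariance diverges
as the crossing is approached; results close to the critical value
should be read qualitatively.

## LNA computation

At a stable steady state, A = N_red · (∂f/∂x) · L (dependent densities
eliminated through the link matrix by the chain rule) and
B = N_red diag(f(x*)) N_redᵀ.  The stationary covariance solves
A C + C Aᵀ + Ω B = 0 via `scipy.linalg.solve_continuous_lyapunov`
(Bartels–Stewart/Schur).  Preconditions are enforced, not assumed: A
with max Re λ > −10⁻¹⁰·‖A‖ is rejected (no unique stationary
covariance), and the solution is symmetrised and checked against the
residual bound ‖AC + CAᵀ + ΩB‖_max < 10⁻⁹ ‖ΩB‖_max.  A brute-force
Kronecker-vectorised solve of the same equation is kept in the tests as
an independent oracle (O(K⁶), fine for K ≤ 6).  The full covariance is
C_full = L C_red Lᵀ, reported in particles² in the declared species
order; `LNAResult.Xi` carries the density-scale covariance C_red/Ω.

Exact structural consequences used as test oracles:

* open zero/first-order networks are product-form Poisson — C diagonal
  with var = mean (Fano 1), which the LNA reproduces exactly;
* conserved totals do not fluctuate: gᵀ C_full g = 0 for every moiety
  vector g;
* C scales linearly in Ω at fixed densities.

## Objectives and the closed loop

Objectives are arithmetic expressions over `var`, `cov`, `corr`, `cv`,
`fano` and `mean` of named species, evaluated on one LNA result per
candidate.  Constraints bound steady-state particle numbers, absolutely
or relative to the *original* model's steady state (captured once at
setup).  Infeasibility — no steady state, instability, violated
constraint, undefined statistic (e.g. CV at zero mean) — is encoded as a
∓∞ sentinel rather than a finite penalty, so optimisers rank any
feasible point above any infeasible one and no penalty magnitude needs
tuning.  Constraints are also the intended guard against the known
degenerate optima of CV/covariance minimisation, where the optimiser
drives copy numbers towards zero and the Gaussian assumption of the LNA
fails.

## Optimisers

* **Particle swarm** (global best): inertia 0.729, cognitive/social
  coefficients 1.49445 (the standard constriction values), velocities
  clamped to half the range, positions clipped to bounds; default swarm
  size 50.
* **Evolutionary programming** (meta-EP): per-parameter Gaussian
  mutation with log-normally self-adapted step sizes (initial 10% of the
  range, floor 10⁻⁸·range), survivor selection by stochastic tournament
  over the merged parent+offspring pool with q = 10% of the pool
  (minimum 2).

Both draw every random number from one `numpy` Generator seeded per run
(the seed is recorded in the result), terminate on an iteration budget
or on stall (best value improving by < 10⁻⁶ relative over 80
iterations), and report a monotone best-so-far trace plus counts of
feasible and infeasible evaluations.

## Stochastic simulation oracle

`gillespie_direct` implements the Direct Method exactly.  Stationary
moments are time-weighted averages over one long trajectory (ergodic
estimate) with a default burn-in of 10% of the horizon; comparisons
start the SSA from the rounded LNA steady-state particle numbers, which
is unbiased at stationarity and shortens the transient.  Standard errors
come from batch means over 20 equal-time blocks.  The inner loop is
compiled with numba when importable (the rate laws are code-generated
into a jittable propensity function); the pure-Python fallback produces
statistically equivalent, but not bitwise-identical, streams.

The LNA-vs-SSA validation runs on the Michaelis–Menten fixture at the
documented comparison parameter set k1 = 5, k2 = 2.5, k3 = 0.2, k4 = 5,
k5 = 4, β = 2, Ω = 100.  This set was chosen, before any agreement was
measured, by two a-priori criteria: every pairwise stationary
correlation non-negligible (|ρ| ≳ 0.12, so every covariance entry is
estimable to ~1% from a run of practical length — at the fixture's
plain defaults some correlations are O(10⁻³) and no feasible run could
resolve them), and means of 100–210 particles (well inside the LNA's
validity regime).  The default horizon t_end = 2·10⁵ time units
(≈ 4·10⁸ reaction events, about a minute with the compiled kernel)
brings every entry's batch-means SE below 1% and the observed
LNA-vs-SSA deviation to ~1.3%.

## Fixture choices

The ERK cascade fixture is a programmatic transcription of the
Kholodenko (2000) ultrasensitive MAPK cascade — 8 species in three
phosphorylation tiers, 10 saturating (de)phosphorylation reactions,
negative feedback of the output on the first step — with the feedback
constant weakened to K_I = 45 and V_cell = 10⁻¹⁴ l so that the reference
parameters sit in the stable-steady-state regime rather than the limit
cycle.  Its three tier totals give Λ = 3, K = 5.

The two-branch cascade is *synthetic*: it emulates the p38-pathway
feature of two parallel kinase branches converging on one downstream
kinase, for exercising correlation and CV workflows under relative
constraints.  It reproduces no published model's numbers.

## Problem sizes and defaults used in the shipped checks

Grid scans use 39 points (1D, step 0.005) and 40×40 (2D); PSO runs use
swarm 50 × 40 iterations (≈2000 closed-loop evaluations, a few seconds
each thousand); the Lyapunov oracle uses 50 random stable systems of
dimension ≤ 6; SSA validations use t_end = 2·10⁵ with 20 batches.

## Limitations

* Stationary fluctuations only: no time-dependent Ξ(t), no two-time
  correlations, no terms beyond LNA order.  Near instabilities and near
  zero-copy-number boundaries the Gaussian approximation degrades.
* Single compartment; no events, rules, delays or time-varying
  parameters.  The SBML importer covers the matching subset only and
  rejects everything else explicitly.
* Passing the SSA validation on the fixtures shows the pipeline is
  correct for the model classes exercised (mass action and saturating
  kinetics at moderate copy numbers); it does not certify LNA accuracy
  for arbitrary models — that is a property of the approximation, not of
  the implementation.
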