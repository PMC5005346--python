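# Methods

## Model

The package analyses a reduced, protein-only model of autoregulated gene
expression. Promoter and mRNA dynamics are eliminated by time-scale
separation, leaving two reaction channels for the protein copy number n:

* **burst production**: with propensity f(n)/μ\*, a single event adds
  μ ∈ {1, 2, …} molecules, μ geometrically distributed with mean μ\*
  (pmf g(μ) = (1/μ\*)(1 − 1/μ\*)^{μ−1}; μ\* = 1 degenerates to single-molecule
  production);
* **degradation**: first order, propensity δn.

f is a smooth, nondecreasing production function (constant, linear,
Michaelis–Menten b + v·n/(n+K), Hill b + v·nʰ/(nʰ+K) with h > 1, or a custom
callable) evaluated at the integer copy number in all stochastic
computations and at the real-valued state in deterministic ones. Dividing
the burst frequency by μ\* keeps the mean production flux equal to f(n)
whatever the burst size, so distributions for different μ\* are directly
comparable. The cell volume V is fixed (no growth dilution); concentrations
are always derived as n/V and never stored separately.

The deterministic description is the molecule-scale ODE ṅ = f(n) − δn
(multiplying the concentration ODE by V), so ODE fixed points and CME modes
live on the same axis. The burst size cancels from the ODE entirely — a
first indication that deterministic analysis can miss burst-driven effects.

### Exact identities used throughout

* stationary recursion: (n+1)p_{n+1} = [f(n)/(δμ\*) + n(μ\*−1)/μ\*] p_n;
* moment balances (exact for the burst CME, derivable from its first two
  moment equations): E[N] = E[f(N)]/δ and
  σ² = μ\*E[N] + Cov(N, f(N))/δ in steady state, hence Fano factor = μ\*
  for constant f;
* mode condition: the PMF rises at n iff d(n) = f(n)/δ − (n+μ\*) ≥ 0;
  extrema satisfy n = ⌈f(n)/δ − μ\*⌉;
* per-step relative slope (local precision): (p_{n+1}−p_n)/p_n =
  d(n)/(μ\*(n+1)) — peaks are sharp where |d| is large and μ\* is small.

The transient variance equation
dσ²/dt = 2Cov(N,f(N)) − (E[f]−δE[N]) + 2μ\*E[f] − 2δσ² was re-derived from
the generator (the geometric second moment is 2μ\*²−μ\*) and is verified
numerically against transient solutions in the test suite.

## Numerics

**Stationary PMF.** The recursion is carried in log space (weights span
hundreds of orders of magnitude for large f/δ). Support grows until (a) the
discrepancy d(n) is negative, i.e. past every mode candidate, and (b) a
certified geometric tail bound p_n·r̄/(1−r̄) < `tail_tol` (default 1e−12)
holds, with r̄ an upper bound on all remaining recursion ratios
(r̄ = (μ\*−1)/μ\* + sup f/(δμ\*(n+1)) for bounded variants; the analogous
slope-corrected bound for linear f; the current ratio, assumed
nonincreasing, for custom callables — custom users should supply bounded,
eventually saturating f). Exceeding `n_cap` raises with an estimate of the
required cap. f(0) = 0 short-circuits to a point mass at 0 (extinction is
absorbing).

**Extrema.** Both the PMF scan and the analytic predictor reduce to the same
plateau-aware sign-scan of step differences; adjacent values equal within
relative 1e−12 merge into plateaus reported as (n_lo, n_hi) (exact ties
occur whenever d(n) = 0 at integer n, e.g. Poisson with integer mean).
n = 0 is a maximum iff p₀ > p₁ strictly; a tie joins the plateau. The final,
monotonically decaying truncation tail is never reported as an extremum.
For regime classification, maxima whose peak probability falls below 1e−6
of the global maximum are ignored — they are either floating-point phantoms
or basins carrying physically negligible weight.

**Fixed points.** Sign-change bracketing of f(n) − δn on a 2048-point grid
over [0, 1.5·sup f/δ + 10], one 64-fold refinement pass per cell to separate
close sigmoid roots, Brent polishing to 1e−10. Stability from f′(n\*) < δ
with analytic derivatives (symbolically generated for Hill);
|f′−δ| < 1e−9·δ is flagged "marginal" rather than labelled.

**Transient CME.** Finite-state truncation on 0..n_cap with an explicit
overflow account: bursts past the cap flow into a tracked leak state, so
total probability is conserved at the generator level and the leak is
reported (raising above `leak_tol`). Integration by BDF (the burst
convolution makes the generator stiff for large δ·n_cap), rtol 1e−8,
atol 1e−12. The independent stationary oracle solves the null space of the
conservative truncated generator directly.

**Moment-equation residuals** evaluate dE[N]/dt and dσ²/dt through the
generator action ṗ = Gp at each snapshot (no finite differencing in time)
and compare with the moment ODEs; relative residuals are ~1e−12 for
adequate caps.

**SSA.** Ensembles and SSA first-passage times use a vectorized direct
method: all trajectories advance one event per pass under a shared active
mask, with geometric burst sizes drawn by inverse CDF
(μ = 1 + ⌊ln u / ln(1−1/μ\*)⌋). Identical seeds give identical histograms.
The generic multi-species network simulator is a plain direct-method loop.

**MFPT.** Exact values solve the linear hitting-time system of the
truncated chain (cap = stationary support + 40μ\*; bursts overshooting the
cap are redirected to it, negligible that deep in the tail). Basins of a
bimodal PMF are operationalized as: start at a mode, target first crossing
of the interior antimode — interval targets ("ge"/"le" a threshold), since
bursts can overshoot any single state.

## Presets and what they do (and do not) show

Four feedback families × burst sizes μ\* ∈ {1, 6, 11} (no burst / medium /
strong) serve as canonical study conditions:

| preset | f | parameters (δ = 1, V = 1) |
|---|---|---|
| `no_feedback` | constant | b = 20 |
| `noncoop` | Michaelis–Menten | b = 1, v = 40, K = 10 |
| `coop_bistable` | Hill | b = 3, v = 40, half-sat 20, h = 4 |
| `coop_monostable_bimodal` | Hill | b = 8, v = 30, half-sat 15, h = 4 |

Parameters were placed directly on the graphical construction (where f/δ
crosses the identity line and the shifted lines n + μ\*) so that the
collection realizes all four {mono,bi}stable × {uni,bi}modal quadrants,
including both disagreement regimes: `coop_bistable` is bistable-bimodal
without bursts, loses its upper mode under strong bursts
(bistable-unimodal), while `noncoop` at μ\* = 6 and
`coop_monostable_bimodal` at μ\* = 6 are monostable-bimodal — the latter
with both modes at positive copy numbers, which requires cooperativity.
Every preset is re-certified by `classify_regime` at generation and test
time. These are synthetic parameter sets chosen for their qualitative
regime structure, not fits to any measured gene; passing tests demonstrate
the mathematical relations between the two descriptions, not biological
accuracy of any particular parameterization.

## Choices where the design was open

* **Mixing horizons.** Ensemble/transient stationarity defaults to
  t_f = 40/δ with a cross-initial-condition TV check. For *bimodal* systems
  started from a point mass this is insufficient on principle: the CME
  relaxes on the basin-switching timescale (spectral gap ≈ 1/τ_up + 1/τ_down;
  ≈ 6/δ for `noncoop` at μ\* = 6), so bimodal convergence tests use 200/δ.
* **Scaling bound.** Enlarging the system s-fold (volume sV, production
  s·f(n/s)) leaves fixed-point concentrations invariant while mode
  concentrations converge to them. The ceiling argument bounds the
  deviation by (μ\*+1)/(sV) when f′ ≤ 0 at the crossing (constant f,
  saturated feedback); at a crossing with slope the deviation carries an
  extra factor 1/(1 − f′/δ). The strict bound is therefore asserted for
  constant production, and the scaling experiment on sloped feedback checks
  the ~1/s contraction and mode/fixed-point agreement instead.
* **Sharpness comparisons.** In the cooperative-vs-non-cooperative matched
  scenario the basin *weights* differ between the systems, so raw peak
  heights are not comparable; sharpness is compared via peak probability
  conditional on the basin (equivalently, the pointwise discrepancy
  ordering), which the cooperative system wins in both basins.
* **Burst size μ\*** may be any real ≥ 1 (success probability 1/μ\*); the
  presets use the integer study values.
* **Hill parameterization** stores K in molecules^h (the literal n^h/(n^h+K)
  form); the `FeedbackFunction.hill` constructor accepts a half-saturation
  point in molecules and converts.

## Limitations

* One species only; the general reaction-network machinery (mass action,
  propensities, SSA) supports multiple species, but the CME recursion,
  mode analysis and scenarios are specific to the burst-death scheme.
* The moment-equation machinery is exercised on the one-species burst model;
  multi-species moment equations are not implemented.
* No tau-leaping/Langevin/hybrid approximations, no time-varying volume,
  no bifurcation continuation.
* Custom feedback callables bypass the certified tail bound (heuristic
  truncation) and use finite-difference derivatives.
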