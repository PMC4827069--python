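# Methods

## Model and assumptions

`actsim` implements a stochastic individual-based model of tumour–immune
coevolution on a finite trait space: cancer cells carrying a (genotype,
phenotype) pair, T-cell types, and cytokine species.  All interactions are
well-mixed (no spatial structure) and rates are *effective* parameters — the
T-cell death rate, for instance, absorbs exhaustion as well as natural
death.  The population is a continuous-time Markov jump process on integer
counts; dividing counts by the carrying capacity `K` gives scaled densities.
`K` controls the order of magnitude of populations and therefore the
amplitude of relative fluctuations; every qualitatively stochastic
phenomenon in the package (extinction during remission, metastable outcome
switching, mutation timing) depends on `K` through this route.

Two features distinguish the process from a standard logistic/Lotka–Volterra
birth–death model:

1. **Birth-reducing competition** `c_b`: competitive pressure first lowers
   the birth rate, `max(0, b(p) − Σ c_b(p,p′) ν(p′))`; pressure in excess of
   the birth rate converts into additional death.  Because mutation happens
   at birth, the realized birth *flux* — not the population size — controls
   the supply of mutants, which is what makes the mutation-timing analysis
   (below) non-trivial.
2. **Phenotypic switching** `s(p,p′) + Σ_w s^w(p,p′) ν(w)`: a reversible,
   genotype-preserving change of phenotype, with a cytokine-density-dependent
   component (inflammation-induced dedifferentiation).  Switching couples the
   fates of phenotypes within a genotype without any birth event.

Therapy kills (`t_kill`) and T-cell divisions release deterministic integer
bursts of cytokines; cytokines decay linearly.

## Stochastic engine

Simulation is an exact Gillespie algorithm: after every event all channels
are rebuilt (trait spaces here have ≤ ~10 traits, so the quadratic rebuild
is cheap and exactness is kept), the waiting time is exponential in the
total rate, and the channel is selected by a cumulative scan in canonical
trait order, which fixes floating-point tie-breaking.  Mutations are
resolved inside the birth event (Bernoulli(μ_g), then the mutation law)
rather than as separate channels — fewer channels, identical law.
Competition and therapy sums exclude the focal individual's own `1/K`
contribution; the difference is O(1/K) but a convention must be fixed for
exact small-population tests.

Two engines implement the same law: a pure-Python reference engine built
from the public `build_channels` / `draw_event` / `apply_event` operations
(transparent, can log every event) and a numba-compiled kernel used for
ensembles.  They consume independent random streams and are cross-checked
statistically (extinction probabilities, waiting-time moments), not
sample-by-sample.  Within an engine, a seed fixes the trajectory exactly;
replicate *i* of an ensemble uses `base_seed + i`.

## Deterministic limit

As K → ∞ the scaled process converges to a quadratic ODE system (logistic +
predator–prey + switching; the birth-rate floor makes the field piecewise
quadratic).  Rare mutations (μ_K → 0) vanish in the limit, so fixed-point
analysis is done with mutation off; the mutation term can be switched on for
finite-μ work.  Integration uses LSODA with `rtol 1e-8 / atol 1e-10` and
clips solver-scale negative values.  Fixed points are located per support
pattern: every subset of traits is pinned to zero, the restricted system is
relaxed along its own flow and polished by Newton, and a candidate is kept
only if the *full* field vanishes (residual < 1e-9) and the point is
non-negative.  Duplicates are merged below 1e-6.  Stability comes from the
spectrum of a central-difference Jacobian (step scaled to density, one-sided
at the zero boundary); a maximal real part within 1e-8 of zero is reported
as `marginal`, never silently stable, and a point sitting exactly on a
birth-rate floor boundary is flagged marginal because the field is
non-smooth there.  Each point also carries the spectrum restricted to its
support's invariant subspace — the quantity that explains metastability:
a point unstable in the full space but stable inside a subspace becomes the
attractor once the stochastic system has hit that subspace by extinction of
a population.

## Invasion fitness of a phenotype-structured mutant

A rare mutant genotype with k phenotypes against a resident equilibrium x̄
is approximated, until it dies out or reaches size εK, by a multi-type
branching process whose mean matrix A has diagonal entries
`(1−μ)·B_eff(p_i) − D_tot(p_i) − Σ_j s(p_i→p_j)` (net per-phenotype growth at
x̄ minus outgoing switches) and off-diagonal `A_ij = s(p_j→p_i)` (column =
parent).  The clone's mean counts obey dn/dt = A n; it is supercritical iff
the leading eigenvalue λ₁ > 0, and the normalized right Perron eigenvector v
is the composition of a surviving clone.  Orientation (right eigenvector,
columns-as-parents) is this package's documented convention.  Irreducibility
is checked as strong connectivity of the positive off-diagonal graph; for
reducible switch structures v is still reported but flagged.  The
Monte-Carlo companion simulates the resident-frozen linear process — the
object the theory actually classifies — via its embedded jump chain (hitting
probabilities do not depend on waiting times).  In tests it is validated
against the extinction probability computed independently from the offspring
generating-function fixed point.

## Mutation timing under birth-reducing competition

For a single type with pure BRC the total mutation rate is
`μ n (b − c_b n/K)` — a parabola in n peaking at `n* = bK/(2 c_b)`, while
the population equilibrates at `n̄ = (b−d)K/(c+c_b)`.  The package reports
the landmarks and the flag `n̄ > n*`, which for c = 0 is exactly `d < b/2`:
the regime where a population *regrowing* after a therapy-like reduction
passes through the rate peak and accumulates mutants faster than the larger
equilibrium population.  The paired SSA experiment
(`brc_mutation_experiment`) measures cumulative mutation events in
matched-duration windows, one arm starting at 0.3 K (regrowth), one at n̄.
With the fixture's b = 2, d = 0.5, c_b = 1, K = 10³, μ = 5·10⁻³ the designed
separation is ≈ 13 vs ≈ 11 events per 3-day window, ~5 standard errors apart
at 150 replicates.  The mutation probability in the fixture (0.5% of
births) is chosen large enough to measure the effect at desk scale; the
landmarks themselves are μ-free.

## Built-in scenarios and what they emulate

All fixture parameter sets are **synthetic**: the quantitative values behind
the motivating experiments are not available to this package, so each regime
was designed from the qualitative structure it must exhibit and, for the
calibrated regime, tuned once against the published timing read-outs.  They
are illustrative regimes, not biological estimates.

**Qualitative one-/two-specificity regimes** (`one_tcell_qualitative`,
`two_tcell_qualitative`, K = 200).  Symmetric melanoma phenotypes (b = 3,
d = 1, cross-competition weaker than self), predator–prey T-cells (prey-
dependent division), TNF-driven x→y switching.  Designed so that the
one-specificity system has exactly the canonical three fixed points — origin
(unstable), tumour-only (stable only in the no-T-cell subspace), interior
(the only fully stable point, with a low differentiated-tumour level) — and
so the deterministic T-cell minimum during remission is ~6 individuals at
K = 200: deep enough that both endings (T-cell survival → controlled tumour;
extinction → relapse) occur across seeds.  Adding the second T-cell type
yields the two further fixed points and makes the former interior point
unstable in the enlarged space; cure becomes reachable.  At K = 10⁴ the same
minimum is ~300 individuals and extinction essentially disappears — the
fluctuation-amplitude role of K.

**Calibrated therapy regime** (`fig4_calibrated`).  Tuned to the published
timing read-outs: tumour initiation at day 0, treatment at day 30, tumour
microscopic (< 1% of pre-treatment count) for ~45–50 days, differentiated
relapse back at original size ≈ day 90, dedifferentiated relapse ≈ day 190.
Design choices, made so the stochastic dichotomy survives the desk-scale
carrying capacity (K = 10³, 50 replicates, minutes of CPU):

- The injected T-cells are a *fixed-size bolus* (95 cells) of effector cells
  with balanced division and death (`b_T = d_T`, no prey-driven expansion;
  exhaustion dominates re-stimulation, which the model omits).  The bolus's
  critical birth–death fluctuation makes its extinction time a broad
  stochastic clock that does not scale with K, and this clock is the
  dichotomy: early firing frees the differentiated clone (relapse ~day 90),
  late firing lets the slow dedifferentiated clone win (~day 190).
- The kill and induced-switch kernels carry a 1/K pair-rate normalization
  (`t_kill = 1.42e-2 · K`, `s^w = 7.3e-2 / K`), so a fixed-size bolus exerts
  a K-independent pressure and the timing structure is invariant under K.
- Melanoma: fast differentiated clone (b = 0.75, d = 0.20; doubling ~1.7 d),
  slow quiescent dedifferentiated clone (b = 0.08, d = 0.004), natural
  reversion y→x at 0.01/day.  The reversion matters: after the crash the
  differentiated population is typically annihilated at K = 10³, and a
  differentiated relapse is re-founded from the dedifferentiated reservoir —
  switching is reversible, so the phenotype, not the lineage, relapses.
- At K = 10³ the dedifferentiated clone is founded by only ~2–4 induced
  switch events, so ~10% of replicates lose it entirely and end in cure, and
  the remission median (~45 d) sits slightly below the 50–60 d target; both
  are discreteness artifacts of the scaled-down carrying capacity (founder
  numbers grow ∝ K).
- `fig4_two_tcell` adds a second bolus targeting the dedifferentiated
  phenotype; the switch-seeded reservoir is then killed as it appears and
  cure becomes the modal outcome (~0.8 of runs at K = 10³) — the package's
  version of the predicted two-specificity therapy.

**Mutant invasion regime** (`mutant_invasion_fig6`).  Single-phenotype
resident at density 2.0; two-phenotype mutant with asymmetric switching
(0.3 / 0.7 per day) whose mean-matrix diagonal entries are −0.2 and −0.4 —
each phenotype declines on its own, yet λ₁ = 0.169 > 0.

**BRC mutation regime** (`brc_mutation_fig7`).  Pure birth-reducing
competition (c = 0) with d < b/2, plus a fitter mutant genotype as the
mutation target.

## What the synthetic regimes do and do not show

Passing tests on these regimes demonstrates that the *mechanisms* — floor
competition, induced switching, metastable outcome selection, the λ₁/v
calculus, the mutation-rate parabola — are implemented correctly and produce
the designed phenomenology at the stated scales.  They do not validate any
biological rate constant, do not resolve spatial structure or additional
immune compartments, and the scaled-down carrying capacities exaggerate
founder-number noise (cure rates, remission spread) relative to realistic
population sizes.

## Numerical choices

- Time unit: days.  Densities: counts / K (dimensionless).
- SSA: full channel rebuild per event; no tau-leaping or other approximate
  acceleration; event cap and horizon as stop rules; per-replicate seeds
  below 2³¹.
- ODE: LSODA, rtol 1e-8, atol 1e-10; fixed-point residual 1e-9, dedup 1e-6,
  stability tolerance 1e-8.
- Eigenproblems: dense solvers on k ≤ ~6 matrices; λ₁ is the
  maximal-real-part eigenvalue and must have |Im| < 1e-10 (essential
  non-negativity), otherwise an error is raised rather than silently
  projected.
- Outcome thresholds: remission = total tumour below 1% of the pre-treatment
  count, relapse = regaining 90% of it, subtype by majority phenotype at the
  crossing record; both fractions are configuration keys.  Classification is
  state-based, so it is invariant under record thinning up to one recording
  interval.
- Float serialization in CLI outputs: 12 significant digits,
  locale-independent.

## Known limitations

- No spatial structure, no explicit re-stimulation events, only the declared
  immune compartments; rates are effective, not mechanistic.
- The deterministic engine classifies marginal spectra conservatively and
  performs no bifurcation continuation.
- The resident-frozen Monte-Carlo oracle ignores resident feedback during
  invasion; the full-feedback simulation is available through the SSA but is
  not the object the branching-process theory classifies.
- Post-invasion attractor selection with multiple basins is exposed only as
  deterministic continuation from user-chosen initial conditions; no basin
  probabilities are computed.
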