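# Methods

## Model and assumptions

The package implements a planar autonomous ODE model of tumor–immune
interaction with an early-detection removal term.  In dimensional form,
tumor cells `C` grow logistically with rate `a1` toward carrying capacity
`a2`, are killed by lymphocytes `L` at a rate saturating in `L`
(`a3 C L/(a4 + L)`), and are removed by detection at a rate saturating in
`C` (`K C/(a + α_aw·C̃·C)`, with maximum effect `K`, baseline constant `a`,
detection threshold `C̃` and awareness parameter `α_aw`).  Lymphocytes
proliferate logistically toward `a6` at a rate gated by tumor presence
(`C/(a7 + C)`), die from tumor contact (`a8 C L`) and by apoptosis
(`a9 L`).  The model assumes a single, well-mixed immune compartment, no
time delays, no stochasticity and no explicit treatment dynamics: early
detection acts as a continuous removal flux, a deliberately coarse summary
of screening-and-treatment programmes.

All analyses run on the dimensionless form (`x = C/a2`, `y = L/a6`,
`τ = a1 t`):

    dx/dτ = x(1 − x) − β x y/(γ + y) − κ x/(α + δ x)
    dy/dτ = ρ y(1 − y) x/(μ + x) − σ x y − η y

Dimensional inputs are converted at the boundary and never used
internally.  Two conversion maps are exposed behind a `mode` flag, because
the conventional substitution list for this model family is not
dimensionally self-consistent: `mode="paper"` applies the printed formulas
(`β = a3 a6/(a1 a2)`, `κ = K/a1`), which carry residual units under the
stated change of variables, while `mode="derived"` applies the consistent
re-derivation (`β = a3/a1`, `κ = K/(a1 a2)`).  The two modes differ only
in β and κ; the default is `mode="paper"` for fidelity to the conventional
parameterization.  The overloaded symbol α is kept as two distinct fields:
the dimensional awareness parameter `alpha_aw` and the dimensionless group
`alpha = a/a2` are never aliased.

Note a direction-of-effect trap built into the formulas: both `alpha` and
`delta = alpha_aw·C̃` sit in the detection *denominator*, so increasing
either weakens detection and raises the tumor burden.  Narratives that
read "more awareness" as tumor-reducing implicitly mean *smaller* α or δ.
The sensitivity stage emits a structured warning about this whenever the
computed α index is positive.

## Default parameters

| symbol | default | meaning |
|--------|---------|---------|
| β | 0.5 | immune kill rate of tumor cells |
| γ | 0.1 | kill half-saturation |
| κ | 3.0 | maximum detection-driven removal |
| α | 0.65 | baseline detection constant |
| δ | 1.0 | awareness × detection-threshold product |
| ρ | 1.0 | immune proliferation rate |
| μ | 0.1 | activation half-saturation |
| σ | 0.3 | tumor-induced immune death |
| η | 0.1 | immune apoptosis rate |

Default initial conditions `(x0, y0) = (0.35, 0.08)` and horizon
`τ ∈ [0, 50]` ship as a packaged JSON fixture; a second fixture holds the
four-trajectory bundle of initial conditions used in phase portraits
((0.3, 0.6), (0.2, 0.8), (0.25, 0.5), (0.1, 0.9)).  All rates admit zero
— `κ = 0` is the canonical "no early detection" comparison — except γ, α
and μ, which appear in denominators and must stay positive.  Two benchmark
regimes recur throughout the tests: the strong-detection default above
(tumor eradicated) and the *persistent-tumor benchmark* `κ = 0.3`, in
which the tumor survives and every quantity normalized by `x(T)` is
well-conditioned.

## Numerical choices

**Integration.**  Adaptive explicit Runge–Kutta (RK45) with `rel_tol =
1e-9`, `abs_tol = 1e-12`, and an automatic LSODA fallback on failure.  The
absolute tolerance sits three decades below the theorem-check slack
`ε_num = 1e-9`: with `abs_tol = 1e-9` the solver's noise floor near the
origin is the same size as the slack, and long eradication runs produce
spurious "negativity" of order `−1e-9`.  Output is an evenly spaced grid
(501 points by default) independent of internal steps.  States are never
clamped during integration; a violation of positivity or of the bounds
`x ≤ max(1, x0)`, `y ≤ max(1, y0)` beyond `ε_num` is reported as a check
failure, because exact solutions provably satisfy both (each equation is
dominated by a logistic one).

**Equilibria.**  The immune nullcline gives
`y*(x) = 1 − (μ + x)(σx + η)/(ρx)`; substituting into the tumor
equilibrium equation leaves a scalar root problem `g(x) = 0` on `(0, 1]`.
Roots are located by a 2,000-point sign scan restricted to the admissible
region `0 < y*(x) < 1`, refined by bisection to `|g| < 1e-12`.  Intervals
in which the admissibility region begins or ends are rescanned on a
257-point subgrid, since a root can hide between the admissibility
boundary and the nearest coarse grid point.  Admissible equilibria require
`0 < x* ≤ 1` and `0 < y* < 1` (populations are fractions of carrying
capacity).  Eigenvalue real parts within `1e-12` of zero are classified
"indeterminate", never "stable" — linearization is inconclusive there.

**Long-run summaries.**  Sweeps and basins summarize each run by the
terminal state of a `τ = 200` integration (not a tail average), and label
an outcome "controlled" when the terminal tumor burden falls below
`1e-3`.  On fixed-point attractors this separates eradication from
persistence by several orders of magnitude.  Near the detection threshold
it does not — see *Findings* below.

**Sensitivity.**  The normalized forward index is
`S_p = (p/x(T)) ∂x(T)/∂p`, computed by integrating the 20-dimensional
forward sensitivity system (state + 18 partials) with the analytic
Jacobian and analytic parameter-partials; a central-finite-difference
route (relative step `1e-4`) serves as an independent cross-check and the
two agree to better than `1e-3` relative on the benchmark.  The default
horizon is `T = 10`.  The index is an elasticity and degenerates when
`x(T)` underflows, which the strong-detection default reaches before
`T = 9`; horizons with `x(T) < 1e-12` are rejected with an explicit error
rather than silently normalized.  (The full pipeline therefore runs its
sensitivity stage at `T = 5` by default.)  Zero-valued parameters have
index exactly 0 by the normalization.

**Fitting.**  Bounded nonlinear least squares (`scipy.optimize`
trust-region reflective) on the residual between the simulated tumor
trajectory and the observations, with five multiplicative-jitter restarts
(factor 0.7–1.3) to guard against the mild multimodality introduced by
the two saturating terms; the best minimum is kept, and non-convergence is
reported as a flag, never an exception.

**Seeds.**  Every stochastic stage takes one integer seed; the pipeline
splits a single top-level seed into per-stage child seeds via
`numpy.random.SeedSequence`.  Reruns with equal seeds are bit-identical.

## The synthetic-data generator

No deposited tumor-burden measurements exist for this model, so the
calibration stage is exercised on synthetic data: the tumor component is
observed at 51 evenly spaced times on `τ ∈ [0, 25]` with additive Gaussian
noise of standard deviation 0.02, clipped at zero; the immune level is
latent.  The generating regime is the persistent-tumor benchmark — under
strong detection the tumor collapses within a few time units and the data
carry almost no information about most parameters.  These defaults are
declared stand-ins for realistic screening data, not reconstructions of
any particular dataset.  What the generator does *not* emulate:
measurement error that scales with tumor size, irregular visit schedules,
censoring, between-patient heterogeneity, or model misspecification.
Passing recovery tests therefore demonstrate that the estimator is
correct and well-behaved under the model's own assumptions, not that the
model is identifiable from clinical data.

## Findings the analyses surface

These behaviours are computed by the test suite and worth knowing before
interpreting output; each is asserted by a dedicated test.

* **The two global-stability inequalities are not sufficient.**  The
  linear Lyapunov candidate `V = x + y` yields the classical conditions
  `κ > α` and `ρμ < βγ + σ` for global stability of the tumor-free state,
  but bounding the saturating losses from below requires the *largest*
  denominators, not the smallest, so the textbook derivation does not go
  through.  A concrete bistable counterexample satisfies both inequalities
  yet keeps a locally stable coexistence state at (0.848, 0.812):
  (β, γ, κ, δ, α, ρ, μ, σ, η) = (0.05, 0.3, 0.5, 5.0, 0.1, 2.0, 0.05,
  0.3, 0.1).  In random condition-satisfying regimes roughly one draw in
  ten fails to reach the origin.  The stability stage warns whenever the
  conditions hold but an admissible interior equilibrium exists; descent
  of `V` should always be confirmed numerically in unfamiliar regimes.
  In the default regime descent does hold from every tested start.

* **A limit-cycle window below the detection threshold.**  Just below
  `κ = α` (roughly `κ ∈ (0.43, 0.65)` at the other defaults) no admissible
  interior equilibrium exists while the tumor-free state is unstable, so
  trajectories approach a periodic orbit whose tumor minima dip below
  `1e-4`.  Terminal-snapshot summaries there are phase-dependent: sweep
  branches look ragged, the controlled/persistent classifier can flicker
  within two grid steps of the analytic threshold, and a snapshot at one
  instant can sit orders of magnitude below the cycle's mean.  Planar
  autonomous dynamics permit exactly this (and no more: chaos is ruled
  out).

* **Detection strength is not always the top-ranked lever.**  On the
  persistent-tumor benchmark the immune kill rate β carries a larger
  tumor-reducing elasticity than κ at every horizon beyond the initial
  transient (−1.80 versus −1.35 at `T = 10`).  κ's dominance emerges only
  in strong-detection regimes, where the elasticity degenerates to the
  collapse-rate form `S_κ ≈ −κT/α` while `x(T)` underflows — a regime the
  package rejects as degenerate rather than reporting.

* **κ and α are jointly near-unidentifiable from tumor-only data.**  Over
  the tumor range the benchmark trajectory visits, the detection term is
  approximately `κ/(α + const)`, so the two parameters trade off almost
  perfectly: the linearized sampling correlation of their estimators is
  0.999 at 2% noise, with standard deviations of 17% (κ) and 24% (α).
  Single-parameter fits are precise (well under 5% error at 2% noise);
  joint (κ, α) fits are reliable only along their identified combination.

## Known limitations

One immune compartment; no delays, stochasticity, spatial structure or
treatment scheduling; local (not global) sensitivity analysis; coexistence
stability assessed numerically through the Jacobian because closed forms
are intractable; fitting assumes the generator's own noise model.  The
limit-cycle window is characterized empirically, not by continuation — no
Hopf/fold detection machinery is included.
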