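# Methods

## Model

A reactor of volume V holds M species with molecular populations large
enough to treat concentrations c_μ as continuous (molecular noise is
neglected).  N reactions fire stochastically; ξ^μ_i denotes the signed
molecularity of species μ in reaction i (substrates negative in the forward
direction).  Boundary exchange enters as per-species rates u^μ (positive =
intake), so the instantaneous imbalance of species μ at fluxes ν is
r_μ(ν) = Σ_i ξ^μ_i ν_i + u^μ.

Over windows short enough that chemical potentials are roughly constant
(concentrations frozen at their steady values c̄_μ), stationary fluxes
minimize

    H(ν) = Σ_μ r_μ(ν)² / c̄_μ = νᵀJν + 2hᵀν + Σ_μ (u^μ)²/c̄_μ ,

with Hebbian couplings J_ij = Σ_μ ξ^μ_i ξ^μ_j / c̄_μ and fields
h_i = Σ_μ ξ^μ_i u^μ / c̄_μ.  J is a Gram matrix, so H is convex and
non-negative; H = 0 is exactly strict mass balance.  We fix the global
prefactor of H to 1: every quantity of interest (minimizers, transition
location, feasibility, sign of entropy-production decay) is invariant under
a positive rescaling of H, and this convention makes the quadratic form
equal the residual form exactly (the constant term Σ(u)²/c̄ is therefore
included).

Scarce intermediates strengthen the couplings (1/c̄ weighting): a species
produced by one reaction and consumed by another yields J_ij < 0, which in
the dynamics below correlates the two fluxes positively; two producers (or
two consumers) of the same species anti-correlate — competition for a
shared resource.

## Stochastic dynamics

Each reaction carries an accumulator y_i; one time step consists of

1. sampling a microscopic direction m_i ∈ {−1, +1} with
   P(m_i = +1) = (1 + tanh y_i)/2, independently per reaction;
2. the gradient move y_i ← y_i − η·ρ·(Σ_j J_ij m_j + h_i).

The log-probability ratio 2y_i tracks the ratio of substrate to product
concentrations, which identifies ΔG_i = −2RT·y_i; the bookkeeping
c_μ ← c_μ + Δt_eff (Σ_i ξ^μ_i m_i + u^μ) with Δt_eff = 2ηρ reproduces the
accumulator evolution exactly to linear order (verified as a test).  The
rescale factor defaults to ρ = 1/M so the drift stays O(1) for large
networks; the learning rate defaults to η = 1.  A mean-field variant
(m = tanh y, deterministic) serves as the test oracle; the sampled variant
is the default.  Accumulators are clipped at |y| = 500 purely as an overflow
guard — tanh is saturated to machine precision near |y| ≈ 19, so the clip
cannot affect the sampled dynamics.

Time-averaged fluxes are estimated from the post-burn-in mean of m (burn-in
defaults to the first half of the run) divided by V·Δt; 256 geometrically
spaced checkpoints record y, the running mean of m, and H evaluated on the
running flux average (checkpoint schedules shorter than the requested count
fall back to every step).

**Classification.**  A reaction is labelled unidirectional when either (a)
its accumulator drifts: |y(T) − y(T/2)|/(T/2) > 10⁻² in rescaled units, or
(b) its sampling is saturated: fewer than ~5 reverse transitions observed
over the post-burn-in window (|m̄| ≥ 1 − 10/(T − burn-in)).  Criterion (b)
is needed because in the balanced phase the gradient vanishes on the H = 0
manifold, so a polarized initial condition can park an accumulator at a
large but finite y: no drift, yet microscopically one-directional.  With
drift-only classification the ergodicity gap would be invisible by
construction.  Direction is the drift sign, or the sign of the final y for
saturated reactions.

## Random ensembles and the phase transition

The standard ensemble draws ξ^μ_i = ±1 with probability p/2 each (0
otherwise; all-zero reactions are redrawn), c̄ = 1, q_max = 1, and marks
each species as a boundary species with probability q, assigning it a
uniform intake u = b0.  Uniform b0 only scales H in the driven phase and
does not move the transition.  Reference study conditions, used by the test
suite and the acceptance script: M = 50, p = 0.25, q = 0.5, b0 = 1,
T = 2·10⁴ steps, 20 realizations per phase point, 11 ratios n = N/M in
[0.25, 4].  These sizes keep the full experiment near two minutes of CPU
while leaving the two phases separated by many standard errors; a full-scale
protocol (200 realizations) is available via `--reps 200`.  The biased
initial condition is y₀ = +5 for every reaction (tanh 5 ≈ 0.9999); any
strongly polarized start serves the ergodicity probe.

Order parameters per phase point: ⟨H⟩/M on the time-averaged fluxes, the
unidirectional fraction φ, and the bidirectional count per species
n(1 − φ).  The critical ratio is estimated twice — the first grid crossing
of ⟨H⟩/M below ε_H = 10⁻² and the interpolated crossing of n(1 − φ) through
1 — with a grid-step error bar; the two estimators agree within one grid
step.  With the reference parameters almost no reaction freezes from the
unbiased start (the interior minimizer of H has |ν*| well below the bounds),
so the transition is located by the vanishing of H and the nbid crossing,
while φ is the ergodicity probe: biased starts freeze a macroscopic fraction
only in the balanced phase.

**Linear stability.**  Perturbations couple only to bidirectional reactions;
the relevant operator is the restricted Gram matrix
C = (1/M) Σ_μ ξ^μ_i ξ^μ_j / c̄_μ.  For i.i.d. entries of variance σ² (= p in
the ±1 ensemble) and aspect ratio r = N_bid/M, the smallest eigenvalue
converges to the Marchenko–Pastur-type edge σ²(1 − √r)², which vanishes at
r = 1: the marginal-stability point coincides with the transition.  The
positive diagonal factor 1 − ν*² from the tanh linearization cannot change
eigenvalue signs and is reported separately.  Finite-size λ_min at M = 400
sits a few percent above the edge; comparisons average a few draws to tame
single-sample (Tracy–Widom-scale) fluctuations.

## Direct minimization, loop removal, feasibility

`minimize_H` rewrites H(ν) = ‖Aν − b‖² with A = ξ/√c̄, b = −u/√c̄ and solves
the box-constrained least-squares problem ([−q_max, q_max] per coordinate;
a-priori irreversibility is expressed by zeroing one bound) with a
bounded-variable least-squares solver; convexity certifies global
optimality, reported via the projected-gradient KKT residual (tolerance
10⁻¹⁰, bound-activity tolerance 10⁻⁹ relative).  The minimizer set is
{ν in box : Aν = Aν*}; `solution_space` parametrizes the balanced case via
an SVD null-space basis (singular values below 10⁻¹⁰·σ_max treated as zero),
and `minimize_flux_norm` returns the unique minimum-‖ν‖₂ point — the
unconstrained minimum-norm solution when it lies inside the box (computed
directly), otherwise an SLSQP projection started from its clipped version.

Thermodynamic feasibility uses the Gordan alternative: either species
potentials g exist with (ξᵀg)_i strictly opposite in sign to every non-zero
flux (g found by LP, normalized |g|∞ ≤ 1 with strictness margin 10⁻⁶;
fluxes below 10⁻⁹ are treated as inactive), or there is a cycle k with
ξk = 0 whose signs match the flux on its support (found by the dual LP,
normalized Σ|k| = 1).  Exactly one certificate exists; subtracting a
sign-matching cycle lowers the flux norm while preserving Aν and the box,
which is why minimum-norm states are always feasible.

## Thermodynamics

ΔG_i = ΔG⁰_i + RT Σ_μ ξ^μ_i ln(c_μ/c₀); flux ratio ν⁺/ν⁻ = exp(−ΔG/RT);
reaction entropy production σ = −(1/T) Σ_i ν_i ΔG_i (non-negative whenever
each flux runs against its Gibbs gradient).  Defaults R = 8.314 J/mol/K,
T = 310 K, c₀ = 1 M, with a dimensionless mode (R = T = c₀ = 1) for
ensemble work.

For the decay relation, the full entropy production (exchange bookkeeping
included) is σ(t) = −(1/T) Σ_μ μ_μ(t) r_μ with μ_μ = RT ln(c_μ/c₀); with
concentrations evolved linearly, c_μ(t) = c̄_μ + r_μ t, its exact initial
slope is dσ/dt = −R·H.  We keep the constant as a named parameter κ in
dσ/dt = −κH/T with default κ = RT (the value implied by the unit prefactor
of H); `entropy_decay_check` evolves concentrations over a window in which
the relative drift stays below 2% (the slowly-varying-potential regime) and
reports the empirical ratio rather than asserting κ.  Standard potentials
are constant in time and drop out of the slope.  The perturbation free
energy of a flux impulse δν held for a time τ is (RTτ²/2)·H_closed(δν)
(H with u ≡ 0), non-negative by construction.

## Red blood cell case study

The fixture is a reconstruction of the standard reduced erythrocyte network
from textbook pathway stoichiometry — glycolysis (with aldolase and triose
phosphate isomerase lumped as FDP → 2 GAP), the 2,3-DPG shunt, the pentose
phosphate pathway (oxidative branch lumped into one G6PDH step, full
non-oxidative recycling), glucose/lactate/CO₂ transport, and the ATPase and
NADPHase pumps: 23 reactions among 30 metabolites, of which five are
extracellular pools (GLC, LAC, K⁺, Na⁺, CO₂; the ATPase row carries the
ionic exchange, −2 K⁺_ext and +3 Na⁺_ext per ATP, with the buffered
intracellular ion pools untracked).  Intracellular concentrations are
typical literature values; the extracellular defaults are GLC 5 mM, LAC
1 mM, K⁺ 4 mM, Na⁺ 140 mM, CO₂ 1.2 mM.  The tables ship as TSV with
recorded checksums.

Mass balance on the 25 intracellular species leaves a null space of
dimension exactly 3, parametrized by (u_GLC, u_DPGM, u_G6PDH); the basis is
normalized so these coordinates are reproduced exactly.  Exchange rates are
linear in the free fluxes with GLC rate = −u_GLC and the carbon identity
6·u_GLC = 3·(LAC rate) + (CO₂ rate); the maximal CO₂:GLC ratio over
admissible states (non-negative exports and pump fluxes; glycolytic
intermediates may run in reverse — no a-priori irreversibility) is the
carbon factor 6.

Minimizing the extracellular H_ext = Σ_s (rate_s)²/x_s over u_G6PDH at fixed
(u_GLC, u_DPGM) gives u* = a·u_GLC + b·u_DPGM with

    a = 6(wL + wP)/(9 wC + wL + wP),   b = −3 wP/(9 wC + wL + wP),
    wL = 1/x_LAC, wC = 1/x_CO2, wP = 4/x_K + 9/x_Na ,

derived by differentiating H_ext along the null-space parametrization; a and
b are invariant under a common rescaling of the five concentrations, a → 6
(all glucose through the PPP) in the CO₂-dominant limit, and the closed form
is guarded by an independent 1-D numeric minimization (bracketing search
plus a three-point parabolic polish, since H_ext is exactly quadratic).  The
PPP fraction is F = u_G6PDH/(6 u_GLC); over the admissible regime (shunt
flux from 0 up to the point where the ATPase flux at optimal routing
vanishes, since b < 0) F ranges between F_min = (a + 2b)/(2(3 + b)) and
F_max = a/6 — [0.118, 0.216] at the default blood concentrations.

## What the synthetic ensembles do and do not show

The random ensemble reproduces the structural features the theory rests on
(i.i.d. sparse stoichiometry, uniform concentrations and bounds, random
boundary driving) but none of the correlations of real metabolic networks:
conserved moieties, heavy-tailed metabolite degrees, stoichiometric
coefficients beyond ±1, heterogeneous time scales (the per-step update
deliberately ignores Arrhenius-type rate heterogeneity — steady states, not
transients, are the object of study).  Passing the ensemble suite therefore
validates the variational machinery and the phase-transition scenario, not
quantitative predictions for any particular organism; the red-cell module is
the (structured) real-network counterpart, and its validation is structural
and algebraic rather than kinetic.

## Numerical choices and limitations

* Seeds: all stochastic components take explicit seeds; ensemble runs spawn
  child seeds so realizations are independent but reproducible, and the
  unbiased/biased curves share network realizations so the ergodicity
  comparison is paired.
* Grid-search oracle: a flat 10⁻³ grid in N = 3 dimensions is out of reach;
  the oracle uses a coarse stage (2·10⁻² relative) whose nearest-grid-point
  bound λ_max·Σ(2·10⁻²·q_i)²/4 is the asserted slack, plus a 10⁻³ refinement
  around the coarse optimum.
* Degenerate inputs: all-zero flux vectors are vacuously feasible (flagged
  trivial); an empty bidirectional set yields r = 0 with an undefined
  λ_min; species with u = 0 and no reactions are retained but flagged by
  validation.
* The Langevin (continuum) limit of the dynamics and analytic
  (replica/generating-functional) phase diagrams are out of scope; the
  discrete dynamics and numerical ensembles stand in for them.
* Physical units are the user's responsibility outside the dimensionless
  mode; the package never converts units.
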