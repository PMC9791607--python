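# Methods

## Model

The totally asymmetric simple exclusion process lives on a 1-D lattice of L
sites with binary occupations τ_i ∈ {0,1}. A particle at site i hops to
site i+1 with unit rate iff the target is empty. Open boundaries inject at
site 1 with rate α (if empty) and remove from site L with rate β; they
represent reservoirs of density α and 1−β. Periodic boundaries wrap site L
to site 1 and conserve the particle number N; the control parameter is the
filling fraction n = N/L. Rates α, β ∈ [0,1] double as per-attempt
probabilities in the discrete-time Monte Carlo realisation below, which is
why the package rejects rates above 1 (a continuous-time event-driven
backend would lift the restriction but is out of scope).

The probability P(τ, t) of a configuration evolves under the master
equation (gain minus loss over all transitions); averaging gives the lattice
continuity equations dρ_i/dt = J_{i−1,i} − J_{i,i+1} with
J_{i,i+1} = ⟨τ_i(1−τ_{i+1})⟩, J_enter = α⟨1−τ_1⟩ and J_exit = β⟨τ_L⟩. These
expectations are exactly what the simulator, the exact oracle and both
mean-field closures estimate or compute.

## Monte Carlo engine (`simulate`, `_kernels`)

* **Random-sequential rule.** One elementary attempt draws a site uniformly;
  the allowed move at that site fires with its rate as probability (bulk
  hops with probability 1). L attempts form one sweep and advance time by
  one unit, so the expected number of hops across a bond per unit time is
  ⟨τ_i(1−τ_{i+1})⟩, making event counts per sweep a direct estimator of the
  current. This attempt-based scheme matches the standard discrete-time
  realisation of the continuous process; it is O(1) per attempt.
* **Parallel rule.** Every decision reads the configuration at time t:
  all bulk particles with empty right neighbours move; site 1 injects with
  probability α only if it was empty at t (even if its occupant departs in
  the same step); site L removes with probability β. One step = one time
  unit. This fully-parallel convention is the one whose stationary state the
  two-site cluster closure solves exactly.
* **Protocol.** The default run is `n_sweeps` total sweeps with the first 5%
  discarded as burn-in (both configurable; the headline measurements use
  10^5 sweeps). Open chains start empty; rings start from a uniformly
  random placement of N particles — which for the random-sequential ring is
  already the stationary (uniform) measure. Parallel chains may settle into
  deterministic cycles (e.g. α = β = 1); all observables are accumulated as
  long-run time averages, which equal the Cesàro averages over such cycles.
* **Errors.** Observables are sampled once per sweep; standard errors are
  batch means over 20 batches by default (60 in the oracle-equivalence
  tests). Batch means absorb the autocorrelation of the sweep series as
  long as batches are much longer than the correlation time; for the small
  lattices where we make quantitative 3-standard-error comparisons this
  holds comfortably.
* **Determinism.** The placement RNG and the compiled kernel's PRNG are both
  derived from the single `seed` argument; identical parameters and seed
  replay bit-identically.

## Exact oracle (`exact`)

All 2^L configurations are enumerated as bit patterns (bit i = site i+1).
For the random-sequential rule the sparse generator W[to, from] holds entry
(α), bulk (1) and exit (β) rates with the diagonal balancing outflow; the
stationary vector solves WP = 0 with ΣP = 1 (dense solve below 2048 states,
sparse LU above). For the parallel rule the one-step matrix M[from, to]
combines the deterministic bulk move with the independent entry/exit
Bernoulli events (at most four outcomes per configuration); the stationary
vector solves PM = P, which for an irreducible chain of any period equals
its long-run time average. Both builders first restrict to the recurrent
class reached from a reference configuration (empty lattice / left-packed
ring) via strongly-connected-component analysis, which handles absorbing
limits such as α = 1, β = 0 cleanly. Stationarity residuals are checked
against 1e−10 before observables are reported. The default size cap is
L = 12 (4096 states).

## One-site mean-field theory (`meanfield`)

Neglecting all correlations (⟨τ_iτ_j⟩ = ⟨τ_i⟩⟨τ_j⟩) and coarse-graining with
lattice constant ε = 1/L gives the viscous conservation law
∂ρ/∂t = ∂/∂x[(ε/2)∂ρ/∂x − ρ(1−ρ)]; in the ε → 0 limit the inviscid law with
flux J(ρ) = ρ(1−ρ). The Riemann problem with left state ρ₋ = α and right
state ρ₊ = 1−β (the reservoir densities), discontinuity at x₀ = 0.5
(the midpoint of the rescaled lattice; configurable):

* α < 1−β: characteristics cross; the weak solution is a shock at
  x₀ + st whose speed s = [J(ρ₊) − J(ρ₋)]/(ρ₊ − ρ₋) = β − α
  (Rankine–Hugoniot). The returned profile is the pre-dissipation
  two-density step; once the shock leaves [0,1] the formula automatically
  yields the constant asymptotic density.
* α > 1−β: a rarefaction fan ρ = ½(1 − (x−x₀)/t) between the edge
  characteristics x₀ + (1−2α)t and x₀ + (1−2(1−β))t, continuous for t > 0.
* α = 1−β: the step has zero amplitude; the profile is constant.

Following the waves to t → ∞ yields five regions — shock expelled right
(ρ → α) or left (ρ → 1−β), fan expelled right or left, fan expanding
forever (ρ → ½) — and reproduces the direct phase classification: LD
(ρ = α, α < min{β, ½}), HD (ρ = 1−β, β < min{α, ½}), MC (ρ = ½, J = ¼,
min{α, β} > ½). Labelling conventions on the measure-zero lines: α = β < ½
is the first-order *coexistence line* (`rho_bulk = None`, delocalised
shock); the second-order lines α = ½ ≤ β and β = ½ ≤ α carry continuous
density and are resolved to the adjoining maximal-current value ½ with an
`on_boundary` flag. The ring needs no classifier: ρ = n, J = n(1−n).

## Two-site cluster theory (`cluster`)

The parallel rule induces particle-hole attraction that the one-site closure
misses. Factorising configuration probabilities over overlapping pairs and
imposing the Kolmogorov consistency conditions closes the pair master
equation into P(10)² − P(10) + ρ(1−ρ) = 0. The physical root is the '−'
branch, P(10) = ½[1 − √(1−4ρ(1−ρ))] = min(ρ, 1−ρ); the '+' root exceeds
min(ρ, 1−ρ) and would make P(00) or P(11) negative, so it is rejected. The
current J = P(10) = min(ρ, 1−ρ) ≥ ρ(1−ρ), strictly inside (0,1). For the
open chain the stationary current follows from the extremal principle
applied to the effective boundary densities ρ(0) = α/(1+α) ≤ ρ(1) =
1/(1+β) (equality only at α = β = 1): J = min over [ρ(0), ρ(1)] of the
flux, i.e. J = min{α/(1+α), ½, β/(1+β)}. The resulting phase diagram has
LD (ρ = α/(1+α)) for α < min{β,1}, HD (ρ = 1/(1+β)) for β < min{α,1}, a
first-order line at α = β < 1, and a maximal-current *point* at α = β = 1
with ρ = ½, J = ½. `extremal_current` evaluates the extremum in closed form
for the two built-in unimodal fluxes and by a 10^4-point grid search for
user-supplied fluxes.

## FTCS solver (`pde`)

The viscous equation is integrated with the forward-time centred-space
scheme: interior nodes use diffusion coefficient ε/2 and advection velocity
2ρ−1 with central differences; the two boundary nodes use the discrete
reservoir equations ρ₁ += Δt[α(1−ρ₁) − ρ₁(1−ρ₂)] and
ρ_L += Δt[ρ_{L−1}(1−ρ_L) − βρ_L]. Grid: Δx = 1/L, ε = 1/L by default
(decoupled via the `eps` argument for refinement studies). The diffusive
stability criterion Δt/Δx² ≤ 1 is enforced before stepping; because it
ignores the advective CFL contribution the default step uses a safety
factor Δt = 0.5Δx² (`dt_factor`). Convergence is declared when
max_i |ρ_i^{j+1} − ρ_i^j| / Δt < tol (default 1e−8), a Δt-independent
residual; non-convergence within `max_steps` raises with the final
residual. Initial condition: uniform ρ = ½ (a Riemann step is available
for transient studies). Profiles are asserted to remain in [0,1] every
step.

In the LD/HD phases the boundary layers decay exponentially, so the
mid-lattice density agrees with the bulk value to below the convergence
tolerance at every tested L; the maximal-current phase has algebraic
boundary layers and is therefore the case where the O(1/L) grid-refinement
trend of the mid-lattice error is actually visible (verified on
L ∈ {25, 50, 100, 200}).

## Validation design and problem sizes

* The exact oracle is the ground truth for the simulator: on every lattice
  L ∈ {2,…,6} and (α,β) ∈ {0.2, 0.5, 0.8}² under both rules (90 runs of
  10^5 sweeps), per-site densities and all currents are compared as
  z-scores against batch-means standard errors. With ~800 comparisons a few
  |z| marginally above 3 are expected by chance even for a perfect sampler,
  so the suite requires max|z| < 5, a ≤2% exceedance fraction at 3, and
  mean z² < 1.5 — thresholds that a systematic bias of even half a standard
  error across the board would break.
* Ring profile flatness is checked per site against ±0.01. At half filling
  the kinematic-wave velocity 1−2n vanishes and density fluctuations relax
  slowly, so that case runs 3×10^6 sweeps where n = 0.25, 0.75 need only
  10^5; the tolerance is identical for all three.
* The parallel ring settles into the deterministic steady flow of the
  underlying cellular automaton, so its fundamental-diagram comparison
  carries a 10^-3 floor on top of the (near-zero) standard errors to absorb
  cycle-alignment remainders in finite windows.

## What the package does and does not show

All quantitative statements concern the idealised model: homogeneous unit
hop rates, uncorrelated Bernoulli boundary events, no attachment/detachment
kinetics, single species, single lane. Agreement of the simulator with the
exact oracle and of both mean-field closures with their respective update
rules says nothing about how well TASEP describes any particular transport
system; it establishes that the implementations are mutually consistent
realisations of the same stochastic process. Known limitations: rates above
1 are not representable in the discrete-time scheme; the exact oracle is
exponential in L; the FTCS solver covers open boundaries only and inherits
the slow algebraic relaxation of the maximal-current phase (its step budget
matters there); ordered-sequential and sublattice-parallel update rules are
not implemented.
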