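# Methods

This note documents the models implemented in `microdaisy`, their
assumptions, the parameter defaults and the numerical choices, in enough
detail to reproduce or modify any of the shipped experiments.

## 1. Model hierarchy

### 1.1 Growth response and perception

Every species responds to pH through the same inverted parabola

    β(pH) = 1 − ((pH_opt − pH)/Δ_H)²,

maximal (β = 1) at the optimum and zero at `pH_opt ± Δ_H`.  `Δ_H` is stored
as a *half-width* in pH units; this is the only convention under which the
denominator is a squared half-width for every configuration we ship
(regulators Δ_H = 9, parasite Δ_H = 2.5, community draws Δ_H ∈ [1, 4]).
β is deliberately *not* clamped at zero: values below zero mean net decay,
and non-negativity of populations is guaranteed by the multiplicative form
of the population equations, not by clamping the rate.

Each strain perceives the free pH shifted by its own excreted product cloud:

    pH_s = pH_f + ω γ_s/δ.

The shift is the equilibrium external product level `γ_s/δ` scaled by the
sensitivity ω, and points in the same direction as the strain's push on the
medium.  Sign convention throughout: `γ > 0` pushes pH up, `γ < 0` down;
chemical labels ("acid-/base-producing") are free-text and carry no
semantics.  This self-reinforcing perception is the stabilizing choice: the
strain that benefits from a shifted medium is the one whose growth pulls the
medium back.

### 1.2 Excretion chemistry and its quasi-steady state

The excreted compound follows linear kinetics: intracellular production at
rate γ, membrane exchange `k_in` (out of the cell) and `k_out` (back in),
washout of the external pool at the dilution rate δ:

    da_i/dt = γ − k_in a_i + k_out a_e
    da_e/dt = k_in a_i − k_out a_e − δ a_e.

Setting both derivatives to zero gives the unique equilibrium

    a_e* = γ/δ,        a_i* = γ (k_out + δ) / (δ k_in).

`a_e*` is the only quantity used downstream (it sets the per-capita pH push
and the perception shift).  Note the internal equilibrium involves *both*
exchange rates; the tests verify the closed forms against direct ODE
integration across a `k` × `δ` sweep to 0.1%.  These kinetics are assumed
fast relative to population dynamics, which justifies using `a_e* = γ/δ`
algebraically in all population-level models (and, in the two-strain model,
the free pH itself is taken as fast, giving the algebraic relation below).
No pH-from-concentration chemistry (e.g. Henderson–Hasselbalch) is modelled;
pH shifts are linear abstractions, and the chemistry is deterministic.

### 1.3 Two-strain consortium

    dX_s/dt = X_s [φ(X) β(pH_s) − δ],    φ(X) = 1 − X_up − X_down
    pH_f    = pH_in + X_up γ/δ − X_down γ/δ.

The free pH is algebraic (quasi-steady state), recomputed from abundances at
every evaluation — it is never integrated.  At an interior coexistence
equilibrium both strains sit at growth–dilution balance, which forces
`pH_f = pH_opt` exactly (shared niche), total abundance
`1 − δ/β(pH_opt + ωγ/δ) = 0.98948` at the reference parameters, and a
population split `X_up − X_down = (pH_opt − pH_in) δ/γ`.  These closed forms
are the oracles for the steady-state solver tests.

Reference parameters: γ = 0.04, δ = 0.01, ω = 0.5, pH_opt = 7, Δ_H = 9.

### 1.4 Parasite

A third species with advantage α perceives `pH_f` directly (no shift) and
excretes nothing, so `pH_f` is *exactly* independent of `X_c`:

    dX_c/dt = X_c [φ(X) β_c(pH_f) α − δ],   φ = 1 − X_a − X_b − X_c.

Defaults: parasite pH_opt = 7, Δ_H = 2.5, α = 1.  A quantitative consequence
worth knowing: a shared-optimum parasite invades the regulated state whenever
`α·β_c(pH_opt) > β_reg(pH_opt ± ωγ/δ) = 0.9506`, after which the surviving
regulator and the parasite coexist where `β_reg = α β_c`.  The regulated
*range* is unchanged (the parasite dies out near the range edges, where the
medium is far from its narrow niche), but the plateau value of `pH_f`
deviates from the optimum by up to ~0.4 (α = 1) or ~1.8 (α = 2) pH units on
the flanks — a "mild perturbation" of the plateau, not of the range.  At the
neutral input `pH_in = 7` the set point stays exactly 7 for every α.

### 1.5 Random multispecies communities

    dX_i/dt  = X_i [φ(X) β(pH_f + ω γ_i/δ) − δ] + ε
    dpH_f/dt = (Σ_i X_i γ_i ω/δ) · S(pH_f),    S(pH) = pH (2b − pH)/b².

There is no external input; the community is the only driver of `pH_f`,
which is now a state variable confined to `[0, 2b]` by the saturation factor
S.  Two conventions had to be fixed where the governing relations are
ambiguous:

* **Per-species perception.**  Each species' growth bracket uses its *own*
  shift `ω γ_i/δ`, consistent with the two-strain model; the alternative —
  a community-wide sum of all γ inside every bracket, with a sign that would
  make each strain perceive a shift opposite to its own push — breaks the
  perception semantics of §1.1 and destroys the stabilizing feedback, so it
  is not the default.
* **Saturation normalization.**  `S` is normalized by `b²` so that S(b) = 1
  and the biotic push has the same scale as in the two-species model at the
  range midpoint; any other positive normalization only rescales time for
  the pH variable.

Sampling (per strain): pH_opt ~ U[4, 9], Δ_H ~ U[1, 4], |γ| ~ U[0.05, 0.2]
with a fair-coin sign.  Community-level: δ = 0.1, ω = 1, ε = 10⁻³, b = 7.
Initial condition: `X_i(0) = 1/(2n)` each (total load ½, far from both the
empty and the saturated state) in a pH 7 medium.  The draw order (optima,
widths, magnitudes, signs) is fixed so that a seed fully determines a
community.

Immigration ε is a mean-field proxy for dispersal/evolutionary rescue; it
keeps every abundance strictly positive and sustains washed-out species at
the level ε/δ = 0.01.

### 1.6 Stochastic forcing

The input perturbation is a bounded uniform random walk: per-step increments
uniform on `± increment_bound · dt` (default 0.5 pH per unit time), with the
cumulative excursion from the start (pH 7) clipped to ±5 pH units.  Because
the community model has no input term, the walk couples *additively to
`pH_f`* after each deterministic step (then re-clipped to `[0, 2b]`), and
the cumulative walk is reported as `pH_in(t)` alongside the trajectory.
This is the minimal coupling consistent with displaying a wandering
cumulative input against a regulated medium; coupling through each species'
perception instead would be a different (and untested) assumption.
Buffering is quantified as `sd(pH_f)/sd(pH_in)` over the final half of the
run; a ratio below 1 means damping.  An abiotic control (no biota) gives a
ratio of exactly 1.

## 2. Numerics

* **Integrators.** Fixed-step explicit Euler for the 2–3 species models
  (default dt = 0.01) and classical RK4 for communities (default dt = 0.05,
  t_end = 5000 — roughly 500 dilution times at δ = 0.1, so the analysis
  window is far past transients).  Abundances are floored at 0 after every
  step; in the no-immigration models values below 10⁻¹² are snapped to 0 so
  extinction is absorbing rather than resurrecting from denormals.
* **Steady states.** Relaxation until `max |dX/dt| < 10⁻⁹` or `t = 10⁵`;
  non-convergence is reported in the output (`converged` flag), never
  raised.  Fixed points of the explicit-Euler map coincide exactly with the
  ODE equilibria, so converged steady states are dt-independent up to the
  residual tolerance; dt only needs to keep the map stable.  A scan is
  solved as one vectorized batch over all grid cells, with converged cells
  frozen and removed; the inner loop is numba-compiled when numba is
  importable, with an equivalent pure-numpy fallback (agreement is tested).
* **Scan protocol.** Every cell starts from the same fixed initial condition
  (X = 0.01 per regulator and per parasite) with no continuation between
  cells, so hysteresis cannot leak across a scan.  Default grids: pH_in ∈
  [0, 16] step 0.1; γ ∈ [0, 0.05] step 0.002; α ∈ [0, 2] step 0.05;
  parasite pH_opt ∈ [3, 11] step 0.2.
* **RK4 stage projection.** Stage arguments are projected onto the invariant
  region (X ≥ 0, pH ∈ [0, 2b]) before evaluating the right-hand side.  For
  interior trajectories this is a no-op; for stiff random communities it
  prevents intermediate stages from leaving the region and exploding through
  the logistic term.  Residual integration failures (non-finite states) are
  recorded per replica under a `failed` label and excluded from regime
  frequencies; at the shipped settings none occur.
* **Homeostatic range.** A grid point qualifies when total steady abundance
  exceeds `pop_floor = 0.05` and `|pH_f − pH_opt| ≤ pH_tolerance = 2.0`; the
  range is the maximal qualifying run containing the grid point nearest the
  optimum.  Both thresholds are configurable; with these defaults the
  reference slice (γ = 0.04) yields [1.1, 12.9], covering the effective
  range 3 ≤ pH_in ≤ 12.  Note the γ = 0 slice is *not* empty under this
  criterion: an unregulated medium trivially satisfies `|pH_f − 7| ≤ 2` for
  inputs within ±2 of the optimum, giving a width-4 interval — the
  regulation signal is the *widening* beyond that trivial band.

## 3. Classification and ensemble statistics

Classification uses the final 20% of a trajectory (by time).  A species
survives when its window-averaged abundance exceeds `2ε/δ = 0.02` — twice
the immigration-sustained level, so immigrants alone never count.  With no
survivors the run is a *collapse*; otherwise it is *oscillatory–chaotic*
when any survivor's relative amplitude `(max − min)/(max + min)` exceeds
0.01, else a *fixed point*.  Periodic, quasi-periodic and chaotic motion are
deliberately not distinguished, and no Lyapunov analysis is attempted.
The thresholds are configurable; absolute regime frequencies shift with
them, so cross-study comparisons should be trend-based (monotonicity in n),
not value-based.

The ensemble driver derives per-replica seed streams as
`SeedSequence(master_seed, spawn_key=(n, replica))`, making every replica
individually reproducible and independent.  All replicas of one size are
integrated as a single vectorized batch; only the analysis window is stored
(thinned 10×, i.e. every 0.5 time units), which the amplitude statistics
tolerate because regime amplitudes at these parameters vary on slower
scales.  The shipped scaled experiment (sizes {2, 5, 10, 20, 30}, N = 50
replicas) reproduces the diversity trend — fixed points become dominant as
n grows — assessed by one-sided Spearman rank correlation at α = 0.05; the
full-size configuration (n = 1..30, N = 200) is available through the same
driver and CLI.

Delay embedding reconstructs attractors as `(X(t), X(t+T), X(t+2T))`.  The
delay T defaults to one tenth of the analysis window, a deterministic and
cheap choice; a first-autocorrelation-minimum selector would adapt T per
series but makes outputs depend on estimator details, so it is left to the
caller.

## 4. What the synthetic experiments do and do not show

The random-community generator emulates the study conditions (uniform niche
and push-rate draws, shared dilution and immigration); it does not emulate
real microbial data — no measurement noise, no strain-specific death rates,
no resource or trophic structure, no spatial dispersal (immigration is the
mean-field proxy), and no evolution.  Passing tests therefore validate the
model's internal claims (regulation ranges, symmetry, trends, buffering),
not quantitative predictions for laboratory consortia.  The two-strain
"wet" design parameters (promoters, knockouts, fluorophores) are outside the
computational scope.

## 5. Known limitations

* Explicit fixed-step integration: very stiff random communities are handled
  by stage projection and honest failure accounting rather than implicit
  solvers.
* Steady-state identification is relaxation-based; there is no bifurcation
  continuation or eigenvalue stability analysis, so only attractors
  reachable from the documented initial condition are reported.
* The forcing couples to the medium only; perception-level noise is not
  implemented.
* Regime frequencies depend on the (configurable) classification thresholds;
  only their trends in n are threshold-robust.
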