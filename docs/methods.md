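# Methods

## Model and assumptions

The ecological substrate is a well-mixed, asexual host population with two
life stages. Juveniles mature at rate g, do not reproduce, and die at rate
b_J; adults reproduce at rate a subject to density-dependent competition
(1 − qN) and die at rate b_A. Transmission is density-dependent with
stage-specific transmission rates β_i = β₀(1 − r_i): resistance r_i is
innate and infection-preventing (it scales the rate of acquiring infection,
not its course). There is no recovery, no vertical transmission, and the
pathogen expresses exactly one kind of virulence at a time: sterility
virulence (infected fecundity reduced to a fraction f) or mortality
virulence (extra death rate α). The analyses enforce f = 1 whenever α > 0
and α = 0 whenever f < 1, although the data structures accept both for
exploration. Infection affects juveniles and adults identically, stages mix
randomly, and the pathogen is monomorphic and evolutionarily static.

Rescaling densities by q and time by b₀ shows that q = 1 and b₀ = 1 can be
fixed without loss of generality; the package keeps both as free parameters
and a property test confirms numerically that solutions for arbitrary
(q, b₀) are exact rescalings of the unit-parameter solutions.

### Trade-offs

Each stage's resistance degrades exactly one other life-history trait
through the cost fraction c₁(1 − e^{c₂ r})/(1 − e^{c₂}) (zero at r = 0,
c₁ at r = 1, convex for c₂ > 0; the c₂ → 0 limit c₁·r is handled
analytically). Juvenile resistance wires to maturation, reproduction or
juvenile mortality; adult resistance to reproduction or adult mortality.
Reproduction and maturation are multiplied by (1 − cost), mortality by
(1 + cost); when both stages wire to reproduction the two factors multiply.
Only accelerating costs (c₂ > 0) are analysed — decelerating costs
typically produce evolutionary repellers rather than the attractors studied
here. Defaults (a₀ = 5, g₀ = 1, b₀ = 1, q = 1, c₁ = 0.5, c₂ = 3) keep the
proportional impact of every trade-off identical so that wirings can be
compared all else being equal.

## Equilibria and R0

The disease-free equilibrium is closed-form. The stage ratio is
S_J*/S_A* = b_A/g and N* = (ag − b_A(b_J + g))/(qag), giving
S_A* = (ag − b_A(b_J + g))/(qa(b_A + g)). The factor (b_A + g) in the
denominator matters: symmetric-looking variants with (b_J + g) only balance
the ODEs when b_J = b_A, which fails whenever a mortality trade-off is
active; the closed form here is validated against long-time integration for
random asymmetric draws. The host is viable iff ag > b_A(b_J + g).

R0 is derived by the next-generation method on the two-dimensional infected
subsystem linearized at the disease-free equilibrium; because the new-
infection operator has rank one, the spectral radius is the explicit
expression quoted in the README. The closed form is cross-checked (to
1e-8 relative) against a next-generation matrix assembled purely
numerically by finite-differencing the ODE right-hand side.

The endemic equilibrium has no closed form. Rather than integrating the
stiff system to stationarity, the solver exploits the model's structure:
fixing the total infected density I = I_J + I_A makes every steady-state
condition linear, so all densities are proportional to S_J with an explicit
scalar for S_J from the birth-balance equation. The scalar mismatch
φ(I) = (I_J + I_A)(I) − I is scanned over a log-spaced grid in (0, 1/q]
(so roots arbitrarily close to the R0 = 1 threshold are caught), each sign
change is bracketed with Brent's method, and every root is polished by a
Newton solve of the full four-dimensional system (typical residuals
~1e-15). This finds *all* coexisting endemic states in one pass, which
doubles as the guard against undetected ecological bistability; stability
is classified by the eigenvalues of the analytic Jacobian. Long-time LSODA
integration from interior initial conditions remains available both as the
tie-breaker when several stable states coexist and as an independent oracle
in the tests. A state is reported extinct when N < 1e-8.

## Invasion analysis

A rare mutant differing in one stage's resistance experiences the resident's
environment frozen at its endemic equilibrium (total density N*, forces of
infection λ_i*). Its invasion fitness is lifetime reproductive success
minus one, assembled from stage-passage probabilities and expected
reproductive outputs; the expression is exactly neutral (w = 0 at machine
precision) when mutant equals resident, which the suite asserts over
hundreds of random draws — this neutrality is the main correctness anchor.
The fitness sign is additionally checked against the dominant eigenvalue of
the mutant's 4×4 linearized invasion dynamics, an oracle kept deliberately
independent of the fitness formula.

Selection gradients use central finite differences with step 1e-5
(one-sided at the trait boundaries); second derivatives and gradient-field
Jacobians use step 1e-4. Classifications are verified to be invariant to
halving these steps.

Co-singular strategies are located by three complementary searches:
bounded least-squares multistarts from a 5×5 interior lattice; a sign grid
whose mixed-sign cells are refined by nested scalar bisection (the juvenile
nullcline is traced through the cell by Brent's method and the adult
gradient driven to zero along it); and an edge/corner scan for boundary
singular strategies, where a trait is pinned at 0 or 1 by an outward
gradient while the other trait's gradient vanishes. The nested-bisection
stage exists because some attractors sit in transition layers only ~1e-3
wide at the pathogen-eradication boundary (the gradient collapses from
strongly positive to cost-only negative as I* → 0), where quasi-Newton
steps overshoot. Duplicate roots within 1e-5 keep the representative with
the smaller gradient residual.

**Stability.** Evolutionary stability per stage is the sign of
∂²w_i/∂(r_i^m)², flagged indeterminate below 1e-6. Convergence is assessed
two ways from the Jacobian J of the gradient field: the *attractor* flag
used for classification requires all eigenvalues of J to have negative real
part — the correct criterion under the model's assumption of equal,
uncorrelated mutational input in the two traits — while the *strong*
convergence flag (J + Jᵀ negative definite, guaranteeing convergence under
any symmetric mutational covariance) is computed and reported alongside.
The distinction is not academic: the high-resistance attractor of the
bistable regime has J eigenvalues (−1.7, −2852) but an indefinite symmetric
part, so the strong criterion alone would misclassify a genuine attractor
of the equal-mutation dynamics (and the simulations confirm it attracts).
Classification: CSS (attractor, both stages ES), branching-candidate
(attractor, not ES), repeller (all eigenvalues positive), saddle-like
(otherwise); boundary points are boundary-attractor/boundary-repeller by
the free-direction derivative and the pinned-direction gradient sign.

Phase planes evaluate the gradient field on a lattice, extract nullclines
as zero contours, and label basins by following the normalized gradient
flow (step 0.02) from each lattice point until capture within 0.03 of an
attractor, with visited cells inheriting the destination. Cells where the
disease cannot persist or the host is non-viable are labelled as such; in
the non-viable region the field falls back to the cost-descent direction so
that trajectories return to the viable region (no selection is defined
there).

## Trait-substitution simulation

The simulation discretizes each trait on a grid of step 0.02 (51 phenotypes
per trait, endpoints included) and couples all extant phenotypes through a
shared arena: one density-dependence term qN and one force of infection
summing infecteds across phenotypes. Each evolutionary event integrates
this coupled system for a 100-time-unit window (LSODA, rtol 1e-7), culls
phenotypes below total density 1e-5, then draws a parent with probability
proportional to its current birth output a(1 − qN)(S_A + f·I_A) — mutants
arise at reproduction with equal per-capita rates across stages — and
introduces a single-trait, one-step mutant (reflecting at the boundaries)
as susceptible juveniles at density 1e-4. The run is fully deterministic
given its seed. These event-loop constants are declared defaults exposed as
arguments, not claims of fidelity to any particular published code path;
the ecological window trades exactness of the timescale separation for
bounded runtime, and doubling it does not change the endpoints in the
regimes tested.

Default problem sizes were chosen for a desktop-class single core: 1500
events suffice for convergence from any corner of trait space in the
single-CSS regime (about 55 successful substitutions are needed for the
longest diagonal, and a favourable mutant needs several windows to sweep),
phase-plane lattices default to 21 points per axis (9–11 in the tests), and
sweep grids to 21 points per swept parameter with continuation seeding.

What the simulation adds over the invasion analysis: it drops the
rare-mutation and small-effect assumptions (several phenotypes routinely
co-segregate). What it does not emulate: demographic stochasticity
(densities are deterministic ODE solutions, so selection acts without
drift), standing genetic variation beyond the mutation kernel, and any
correlation between juvenile and adult mutations. Agreement between the
simulation endpoints and the predicted attractors therefore validates the
adaptive-dynamics machinery, not the model's realism for any particular
host-pathogen system.

## Numerical choices and degenerate inputs

- Equilibrium residual tolerance 1e-9 (achieved ~1e-15 after polishing);
  singular-point gradient tolerance 1e-7; deduplication 1e-5.
- R0 ≤ 1 short-circuits the endemic solver to the disease-free state;
  marginal host viability (ag = b_A(b_J + g)) reports extinction with zero
  densities. Full resistance at both stages with default cost strengths can
  sit exactly on this viability boundary, which is why several tests use
  weaker costs when probing the (1, 1) corner.
- The no-trade-off limit (c₁ = 0) makes resistance pure benefit, but
  fixation at (1, 1) is reachable only if the pathogen remains endemic over
  the whole trait lattice; at β₀ = 8 the pathogen is eradicated part-way
  (selection then vanishes), so the fixation check runs at β₀ = 1000.
- Near the onset of mortality virulence the two stages switch on resistance
  at different α, so the adult-above-juvenile ordering under
  juvenile~reproduction wirings is asserted beyond the adult onset (and in
  peak/mean aggregate); at the onset grid point itself the juvenile trait
  can transiently lead.
- Sweeps in continuation mode seed each point with the previous attractors
  (fast, can follow hysteresis); global mode re-runs the full multistart.
  Both are exposed, and they agree wherever the attractor is unique.

## Known limitations

Boundary singular strategies on an edge are classified from the
free-direction derivative only, without a full constrained second-order
analysis; branching candidates are flagged but branching itself is not
analysed further; pathogen coevolution, recovery, tolerance, stage-specific
virulence and assortative mixing are out of scope by design.
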