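# stageres

**Why are juveniles more resistant to infection than adults in some species,
and less resistant in others?** `stageres` is a simulation and analysis
library for the evolution of innate, infection-preventing resistance that
differs between host life stages. It implements an age-structured
susceptible–infected model in which juvenile resistance (r_J) and adult
resistance (r_A) coevolve, each trading off against another life-history
trait (maturation, reproduction or mortality), and analyses the joint
evolutionary dynamics with evolutionary invasion analysis (adaptive
dynamics), verified by stochastic trait-substitution simulation.

The headline scientific result the package reproduces: trade-offs between
**juvenile resistance and adult reproduction are intrinsically more costly**
than trade-offs with maturation or mortality, so hosts consistently evolve
lower juvenile than adult resistance under that wiring — even when infection
causes a lifelong loss of fecundity.

## The model

Hosts are juveniles or adults, susceptible or infected, with densities
S_J, S_A, I_J, I_A (N = S_J + S_A + I_J + I_A):

```
dS_J/dt = a(1 − qN)(S_A + f·I_A) − (b_J + g + λ_J) S_J
dS_A/dt = g S_J − (b_A + λ_A) S_A
dI_J/dt = λ_J S_J − (b_J + g + α) I_J
dI_A/dt = g I_J + λ_A S_A − (b_A + α) I_A
```

with forces of infection λ_i = β₀(1 − r_i)(I_J + I_A). The pathogen carries
either sterility virulence (fecundity of infected hosts reduced to a
fraction f) or mortality virulence (extra death rate α). Resistance r_i ∈
[0, 1] shields stage i from infection but degrades one wired trait through
the accelerating cost function c₁(1 − e^{c₂ r})/(1 − e^{c₂}).

The pathogen's basic reproductive ratio has the closed form

```
R0 = β₀ (ag − b_A(b_J+g)) [ (1−r_J)(b_A+α+g) b_A + (1−r_A) g (b_J+α+g) ]
     ─────────────────────────────────────────────────────────────────────
             q a g (b_A+g)(b_A+α)(b_J+g+α)
```

and the disease persists iff R0 > 1. A rare mutant in one resistance trait
has invasion fitness equal to its lifetime reproductive success in the
resident's endemic environment minus one; co-singular strategies are trait
pairs where both selection gradients vanish, classified by evolutionary
stability (second derivatives of fitness) and convergence stability
(eigenvalues of the Jacobian of the gradient field).

## Worked example

```python
from stageres import (Params, TradeoffWiring, ResistancePair,
                      basic_reproduction_number, endemic_equilibrium,
                      find_cosingular, simulate_evolution)

p = Params(beta0=8.0, f=0.1, alpha=0.0)     # strong sterility virulence
w = TradeoffWiring("juvenile_mortality", "reproduction")

basic_reproduction_number(p, w, ResistancePair(0.0, 0.0))
# 4.8  -> the pathogen invades a fully susceptible host population

css = [q for q in find_cosingular(p, w) if q.is_attractor][0]
(css.rJ, css.rA, css.classification)
# (0.6039, 0.4937, 'CSS')  -> a single continuously stable strategy

res = simulate_evolution(p, w, ResistancePair(0.0, 0.0), n_events=1500, seed=1)
(res.final.rJ, res.final.rA)
# (0.589, 0.493) -> the simulation, free of the small-mutation
#                   assumption, lands within one 0.02 grid step of the CSS
```

Juvenile resistance evolves *above* adult resistance here because the adult
trait pays its cost through reproduction. Swap the wiring so that the
juvenile trait costs reproduction (`TradeoffWiring("reproduction", ...)`)
and the ordering flips — run `python examples/05_virulence_sweeps.py` to
see both, and the other `examples/*.py` scripts for the epidemic threshold,
phase planes with bistability, and trait-distribution summaries.

A thin CLI mirrors the library:

```bash
stageres r0 --set beta0=8 --set alpha=0          # prints 4.8
stageres singular --set beta0=8 --set f=0.1 --out singular.csv
stageres sweep --param f --values 1:0:21 --set beta0=8 --out sweep.csv
stageres reproduce-figure 3 --out figures/       # both phase-plane CSVs
stageres simulate --set f=0.1 --set beta0=8 --seed 1 --out run.csv
```

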