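"""Ecology basics: R0, the disease-free equilibrium and the endemic state.

Builds the default host population (adult reproduction a0=5, maturation
g0=1, mortality b0=1, density dependence q=1), infects it with a pathogen of
baseline transmissibility beta0=8 and strong sterility virulence (f=0.1),
and prints the quantities that govern whether the disease spreads.
"""

from stageres import (
    Params,
    ResistancePair,
    TradeoffWiring,
    basic_reproduction_number,
    disease_free_equilibrium,
    endemic_equilibrium,
)

p = Params(beta0=8.0, f=0.1, alpha=0.0)
w = TradeoffWiring("juvenile_mortality", "reproduction")
r = ResistancePair(0.0, 0.0)  # fully susceptible hosts at both stages

dfe = disease_free_equilibrium(p, w, r)
print(f"disease-free equilibrium: S_J*={dfe.state.SJ:.4f}, S_A*={dfe.state.SA:.4f}")
print("  -> the stable stage structure of the healthy host population")

r0 = basic_reproduction_number(p, w, r)
print(f"basic reproductive ratio R0 = {r0:.4f}")
print("  -> each infected host causes ~4.8 new infections in the naive")
print("     population; R0 > 1, so the disease invades")

eq = endemic_equilibrium(p, w, r)
s = eq.state
print(
    f"endemic equilibrium: S_J={s.SJ:.4f} S_A={s.SA:.4f} "
    f"I_J={s.IJ:.4f} I_A={s.IA:.4f} (stable={eq.stable})"
)
print(f"  -> {s.infected / s.N:.1%} of hosts are infected at the endemic state")

beta_crit = 5.0 / 3.0  # R0(beta0) is linear, R0 = 1 at beta0 = 5/3 here
print(f"epidemic threshold: beta0 = {beta_crit:.4f} (R0 crosses 1)")
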