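"""Adaptive dynamics: selection gradients and the co-singular strategy.

With juvenile resistance costing extra juvenile mortality and adult
resistance costing reproduction, strong sterility virulence (f=0.1) selects
for intermediate resistance at both stages.  This script computes the
selection gradients at a fully susceptible resident and then locates and
classifies the joint evolutionary endpoint.
"""

from stageres import (
    Params,
    ResistancePair,
    TradeoffWiring,
    find_cosingular,
    resident_context,
    selection_gradients,
)

p = Params(beta0=8.0, f=0.1, alpha=0.0)
w = TradeoffWiring("juvenile_mortality", "reproduction")

ctx = resident_context(p, w, ResistancePair(0.0, 0.0))
gJ, gA = selection_gradients(ctx, p, w)
print(f"selection gradients at (0, 0): dwJ/drJ = {gJ:.4f}, dwA/drA = {gA:.4f}")
print("  -> both positive: resistance invades a fully susceptible population")

points = find_cosingular(p, w)
for q in points:
    print(
        f"singular strategy (rJ*, rA*) = ({q.rJ:.4f}, {q.rA:.4f}): "
        f"{q.classification} (ES: J={q.es_J}, A={q.es_A}; convergent={q.convergent})"
    )
print("  -> a single continuously stable strategy: gradual evolution settles")
print("     there from any starting traits, and no nearby mutant can invade;")
print("     juvenile resistance exceeds adult resistance because the adult")
print("     trait pays its cost through reproduction")
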