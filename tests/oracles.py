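"""Independent numerical oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: the mutant growth
rate is the dominant eigenvalue of the mutant's linearized invasion
subsystem written out from the model definition, not the lifetime-
reproduction fitness expression.
"""

from __future__ import annotations

import numpy as np

from stageres import Params, ResidentContext, TradeoffWiring
from stageres.tradeoffs import effective_rates


def mutant_growth_rate(
    p: Params, w: TradeoffWiring, ctx: ResidentContext, stage: str, value: float
) -> float:
    """Dominant eigenvalue (real part) of the linear dynamics of a rare
    mutant's four densities in the resident's equilibrium environment."""
    pair = ctx.resident.with_trait(stage, value)
    rm = effective_rates(p, w, pair)
    itot = ctx.equilibrium.state.infected
    N = ctx.equilibrium.state.N
    lamJ = p.beta0 * (1.0 - pair.rJ) * itot
    lamA = p.beta0 * (1.0 - pair.rA) * itot
    dens = rm.a * (1.0 - p.q * N)
    M = np.array(
        [
            [-(rm.bJ + rm.g + lamJ), dens, 0.0, p.f * dens],
            [rm.g, -(rm.bA + lamA), 0.0, 0.0],
            [lamJ, 0.0, -(rm.bJ + rm.g + p.alpha), 0.0],
            [0.0, lamA, rm.g, -(rm.bA + p.alpha)],
        ]
    )
    return float(np.max(np.real(np.linalg.eigvals(M))))
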