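"""Trade-off cost functions and realized (effective) life-history rates.

The cost of resistance level ``r`` with strength ``c1`` and curvature ``c2``
is ``c1 * (1 - exp(c2 * r)) / (1 - exp(c2))``: zero at r=0, c1 at r=1,
strictly increasing, and convex (accelerating) for c2 > 0.  The cost scales
the wired trait down for reproduction and maturation (factor ``1 - cost``)
and up for mortality (factor ``1 + cost``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import Params, ResistancePair, TradeoffWiring

__all__ = ["tradeoff_cost", "effective_rates", "EffectiveRates"]


def tradeoff_cost(r: float, c1: float, c2: float) -> float:
    """Fractional cost of resistance ``r``, in [0, c1].

    The curvature c2 controls deviation from linearity; c2 -> 0 is the
    linear limit ``c1 * r`` (removable singularity, handled analytically).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > 1):
        raise ValueError("resistance must lie in [0, 1]")
    if not 0.0 <= c1 <= 1.0:
        raise ValueError(f"trade-off strength c1 must lie in [0, 1], got {c1}")
    if abs(c2) < 1e-12:
        out = c1 * r
    else:
        out = c1 * np.expm1(c2 * r) / np.expm1(c2)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EffectiveRates:
    """Life-history and transmission rates realized at a given trait pair.

    ``a``: reproduction, ``g``: maturation, ``bJ``/``bA``: stage mortality,
    ``betaJ``/``betaA``: stage transmission rates ``beta0 * (1 - r_i)``.
    """

    a: float
    g: float
    bJ: float
    bA: float
    betaJ: float
    betaA: float


def effective_rates(p: Params, w: TradeoffWiring, r: ResistancePair) -> EffectiveRates:
    """Apply each stage's trade-off cost to exactly the wired trait.

    Unwired traits keep their baseline values.  When both stages trade off
    with reproduction, the two cost factors multiply.
    """
    costJ = tradeoff_cost(r.rJ, p.c1J, p.c2J)
    costA = tradeoff_cost(r.rA, p.c1A, p.c2A)

    a = p.a0
    g = p.g0
    bJ = p.b0
    bA = p.b0

    if w.juvenile_target == "maturation":
        g = p.g0 * (1.0 - costJ)
    elif w.juvenile_target == "reproduction":
        a = a * (1.0 - costJ)
    else:  # juvenile_mortality
        bJ = p.b0 * (1.0 + costJ)

    if w.adult_target == "reproduction":
        a = a * (1.0 - costA)
    else:  # adult_mortality
        bA = p.b0 * (1.0 + costA)

    return EffectiveRates(
        a=a,
        g=g,
        bJ=bJ,
        bA=bA,
        betaJ=p.beta0 * (1.0 - r.rJ),
        betaA=p.beta0 * (1.0 - r.rA),
    )
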